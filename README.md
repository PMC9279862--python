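# ffrbench

Estimation of fractional flow reserve (FFR) from bench-style stenosis
pressure–flow measurements, with a synthetic flow-loop generator and the
cohort statistics used to validate such estimates against invasive FFR.

FFR — the ratio P_d/P_a of mean trans-stenotic to aortic pressure at
maximal hyperemia, with ≤ 0.80 the conventional ischemia cutoff — can be
estimated without inducing hyperemia: characterize the stenosis by its
pressure-drop/flow relation

    ΔP(Q) = a·Q + b·Q²      (viscous + expansion-loss terms)

from steady-flow sweeps at constant aortic pressure, then intersect that
curve with a maximal-vasodilation line Q = m·(P_d − P_zf) describing a
normal microvascular bed (zero-flow pressure P_zf = 20 mmHg, resting flow
50 mL/min for a 3 mm vessel). The intersection is the inferred hyperemic
operating point, giving the FFR estimate and the distal microvascular
resistance R_d = (P_d − P_zf)/Q_h.

The package is written for hemodynamics researchers who want a tested,
fully scriptable version of this pipeline: a generator that emulates the
bench experiment (triplicate sweeps, sensor noise with a ≤1%
ratio-uncertainty budget, cohorts with known ground truth), sklearn-style
estimators for the curve fit and the FFR computation, and the
method-comparison suite (Spearman, Bland–Altman, ROC/AUC with DeLong CI,
Youden threshold, Clopper–Pearson intervals).

See `docs/methods.md` for the model, its assumptions, and what the
synthetic data do and do not emulate.

## Worked example

```python
import numpy as np
from ffrbench import (
    FFR3DEstimator, FluidProperties, NoiseModel, VesselGeometry,
    stenosis_coefficients, simulate_measurements, build_cfr_line,
    solve_hyperemia, PQCurveFit, SyntheticVessel,
)

# A 3 mm vessel with a 50% diameter stenosis over 10 mm
geometry = VesselGeometry(reference_diameter_mm=3.0,
                          percent_diameter_stenosis=50.0,
                          stenosis_length_mm=10.0)
coeffs = stenosis_coefficients(geometry, FluidProperties())
line = build_cfr_line()          # slope 2.5 mL/min/mmHg through (20 mmHg, 0)
truth = solve_hyperemia(
    PQCurveFit(a=coeffs.a, b=coeffs.b, covariance=np.zeros((2, 2)),
               rmse=0.0, n_points=0),
    p_a=90.0, line=line)
vessel = SyntheticVessel("demo", geometry, coeffs, 90.0, line, truth.ffr3d)

# Simulate the bench protocol and estimate FFR from the noisy records
data = simulate_measurements(vessel, noise=NoiseModel(seed=7))
est = FFR3DEstimator().fit(data)
print(f"a = {est.a_:.4f} mmHg·min/mL, b = {est.b_:.6f} mmHg·min²/mL²")
print(f"Q_h = {est.q_h_:.1f} mL/min, P_d = {est.p_d_h_:.1f} mmHg")
print(f"FFR = {est.ffr3d_:.3f} (truth {vessel.true_ffr:.3f}), "
      f"R_d = {est.r_d_:.3f} mmHg·min/mL")
```

Output:

```
a = 0.0482 mmHg·min/mL, b = 0.000170 mmHg·min²/mL²
Q_h = 148.0 mL/min, P_d = 79.2 mmHg
FFR = 0.879 (truth 0.882), R_d = 0.400 mmHg·min/mL
```

The fitted coefficients recover the ground truth (a = 0.0424,
b = 0.000195) to within sensor noise — note the FFR estimate (0.879 vs
truth 0.882) is far more accurate than either coefficient alone, because
the intersection depends on ΔP near the operating point where the two
coefficient errors cancel. At inferred hyperemia this lesion drops distal
pressure by ~12% of aortic: above the 0.80 cutoff, non-ischemic.
R_d = 0.400 is exactly the reciprocal of the maximal-vasodilation slope,
as it must be on the line.

## Command line

```
ffrbench simulate --n 28 --seed 7 --out runs/demo       # cohort + measurements
ffrbench fit     --measurements runs/demo/measurements.csv --out runs/fits.json
ffrbench ffr3d   --measurements runs/demo/measurements.csv --out runs/est
ffrbench cohort  --pairs runs/pairs.csv --out runs/report.json
```

Measurements travel as CSV (`vessel_id,replicate,Q_ml_min,Pa_mmHg,Pd_mmHg`),
reports as JSON; every artifact embeds the seed and config hash.

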