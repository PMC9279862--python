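# Methods

## The estimation problem

Fractional flow reserve (FFR) is the ratio of mean pressure distal to a
coronary stenosis to aortic pressure at maximal hyperemia; values ≤ 0.80
indicate hemodynamically significant disease. On a steady-flow bench rig a
stenosed vessel can be characterized without any pharmacological stimulus:
one measures the pressure drop ΔP across the stenosis at several prescribed
flow rates Q while holding the inlet (aortic) pressure P_a at the patient's
catheterization value, and then *infers* the hyperemic operating point from
the intersection of that ΔP–Q curve with a maximal-vasodilation line. This
package implements that estimation pipeline in silico, together with a
generator that emulates the bench experiment and the cohort statistics used
to compare the estimate against an invasive reference.

## Stenosis pressure-drop model

The rig is a two-resistance series circuit: the stenosis (flow-dependent
resistance R_p) feeding the microvascular bed (R_d), with outflow pressure
zero (reservoir open to atmosphere). The stenosis is modelled by the
classical two-term law

    ΔP(Q) = A·Q + B·Q²,

whose terms have first-principles forms used by the synthetic generator:

- **Viscous term** — excess Hagen–Poiseuille resistance of the stenotic
  segment over the same segment at reference calibre:
  `A_SI = (128 μ L / π)(d_s⁻⁴ − d₀⁻⁴)`, with μ the dynamic viscosity,
  L the stenosis length, d_s the minimal lumen diameter and d₀ the
  reference diameter. A = 0 for an unobstructed vessel.
- **Expansion loss** — Borda–Carnot loss at the abrupt area recovery from
  throat area A_s to reference area A₀:
  `B_SI = K_e (ρ/2)(A₀/A_s − 1)² / A₀²`, with K_e = 1 by default.

Fluid defaults are a blood-analog mixture: viscosity 4.5 cP, density
1.04 g/cm³. All generator constants are SI with exact conversions to the
catheter-lab unit convention (mmHg, mL/min, mm); 1 mmHg = 133.322387415 Pa.
The quadratic-through-origin family is fixed — ΔP must vanish at zero flow
in a rigid loop — and no intercept or cubic term is fitted.

## Bench-measurement emulation

For each vessel the generator emits triplicate sweeps over prescribed flow
setpoints (default 7 points, 20–220 mL/min, spanning rest to deep
hyperemia) at constant P_a, with independent zero-mean Gaussian
*relative* errors on each recorded channel (flow, P_a, P_d). Defaults are
0.5% per channel, so the propagated relative uncertainty of the pressure
ratio P_d/P_a is √2·0.5% ≈ 0.71% and of the flow ratio 0.5% — an
instrumentation budget within 1%. For severe stenoses the full sweep would
drive the distal pressure non-physically low; `adapt_flow_setpoints`
mimics the operator narrowing the range, keeping setpoints whose noise-free
P_d stays above a 10 mmHg floor (or substituting an evenly spaced 7-point
sweep up to that limit when fewer than three survive). Everything is
deterministic given the seed.

## Curve fitting

Replicate sweeps are averaged first (per the bench protocol), one point per
setpoint, pairing records by flow rank within each replicate; a replicate
record with P_d exceeding P_a by more than 1% of P_a is physically
impossible and is dropped with a logged reason (smaller excursions are
ordinary noise and kept). The averaged points are fitted by least squares
with non-negativity on both coefficients, enforced by active-set
enumeration — with two parameters the candidate sets {both free, b=0, a=0,
both zero} are fitted directly and the feasible minimum-SSR fit wins.

Weighting: points are weighted by the inverse variance of their means only
when each setpoint has at least five replicates. With triplicates the
per-point sample variance has two degrees of freedom and its reciprocal is
heavy-tailed (the mean of 1/χ²₂ diverges), and Monte-Carlo shows such
weights roughly double the median coefficient error relative to uniform
weighting — so few-replicate data are fitted unweighted.

Coefficient covariance comes from the weighted normal equations
((XᵀWX)⁻¹ when weights are inverse variances, residual-scaled otherwise),
with zero rows/columns for clamped coefficients.

### Attainable accuracy

At the default noise, the per-averaged-point ΔP standard deviation is
0.005·√(P_a² + P_d²)/√3 ≈ 0.3–0.37 mmHg. The Cramér–Rao bound of the
7-setpoint triplicate design then puts the *median* relative error of the
fitted coefficients at roughly 2% (â) and 5% (b̂) for a mid-severity vessel
— the linear and quadratic regressors are strongly collinear over a
physiological flow range. The fit is verified to operate within ~1.4× of
this bound. The FFR estimate is far more stable than the individual
coefficients (sd < 0.01 across seeds) because the intersection depends on
ΔP near the operating point, where the coefficient errors are
anticorrelated and largely cancel.

## Hyperemia and FFR

Maximal vasodilation is a linear coronary-flow-reserve line
Q = m·(P_d − P_zf): the flow a normal microvascular bed accepts at distal
perfusion pressure P_d, vanishing at the zero-flow pressure P_zf
(default 20 mmHg). The slope is parameterized through interpretable
anchors — resting flow q_rest (default 50 mL/min for a 3 mm vessel), a
normal-vessel flow reserve cfr_normal (default 3.5) reached at perfusion
pressure p_normal (default 90 mmHg) — giving
m = cfr_normal·q_rest/(p_normal − P_zf) = 2.5 mL/min/mmHg at defaults.
q_rest is held at 50 mL/min regardless of vessel calibre (resting flow is
preserved across stenosis severities); a diameter-scaling hook exists on
the line object but is off by default.

Substituting P_d = P_a − ΔP(Q) into the line yields

    m·b·Q² + (1 + m·a)·Q − m·(P_a − P_zf) = 0,

which has exactly one positive root whenever P_a > P_zf (the mismatch
function is strictly decreasing from a positive value). The root is
evaluated in the cancellation-free form Q_h = 2c/(β + √(β² + 4 m b c)) with
β = 1 + m·a and c = m·(P_a − P_zf), which reduces smoothly to the linear
solution c/β as b → 0. Then FFR = (P_a − ΔP(Q_h))/P_a and
R_d = (P_d − P_zf)/Q_h, which algebraically equals 1/m; the solver asserts
P_zf/P_a < FFR ≤ 1 on every solve. FFR is reported at the fitted curve's
intersection, with no interpolation back onto measured points. A bisection
solver exists in the test suite purely as an independent oracle.

## Synthetic cohorts

`generate_cohort` samples per-vessel: % diameter stenosis from a truncated
normal (mean 53.7, sd 17.1, bounds [0, 95] — an intermediate-lesion
population), reference diameter TruncNormal(3.0, 0.25, [2, 4]) mm, stenosis
length TruncNormal(20, 5, [5, 40]) mm, aortic pressure
TruncNormal(90, 10, [60, 130]) mmHg, and a per-vessel CFR-line slope
jittered multiplicatively (lognormal, sd 0.15) around the population line
to emulate patient-specific microvasculature. The vessel's ground-truth
FFR is computed by the same intersection solver with its *own* jittered
line; the estimation pipeline, run with the *population* line plus sensor
noise, therefore disagrees with the truth in the way a bench estimate
disagrees with an invasive measurement. These defaults were calibrated
once so that the implied prevalence of true FFR ≤ 0.80 sits near 54% in
large cohorts (measured 50–53% at n = 2000 across seeds), then frozen.

What the generator does **not** emulate: pulsatile flow, compliant walls,
non-Newtonian rheology, side branches and collateral flow, pressure-wire
drift, and any real discrepancy between a printed lumen and the patient's —
so the synthetic reference is much closer to the pipeline's estimate than
an invasive FFR would be. Concordance statistics on synthetic cohorts
(Spearman r ≈ 0.97–0.99, limits of agreement ≈ ±0.05) are therefore upper
bounds on real-data agreement, and passing tests demonstrate correctness
of the estimation machinery, not clinical performance.

## Cohort statistics

- Spearman rank correlation (average ranks for ties); p-value from the
  t-approximation, with exact permutation enumeration available for n ≤ 8.
- Paired t-test for the mean comparison (the conventional choice for
  paired continuous measurements).
- Bland–Altman: bias = mean(d), limits of agreement bias ± 1.96·sd(d)
  (sample sd), proportional bias as Spearman of d against pair means.
- ROC against reference FFR ≤ 0.80, predicted positive when the estimate
  ≤ threshold; AUC via the Mann–Whitney formulation (identical to the
  trapezoidal area, property-tested); AUC CI by DeLong's method (validated
  once against R pROC); Youden-optimal threshold with ties broken toward
  higher specificity, then toward the stricter (lower) threshold;
  sensitivity/specificity CIs by Clopper–Pearson.

## Problem sizes and tolerances

Default test problem sizes: 1,000-draw solver-oracle sweeps, 100-vessel
noise-free round trips (coefficients and FFR recovered to < 1e-6
relative), 200-seed noise studies, 2,000-vessel prevalence checks. The
solver-vs-bisection agreement tolerance is |ΔQ| < 1e-6 mL/min with the
intersection residual < 1e-9. Ratio-uncertainty propagation is first-order
(exact for these multiplicative models to within ~0.003% at 0.5% noise;
cross-checked by Monte-Carlo at 1e5 draws within 5%).

## Known limitations

- The quadratic ΔP–Q law is a modelling choice; real lesions with diffuse
  disease or serial components may deviate from the two-term form.
- The CFR-line slope construction uses invented (though physiologically
  conventional) anchors for cfr_normal and p_normal; only P_zf and q_rest
  have established default values.
- The coefficient split (a vs b) is ill-conditioned at bench noise levels
  (see "Attainable accuracy"); downstream FFR is robust to this, but the
  individual coefficients should not be over-interpreted at triplicate
  sample sizes.
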