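"""Synthetic bench-loop generator.

Emulates a steady-flow coronary circulation rig: a pump drives a blood-analog
fluid through a stenosed test section at prescribed flow setpoints while the
inlet (aortic) pressure is held at the patient's catheterization value; the
pressure drop across the stenosis and the distal pressure are recorded in
triplicate with small multiplicative sensor noise.

The stenosis pressure-drop law is the classical two-term model

    ΔP(Q) = A·Q + B·Q²

with A a Poiseuille viscous term over the stenotic segment (in excess of the
reference-calibre segment, so A = 0 for an unobstructed vessel) and B a
Borda–Carnot expansion loss downstream of the throat.  Both terms are derived
from first principles in SI units and converted to mmHg·min/mL conventions;
the constants are documented inline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datatypes import (
    FluidProperties,
    InvalidGeometryError,
    NoiseModel,
    PQCoefficients,
    PressureFlowDataset,
    SyntheticVessel,
    UnphysicalOperatingPointError,
    VesselGeometry,
)

__all__ = [
    "FluidProperties",
    "VesselGeometry",
    "PQCoefficients",
    "NoiseModel",
    "SyntheticVessel",
    "CohortParams",
    "DEFAULT_FLOW_SETPOINTS",
    "stenosis_coefficients",
    "pressure_drop",
    "adapt_flow_setpoints",
    "simulate_measurements",
    "generate_cohort",
]

# Unit conversions (exact definitions).
_CP_TO_PA_S = 1.0e-3          # 1 cP = 1e-3 Pa·s
_MM_TO_M = 1.0e-3
_G_CM3_TO_KG_M3 = 1.0e3
_ML_MIN_TO_M3_S = 1.0e-6 / 60.0
_PA_TO_MMHG = 1.0 / 133.322387415

#: Default prescribed flow setpoints, mL/min — 7 points spanning the
#: physiological coronary range from near-rest to deep hyperemia.
DEFAULT_FLOW_SETPOINTS = (20.0, 50.0, 80.0, 120.0, 160.0, 190.0, 220.0)


def stenosis_coefficients(
    geometry: VesselGeometry,
    fluid: FluidProperties = FluidProperties(),
    expansion_loss_coefficient: float = 1.0,
) -> PQCoefficients:
    """Viscous + expansion-loss coefficients of ΔP = A·Q + B·Q².

    A (mmHg·min/mL) is the Hagen–Poiseuille resistance of the stenotic
    segment *in excess of* the same segment at reference calibre:

        A_SI = (128 μ L / π) · (1/d_s⁴ − 1/d₀⁴)        [Pa·s/m³]

    B (mmHg·min²/mL²) is the Borda–Carnot sudden-expansion loss from the
    throat area A_s back to the reference area A₀:

        B_SI = K_e · (ρ/2) · (A₀/A_s − 1)² / A₀²       [Pa·s²/m⁶]

    with K_e the expansion-loss coefficient (1.0 for a sharp expansion).
    Both vanish when the % diameter stenosis is zero.
    """
    d0 = geometry.reference_diameter_mm * _MM_TO_M
    ds = geometry.minimal_lumen_diameter_mm * _MM_TO_M
    if ds <= 0:
        raise InvalidGeometryError("minimal lumen diameter must be > 0")
    length = geometry.stenosis_length_mm * _MM_TO_M
    mu = fluid.viscosity_cp * _CP_TO_PA_S
    rho = fluid.density_g_cm3 * _G_CM3_TO_KG_M3

    a_si = (128.0 * mu * length / math.pi) * (1.0 / ds**4 - 1.0 / d0**4)
    area0 = math.pi * d0**2 / 4.0
    area_s = math.pi * ds**2 / 4.0
    b_si = expansion_loss_coefficient * (rho / 2.0) * (area0 / area_s - 1.0) ** 2 / area0**2

    a = a_si * _PA_TO_MMHG * _ML_MIN_TO_M3_S
    b = b_si * _PA_TO_MMHG * _ML_MIN_TO_M3_S**2
    return PQCoefficients(a=a, b=b)


def pressure_drop(coeffs: PQCoefficients, q) -> np.ndarray | float:
    """Evaluate ΔP(Q) = A·Q + B·Q² in mmHg for flow ``q`` in mL/min (q >= 0)."""
    q_arr = np.asarray(q, dtype=float)
    if np.any(q_arr < 0):
        raise ValueError("flow must be non-negative")
    out = coeffs.a * q_arr + coeffs.b * q_arr**2
    return float(out) if np.isscalar(q) or q_arr.ndim == 0 else out


def adapt_flow_setpoints(
    vessel: SyntheticVessel,
    setpoints=DEFAULT_FLOW_SETPOINTS,
    min_distal_pressure: float = 10.0,
) -> np.ndarray:
    """Restrict the sweep to flows the vessel can sustain on the bench.

    Mimics the operator narrowing the prescribed flow range for severe
    stenoses: keeps the nominal setpoints whose noise-free distal pressure
    stays above ``min_distal_pressure`` mmHg; if fewer than three survive,
    substitutes an evenly spaced 7-point sweep up to the flow at which the
    distal pressure reaches that floor.
    """
    setpoints = np.asarray(setpoints, dtype=float)
    a, b = vessel.coefficients.a, vessel.coefficients.b
    head = vessel.aortic_pressure - min_distal_pressure
    if head <= 0:
        raise UnphysicalOperatingPointError(
            f"vessel {vessel.id!r}: aortic pressure {vessel.aortic_pressure:g} mmHg "
            f"leaves no headroom above the {min_distal_pressure:g} mmHg floor"
        )
    dp = a * setpoints + b * setpoints**2
    keep = setpoints[dp <= head]
    if keep.size >= 3:
        return keep
    if a == 0 and b == 0:
        return setpoints
    if b > 0:
        q_max = 2.0 * head / (a + math.sqrt(a * a + 4.0 * b * head))
    else:
        q_max = head / a
    return np.linspace(q_max / 7.0, q_max, 7)


def simulate_measurements(
    vessel: SyntheticVessel,
    flow_setpoints=DEFAULT_FLOW_SETPOINTS,
    noise: NoiseModel = NoiseModel(),
    n_replicates: int = 3,
    rng: np.random.Generator | None = None,
) -> PressureFlowDataset:
    """Simulate replicate (Q, P_a, P_d) records at prescribed flow setpoints.

    At each setpoint the noise-free state is Q, P_a (held constant across
    setpoints, as on a rig where the downstream valve absorbs the operating
    point change) and P_d = P_a − ΔP(Q).  Each recorded channel gets an
    independent zero-mean Gaussian relative error.  Deterministic given
    ``noise.seed`` (or an explicit ``rng``).
    """
    setpoints = np.asarray(flow_setpoints, dtype=float)
    if setpoints.size == 0:
        raise ValueError("flow_setpoints must be non-empty")
    if np.any(setpoints < 0) or np.any(np.diff(setpoints) < 0):
        raise ValueError("flow_setpoints must be non-negative and sorted ascending")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")

    p_a = vessel.aortic_pressure
    dp = vessel.coefficients.a * setpoints + vessel.coefficients.b * setpoints**2
    p_d = p_a - dp
    bad = np.nonzero(p_d <= 0)[0]
    if bad.size:
        raise UnphysicalOperatingPointError(
            f"vessel {vessel.id!r}: distal pressure would be <= 0 at "
            f"Q = {setpoints[bad[0]]:g} mL/min (ΔP = {dp[bad[0]]:.1f} mmHg)"
        )

    if rng is None:
        rng = np.random.default_rng(noise.seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        eps = rng.standard_normal((setpoints.size, 3))
        q_obs = setpoints * (1.0 + noise.flow_relative_sd * eps[:, 0])
        pa_obs = p_a * (1.0 + noise.pressure_relative_sd * eps[:, 1])
        pd_obs = p_d * (1.0 + noise.pressure_relative_sd * eps[:, 2])
        for k in range(setpoints.size):
            rows.append((vessel.id, rep, q_obs[k], pa_obs[k], pd_obs[k]))

    df = pd.DataFrame(rows, columns=["vessel_id", "replicate", "Q_ml_min", "Pa_mmHg", "Pd_mmHg"])
    meta = {
        "flow_setpoints_ml_min": [float(s) for s in setpoints],
        "n_replicates": int(n_replicates),
        "noise": {
            "flow_relative_sd": noise.flow_relative_sd,
            "pressure_relative_sd": noise.pressure_relative_sd,
            "seed": noise.seed,
        },
        "aortic_pressure_mmHg": {vessel.id: float(p_a)},
    }
    return PressureFlowDataset(df, meta)


@dataclass(frozen=True)
class CohortParams:
    """Distributional settings for a synthetic vessel cohort.

    Diameter stenosis is drawn from a truncated normal anchored to an
    intermediate-lesion population (mean 53.7%, sd 17.1%); geometry, aortic
    pressure and microvascular (CFR-line slope) jitter defaults were
    calibrated once so that the implied prevalence of true FFR <= 0.80
    matches a ~54% ischemic cohort, then frozen.
    """

    ds_mean: float = 53.7
    ds_sd: float = 17.1
    ds_bounds: tuple[float, float] = (0.0, 95.0)
    diameter_mean_mm: float = 3.0
    diameter_sd_mm: float = 0.25
    diameter_bounds_mm: tuple[float, float] = (2.0, 4.0)
    length_mean_mm: float = 20.0
    length_sd_mm: float = 5.0
    length_bounds_mm: tuple[float, float] = (5.0, 40.0)
    pa_mean: float = 90.0
    pa_sd: float = 10.0
    pa_bounds: tuple[float, float] = (60.0, 130.0)
    q_rest: float = 50.0
    cfr_normal: float = 3.5
    p_normal: float = 90.0
    p_zf: float = 20.0
    slope_jitter_sd: float = 0.15

    def __post_init__(self) -> None:
        for name in ("ds_sd", "diameter_sd_mm", "length_sd_mm", "pa_sd", "slope_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("ds_bounds", "diameter_bounds_mm", "length_bounds_mm", "pa_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must satisfy low < high")
        if self.p_normal <= self.p_zf:
            raise ValueError("p_normal must exceed p_zf")


def _trunc_normal(rng, mean, sd, bounds, size):
    """Truncated normal by rejection; exact for sd = 0 (returns the mean)."""
    lo, hi = bounds
    if sd == 0:
        if not (lo <= mean <= hi):
            raise ValueError("degenerate distribution mean outside bounds")
        return np.full(size, float(mean))
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(ok.size, size - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def generate_cohort(
    n_vessels: int,
    cohort_params: CohortParams = CohortParams(),
    seed: int = 0,
) -> list[SyntheticVessel]:
    """Sample ``n_vessels`` synthetic vessels with known ground-truth FFR.

    Each vessel gets its own CFR line (population slope jittered
    multiplicatively, lognormal with sd ``slope_jitter_sd``) standing in for
    patient-specific microvasculature; the ground-truth FFR is computed by
    the same curve–line intersection the pipeline uses, with the vessel's
    own true line.
    """
    from .hyperemia import build_cfr_line, solve_hyperemia
    from .pq_curve import PQCurveFit

    if n_vessels < 1:
        raise ValueError("n_vessels must be >= 1")
    p = cohort_params
    rng = np.random.default_rng(seed)

    ds = _trunc_normal(rng, p.ds_mean, p.ds_sd, p.ds_bounds, n_vessels)
    d0 = _trunc_normal(rng, p.diameter_mean_mm, p.diameter_sd_mm, p.diameter_bounds_mm, n_vessels)
    length = _trunc_normal(rng, p.length_mean_mm, p.length_sd_mm, p.length_bounds_mm, n_vessels)
    p_a = _trunc_normal(rng, p.pa_mean, p.pa_sd, p.pa_bounds, n_vessels)
    log_jitter = rng.normal(0.0, p.slope_jitter_sd, size=n_vessels) if p.slope_jitter_sd else np.zeros(n_vessels)

    base_line = build_cfr_line(
        q_rest=p.q_rest, cfr_normal=p.cfr_normal, p_normal=p.p_normal, p_zf=p.p_zf
    )
    vessels = []
    for i in range(n_vessels):
        geometry = VesselGeometry(
            reference_diameter_mm=float(d0[i]),
            percent_diameter_stenosis=float(ds[i]),
            stenosis_length_mm=float(length[i]),
        )
        coeffs = stenosis_coefficients(geometry)
        line = replace(base_line, slope=base_line.slope * math.exp(log_jitter[i]))
        fit = PQCurveFit(
            a=coeffs.a, b=coeffs.b, covariance=np.zeros((2, 2)), rmse=0.0, n_points=0
        )
        sol = solve_hyperemia(fit, p_a=float(p_a[i]), line=line)
        vessels.append(
            SyntheticVessel(
                id=f"V{i + 1:04d}",
                geometry=geometry,
                coefficients=coeffs,
                aortic_pressure=float(p_a[i]),
                true_cfr_line=line,
                true_ffr=sol.ffr3d,
            )
        )
    return vessels
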