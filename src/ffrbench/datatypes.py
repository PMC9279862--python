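"""Shared domain containers for the FFR bench-loop pipeline.

Every quantity carries the units of the catheterization-laboratory
convention: pressures in mmHg, flow in mL/min, lengths and diameters in mm,
so the stenosis coefficient ``a`` is mmHg·min/mL and ``b`` is mmHg·min²/mL².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FluidProperties",
    "VesselGeometry",
    "PQCoefficients",
    "NoiseModel",
    "CFRLine",
    "PQCurveFit",
    "RatioUncertainty",
    "HyperemiaSolution",
    "SyntheticVessel",
    "PressureFlowDataset",
    "MEASUREMENT_COLUMNS",
    "InvalidGeometryError",
    "UnphysicalOperatingPointError",
    "FitError",
    "DatasetStructureError",
]

#: CSV schema for raw bench measurements.
MEASUREMENT_COLUMNS = ["vessel_id", "replicate", "Q_ml_min", "Pa_mmHg", "Pd_mmHg"]


class InvalidGeometryError(ValueError):
    """Vessel geometry with no open lumen (or otherwise non-physical)."""


class UnphysicalOperatingPointError(ValueError):
    """An operating point whose noise-free distal pressure would be <= 0."""


class FitError(ValueError):
    """Curve fit cannot be performed (rank deficiency, non-finite input)."""


class DatasetStructureError(ValueError):
    """Measurement table violates the replicate/setpoint structure."""


@dataclass(frozen=True)
class FluidProperties:
    """Blood-analog fluid: dynamic viscosity in cP, density in g/cm³.

    Defaults match a 60:40 water–glycerol mixture commonly used as a
    Newtonian blood analog (4.5 cP, 1.04 g/cm³).
    """

    viscosity_cp: float = 4.5
    density_g_cm3: float = 1.04

    def __post_init__(self) -> None:
        if not (self.viscosity_cp > 0 and self.density_g_cm3 > 0):
            raise ValueError("fluid viscosity and density must be strictly positive")


@dataclass(frozen=True)
class VesselGeometry:
    """Idealized stenosed segment: reference diameter, % diameter stenosis, length."""

    reference_diameter_mm: float
    percent_diameter_stenosis: float
    stenosis_length_mm: float

    def __post_init__(self) -> None:
        if self.reference_diameter_mm <= 0:
            raise InvalidGeometryError("reference diameter must be > 0")
        if not (0.0 <= self.percent_diameter_stenosis < 100.0):
            raise InvalidGeometryError("percent diameter stenosis must lie in [0, 100)")
        if self.stenosis_length_mm < 0:
            raise InvalidGeometryError("stenosis length must be >= 0")
        if self.minimal_lumen_diameter_mm <= 0:
            raise InvalidGeometryError("minimal lumen diameter must be > 0")

    @property
    def minimal_lumen_diameter_mm(self) -> float:
        return self.reference_diameter_mm * (1.0 - self.percent_diameter_stenosis / 100.0)


@dataclass(frozen=True)
class PQCoefficients:
    """Coefficients of the stenosis pressure-drop law ΔP = A·Q + B·Q².

    ``a`` is the viscous (Poiseuille) term in mmHg·min/mL; ``b`` the
    expansion-loss term in mmHg·min²/mL².
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("pressure-drop coefficients must be non-negative")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian sensor noise: relative sd on flow and pressure.

    Defaults (0.5% each) keep the propagated relative uncertainty of the
    pressure ratio P_d/P_a at √2·0.5% ≈ 0.71% and of the flow ratio at
    0.5%, i.e. within the 1% bound quoted for bench instrumentation.
    """

    flow_relative_sd: float = 0.005
    pressure_relative_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flow_relative_sd < 0 or self.pressure_relative_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class CFRLine:
    """Maximal-vasodilation flow vs distal perfusion pressure: Q = m·(P_d − P_zf).

    ``p_zf`` is the zero-flow mean pressure (mmHg; flow ceases there),
    ``slope`` m is in mL/min per mmHg, ``q_rest`` the assumed resting flow
    (mL/min) for the reference vessel calibre.
    """

    slope: float
    p_zf: float = 20.0
    q_rest: float = 50.0
    reference_diameter_basis_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("CFR line slope must be > 0")
        if self.p_zf < 0:
            raise ValueError("zero-flow pressure must be >= 0")
        if self.q_rest <= 0:
            raise ValueError("resting flow must be > 0")

    def flow_at(self, p_d: float) -> float:
        """Maximal-vasodilation flow (mL/min) at distal pressure ``p_d``."""
        return self.slope * (p_d - self.p_zf)


@dataclass(frozen=True)
class PQCurveFit:
    """Fitted ΔP = a·Q + b·Q² with diagnostics.

    ``covariance`` is the 2×2 covariance of (a, b) from the weighted normal
    equations (entries for clamped coefficients are zero); stenosis
    resistance is R_p(Q) = a + b·Q.
    """

    a: float
    b: float
    covariance: np.ndarray
    rmse: float
    n_points: int

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise FitError("fitted coefficients must be non-negative")
        if self.rmse < 0:
            raise FitError("rmse must be >= 0")

    def pressure_drop(self, q):
        q = np.asarray(q, dtype=float)
        return self.a * q + self.b * q * q

    def resistance(self, q):
        """Flow-dependent stenosis resistance R_p(Q) = a + b·Q, mmHg·min/mL."""
        q = np.asarray(q, dtype=float)
        return self.a + self.b * q


@dataclass(frozen=True)
class RatioUncertainty:
    """Per-point relative sd of the pressure ratio P_d/P_a and flow ratio Q/Q_b."""

    pressure_ratio_rel_sd: np.ndarray
    flow_ratio_rel_sd: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.pressure_ratio_rel_sd, self.flow_ratio_rel_sd):
            a = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(a)) or np.any(a < 0):
                raise ValueError("ratio uncertainties must be finite and non-negative")


@dataclass(frozen=True)
class HyperemiaSolution:
    """Intersection of the ΔP–Q curve with the CFR line: the hyperemic state.

    ``ffr3d`` = P_d(hyperemia)/P_a; ``r_d`` = (P_d − P_zf)/Q_h is the distal
    microvascular resistance, algebraically equal to 1/slope of the line.
    """

    q_h: float
    p_d_h: float
    ffr3d: float
    r_d: float
    p_a: float

    def __post_init__(self) -> None:
        if self.q_h <= 0:
            raise ValueError("hyperemic flow must be > 0")
        if not (0 < self.ffr3d <= 1 + 1e-12):
            raise ValueError("FFR must lie in (0, 1]")
        if self.r_d <= 0:
            raise ValueError("distal resistance must be > 0")


@dataclass(frozen=True)
class SyntheticVessel:
    """A virtual bench vessel with known ground truth."""

    id: str
    geometry: VesselGeometry
    coefficients: PQCoefficients
    aortic_pressure: float
    true_cfr_line: CFRLine
    true_ffr: float

    def __post_init__(self) -> None:
        if self.aortic_pressure <= self.true_cfr_line.p_zf:
            raise ValueError("aortic pressure must exceed the zero-flow pressure")
        if not (0 < self.true_ffr <= 1):
            raise ValueError("true FFR must lie in (0, 1]")


@dataclass
class PressureFlowDataset:
    """Replicate (Q, P_a, P_d) records for one or more vessels.

    ``measurements`` is a DataFrame with columns ``vessel_id, replicate,
    Q_ml_min, Pa_mmHg, Pd_mmHg``; ``metadata`` carries fluid properties,
    nominal setpoints, seeds — anything needed to regenerate the table.
    """

    measurements: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in MEASUREMENT_COLUMNS if c not in self.measurements.columns]
        if missing:
            raise DatasetStructureError(f"missing measurement columns: {missing}")
        self.measurements = self.measurements[MEASUREMENT_COLUMNS].reset_index(drop=True)

    def vessel_ids(self) -> list[str]:
        return list(dict.fromkeys(self.measurements["vessel_id"]))

    def for_vessel(self, vessel_id: str) -> "PressureFlowDataset":
        sub = self.measurements[self.measurements["vessel_id"] == vessel_id]
        if sub.empty:
            raise KeyError(f"no measurements for vessel {vessel_id!r}")
        return PressureFlowDataset(sub.copy(), dict(self.metadata))

    def n_setpoints(self) -> int:
        per_rep = self.measurements.groupby(["vessel_id", "replicate"]).size()
        return int(per_rep.iloc[0]) if len(per_rep) else 0

    def validate_structure(self) -> None:
        """Check >= 3 setpoints per vessel and equal replicate counts."""
        for vid in self.vessel_ids():
            sub = self.measurements[self.measurements["vessel_id"] == vid]
            counts = sub.groupby("replicate").size()
            if counts.nunique() != 1:
                raise DatasetStructureError(
                    f"vessel {vid!r}: replicates have unequal numbers of setpoints"
                )
            if counts.iloc[0] < 3:
                raise DatasetStructureError(
                    f"vessel {vid!r}: at least 3 distinct flow setpoints required"
                )
        q = self.measurements["Q_ml_min"]
        if (q < 0).any():
            raise DatasetStructureError("negative flow values present")
        if (self.measurements["Pa_mmHg"] <= 0).any():
            raise DatasetStructureError("non-positive aortic pressures present")

    def __len__(self) -> int:
        return len(self.measurements)

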