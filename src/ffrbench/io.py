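"""File I/O and run configuration.

Measurements travel as plain CSV (``vessel_id,replicate,Q_ml_min,Pa_mmHg,
Pd_mmHg``), reports as JSON; configuration is YAML or JSON.  Every emitted
artifact embeds the seed and a hash of the effective configuration so any
reported number can be regenerated from the repository alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import MEASUREMENT_COLUMNS, NoiseModel, PressureFlowDataset
from .synthetic import DEFAULT_FLOW_SETPOINTS, CohortParams, FluidProperties

__all__ = [
    "RunConfig",
    "MeasurementParseError",
    "read_measurements",
    "write_measurements",
    "write_json",
    "config_hash",
]


class MeasurementParseError(ValueError):
    """Measurement CSV malformed; the message names the offending location."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with documented defaults.

    Fluid properties and the CFR-line anchors (P_zf = 20 mmHg, resting flow
    50 mL/min) follow the bench-loop conventions; flow setpoints and the
    cohort distributions are this package's documented choices.
    """

    fluid: FluidProperties = FluidProperties()
    noise: NoiseModel = NoiseModel()
    cohort: CohortParams = CohortParams()
    flow_setpoints: tuple[float, ...] = DEFAULT_FLOW_SETPOINTS
    n_replicates: int = 3
    p_zf: float = 20.0
    q_rest: float = 50.0
    cfr_normal: float = 3.5
    p_normal: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if any(q < 0 for q in self.flow_setpoints):
            raise ValueError("flow setpoints must be non-negative")
        if self.p_normal <= self.p_zf:
            raise ValueError("p_normal must exceed p_zf")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in {".yml", ".yaml"} else json.load(fh)
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "fluid" in kwargs:
            kwargs["fluid"] = FluidProperties(**kwargs["fluid"])
        if "noise" in kwargs:
            kwargs["noise"] = NoiseModel(**kwargs["noise"])
        if "cohort" in kwargs:
            kwargs["cohort"] = CohortParams(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in kwargs["cohort"].items()
            })
        if "flow_setpoints" in kwargs:
            kwargs["flow_setpoints"] = tuple(float(q) for q in kwargs["flow_setpoints"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["flow_setpoints"] = list(self.flow_setpoints)
        for key in ("ds_bounds", "diameter_bounds_mm", "length_bounds_mm", "pa_bounds"):
            d["cohort"][key] = list(d["cohort"][key])
        return d


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the effective configuration."""
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def read_measurements(path: str | Path) -> PressureFlowDataset:
    """Read a measurement CSV, validating schema and cell types.

    Malformed rows are reported with 1-based file line numbers (header is
    line 1).
    """
    path = Path(path)
    if not path.exists():
        raise MeasurementParseError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise MeasurementParseError(f"{path}: empty file") from None
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise MeasurementParseError(f"{path}: missing column(s) {', '.join(missing)}")
    if df.empty:
        raise MeasurementParseError(f"{path}: no data rows")

    numeric = {}
    for col in ("replicate", "Q_ml_min", "Pa_mmHg", "Pd_mmHg"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            line = int(bad[0]) + 2  # +1 header, +1 1-based
            raise MeasurementParseError(
                f"{path}: non-numeric value {df[col].iloc[bad[0]]!r} "
                f"in column {col} at line {line}"
            )
        numeric[col] = vals
    out = pd.DataFrame({
        "vessel_id": df["vessel_id"].astype(str),
        "replicate": numeric["replicate"].astype(int),
        "Q_ml_min": numeric["Q_ml_min"].astype(float),
        "Pa_mmHg": numeric["Pa_mmHg"].astype(float),
        "Pd_mmHg": numeric["Pd_mmHg"].astype(float),
    })
    return PressureFlowDataset(out, {"source": str(path)})


def write_measurements(dataset: PressureFlowDataset, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    dataset.measurements.to_csv(path, index=False, float_format="%.10g")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")
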