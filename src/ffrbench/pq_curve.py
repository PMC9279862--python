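"""Averaging and fitting of stenosis pressure-drop vs flow curves.

Raw bench data arrive as replicate sweeps over the same flow setpoints.
Replicates are averaged first (matching the bench protocol of averaging the
three sweeps into one ΔP–Q curve), then a quadratic-through-origin
ΔP = a·Q + b·Q² is fitted by weighted least squares with non-negativity on
both coefficients.  First-order propagation of the sensor noise into the
pressure-ratio (P_d/P_a) and flow-ratio (Q/Q_b) uncertainties is provided to
verify the instrumentation budget (relative uncertainty ≲ 1%).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import (
    CFRLine,
    DatasetStructureError,
    FitError,
    NoiseModel,
    PQCurveFit,
    PressureFlowDataset,
    RatioUncertainty,
)

__all__ = [
    "PQCurveFit",
    "RatioUncertainty",
    "PQCurveRegressor",
    "average_replicates",
    "fit_pq_curve",
    "propagate_uncertainty",
]

logger = logging.getLogger(__name__)

#: A replicate with P_d exceeding P_a by more than this fraction of P_a is
#: rejected as physically impossible beyond noise; smaller excursions are
#: kept with a logged warning.
PD_OVER_PA_TOLERANCE = 0.01


def average_replicates(dataset: PressureFlowDataset) -> pd.DataFrame:
    """Average replicate sweeps into one (q̄, ΔP̄) point per setpoint.

    Setpoints are identified by flow rank within each replicate (the bench
    prescribes the same ascending setpoints every sweep, so the k-th
    smallest flow of each replicate is the same nominal setpoint).  Returns
    a DataFrame with columns ``q_mean, pa_mean, pd_mean, dp_mean, dp_sd,
    q_sd, n_replicates`` ordered by setpoint; ΔP̄ = mean(P_a) − mean(P_d)
    and the sd is the sample sd (ddof=1) of the per-replicate ΔP.
    """
    dataset.validate_structure()
    df = dataset.measurements.copy()
    if df["vessel_id"].nunique() != 1:
        raise DatasetStructureError(
            "average_replicates operates on a single vessel; use for_vessel() first"
        )

    # Group records into setpoints by flow rank within each replicate while
    # the table is still balanced, then reject physically impossible records
    # (the group identity survives the rejection).
    df = df.sort_values(["replicate", "Q_ml_min"], kind="mergesort")
    df["setpoint"] = df.groupby("replicate").cumcount()

    over = df["Pd_mmHg"] > df["Pa_mmHg"]
    if over.any():
        excess = (df.loc[over, "Pd_mmHg"] - df.loc[over, "Pa_mmHg"]) / df.loc[over, "Pa_mmHg"]
        fatal = excess > PD_OVER_PA_TOLERANCE
        if fatal.any():
            n = int(fatal.sum())
            logger.warning("rejecting %d record(s) with Pd > Pa beyond tolerance", n)
            df = df.drop(excess.index[fatal])
        kept = int((~fatal).sum())
        if kept:
            logger.info("%d record(s) have Pd marginally above Pa (noise); kept", kept)
    if df.groupby("setpoint").size().min() < 1:
        raise DatasetStructureError("a setpoint lost all replicates to rejection")

    df["dp"] = df["Pa_mmHg"] - df["Pd_mmHg"]
    g = df.groupby("setpoint")
    out = pd.DataFrame(
        {
            "q_mean": g["Q_ml_min"].mean(),
            "pa_mean": g["Pa_mmHg"].mean(),
            "pd_mean": g["Pd_mmHg"].mean(),
            "dp_sd": g["dp"].std(ddof=1).fillna(0.0),
            "q_sd": g["Q_ml_min"].std(ddof=1).fillna(0.0),
            "n_replicates": g["dp"].count(),
        }
    )
    out["dp_mean"] = out["pa_mean"] - out["pd_mean"]
    if len(out) < 3:
        raise DatasetStructureError("need >= 3 distinct flow setpoints to characterize the curve")
    return out.reset_index(drop=True)[
        ["q_mean", "pa_mean", "pd_mean", "dp_mean", "dp_sd", "q_sd", "n_replicates"]
    ]


class PQCurveRegressor(RegressorMixin, BaseEstimator):
    """Weighted least-squares fit of ΔP = a·Q + b·Q² through the origin.

    Non-negativity of both coefficients is enforced by active-set
    enumeration: with two parameters the candidate sets {both free, b = 0,
    a = 0, both 0} are fitted directly and the feasible fit with the lowest
    weighted residual sum of squares wins.  Weights are 1/sd² when
    per-point sds are supplied (and all positive), uniform otherwise.

    Attributes
    ----------
    a_, b_ : float
        Fitted coefficients (mmHg·min/mL and mmHg·min²/mL²).
    covariance_ : ndarray of shape (2, 2)
        Covariance of (a, b) from the weighted normal equations; rows and
        columns of clamped coefficients are zero.
    rmse_ : float
        Unweighted root-mean-square residual, mmHg.
    n_points_ : int
        Number of averaged points used.
    """

    def fit(self, X, y, sd=None):
        q = np.asarray(X, dtype=float).reshape(-1)
        dp = np.asarray(y, dtype=float).reshape(-1)
        if q.shape != dp.shape:
            raise ValueError("q and dp must have the same length")
        if q.size < 3 or np.unique(q).size < 3:
            raise FitError("need >= 3 distinct flow values to fit the quadratic")
        if not (np.all(np.isfinite(q)) and np.all(np.isfinite(dp))):
            raise FitError("non-finite values in fit input")

        if sd is not None:
            sd = np.asarray(sd, dtype=float).reshape(-1)
            if sd.shape != q.shape:
                raise ValueError("sd must match the number of points")
            w = 1.0 / sd**2 if np.all(sd > 0) else np.ones_like(q)
        else:
            w = np.ones_like(q)

        design = np.column_stack([q, q * q])
        best = None
        for free in ((0, 1), (0,), (1,), ()):
            coef = np.zeros(2)
            if free:
                cols = design[:, list(free)]
                xtw = cols.T * w
                gram = xtw @ cols
                if np.linalg.matrix_rank(gram) < len(free):
                    continue
                sol = np.linalg.solve(gram, xtw @ dp)
                coef[list(free)] = sol
            if np.any(coef < 0):
                continue
            resid = dp - design @ coef
            ssr = float(np.sum(w * resid**2))
            if best is None or ssr < best[0] - 1e-12:
                best = (ssr, coef, free)
        if best is None:
            raise FitError("rank-deficient design: flow values do not span a quadratic")

        _, coef, free = best
        self.a_, self.b_ = float(coef[0]), float(coef[1])
        resid = dp - design @ coef
        self.rmse_ = float(np.sqrt(np.mean(resid**2)))
        self.n_points_ = int(q.size)

        cov = np.zeros((2, 2))
        if free:
            cols = design[:, list(free)]
            xtw = cols.T * w
            gram_inv = np.linalg.inv(xtw @ cols)
            if sd is not None and np.all(sd > 0):
                sub = gram_inv  # weights are inverse variances: cov = (XᵀWX)⁻¹
            else:
                dof = max(q.size - len(free), 1)
                sub = gram_inv * float(np.sum(resid**2)) / dof
            for i, fi in enumerate(free):
                for j, fj in enumerate(free):
                    cov[fi, fj] = sub[i, j]
        self.covariance_ = cov
        return self

    def predict(self, X):
        check_is_fitted(self, "a_")
        q = np.asarray(X, dtype=float)
        return self.a_ * q + self.b_ * q * q

    def to_fit(self) -> PQCurveFit:
        check_is_fitted(self, "a_")
        return PQCurveFit(
            a=self.a_, b=self.b_, covariance=self.covariance_,
            rmse=self.rmse_, n_points=self.n_points_,
        )


def fit_pq_curve(points: pd.DataFrame) -> PQCurveFit:
    """Fit the averaged (q, ΔP) points from :func:`average_replicates`.

    The weight of each averaged point uses the standard error of its mean,
    dp_sd/√n_replicates, not the raw replicate scatter — but only when at
    least 5 replicates back each variance estimate.  With triplicates the
    reciprocal of a 2-df sample variance is heavy-tailed (no finite mean),
    and weighting by it is measurably less efficient than uniform weights,
    so few-replicate data are fitted unweighted.
    """
    reg = PQCurveRegressor()
    if (points["n_replicates"] >= 5).all() and (points["dp_sd"] > 0).all():
        sd_mean = points["dp_sd"] / np.sqrt(points["n_replicates"])
        reg.fit(points["q_mean"], points["dp_mean"], sd=sd_mean)
    else:
        reg.fit(points["q_mean"], points["dp_mean"])
    return reg.to_fit()


def propagate_uncertainty(
    points: pd.DataFrame, noise: NoiseModel, cfr_line: CFRLine
) -> RatioUncertainty:
    """First-order propagation of sensor noise into ratio uncertainties.

    For independent multiplicative errors the relative sd of P_d/P_a is
    √(σ_Pd² + σ_Pa²) and of Q/Q_b (with the resting flow Q_b a fixed model
    constant) is σ_Q; both are per measurement point.
    """
    if cfr_line.q_rest <= 0:
        raise ValueError("resting flow must be > 0")
    pa = np.asarray(points["pa_mean"], dtype=float)
    pd_ = np.asarray(points["pd_mean"], dtype=float)
    if np.any(pa <= 0) or np.any(pd_ <= 0):
        raise ValueError("pressures must be > 0 for ratio uncertainty propagation")
    n = len(points)
    pr = np.full(n, float(np.hypot(noise.pressure_relative_sd, noise.pressure_relative_sd)))
    fr = np.full(n, float(noise.flow_relative_sd))
    return RatioUncertainty(pressure_ratio_rel_sd=pr, flow_ratio_rel_sd=fr)
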