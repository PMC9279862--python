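"""Hyperemic-flow determination and FFR from the curve–line intersection.

Maximal vasodilation is represented by a linear coronary-flow-reserve line
Q = m·(P_d − P_zf): flow the microvasculature would accept at distal
perfusion pressure P_d, vanishing at the zero-flow pressure P_zf.  The
stenosis imposes P_d = P_a − ΔP(Q) with ΔP = a·Q + b·Q².  Their unique
intersection is the hyperemic operating point, giving

    FFR = P_d(hyperemia) / P_a,      R_d = (P_d − P_zf) / Q_h.

Substituting the curve into the line yields the quadratic

    m·b·Q² + (1 + m·a)·Q − m·(P_a − P_zf) = 0,

whose positive root is computed in the cancellation-free form
Q = 2c / (β + √(β² + 4·m·b·c)) with β = 1 + m·a, c = m·(P_a − P_zf); this
reduces smoothly to the linear solution c/β as b → 0.
"""

from __future__ import annotations

import logging
import math

from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .datatypes import CFRLine, FitError, HyperemiaSolution, PQCurveFit, PressureFlowDataset

__all__ = [
    "CFRLine",
    "HyperemiaSolution",
    "build_cfr_line",
    "solve_hyperemia",
    "compute_rd",
    "ffr3d_pipeline",
    "FFR3DEstimator",
    "NoPerfusionPressureError",
]

logger = logging.getLogger(__name__)


class NoPerfusionPressureError(ValueError):
    """Aortic pressure does not exceed the zero-flow pressure."""


def build_cfr_line(
    q_rest: float = 50.0,
    cfr_normal: float = 3.5,
    p_normal: float = 90.0,
    p_zf: float = 20.0,
) -> CFRLine:
    """Construct the maximal-vasodilation line from interpretable anchors.

    The line passes through (P_zf, 0) and through the hyperemic state of a
    normal vessel: flow cfr_normal·q_rest at distal pressure p_normal, so
    m = cfr_normal·q_rest / (p_normal − p_zf).  Defaults: resting flow
    50 mL/min for a 3 mm vessel, zero-flow pressure 20 mmHg, and a normal
    coronary flow reserve of 3.5 at 90 mmHg perfusion pressure.
    """
    if p_normal <= p_zf:
        raise ValueError("p_normal must exceed p_zf")
    if cfr_normal < 1:
        raise ValueError("cfr_normal must be >= 1")
    if q_rest <= 0:
        raise ValueError("q_rest must be > 0")
    slope = cfr_normal * q_rest / (p_normal - p_zf)
    return CFRLine(slope=slope, p_zf=p_zf, q_rest=q_rest)


def solve_hyperemia(fit: PQCurveFit, p_a: float, line: CFRLine) -> HyperemiaSolution:
    """Intersect the fitted ΔP–Q curve with the CFR line.

    Returns the unique positive-flow intersection (it exists and is unique
    because g(Q) = m·(P_a − P_zf − ΔP(Q)) − Q is strictly decreasing with
    g(0) > 0 whenever P_a > P_zf).
    """
    if not (math.isfinite(fit.a) and math.isfinite(fit.b)):
        raise FitError("non-finite curve coefficients")
    if p_a <= line.p_zf:
        raise NoPerfusionPressureError(
            f"aortic pressure {p_a:g} mmHg does not exceed P_zf = {line.p_zf:g} mmHg"
        )
    m = line.slope
    alpha = m * fit.b
    beta = 1.0 + m * fit.a
    c = m * (p_a - line.p_zf)
    # 2c/(β+√(β²+4αc)) avoids subtractive cancellation for small α·c/β².
    q_h = 2.0 * c / (beta + math.sqrt(beta * beta + 4.0 * alpha * c))
    dp = fit.a * q_h + fit.b * q_h * q_h
    p_d_h = p_a - dp
    ffr = p_d_h / p_a
    r_d = compute_rd(p_d_h, line.p_zf, q_h)
    return HyperemiaSolution(q_h=q_h, p_d_h=p_d_h, ffr3d=ffr, r_d=r_d, p_a=p_a)


def compute_rd(p_d_h: float, p_zf: float, q_h: float) -> float:
    """Distal microvascular resistance R_d = (P_d − P_zf)/Q_h, mmHg·min/mL."""
    if q_h <= 0:
        raise ValueError("hyperemic flow must be > 0")
    if p_d_h <= p_zf:
        raise ValueError("distal pressure must exceed the zero-flow pressure")
    return (p_d_h - p_zf) / q_h


class FFR3DEstimator(BaseEstimator):
    """End-to-end FFR estimator for one vessel's pressure–flow table.

    ``fit`` averages the replicate sweeps, fits the quadratic ΔP–Q curve,
    and intersects it with the CFR line built from the constructor
    parameters.  The aortic pressure used for the intersection is the mean
    measured P_a unless ``p_a`` is passed explicitly.

    Parameters
    ----------
    p_zf : float, default 20.0
        Zero-flow mean pressure of the CFR line, mmHg.
    q_rest : float, default 50.0
        Resting flow, mL/min (held constant regardless of vessel calibre).
    cfr_normal : float, default 3.5
        Flow reserve of a normal vessel, anchoring the line slope.
    p_normal : float, default 90.0
        Distal pressure at which a normal vessel reaches cfr_normal, mmHg.

    Attributes
    ----------
    a_, b_ : fitted curve coefficients
    q_h_, p_d_h_, ffr3d_, r_d_ : hyperemic solution
    cfr_line_ : CFRLine used for the intersection
    curve_fit_ : PQCurveFit with covariance and rmse
    """

    def __init__(self, p_zf: float = 20.0, q_rest: float = 50.0,
                 cfr_normal: float = 3.5, p_normal: float = 90.0):
        self.p_zf = p_zf
        self.q_rest = q_rest
        self.cfr_normal = cfr_normal
        self.p_normal = p_normal

    def fit(self, X: PressureFlowDataset, y=None, p_a: float | None = None,
            cfr_line: CFRLine | None = None):
        from .pq_curve import average_replicates, fit_pq_curve

        points = average_replicates(X)
        fit = fit_pq_curve(points)
        line = cfr_line if cfr_line is not None else build_cfr_line(
            q_rest=self.q_rest, cfr_normal=self.cfr_normal,
            p_normal=self.p_normal, p_zf=self.p_zf,
        )
        if p_a is None:
            p_a = float(points["pa_mean"].mean())
        sol = solve_hyperemia(fit, p_a=p_a, line=line)
        logger.info(
            "vessel fit: a=%.5g b=%.5g rmse=%.3g -> Qh=%.4g mL/min, FFR=%.4f",
            fit.a, fit.b, fit.rmse, sol.q_h, sol.ffr3d,
        )
        self.curve_fit_ = fit
        self.a_, self.b_ = fit.a, fit.b
        self.cfr_line_ = line
        self.solution_ = sol
        self.q_h_, self.p_d_h_ = sol.q_h, sol.p_d_h
        self.ffr3d_, self.r_d_ = sol.ffr3d, sol.r_d
        self.p_a_ = sol.p_a
        return self

    def predict(self, X=None):
        """Return the fitted FFR (the estimator's single per-vessel output)."""
        check_is_fitted(self, "ffr3d_")
        return self.ffr3d_


def ffr3d_pipeline(
    dataset: PressureFlowDataset,
    p_a: float | None = None,
    line: CFRLine | None = None,
) -> HyperemiaSolution:
    """Average → fit → intersect for a single-vessel dataset."""
    est = FFR3DEstimator()
    est.fit(dataset, p_a=p_a, cfr_line=line)
    return est.solution_
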