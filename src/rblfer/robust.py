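"""Robust-regression detection of collectively deviating residues.

Residues undergoing a concerted motion (e.g. a transient helix
translocation) sit on a second line roughly parallel to the main REFER
line.  They are found by iteratively reweighted least squares (IRLS) with
Tukey bisquare weights: points far from the consensus line receive weights
near zero, are flagged, the main lines are refit without them, and the
outliers' mean vertical displacement from the refit lines gives the
parallel offset (log10 units) and the implied multiplicative rate factor.

The IRLS follows the common robust-linear-model recipe: residuals are
leverage-adjusted (r / sqrt(1 - h_ii), toggleable), the scale is the
median absolute residual divided by 0.6745 recomputed each iteration, and
the tuning constant is 4.685 (95% Gaussian efficiency).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_model import DomainError, ResidueExchangeRecord
from .refer import ReferFit, fit_refer

__all__ = [
    "RobustFitResult",
    "OutlierReport",
    "robust_fit",
    "flag_outliers",
    "refit_without_outliers",
    "detect_collective_outliers",
]

BISQUARE_TUNE = 4.685
DEFAULT_WEIGHT_THRESHOLD = 0.5


@dataclass(frozen=True)
class RobustFitResult:
    """IRLS line with per-point bisquare weights in [0, 1]."""

    slope: float
    intercept: float
    weights: np.ndarray
    scale: float
    n_iter: int
    converged: bool
    residue_ids: tuple | None = None

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(x) + self.intercept


@dataclass(frozen=True)
class OutlierReport:
    """Flagged residues, the refit on the retained ones, and the offsets.

    ``offset_f``/``offset_b`` are the mean signed vertical displacements
    of the outliers from the redrawn forward/backward lines (log10
    units); ``rate_factor_f``/``rate_factor_b`` = 10**offset are the
    implied multiplicative rate changes.  ``parallel_intercept_f``/``_b``
    are intercepts of the outliers' own lines with slope pinned to the
    refit slopes.
    """

    outlier_ids: frozenset
    retained_ids: frozenset
    refit: ReferFit
    offset_f: float
    offset_b: float
    rate_factor_f: float
    rate_factor_b: float
    parallel_intercept_f: float
    parallel_intercept_b: float


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    sw = np.sum(w)
    if sw <= 0:
        raise DomainError("all robust weights collapsed to zero")
    xm = np.sum(w * x) / sw
    ym = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xm) ** 2)
    if sxx == 0:
        raise DomainError("zero weighted variance in the abscissa")
    slope = np.sum(w * (x - xm) * (y - ym)) / sxx
    return float(slope), float(ym - slope * xm)


def robust_fit(x: Sequence[float], y: Sequence[float], *,
               residue_ids: Sequence | None = None,
               tune: float = BISQUARE_TUNE,
               leverage_adjust: bool = True,
               max_iter: int = 100,
               tol: float = 1e-8) -> RobustFitResult:
    """IRLS bisquare line fit, deterministic from an OLS start."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-D arrays of equal length")
    if n < 5:
        raise DomainError(f"robust_fit needs >= 5 points, got {n}")
    if np.ptp(x) == 0.0:
        raise DomainError("zero variance in the abscissa")
    if residue_ids is not None and len(residue_ids) != n:
        raise DomainError("residue_ids length must match the data")

    # hat-matrix diagonal of the simple-regression design
    xc = x - x.mean()
    h = 1.0 / n + xc ** 2 / np.sum(xc ** 2)
    adj = np.sqrt(np.clip(1.0 - h, 1e-8, None)) if leverage_adjust else 1.0

    w = np.ones(n)
    slope, intercept = _wls(x, y, w)
    scale = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        r = (y - slope * x - intercept) / adj
        scale = float(np.median(np.abs(r))) / 0.6745
        if scale < 1e-10 * max(1.0, float(np.max(np.abs(y)))):
            # majority of points sit exactly on the line: trust them fully,
            # reject everything with a genuinely nonzero residual
            tiny = 1e-8 * max(1.0, float(np.max(np.abs(y))))
            w = np.where(np.abs(r) <= tiny, 1.0, 0.0)
            slope, intercept = _wls(x, y, w)
            converged = True
            break
        u = r / (tune * scale)
        w = np.where(np.abs(u) < 1.0, (1.0 - u ** 2) ** 2, 0.0)
        new_slope, new_intercept = _wls(x, y, w)
        if max(abs(new_slope - slope), abs(new_intercept - intercept)) < tol:
            slope, intercept = new_slope, new_intercept
            converged = True
            break
        slope, intercept = new_slope, new_intercept
    return RobustFitResult(slope=slope, intercept=intercept, weights=w,
                           scale=scale, n_iter=it, converged=converged,
                           residue_ids=tuple(residue_ids) if residue_ids is not None else None)


def flag_outliers(forward: RobustFitResult, backward: RobustFitResult,
                  weight_threshold: float = DEFAULT_WEIGHT_THRESHOLD) -> frozenset:
    """Residues whose weight falls below threshold in either direction."""
    if forward.residue_ids is None or backward.residue_ids is None:
        raise DomainError("both fits must carry residue_ids")
    if forward.residue_ids != backward.residue_ids:
        raise DomainError("forward and backward fits cover different residues")
    flagged = {
        rid
        for rid, wf, wb in zip(forward.residue_ids, forward.weights, backward.weights)
        if wf < weight_threshold or wb < weight_threshold
    }
    return frozenset(flagged)


def refit_without_outliers(records: Sequence[ResidueExchangeRecord],
                           outlier_ids: frozenset | set,
                           min_retained: int = 4) -> OutlierReport:
    """Redraw the REFER lines without the outliers and measure their offset."""
    outlier_ids = frozenset(outlier_ids)
    retained = [r for r in records if r.residue_id not in outlier_ids]
    outliers = [r for r in records if r.residue_id in outlier_ids]
    if len(retained) < min_retained:
        raise DomainError(
            f"only {len(retained)} residues retained; need >= {min_retained}"
        )
    refit = fit_refer(retained, min_n=min_retained)

    if outliers:
        xo = np.array([r.log_K for r in outliers])
        yo_f = np.array([r.log_k for r in outliers])
        yo_b = np.array([r.log_kb for r in outliers])
        off_f = float(np.mean(yo_f - refit.predict_forward(xo)))
        off_b = float(np.mean(yo_b - refit.predict_backward(xo)))
    else:
        off_f = off_b = 0.0
    return OutlierReport(
        outlier_ids=outlier_ids,
        retained_ids=frozenset(r.residue_id for r in retained),
        refit=refit,
        offset_f=off_f, offset_b=off_b,
        rate_factor_f=10.0 ** off_f, rate_factor_b=10.0 ** off_b,
        parallel_intercept_f=refit.intercept_f + off_f,
        parallel_intercept_b=refit.intercept_b + off_b,
    )


def detect_collective_outliers(records: Sequence[ResidueExchangeRecord],
                               weight_threshold: float = DEFAULT_WEIGHT_THRESHOLD,
                               leverage_adjust: bool = True,
                               min_retained: int = 4,
                               ) -> tuple[RobustFitResult, RobustFitResult, OutlierReport]:
    """Full pipeline: robust fits in both directions, flagging, and refit."""
    ids = [r.residue_id for r in records]
    log_K = [r.log_K for r in records]
    fwd = robust_fit(log_K, [r.log_k for r in records], residue_ids=ids,
                     leverage_adjust=leverage_adjust)
    bwd = robust_fit(log_K, [r.log_kb for r in records], residue_ids=ids,
                     leverage_adjust=leverage_adjust)
    flagged = flag_outliers(fwd, bwd, weight_threshold)
    report = refit_without_outliers(records, flagged, min_retained=min_retained)
    return fwd, bwd, report
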