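"""Geometry and taxonomy of the log k vs log k' scatter.

The correlation between log k and log k' must be inspected before a REFER
plot is trusted, because the triad identity log K = log k - log k' can
manufacture linearity from unrelated rates.  The scatter is summarized by
the Pearson correlation, a 95% confidence ellipse of the point cloud, and
the flatness f = 1 - b/a of that ellipse (a, b long/short semi-axes).

Taxonomy (by the slope signatures the types induce in the REFER plot):

- N       significant negative correlation; forward slope in (0, 1).
- P / P'  significant positive correlation; P when log k' varies more
          than log k, P' otherwise.  REFER slopes leave the interpretable
          band.
- V / H   no correlation but a flattened cloud: V when the spread is in
          log k' (forward slope -> 0, backward -> -1), H when the spread
          is in log k (forward -> 1, backward -> 0).
- nr      no relation: neither correlated nor flattened.

The plane is drawn with log k horizontal and log k' vertical by default,
which is the orientation under which a vertically flattened cloud yields
forward slope 0; pass ``orientation="kprime-horizontal"`` to flip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_model import DomainError, ResidueExchangeRecord

__all__ = [
    "ConfidenceEllipse",
    "KKClassification",
    "confidence_ellipse",
    "flatness",
    "classify_kk_type",
]

DEFAULT_FLATNESS_THRESHOLD = 0.6
DEFAULT_ANGLE_TOLERANCE = 20.0


@dataclass(frozen=True)
class ConfidenceEllipse:
    """Covariance confidence ellipse of a 2-D point cloud.

    Semi-axes are sqrt(eigenvalue * q) with q the chi-square(2 dof)
    quantile at ``level``; ``angle`` is the long-axis orientation versus
    the horizontal, in degrees within (-90, 90].
    """

    center: tuple[float, float]
    a: float
    b: float
    angle: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise DomainError(f"level must be in (0, 1), got {self.level!r}")
        if not (self.a >= self.b >= 0.0):
            raise DomainError(f"require a >= b >= 0, got a={self.a!r}, b={self.b!r}")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside (or on) the ellipse."""
        th = math.radians(self.angle)
        dx = np.asarray(x) - self.center[0]
        dy = np.asarray(y) - self.center[1]
        u = dx * math.cos(th) + dy * math.sin(th)
        v = -dx * math.sin(th) + dy * math.cos(th)
        b = max(self.b, 1e-300)
        return (u / self.a) ** 2 + (v / b) ** 2 <= 1.0


@dataclass(frozen=True)
class KKClassification:
    pearson_r: float
    p_value: float
    ellipse: ConfidenceEllipse
    flatness: float
    kk_type: str


def confidence_ellipse(x: Sequence[float], y: Sequence[float],
                       level: float = 0.95) -> ConfidenceEllipse:
    """Confidence ellipse from the sample covariance (n-1 denominator).

    Collinear input is allowed and yields b = 0; fewer than 3 points or a
    zero-variance cloud raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise DomainError(f"need >= 3 points for a confidence ellipse, got {n}")
    cov = np.cov(x, y, ddof=1)
    if not np.any(cov):
        raise DomainError("degenerate point cloud: zero total variance")
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    q = stats.chi2.ppf(level, df=2)
    a, b = float(np.sqrt(evals[0] * q)), float(np.sqrt(evals[1] * q))
    vx, vy = evecs[0, 0], evecs[1, 0]
    angle = math.degrees(math.atan2(vy, vx))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    return ConfidenceEllipse(center=(float(np.mean(x)), float(np.mean(y))),
                             a=a, b=b, angle=angle, level=level)


def flatness(ellipse: ConfidenceEllipse) -> float:
    """f = 1 - b/a; 0 for a circle, 1 for a fully collinear cloud."""
    if ellipse.a == 0.0:
        raise DomainError("flatness undefined for a zero-size ellipse")
    return 1.0 - ellipse.b / ellipse.a


def classify_kk_type(log_k: Sequence[float], log_kb: Sequence[float],
                     alpha: float = 0.05,
                     flatness_threshold: float = DEFAULT_FLATNESS_THRESHOLD,
                     angle_tolerance: float = DEFAULT_ANGLE_TOLERANCE,
                     level: float = 0.95,
                     orientation: str = "k-horizontal") -> KKClassification:
    """Classify the (log k, log k') scatter into {N, V, H, P, Pprime, nr}.

    Significant negative correlation -> N.  Significant positive
    correlation -> P when Var(log k') > Var(log k) (ties toward P), else
    Pprime.  Insignificant correlation with a flat ellipse (f >=
    ``flatness_threshold``) whose long axis lies within
    ``angle_tolerance`` degrees of the vertical -> V, of the horizontal
    -> H.  Anything else -> nr.
    """
    log_k = np.asarray(log_k, dtype=float)
    log_kb = np.asarray(log_kb, dtype=float)
    if len(log_k) < 4:
        raise DomainError(f"need >= 4 points to classify, got {len(log_k)}")
    if orientation == "k-horizontal":
        x, y = log_k, log_kb
    elif orientation == "kprime-horizontal":
        x, y = log_kb, log_k
    else:
        raise DomainError(f"unknown orientation {orientation!r}")

    r, p = stats.pearsonr(log_k, log_kb)
    ell = confidence_ellipse(x, y, level=level)
    f = flatness(ell)

    if p < alpha:
        if r < 0:
            kk_type = "N"
        else:
            kk_type = "P" if np.var(log_kb, ddof=1) >= np.var(log_k, ddof=1) else "Pprime"
    elif f >= flatness_threshold:
        if abs(ell.angle) >= 90.0 - angle_tolerance:
            # long axis near vertical: spread in the y variable
            kk_type = "V" if orientation == "k-horizontal" else "H"
        elif abs(ell.angle) <= angle_tolerance:
            kk_type = "H" if orientation == "k-horizontal" else "V"
        else:
            kk_type = "nr"
    else:
        kk_type = "nr"
    return KKClassification(pearson_r=float(r), p_value=float(p), ellipse=ell,
                            flatness=f, kk_type=kk_type)


def classify_records(records: Sequence[ResidueExchangeRecord],
                     **kwargs) -> KKClassification:
    """Convenience wrapper taking residue records instead of raw arrays."""
    return classify_kk_type([r.log_k for r in records],
                            [r.log_kb for r in records], **kwargs)
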