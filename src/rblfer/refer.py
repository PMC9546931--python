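"""REFER (rate-equilibrium free energy relationship) regression.

A REFER plot places log K on the abscissa and log k (forward, "blue") or
log k' (backward, "orange") on the ordinate; ordinary least squares gives
the two lines.  Because log k - log k' = log K residue by residue, the two
OLS slopes on the same residues satisfy slope_f - slope_b = 1 exactly.

A line is drawn solid when its correlation is significant and the slope
falls in the physically interpretable band ([0, 1] forward, [-1, 0]
backward, transition-state similarity reading), dashed when significant
but outside the band, and not drawn at all when insignificant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import DomainError, ResidueExchangeRecord

__all__ = ["ReferFit", "fit_refer", "classify_slope", "refer_summary"]

DEFAULT_ALPHA = 0.05
FORWARD_BAND = (0.0, 1.0)
BACKWARD_BAND = (-1.0, 0.0)


@dataclass(frozen=True)
class ReferFit:
    """Forward and backward least-squares lines on the (log K, log rate) plane."""

    slope_f: float
    intercept_f: float
    r2_f: float
    p_forward: float
    line_class_f: str
    slope_b: float
    intercept_b: float
    r2_b: float
    p_backward: float
    line_class_b: str
    n: int
    ok: bool = True
    reason: str = ""

    def predict_forward(self, log_K: np.ndarray) -> np.ndarray:
        return self.slope_f * np.asarray(log_K) + self.intercept_f

    def predict_backward(self, log_K: np.ndarray) -> np.ndarray:
        return self.slope_b * np.asarray(log_K) + self.intercept_b


def classify_slope(slope: float, p_value: float, alpha: float = DEFAULT_ALPHA,
                   band: tuple[float, float] = FORWARD_BAND) -> str:
    """Line style for a REFER least-squares line.

    ``none`` when the correlation is insignificant (p >= alpha); ``solid``
    when significant with slope inside the closed interpretable band;
    ``dashed`` when significant but outside.
    """
    if p_value >= alpha or math.isnan(p_value):
        return "none"
    lo, hi = band
    return "solid" if lo <= slope <= hi else "dashed"


def _no_fit(n: int, reason: str) -> ReferFit:
    nan = math.nan
    return ReferFit(nan, nan, nan, nan, "none", nan, nan, nan, nan, "none",
                    n=n, ok=False, reason=reason)


def fit_refer(records: Sequence[ResidueExchangeRecord], min_n: int = 4,
              alpha: float = DEFAULT_ALPHA) -> ReferFit:
    """OLS REFER fit of both directions on one residue ensemble.

    Raises on n < min_n; a degenerate abscissa (zero variance in log K)
    yields a no-fit result with an explicit reason rather than an
    exception, since such tables are legal inputs.
    """
    n = len(records)
    if n < min_n:
        raise DomainError(f"need at least {min_n} residues, got {n}")
    log_K = np.array([r.log_K for r in records])
    log_k = np.array([r.log_k for r in records])
    log_kb = np.array([r.log_kb for r in records])
    if np.ptp(log_K) == 0.0:
        return _no_fit(n, "degenerate abscissa: zero variance in log K")

    fwd = stats.linregress(log_K, log_k)
    bwd = stats.linregress(log_K, log_kb)
    return ReferFit(
        slope_f=fwd.slope, intercept_f=fwd.intercept, r2_f=fwd.rvalue ** 2,
        p_forward=fwd.pvalue,
        line_class_f=classify_slope(fwd.slope, fwd.pvalue, alpha, FORWARD_BAND),
        slope_b=bwd.slope, intercept_b=bwd.intercept, r2_b=bwd.rvalue ** 2,
        p_backward=bwd.pvalue,
        line_class_b=classify_slope(bwd.slope, bwd.pvalue, alpha, BACKWARD_BAND),
        n=n,
    )


def refer_summary(fits: Mapping[str, ReferFit]) -> pd.DataFrame:
    """One row per dataset; slope cells of undrawn lines are marked NaN.

    The ``slope_f``/``slope_b`` columns carry the fitted values only for
    drawn (solid or dashed) lines, mirroring the plotting rule; raw fitted
    slopes are preserved in ``slope_f_raw``/``slope_b_raw``.
    """
    if not fits:
        raise DomainError("refer_summary requires at least one fit")
    rows = []
    for name, fit in fits.items():
        rows.append({
            "dataset": name,
            "n": fit.n,
            "slope_f": fit.slope_f if fit.line_class_f != "none" else math.nan,
            "slope_b": fit.slope_b if fit.line_class_b != "none" else math.nan,
            "slope_f_raw": fit.slope_f,
            "slope_b_raw": fit.slope_b,
            "intercept_f": fit.intercept_f,
            "intercept_b": fit.intercept_b,
            "r2_f": fit.r2_f,
            "r2_b": fit.r2_b,
            "p_forward": fit.p_forward,
            "p_backward": fit.p_backward,
            "line_class_f": fit.line_class_f,
            "line_class_b": fit.line_class_b,
            "ok": fit.ok,
            "reason": fit.reason,
        })
    return pd.DataFrame(rows)
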