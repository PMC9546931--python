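"""REFER and log k vs log k' plots (vector output).

Styling mirrors the field's conventions: forward data/lines blue,
backward orange; solid lines for interpretable slopes, dashed for
uninterpretable ones, no line when insignificant; outliers green
(forward) and magenta (backward); the k-k' plot carries the 95%
confidence ellipse and uses equal axis ranges so flatness reads
correctly.
"""

from __future__ import annotations

import math
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Ellipse

from .core_model import ResidueExchangeRecord
from .refer import ReferFit
from .scatter import KKClassification

__all__ = ["refer_plot", "kk_plot"]

_STYLE = {"solid": "-", "dashed": "--"}


def refer_plot(records: Sequence[ResidueExchangeRecord], fit: ReferFit,
               outlier_ids: frozenset | set = frozenset(), ax=None):
    """REFER plot: log k and log k' against log K with the fitted lines."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x = np.array([r.log_K for r in records])
    yf = np.array([r.log_k for r in records])
    yb = np.array([r.log_kb for r in records])
    out = np.array([r.residue_id in outlier_ids for r in records])

    ax.errorbar(x[~out], yf[~out], yerr=_err(records, "err_logk", ~out),
                xerr=_err(records, "err_logK", ~out), fmt="o", color="tab:blue",
                ms=4, lw=0.8, label="log k")
    ax.errorbar(x[~out], yb[~out], yerr=_err(records, "err_logkb", ~out),
                xerr=_err(records, "err_logK", ~out), fmt="o", color="tab:orange",
                ms=4, lw=0.8, label="log k'")
    if out.any():
        ax.plot(x[out], yf[out], "o", color="tab:green", ms=5, label="outlier (k)")
        ax.plot(x[out], yb[out], "o", color="magenta", ms=5, label="outlier (k')")

    grid = np.linspace(x.min(), x.max(), 2)
    if fit.line_class_f in _STYLE:
        ax.plot(grid, fit.predict_forward(grid), _STYLE[fit.line_class_f],
                color="tab:blue", lw=1.2)
    if fit.line_class_b in _STYLE:
        ax.plot(grid, fit.predict_backward(grid), _STYLE[fit.line_class_b],
                color="tab:orange", lw=1.2)
    ax.set_xlabel("log K")
    ax.set_ylabel("log k, log k'")
    ax.legend(fontsize=7)
    return ax


def _err(records, attr, mask):
    vals = [getattr(r, attr) for r in records]
    if all(v is None for v in vals):
        return None
    arr = np.array([0.0 if v is None else v for v in vals])
    return arr[mask]


def kk_plot(records: Sequence[ResidueExchangeRecord],
            classification: KKClassification,
            outlier_ids: frozenset | set = frozenset(), ax=None):
    """log k (x) vs log k' (y) scatter with the confidence ellipse overlaid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.2, 4.2))
    x = np.array([r.log_k for r in records])
    y = np.array([r.log_kb for r in records])
    out = np.array([r.residue_id in outlier_ids for r in records])
    ax.plot(x[~out], y[~out], "o", color="gold", mec="k", mew=0.3, ms=5)
    if out.any():
        ax.plot(x[out], y[out], "o", color="purple", ms=5)

    ell = classification.ellipse
    ax.add_patch(Ellipse(ell.center, 2 * ell.a, 2 * ell.b, angle=ell.angle,
                         fill=False, color="k", lw=1.0))
    # equal ranges so the flatness of the ellipse is visually faithful
    half = max(x.max() - x.min(), y.max() - y.min(), 2 * ell.a) / 2 * 1.2
    cx, cy = (x.max() + x.min()) / 2, (y.max() + y.min()) / 2
    ax.set_xlim(cx - half, cx + half)
    ax.set_ylim(cy - half, cy + half)
    ax.set_aspect("equal")
    ax.set_xlabel("log k")
    ax.set_ylabel("log k'")
    ax.set_title(
        f"type {classification.kk_type}  R = {classification.pearson_r:.2f}  "
        f"f = {classification.flatness:.2f}", fontsize=9)
    return ax
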