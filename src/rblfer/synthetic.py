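"""Synthetic residue ensembles, fake-linearity draws, and HX occupancies.

Three generators provide every input the analysis pipeline consumes:

1. ``generate_lfer_ensemble`` — residue ensembles obeying the linear free
   energy relationship log k = rho*log K + c with residue-to-residue
   spread in log K, additive Gaussian noise on log k, and an optional
   collectively offset residue block mimicking a concerted motion such as
   a helix translocation.  log k' is derived as log k - log K, so the
   triad identity K = k/k' holds exactly by construction.
2. ``simulate_fake_linearity`` — the uniform-random gedankenexperiment:
   k and k' drawn independently from uniform ranges produce a REFER plot
   with deceptively good linearity even though log k and log k' are
   unrelated (type nr).
3. ``generate_hx_dataset`` — proton occupancies from the two-process HX
   scheme across a pH ladder and pulse schedule.

All generators take an explicit integer seed; no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    DomainError,
    HXObservation,
    HXParameters,
    KIntModel,
    ResidueExchangeRecord,
    hx_observed_rate,
)
from .refer import ReferFit, fit_refer
from .scatter import KKClassification, classify_kk_type

__all__ = [
    "EnsembleSpec",
    "FakeSpec",
    "FakeLinearityResult",
    "generate_lfer_ensemble",
    "simulate_fake_linearity",
    "generate_hx_dataset",
]


@dataclass(frozen=True)
class EnsembleSpec:
    """Recipe for an LFER-obeying residue ensemble.

    Defaults emulate the collected residue-resolved datasets: a few dozen
    residues, log K spread over ~2 decades, REFER slope well inside
    (0, 1), and ~0.1 log-unit noise on log k.  ``outlier_block`` marks a
    contiguous index range [start, stop) whose log k (and hence log k')
    is shifted by ``outlier_delta`` log units — a collective-motion mimic.
    """

    n_residues: int = 40
    rho_true: float = 0.4
    intercept_true: float = 1.0
    logK_center: float = 0.0
    logK_spread: float = 1.0
    noise_sigma: float = 0.1
    outlier_block: tuple[int, int] | None = None
    outlier_delta: float = 0.0
    logK_dist: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise DomainError(f"n_residues must be >= 4, got {self.n_residues}")
        if self.noise_sigma < 0:
            raise DomainError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.logK_spread <= 0:
            raise DomainError(f"logK_spread must be > 0, got {self.logK_spread}")
        if self.logK_dist not in ("uniform", "normal"):
            raise DomainError(f"logK_dist must be 'uniform' or 'normal', got {self.logK_dist!r}")
        if self.outlier_block is not None:
            lo, hi = self.outlier_block
            if not (0 <= lo < hi <= self.n_residues):
                raise DomainError(
                    f"outlier_block {self.outlier_block} outside residue range "
                    f"[0, {self.n_residues})"
                )


def generate_lfer_ensemble(spec: EnsembleSpec) -> list[ResidueExchangeRecord]:
    """Draw one residue ensemble; deterministic for a fixed spec/seed."""
    rng = np.random.default_rng(spec.seed)
    if spec.logK_dist == "uniform":
        log_K = rng.uniform(spec.logK_center - spec.logK_spread,
                            spec.logK_center + spec.logK_spread, spec.n_residues)
    else:
        log_K = rng.normal(spec.logK_center, spec.logK_spread, spec.n_residues)
    log_k = spec.rho_true * log_K + spec.intercept_true
    if spec.noise_sigma > 0:
        log_k = log_k + rng.normal(0.0, spec.noise_sigma, spec.n_residues)
    if spec.outlier_block is not None:
        lo, hi = spec.outlier_block
        log_k[lo:hi] += spec.outlier_delta
    log_kb = log_k - log_K
    width = len(str(spec.n_residues))
    return [
        ResidueExchangeRecord.from_rates(
            residue_id=f"R{i + 1:0{width}d}",
            k_forward=10.0 ** log_k[i],
            k_backward=10.0 ** log_kb[i],
            source="synthetic-lfer",
        )
        for i in range(spec.n_residues)
    ]


@dataclass(frozen=True)
class FakeSpec:
    """The uniform-random fake-linearity construction.

    Per repeat, ``n_residues`` forward rates k ~ U(k_low, k_high) and
    backward rates k' ~ U(kb_low, kb_high) are drawn independently and
    K = k/k' is formed — a single hidden (K, k, k') triple blurred by
    unnecessarily large scatter.  ``log_uniform=True`` draws the
    logarithms uniformly instead (sensitivity variant).
    """

    n_residues: int = 15
    k_low: float = 3.0
    k_high: float = 7.0
    kb_low: float = 8.0
    kb_high: float = 12.0
    n_reps: int = 30
    log_uniform: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise DomainError(f"n_residues must be >= 4, got {self.n_residues}")
        if self.n_reps < 1:
            raise DomainError(f"n_reps must be >= 1, got {self.n_reps}")
        for lo, hi, name in ((self.k_low, self.k_high, "k"),
                             (self.kb_low, self.kb_high, "kb")):
            if not (0 < lo < hi):
                raise DomainError(
                    f"{name} range must satisfy 0 < low < high, got ({lo}, {hi})"
                )


@dataclass(frozen=True)
class FakeLinearityResult:
    """Per-rep datasets plus cross-rep aggregates and diagnostics.

    ``aggregate`` has one row per residue with mean/SD/SE of k and k'
    across repeats (SE = SD/sqrt(n_reps)); both dispersion measures are
    reported since published error bars use either convention.
    ``fit_single``/``classification_single`` diagnose the first repeat
    (the few-measurement scenario); ``fit_mean`` fits the per-residue
    means (the many-repeat scenario).
    """

    spec: FakeSpec
    reps: list[list[ResidueExchangeRecord]]
    aggregate: pd.DataFrame
    fit_single: ReferFit
    classification_single: KKClassification
    fit_mean: ReferFit


def _draw_fake_rep(spec: FakeSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    if spec.log_uniform:
        k = 10.0 ** rng.uniform(math.log10(spec.k_low), math.log10(spec.k_high),
                                spec.n_residues)
        kb = 10.0 ** rng.uniform(math.log10(spec.kb_low), math.log10(spec.kb_high),
                                 spec.n_residues)
    else:
        k = rng.uniform(spec.k_low, spec.k_high, spec.n_residues)
        kb = rng.uniform(spec.kb_low, spec.kb_high, spec.n_residues)
    return k, kb


def simulate_fake_linearity(spec: FakeSpec) -> FakeLinearityResult:
    """Run the fake-linearity construction and its REFER diagnostics."""
    if spec.k_low == spec.k_high or spec.kb_low == spec.kb_high:
        raise DomainError("zero-width rate range: all points identical, "
                          "regression degenerate")
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.n_residues))
    reps: list[list[ResidueExchangeRecord]] = []
    ks = np.empty((spec.n_reps, spec.n_residues))
    kbs = np.empty((spec.n_reps, spec.n_residues))
    for rep in range(spec.n_reps):
        k, kb = _draw_fake_rep(spec, rng)
        ks[rep], kbs[rep] = k, kb
        reps.append([
            ResidueExchangeRecord.from_rates(
                residue_id=f"R{i + 1:0{width}d}",
                k_forward=float(k[i]), k_backward=float(kb[i]),
                source="synthetic-fake",
            )
            for i in range(spec.n_residues)
        ])

    sqrt_n = math.sqrt(spec.n_reps)
    sd_k = ks.std(axis=0, ddof=1) if spec.n_reps > 1 else np.zeros(spec.n_residues)
    sd_kb = kbs.std(axis=0, ddof=1) if spec.n_reps > 1 else np.zeros(spec.n_residues)
    aggregate = pd.DataFrame({
        "residue_id": [f"R{i + 1:0{width}d}" for i in range(spec.n_residues)],
        "k_mean": ks.mean(axis=0),
        "k_sd": sd_k,
        "k_se": sd_k / sqrt_n,
        "kb_mean": kbs.mean(axis=0),
        "kb_sd": sd_kb,
        "kb_se": sd_kb / sqrt_n,
    })

    first = reps[0]
    fit_single = fit_refer(first)
    classification = classify_kk_type([r.log_k for r in first],
                                      [r.log_kb for r in first])
    mean_records = [
        ResidueExchangeRecord.from_rates(
            residue_id=row.residue_id, k_forward=row.k_mean,
            k_backward=row.kb_mean, source="synthetic-fake-mean",
        )
        for row in aggregate.itertuples()
    ]
    fit_mean = fit_refer(mean_records)
    return FakeLinearityResult(spec=spec, reps=reps, aggregate=aggregate,
                               fit_single=fit_single,
                               classification_single=classification,
                               fit_mean=fit_mean)


def generate_hx_dataset(truth: Mapping[str, HXParameters],
                        ph_values: Sequence[float] = tuple(range(6, 12)),
                        pulse_durations: Sequence[float] = (0.05, 0.5),
                        kint_model: KIntModel | None = None,
                        noise_sigma: float = 0.0,
                        seed: int = 0) -> list[HXObservation]:
    """Forward-simulate proton occupancies over a pH ladder.

    occupancy = exp(-k_obs * t) plus Gaussian noise truncated to [0, 1];
    deterministic given the seed.
    """
    if noise_sigma < 0:
        raise DomainError(f"noise_sigma must be >= 0, got {noise_sigma}")
    kint_model = kint_model or KIntModel()
    rng = np.random.default_rng(seed)
    out: list[HXObservation] = []
    for rid, params in truth.items():
        for ph in ph_values:
            k_int = kint_model.rate(ph, rid)
            k_obs, _ = hx_observed_rate(params, k_int)
            for t in pulse_durations:
                occ = math.exp(-k_obs * t)
                if noise_sigma > 0:
                    occ = float(np.clip(occ + rng.normal(0.0, noise_sigma), 0.0, 1.0))
                out.append(HXObservation(
                    residue_id=rid, pH=float(ph), pulse_duration=float(t),
                    occupancy=occ,
                    err_occupancy=noise_sigma if noise_sigma > 0 else None,
                ))
    return out
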