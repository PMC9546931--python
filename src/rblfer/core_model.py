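"""Domain types and kinetics for residue-specific two-state exchange.

A residue-resolved two-state exchange is described by an equilibrium
constant K and forward/backward rate constants k and k' that obey the
triad identity K = k/k' (log K = log k - log k').  Hydrogen-exchange (HX)
data follow the two-process scheme

    NH(closed)  <k_op/k_cl>  NH(open)  --k_int-->  ND(exchanged)

where k_op and k_cl are the structural opening/closing rates and k_int is
the intrinsic, strongly pH-dependent chemical exchange rate.  Under the
steady-state (Linderstrom-Lang) approximation the observed exchange rate
is k_obs = k_op * k_int / (k_op + k_cl + k_int), which interpolates
between the EX1 limit (k_int >> k_cl, k_obs -> k_op) and the EX2 limit
(k_int << k_cl, k_obs -> (k_op/k_cl) * k_int).

All logarithms in this package are base 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DomainError",
    "ResidueExchangeRecord",
    "HXParameters",
    "HXObservation",
    "HXFitResult",
    "KIntModel",
    "equilibrium_from_rates",
    "intrinsic_rate",
    "hx_observed_rate",
    "hx_exact_slow_rate",
    "occupancy_after_pulse",
    "fit_hx_rates",
]

LN10 = math.log(10.0)

#: default tolerance (log10 units) for the K = k/k' consistency check
DEFAULT_TRIAD_TOL = 0.05

#: default EX1/EX2 regime threshold: EX1 if k_int >= R*k_cl, EX2 if k_int <= k_cl/R
DEFAULT_REGIME_RATIO = 10.0

#: optimizer box for (k_op, k_cl), s^-1
HX_RATE_BOUNDS = (1e-6, 1e8)


class DomainError(ValueError):
    """Raised when a physical precondition (positivity, range) is violated."""


def _require_positive(name: str, value: float) -> None:
    if not (value > 0) or not math.isfinite(value):
        raise DomainError(f"{name} must be a positive finite number, got {value!r}")


def _require_nonneg(name: str, value: float | None) -> None:
    if value is not None and (not math.isfinite(value) or value < 0):
        raise DomainError(f"{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class ResidueExchangeRecord:
    """One residue's (K, k, k') triad with optional log10-scale uncertainties.

    ``triad_tol`` is the allowed |log10 K - (log10 k - log10 k')| slack in
    log10 units; source tables recovered at limited precision need a
    nonzero tolerance.
    """

    residue_id: str
    K: float
    k_forward: float
    k_backward: float
    err_logK: float | None = None
    err_logk: float | None = None
    err_logkb: float | None = None
    source: str = ""
    triad_tol: float = field(default=DEFAULT_TRIAD_TOL, repr=False, compare=False)

    def __post_init__(self) -> None:
        _require_positive("K", self.K)
        _require_positive("k_forward", self.k_forward)
        _require_positive("k_backward", self.k_backward)
        _require_nonneg("err_logK", self.err_logK)
        _require_nonneg("err_logk", self.err_logk)
        _require_nonneg("err_logkb", self.err_logkb)
        mismatch = abs(self.log_K - (self.log_k - self.log_kb))
        if mismatch > self.triad_tol:
            raise DomainError(
                f"residue {self.residue_id!r}: K = {self.K:g} is inconsistent with "
                f"k/k' = {self.k_forward / self.k_backward:g} "
                f"(|log10 mismatch| = {mismatch:.3g} > {self.triad_tol:g})"
            )

    @classmethod
    def from_rates(cls, residue_id: str, k_forward: float, k_backward: float,
                   **kwargs) -> "ResidueExchangeRecord":
        """Build a record with K derived from the rates (triad exact)."""
        _require_positive("k_forward", k_forward)
        _require_positive("k_backward", k_backward)
        return cls(residue_id=residue_id, K=k_forward / k_backward,
                   k_forward=k_forward, k_backward=k_backward, **kwargs)

    @property
    def log_K(self) -> float:
        return math.log10(self.K)

    @property
    def log_k(self) -> float:
        return math.log10(self.k_forward)

    @property
    def log_kb(self) -> float:
        return math.log10(self.k_backward)


@dataclass(frozen=True)
class HXParameters:
    """Opening/closing rates of the two-state HX scheme.

    K_op = k_op/k_cl plays the role of the record-level equilibrium
    constant for HX datasets.  The EX1/EX2 regime is a property of a
    (parameters, k_int) pair, not of the parameters alone.
    """

    k_op: float
    k_cl: float

    def __post_init__(self) -> None:
        _require_positive("k_op", self.k_op)
        _require_positive("k_cl", self.k_cl)

    @property
    def K_op(self) -> float:
        return self.k_op / self.k_cl

    def regime(self, k_int: float, ratio: float = DEFAULT_REGIME_RATIO) -> str:
        """EX1 if k_int >= ratio*k_cl, EX2 if k_int <= k_cl/ratio, else intermediate."""
        _require_positive("k_int", k_int)
        if k_int >= ratio * self.k_cl:
            return "EX1"
        if k_int <= self.k_cl / ratio:
            return "EX2"
        return "intermediate"


@dataclass(frozen=True)
class HXObservation:
    """Proton occupancy of one residue after a labeling pulse at a given pH."""

    residue_id: str
    pH: float
    pulse_duration: float
    occupancy: float
    err_occupancy: float | None = None

    def __post_init__(self) -> None:
        _require_positive("pulse_duration", self.pulse_duration)
        if not (0.0 <= self.occupancy <= 1.0):
            raise DomainError(
                f"occupancy must lie in [0, 1], got {self.occupancy!r} "
                f"for residue {self.residue_id!r}"
            )
        _require_nonneg("err_occupancy", self.err_occupancy)


def equilibrium_from_rates(k_forward: float, k_backward: float) -> float:
    """K = k/k' for a two-state exchange."""
    _require_positive("k_forward", k_forward)
    _require_positive("k_backward", k_backward)
    return k_forward / k_backward


def intrinsic_rate(pH: float, k_ref: float, pH_ref: float) -> float:
    """Base-catalysis intrinsic exchange rate: k_int = k_ref * 10**(pH - pH_ref).

    One decade per pH unit; ``k_ref`` is the rate at the reference pH.
    """
    _require_positive("k_ref", k_ref)
    return k_ref * 10.0 ** (pH - pH_ref)


class HXRate(NamedTuple):
    k_obs: float
    regime: str


def hx_observed_rate(params: HXParameters, k_int: float,
                     regime_ratio: float = DEFAULT_REGIME_RATIO) -> HXRate:
    """Steady-state observed exchange rate and EX1/EX2 regime label.

    k_obs = k_op*k_int / (k_op + k_cl + k_int).  The label is EX1 when
    k_int >= regime_ratio*k_cl, EX2 when k_int <= k_cl/regime_ratio, and
    "intermediate" otherwise.
    """
    _require_positive("k_int", k_int)
    k_obs = params.k_op * k_int / (params.k_op + params.k_cl + k_int)
    return HXRate(k_obs, params.regime(k_int, regime_ratio))


def hx_exact_slow_rate(params: HXParameters, k_int: float) -> float:
    """Slow-phase rate of the exact two-exponential solution (test oracle).

    Smaller-magnitude eigenvalue of the 2x2 rate matrix of the
    closed <-> open -> exchanged scheme:

        d/dt [C, O] = [[-k_op, k_cl], [k_op, -(k_cl + k_int)]] @ [C, O]
    """
    if k_int < 0:
        raise DomainError(f"k_int must be >= 0, got {k_int!r}")
    if k_int == 0.0:
        return 0.0
    m = np.array([[-params.k_op, params.k_cl],
                  [params.k_op, -(params.k_cl + k_int)]])
    eig = np.linalg.eigvals(m)
    return float(np.min(np.abs(eig)))


def occupancy_after_pulse(k_obs: float, t: float) -> float:
    """Fraction of unexchanged protons after a pulse of duration t: exp(-k_obs*t)."""
    if k_obs < 0:
        raise DomainError(f"k_obs must be >= 0, got {k_obs!r}")
    if t < 0:
        raise DomainError(f"t must be >= 0, got {t!r}")
    return math.exp(-k_obs * t)


@dataclass(frozen=True)
class KIntModel:
    """Intrinsic-rate model k_int(pH) = k_ref * 10**(pH - pH_ref).

    ``per_residue`` optionally overrides (k_ref, pH_ref) per residue id,
    e.g. from an externally supplied sequence-dependent rate table.
    """

    k_ref: float = 1.0
    pH_ref: float = 7.0
    per_residue: Mapping[str, tuple[float, float]] | None = None

    def rate(self, pH: float, residue_id: str | None = None) -> float:
        if self.per_residue is not None and residue_id in self.per_residue:
            k_ref, pH_ref = self.per_residue[residue_id]
            return intrinsic_rate(pH, k_ref, pH_ref)
        return intrinsic_rate(pH, self.k_ref, self.pH_ref)


@dataclass(frozen=True)
class HXFitResult:
    """Per-residue (k_op, k_cl) estimate with status.

    status is one of:

    - ``"ok"`` — both rates identifiable; standard errors from the fit.
    - ``"regime-limited"`` — data lie in one exchange regime; only
      K_op = k_op/k_cl is estimable (EX2-only designs), k_op/k_cl are NaN.
    - ``"fully-protected"`` — occupancies ~ 1 everywhere, no estimate.
    """

    residue_id: str
    status: str
    k_op: float = math.nan
    k_cl: float = math.nan
    se_k_op: float = math.nan
    se_k_cl: float = math.nan
    K_op: float = math.nan
    se_K_op: float = math.nan
    n_obs: int = 0
    message: str = ""

    @property
    def params(self) -> HXParameters | None:
        if self.status == "ok":
            return HXParameters(self.k_op, self.k_cl)
        return None


def _occupancy_model(log_kop: float, log_kcl: float,
                     k_int: np.ndarray, t: np.ndarray) -> np.ndarray:
    k_op = 10.0 ** log_kop
    k_cl = 10.0 ** log_kcl
    k_obs = k_op * k_int / (k_op + k_cl + k_int)
    return np.exp(-k_obs * t)


def _fit_one_residue(residue_id: str, k_int: np.ndarray, t: np.ndarray,
                     occ: np.ndarray, sigma: np.ndarray | None,
                     regime_ratio: float, protected_level: float) -> HXFitResult:
    n = len(occ)
    if n < 3:
        raise DomainError(
            f"residue {residue_id!r}: need >= 3 observations, got {n}"
        )
    if np.all(occ >= protected_level):
        return HXFitResult(residue_id, "fully-protected", n_obs=n,
                           message="occupancy ~ 1 at every condition; "
                                   "amide fully protected, no estimate")
    if np.all(occ <= 1.0 - protected_level) and np.ptp(occ) < 0.02:
        return HXFitResult(residue_id, "regime-limited", n_obs=n,
                           message="occupancy ~ 0 everywhere; rates exceed "
                                   "the probed window")

    w = 1.0 / sigma if sigma is not None else None

    def resid(theta: np.ndarray) -> np.ndarray:
        r = _occupancy_model(theta[0], theta[1], k_int, t) - occ
        return r * w if w is not None else r

    lo, hi = math.log10(HX_RATE_BOUNDS[0]), math.log10(HX_RATE_BOUNDS[1])
    best = None
    # coarse multistart keeps the box-constrained fit off local shelves
    for g_op in (-2.0, 0.0, 2.0):
        for g_cl in (0.0, 2.0, 4.0):
            sol = least_squares(resid, x0=[g_op, g_cl], bounds=([lo, lo], [hi, hi]),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
            if best is None or sol.cost < best.cost - 1e-15:
                best = sol
    assert best is not None
    log_kop, log_kcl = best.x
    k_op, k_cl = 10.0 ** log_kop, 10.0 ** log_kcl

    # identifiability: in a single-regime design the two log-rate directions
    # collapse (EX2 data constrain only log k_op - log k_cl)
    sv = np.linalg.svd(best.jac, compute_uv=False)
    ill_conditioned = sv[-1] < 1e-4 * sv[0]
    all_ex2 = bool(np.all(k_int <= k_cl / regime_ratio))
    if ill_conditioned or all_ex2:
        return _fit_ratio_only(residue_id, k_int, t, occ, w, n)

    dof = max(n - 2, 1)
    s2 = 2.0 * best.cost / dof
    try:
        cov = np.linalg.inv(best.jac.T @ best.jac) * s2
        se_log = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        se_logK = math.sqrt(max(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1], 0.0))
    except np.linalg.LinAlgError:
        se_log = np.array([math.nan, math.nan])
        se_logK = math.nan
    K_op = k_op / k_cl
    return HXFitResult(
        residue_id, "ok", k_op=k_op, k_cl=k_cl,
        se_k_op=k_op * LN10 * float(se_log[0]),
        se_k_cl=k_cl * LN10 * float(se_log[1]),
        K_op=K_op, se_K_op=K_op * LN10 * se_logK, n_obs=n,
    )


def _fit_ratio_only(residue_id: str, k_int: np.ndarray, t: np.ndarray,
                    occ: np.ndarray, w: np.ndarray | None, n: int) -> HXFitResult:
    """EX2-limited design: fit only K_op via k_obs = K_op*k_int/(1 + K_op)."""

    def resid(theta: np.ndarray) -> np.ndarray:
        K_op = 10.0 ** theta[0]
        r = np.exp(-(K_op * k_int / (1.0 + K_op)) * t) - occ
        return r * w if w is not None else r

    sol = least_squares(resid, x0=[-2.0], bounds=([-14.0], [14.0]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    K_op = 10.0 ** sol.x[0]
    dof = max(n - 1, 1)
    s2 = 2.0 * sol.cost / dof
    jtj = float((sol.jac.T @ sol.jac).item())
    se_logK = math.sqrt(s2 / jtj) if jtj > 0 else math.nan
    return HXFitResult(
        residue_id, "regime-limited", K_op=K_op,
        se_K_op=K_op * LN10 * se_logK, n_obs=n,
        message="observations span a single exchange regime (EX2-like); "
                "only the ratio K_op = k_op/k_cl is estimable",
    )


def fit_hx_rates(observations: Iterable[HXObservation],
                 kint_model: KIntModel | None = None,
                 *,
                 regime_ratio: float = DEFAULT_REGIME_RATIO,
                 pool_pulses: bool = True,
                 protected_level: float = 0.98,
                 use_errors: bool = False) -> dict:
    """Fit pH-independent (k_op, k_cl) per residue from occupancy data.

    Observations for each residue must span a pH ladder; ``pool_pulses``
    (default True) fits a single (k_op, k_cl) pair jointly across all
    pulse durations, mirroring the pooling used when rates are assumed
    unchanged between labeling windows.  With ``pool_pulses=False`` each
    pulse duration is fit separately and the result maps
    (residue_id, pulse_duration) -> HXFitResult.

    ``use_errors`` weights residuals by 1/err_occupancy when every
    observation carries an uncertainty.
    """
    kint_model = kint_model or KIntModel()
    by_res: dict[str, list[HXObservation]] = {}
    for ob in observations:
        by_res.setdefault(ob.residue_id, []).append(ob)
    if not by_res:
        raise DomainError("no observations supplied")

    results: dict = {}
    for rid, obs in by_res.items():
        groups: dict = {None: obs} if pool_pulses else {}
        if not pool_pulses:
            for ob in obs:
                groups.setdefault(ob.pulse_duration, []).append(ob)
        for key, group in groups.items():
            k_int = np.array([kint_model.rate(ob.pH, rid) for ob in group])
            t = np.array([ob.pulse_duration for ob in group])
            occ = np.array([ob.occupancy for ob in group])
            sigma = None
            if use_errors and all(ob.err_occupancy for ob in group):
                sigma = np.array([ob.err_occupancy for ob in group])
            fit = _fit_one_residue(rid, k_int, t, occ, sigma,
                                   regime_ratio, protected_level)
            if pool_pulses:
                results[rid] = fit
            else:
                results[(rid, key)] = fit
    return results
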