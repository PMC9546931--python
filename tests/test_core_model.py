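"""Unit tests for the two-state exchange types and HX kinetics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rblfer import (
    DomainError,
    HXParameters,
    KIntModel,
    ResidueExchangeRecord,
    equilibrium_from_rates,
    fit_hx_rates,
    generate_hx_dataset,
    hx_exact_slow_rate,
    hx_observed_rate,
    intrinsic_rate,
    occupancy_after_pulse,
)

rates = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False,
                  allow_infinity=False)


class TestEquilibriumFromRates:
    @pytest.mark.parametrize("k, kb, expected", [
        (2.0, 2.0, 1.0),
        (10.0, 2.0, 5.0),
        (3.0, 8.0, 0.375),
    ])
    def test_examples(self, k, kb, expected):
        assert equilibrium_from_rates(k, kb) == pytest.approx(expected, rel=1e-15)

    @pytest.mark.parametrize("k, kb", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0)])
    def test_nonpositive_rates_rejected(self, k, kb):
        with pytest.raises(DomainError, match="k_"):
            equilibrium_from_rates(k, kb)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(k=rates, kb=rates)
    def test_log_identity(self, k, kb):
        """log10 K agrees with log10 k - log10 k' to ~machine precision."""
        logK = math.log10(equilibrium_from_rates(k, kb))
        assert logK == pytest.approx(math.log10(k) - math.log10(kb),
                                     rel=1e-12, abs=1e-12)


class TestIntrinsicRate:
    @pytest.mark.parametrize("pH, expected", [
        (7.0, 1.0), (8.0, 10.0), (5.0, 0.01),
    ])
    def test_one_decade_per_ph_unit(self, pH, expected):
        assert intrinsic_rate(pH, 1.0, 7.0) == pytest.approx(expected)

    def test_strictly_increasing_in_ph(self):
        phs = np.linspace(4, 12, 33)
        vals = [intrinsic_rate(p, 0.5, 7.0) for p in phs]
        assert np.all(np.diff(vals) > 0)

    def test_nonpositive_reference_rate_rejected(self):
        with pytest.raises(DomainError):
            intrinsic_rate(7.0, 0.0, 7.0)


class TestObservedRate:
    def test_exact_arithmetic(self):
        k_obs, regime = hx_observed_rate(HXParameters(2.0, 3.0), 5.0)
        assert k_obs == pytest.approx(1.0, rel=1e-15)
        assert regime == "intermediate"

    def test_ex1_limit(self):
        k_obs, regime = hx_observed_rate(HXParameters(1.0, 1000.0), 1e9)
        assert regime == "EX1"
        assert k_obs == pytest.approx(1.0, rel=2e-3)

    def test_ex2_limit_grid(self):
        """k_obs -> (k_op/k_cl)*k_int with error bounded by the regime ratio."""
        p = HXParameters(1.0, 1000.0)
        for k_int in np.logspace(-4, 0, 9):
            k_obs, regime = hx_observed_rate(p, k_int)
            assert regime == "EX2"
            expected = p.K_op * k_int
            assert abs(k_obs - expected) / expected <= 10 * k_int / p.k_cl + 1e-3

    def test_ex1_limit_grid(self):
        p = HXParameters(2.0, 50.0)
        for k_int in np.logspace(3, 7, 9):
            k_obs, regime = hx_observed_rate(p, k_int)
            assert regime == "EX1"
            assert abs(k_obs - p.k_op) / p.k_op <= 10 * p.k_cl / k_int

    def test_matches_matrix_oracle_in_folded_regime(self):
        """Steady-state rate tracks the exact slow eigenvalue when k_op << k_cl."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            k_cl = 10.0 ** rng.uniform(0, 5)
            k_op = k_cl * 10.0 ** rng.uniform(-5, -2)  # k_op <= 0.01 k_cl
            k_int = 10.0 ** rng.uniform(-3, 7)
            p = HXParameters(k_op, k_cl)
            exact = hx_exact_slow_rate(p, k_int)
            approx = hx_observed_rate(p, k_int).k_obs
            assert approx == pytest.approx(exact, rel=0.01)


class TestExactSlowRate:
    def test_zero_intrinsic_rate_means_no_exchange(self):
        assert hx_exact_slow_rate(HXParameters(2.0, 3.0), 0.0) == 0.0

    def test_slow_phase_is_smaller_eigenvalue(self):
        p = HXParameters(1.0, 1000.0)
        slow = hx_exact_slow_rate(p, 1.0)
        # total decay rate is the trace; fast phase carries the rest
        assert slow < (p.k_op + p.k_cl + 1.0) / 2


class TestOccupancy:
    @pytest.mark.parametrize("k_obs, t, expected", [
        (0.0, 100.0, 1.0),
        (math.log(2), 1.0, 0.5),
        (5.0, 0.0, 1.0),
    ])
    def test_examples(self, k_obs, t, expected):
        assert occupancy_after_pulse(k_obs, t) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            occupancy_after_pulse(-1.0, 1.0)
        with pytest.raises(DomainError):
            occupancy_after_pulse(1.0, -1.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(k=st.floats(0, 100), t=st.floats(0, 100))
    def test_bounded_in_unit_interval(self, k, t):
        assert 0.0 <= occupancy_after_pulse(k, t) <= 1.0


class TestRecordInvariants:
    def test_triad_consistency_enforced(self):
        with pytest.raises(DomainError, match="inconsistent"):
            ResidueExchangeRecord("A1", K=2.0, k_forward=10.0, k_backward=2.0)

    def test_consistent_triad_accepted(self):
        rec = ResidueExchangeRecord("A1", K=5.0, k_forward=10.0, k_backward=2.0)
        assert rec.log_K == pytest.approx(rec.log_k - rec.log_kb)

    def test_from_rates_is_triad_exact(self):
        rec = ResidueExchangeRecord.from_rates("A1", 3.0, 8.0)
        assert rec.K == pytest.approx(0.375, rel=1e-15)

    def test_positivity(self):
        with pytest.raises(DomainError, match="k_forward"):
            ResidueExchangeRecord("A1", K=1.0, k_forward=-1.0, k_backward=1.0)


class TestFitHXRates:
    TRUTH = HXParameters(5.0, 500.0)

    def test_noiseless_round_trip_recovers_truth(self):
        """pH 6-11 ladder spanning EX2 through EX1 pins both rates to <1%."""
        obs = generate_hx_dataset({"A": self.TRUTH})
        fit = fit_hx_rates(obs)["A"]
        assert fit.status == "ok"
        assert fit.k_op == pytest.approx(5.0, rel=0.01)
        assert fit.k_cl == pytest.approx(500.0, rel=0.01)
        assert fit.se_k_op >= 0 or math.isnan(fit.se_k_op)

    def test_ex2_only_design_is_regime_limited(self):
        """Low-pH data determine only the ratio K_op, and say so."""
        obs = generate_hx_dataset({"A": self.TRUTH}, ph_values=[6.0, 6.5, 7.0],
                                  pulse_durations=(200.0, 2000.0))
        fit = fit_hx_rates(obs)["A"]
        assert fit.status == "regime-limited"
        assert fit.K_op == pytest.approx(0.01, rel=0.05)
        assert math.isnan(fit.k_op)

    def test_fully_protected_residue_has_no_estimate(self):
        obs = generate_hx_dataset({"B": HXParameters(1e-6, 1000.0)})
        fit = fit_hx_rates(obs)["B"]
        assert fit.status == "fully-protected"
        assert "protect" in fit.message

    def test_noisy_recovery_is_reasonable(self):
        obs = generate_hx_dataset({"A": self.TRUTH}, noise_sigma=0.02, seed=11)
        fit = fit_hx_rates(obs)["A"]
        assert fit.status == "ok"
        assert fit.k_op == pytest.approx(5.0, rel=0.5)

    def test_unpooled_fit_returns_per_pulse_estimates(self):
        obs = generate_hx_dataset({"A": self.TRUTH})
        fits = fit_hx_rates(obs, pool_pulses=False)
        assert set(fits) == {("A", 0.05), ("A", 0.5)}

    def test_per_residue_kint_override(self):
        model = KIntModel(per_residue={"A": (2.0, 7.0)})
        assert model.rate(8.0, "A") == pytest.approx(20.0)
        assert model.rate(8.0, "B") == pytest.approx(10.0)

    def test_noiseless_objective_minimum_at_truth(self):
        """Grid refinement around the generating parameters: no better point."""
        obs = generate_hx_dataset({"A": self.TRUTH})
        model = KIntModel()
        k_int = np.array([model.rate(o.pH) for o in obs])
        t = np.array([o.pulse_duration for o in obs])
        occ = np.array([o.occupancy for o in obs])

        def sse(k_op, k_cl):
            k_obs = k_op * k_int / (k_op + k_cl + k_int)
            return np.sum((np.exp(-k_obs * t) - occ) ** 2)

        truth_sse = sse(5.0, 500.0)
        for d_op in (-0.05, 0.05):
            for d_cl in (-0.05, 0.05):
                assert sse(5.0 * 10 ** d_op, 500.0 * 10 ** d_cl) > truth_sse
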