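"""The deterministic illness-death mathematics: intensities, annual
transition probabilities, cohort occupancy, and outcome probabilities."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from illnessdeath.process import (
    RateSchedule,
    TrendMatrix,
    annual_transition_probs,
    cohort_outcome_probabilities,
    intensity_matrix,
    mortality_prob,
    outcome_probabilities,
    prevalence,
    state_occupancy,
    transition_prob_array,
)

rates_st = st.floats(min_value=0.0, max_value=2.0, allow_nan=False)


def ode_transition_matrix(i, f, r, rtol=1e-12):
    """Independent oracle: integrate dP/dt = P Q from the identity over [0, 1]."""
    Q = intensity_matrix(i, f, r)

    def rhs(_, y):
        return (y.reshape(3, 3) @ Q).ravel()

    sol = solve_ivp(rhs, (0.0, 1.0), np.eye(3).ravel(), rtol=rtol, atol=1e-14,
                    method="DOP853")
    return sol.y[:, -1].reshape(3, 3)


class TestIntensityMatrix:
    def test_structure(self):
        Q = intensity_matrix(0.1, 0.2, 0.05)
        assert np.allclose(Q[0], [-0.1, 0.1, 0.0])
        assert np.allclose(Q[1], [0.05, -0.25, 0.2])
        assert np.allclose(Q[2], 0.0)
        assert np.allclose(Q.sum(axis=1), 0.0)

    def test_zero_rates_give_zero_matrix(self):
        assert np.allclose(intensity_matrix(0, 0, 0), 0.0)

    @pytest.mark.parametrize("bad", [{"i": -0.1}, {"f": np.nan}, {"r": np.inf}])
    def test_invalid_rate_names_offender(self, bad):
        kwargs = {"i": 0.1, "f": 0.1, "r": 0.1, **bad}
        (name,) = bad.keys()
        with pytest.raises(ValueError, match=name):
            intensity_matrix(**kwargs)


class TestAnnualTransitionProbs:
    def test_zero_rates_identity(self):
        assert np.allclose(annual_transition_probs(0, 0, 0), np.eye(3))

    def test_incidence_only_closed_form(self):
        P = annual_transition_probs(0.1, 0.0, 0.0)
        assert P[0, 0] == pytest.approx(np.exp(-0.1), abs=1e-12)
        assert P[0, 1] == pytest.approx(1 - np.exp(-0.1), abs=1e-12)
        assert P[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_expm(self):
        Q = intensity_matrix(0.1, 0.2, 0.05)
        assert np.allclose(annual_transition_probs(0.1, 0.2, 0.05), expm(Q), atol=1e-13)

    @pytest.mark.parametrize("i,f,r", [(0.1, 0.2, 0.05), (1.5, 0.01, 0.0), (0.0, 2.0, 1.0)])
    def test_matches_ode_oracle(self, i, f, r):
        assert np.allclose(annual_transition_probs(i, f, r),
                           ode_transition_matrix(i, f, r), atol=1e-10)

    @given(i=rates_st, f=rates_st, r=rates_st)
    def test_row_stochastic(self, i, f, r):
        P = annual_transition_probs(i, f, r)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert np.all((P >= 0) & (P <= 1))
        assert np.allclose(P[2], [0, 0, 1])

    def test_death_probs_nondecreasing_in_case_fatality(self):
        fs = np.linspace(0.0, 2.0, 21)
        for i in (0.05, 0.5, 1.5):
            for r in (0.0, 0.3):
                P = transition_prob_array(np.full_like(fs, i), fs, np.full_like(fs, r))
                assert np.all(np.diff(P[:, 0, 2]) >= -1e-12)
                assert np.all(np.diff(P[:, 1, 2]) >= -1e-12)

    def test_extreme_rates_stay_finite(self):
        P = annual_transition_probs(1e12, 1e10, 5.0)
        assert np.all(np.isfinite(P))
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)


class TestStateOccupancy:
    def test_zero_rates_static(self):
        sched = RateSchedule(i=np.zeros(11), f=np.zeros(11), r=np.zeros(11))
        S = state_occupancy(sched)
        assert np.allclose(S, np.tile([1.0, 0, 0], (11, 1)))

    def test_probability_conserved(self):
        rng = np.random.default_rng(0)
        sched = RateSchedule(i=rng.uniform(0, 0.5, 51), f=rng.uniform(0, 0.5, 51),
                             r=rng.uniform(0, 0.2, 51))
        S = state_occupancy(sched)
        assert np.allclose(S.sum(axis=1), 1.0, atol=1e-10)

    def test_constant_rates_match_matrix_power(self):
        i, f, r = 0.01, 0.1, 0.0
        A = 50
        sched = RateSchedule(i=np.full(A + 1, i), f=np.full(A + 1, f), r=np.full(A + 1, r))
        S = state_occupancy(sched)
        P = annual_transition_probs(i, f, r)
        expected = np.array([[1.0, 0, 0] @ np.linalg.matrix_power(P, a) for a in range(A + 1)])
        assert np.allclose(S, expected, atol=1e-12)

    def test_invalid_s0_rejected(self):
        sched = RateSchedule(i=np.zeros(3), f=np.zeros(3), r=np.zeros(3))
        with pytest.raises(ValueError, match="probability vector"):
            state_occupancy(sched, S0=[0.5, 0.2, 0.2])


class TestPrevalenceAndMortality:
    @pytest.mark.parametrize("S,expected", [
        ([0.5, 0.5, 0.0], 0.5),
        ([1.0, 0.0, 0.0], 0.0),
        ([0.2, 0.3, 0.5], 0.6),
    ])
    def test_prevalence(self, S, expected):
        assert prevalence(np.array(S)) == pytest.approx(expected)

    def test_prevalence_everyone_dead(self):
        with pytest.raises(ValueError, match="alive"):
            prevalence(np.array([0.0, 0.0, 1.0]))

    def test_mortality_prob(self):
        P = np.eye(3)
        P[0, 2], P[1, 2] = 0.01, 0.2
        assert mortality_prob(P, 1.0) == pytest.approx(0.2)
        assert mortality_prob(P, 0.0) == pytest.approx(0.01)
        assert mortality_prob(P, 0.5) == pytest.approx(0.105)


class TestOutcomeProbabilities:
    def test_zero_rates_all_zero(self):
        sched = RateSchedule(i=np.zeros(21), f=np.zeros(21), r=np.zeros(21))
        out = outcome_probabilities(sched)
        for m in ("inc", "prev", "mort", "rem"):
            assert np.allclose(out.for_measure(m), 0.0)

    def test_no_remission_rate_no_remission_probability(self, single_truth):
        sched = single_truth.rates[("all", "all")]
        assert np.all(sched.r == 0)
        assert np.allclose(outcome_probabilities(sched).rem, 0.0)

    def test_composes_individually_tested_operations(self, single_truth):
        """Oracle: rebuild every outcome from the independently tested pieces."""
        sched = single_truth.rates[("all", "all")]
        out = outcome_probabilities(sched)
        S = state_occupancy(sched)
        P = transition_prob_array(sched.i, sched.f, sched.r)
        pi = np.array([prevalence(S[a]) for a in range(len(S))])
        assert np.allclose(out.inc, 1 - P[:, 0, 0], atol=1e-12)
        assert np.allclose(out.prev, pi, atol=1e-12)
        assert np.allclose(out.mort, mortality_prob(P, pi), atol=1e-12)
        assert np.allclose(out.rem, P[:, 1, 0], atol=1e-12)

    def test_all_probabilities_in_unit_interval(self, single_truth):
        out = single_truth.outcome_probs(("all", "all"))
        for m in ("inc", "prev", "mort", "rem"):
            v = out.for_measure(m)
            assert np.all((v >= 0) & (v <= 1))


class TestTrendMatrix:
    def test_current_year_must_be_one(self):
        rho = np.ones((11, 101))
        rho[:, -1] = 1.1
        with pytest.raises(ValueError, match="y=100"):
            TrendMatrix(rho)

    def test_positive_entries_required(self):
        rho = np.ones((11, 101))
        rho[0, 0] = 0.0
        with pytest.raises(ValueError, match="positive"):
            TrendMatrix(rho)

    def test_from_year_ratios_backfill_and_log_interpolation(self):
        A = 10
        vals = np.full((A + 1, 2), 1.0)
        vals[:, 0] = 4.0  # year 60: fourfold rates
        tm = TrendMatrix.from_year_ratios(A, [60, 100], vals)
        assert np.allclose(tm.rho[:, :61], 4.0)      # carried backward
        assert np.allclose(tm.rho[:, 80], 2.0)       # geometric midpoint
        assert np.allclose(tm.rho[:, 100], 1.0)

    def test_csv_round_trip(self, tmp_path):
        A = 5
        rng = np.random.default_rng(3)
        vals = np.exp(rng.normal(0, 0.2, (A + 1, 2)))
        tm = TrendMatrix.from_year_ratios(A, [50, 90], vals)
        path = tmp_path / "trend.csv"
        tm.to_csv(path)
        back = TrendMatrix.from_csv(path)
        assert np.allclose(tm.rho, back.rho)


class TestCohortOutcomeProbabilities:
    def test_unit_trends_reduce_to_no_trend_pathway(self, single_truth):
        sched = single_truth.rates[("all", "all")]
        A = sched.max_age
        ones = TrendMatrix.ones(A)
        plain = outcome_probabilities(sched)
        cohort = cohort_outcome_probabilities(sched, ones, ones)
        for m in ("inc", "prev", "mort", "rem"):
            assert np.allclose(cohort.for_measure(m), plain.for_measure(m), atol=1e-12)

    def test_age_zero_unaffected_by_past_trends(self, single_truth):
        sched = single_truth.rates[("all", "all")]
        A = sched.max_age
        rho = np.ones((A + 1, 101))
        rho[:, :-1] = 2.0  # double all past incidence
        doubled = TrendMatrix(rho)
        out = cohort_outcome_probabilities(sched, doubled, TrendMatrix.ones(A))
        plain = outcome_probabilities(sched)
        for m in ("inc", "prev", "mort", "rem"):
            assert out.for_measure(m)[0] == pytest.approx(plain.for_measure(m)[0], abs=1e-12)

    def test_matches_explicit_cohort_loop(self, single_truth):
        """Oracle: build every birth cohort's occupancy one at a time."""
        sched = single_truth.rates[("all", "all")]
        A = sched.max_age
        rng = np.random.default_rng(7)
        ri = np.exp(rng.normal(0.2, 0.1, (A + 1, 101)))
        rf = np.exp(rng.normal(0.1, 0.1, (A + 1, 101)))
        ri[:, -1] = rf[:, -1] = 1.0
        ti, tf = TrendMatrix(ri), TrendMatrix(rf)
        out = cohort_outcome_probabilities(sched, ti, tf)

        from illnessdeath.process import annual_transition_probs as atp

        prev_expected = np.empty(A + 1)
        for c in range(A + 1):
            S = np.array([1.0, 0.0, 0.0])
            for b in range(c):
                y = 100 - c + b
                P = atp(ri[b, y] * sched.i[b], rf[b, y] * sched.f[b], sched.r[b])
                S = S @ P
            prev_expected[c] = S[1] / (S[0] + S[1])
        assert np.allclose(out.prev, prev_expected, atol=1e-12)

    def test_trend_grid_must_cover_ages(self, single_truth):
        sched = single_truth.rates[("all", "all")]
        small = TrendMatrix.ones(10)
        with pytest.raises(ValueError, match="ages"):
            cohort_outcome_probabilities(sched, small, small)
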