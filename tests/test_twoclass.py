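"""Two-class birth-death chain: rates, exact MFPT, eigen oracle, master
equation and Monte Carlo."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ratchet import (
    TwoClassParams,
    build_rates,
    default_n0,
    evolve_master,
    exact_mfpt,
    mc_click_times,
    mfpt_linear_solve,
    qsd_eigen,
)


class TestBuildRates:
    def test_absorbing_and_reflecting_boundaries(self, tc_canonical):
        r = build_rates(tc_canonical)
        assert r.t_plus[0] == 0.0 and r.t_minus[0] == 0.0
        assert r.t_plus[r.N] == 0.0

    def test_hand_computed_example(self):
        # N=2, u=0.1, s_eff=0.5 at n=1: direct arithmetic on the rates
        r = build_rates(TwoClassParams(N=2, u=0.1, s_eff=0.5))
        assert r.t_plus[1] == pytest.approx(0.3)
        assert r.t_minus[1] == pytest.approx(0.2)

    @given(
        N=st.integers(2, 300),
        u=st.floats(0.0, 0.5),
        s_eff=st.floats(0.01, 0.9),
    )
    @settings(max_examples=100, deadline=None)
    def test_probabilities_bounded(self, N, u, s_eff):
        r = build_rates(TwoClassParams(N=N, u=u, s_eff=s_eff))
        total = r.t_plus + r.t_minus
        assert np.all(r.t_plus >= 0) and np.all(r.t_minus >= 0)
        assert np.all(total <= 1.0 + 1e-12)

    def test_rates_balance_at_fixed_point(self, tc_canonical):
        # t_plus - t_minus changes sign exactly once, within one of N x*
        r = build_rates(tc_canonical)
        diff = (r.t_plus - r.t_minus)[1 : r.N]
        n_star = tc_canonical.N * tc_canonical.x_star
        # strictly positive below the fixed point, strictly negative above,
        # with at most a single zero touch at the balance point itself
        last_pos = np.flatnonzero(diff > 0)[-1] + 1
        first_neg = np.flatnonzero(diff < 0)[0] + 1
        assert first_neg - last_pos in (1, 2)
        assert abs(last_pos - n_star) <= 1.0
        assert abs(first_neg - n_star) <= 2.0


class TestExactMFPT:
    def test_single_individual_geometric_waiting(self):
        # N=1: the only transition is loss at rate u per step
        tc = TwoClassParams(N=1, u=0.2, s_eff=0.5)
        r = build_rates(tc)
        assert exact_mfpt(r, 1) == pytest.approx(1.0 / 0.2, rel=1e-12)

    @pytest.mark.parametrize("lam0", [0.1, 0.3, 0.6])
    @pytest.mark.parametrize("s_eff", [0.05, 0.1, 0.2])
    def test_matches_linear_system_oracle(self, lam0, s_eff):
        tc = TwoClassParams(N=150, u=lam0 * s_eff, s_eff=s_eff)
        r = build_rates(tc)
        T = mfpt_linear_solve(r)
        for n0 in (1, default_n0(tc), 150):
            assert exact_mfpt(r, n0) == pytest.approx(T[n0 - 1], rel=1e-9)

    def test_monotone_in_initial_count(self):
        tc = TwoClassParams(N=60, u=0.02, s_eff=0.1)
        r = build_rates(tc)
        values = [exact_mfpt(r, n0) for n0 in range(1, 61)]
        assert np.all(np.diff(values) >= -1e-9)

    def test_unreachable_absorption_is_infinite(self):
        # u = 0 from the top state: the chain can never leave n = N
        tc = TwoClassParams(N=10, u=0.0, s_eff=0.2)
        r = build_rates(tc)
        assert exact_mfpt(r, 10) == np.inf

    def test_invalid_n0(self, tc_canonical):
        r = build_rates(tc_canonical)
        with pytest.raises(ValueError):
            exact_mfpt(r, 0)


class TestQSDEigen:
    def test_rate_matches_inverse_mfpt_in_rare_regime(self, tc_canonical):
        r = build_rates(tc_canonical)
        rate, _ = qsd_eigen(r)
        mte = exact_mfpt(r)
        assert rate * mte == pytest.approx(1.0, rel=0.01)

    def test_flux_identity(self, tc_canonical):
        # decay rate equals the probability flux into the absorbing state
        r = build_rates(tc_canonical)
        rate, table = qsd_eigen(r)
        assert table.flags["flux_rate"] == pytest.approx(rate, rel=1e-6)

    def test_qsd_normalised_and_peaked_at_fixed_point(self, tc_canonical):
        r = build_rates(tc_canonical)
        _, table = qsd_eigen(r)
        assert table.mass.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(table.mass >= 0.0)
        # sharply peaked around N x*: the finite-N prefactor skews the mode
        # by O(1/s_eff) individuals, well inside one Gaussian peak width
        # sqrt(N / S''(x*))
        from ratchet.wkb import action_curvature

        width = np.sqrt(tc_canonical.N / action_curvature(tc_canonical.x_star,
                                                          tc_canonical))
        assert abs(table.mode() - tc_canonical.N * tc_canonical.x_star) < width

    def test_dense_cap(self):
        tc = TwoClassParams(N=6000, u=0.03, s_eff=0.1)
        with pytest.raises(ValueError):
            qsd_eigen(build_rates(tc))


class TestMasterEquation:
    def test_probability_conserved_over_many_steps(self):
        tc = TwoClassParams(N=60, u=0.06, s_eff=0.15)
        r = build_rates(tc)
        p0 = np.zeros(61)
        p0[default_n0(tc)] = 1.0
        out = evolve_master(r, p0, n_steps=1_000_000)
        assert abs(out["total"] - 1.0) < 1e-10

    def test_late_time_survival_decays_at_eigen_rate(self):
        # ln-survival slope over t in [2, 5] MTE matches the dominant
        # eigenvalue to < 2%
        tc = TwoClassParams(N=60, u=0.06, s_eff=0.15)
        r = build_rates(tc)
        rate, _ = qsd_eigen(r)
        mte_steps = exact_mfpt(r) * tc.N
        p0 = np.zeros(61)
        p0[default_n0(tc)] = 1.0
        record = max(int(mte_steps // 50), 1)
        out = evolve_master(r, p0, n_steps=int(5.2 * mte_steps), record_every=record)
        t = np.arange(1, len(out["survival"]) + 1) * record
        mask = (t >= 2 * mte_steps) & (t <= 5 * mte_steps)
        slope = np.polyfit(t[mask], np.log(out["survival"][mask]), 1)[0]
        fitted_rate = -slope * tc.N  # per generation
        assert fitted_rate == pytest.approx(rate, rel=0.02)


class TestMonteCarlo:
    def test_mean_matches_exact_mfpt(self):
        tc = TwoClassParams(N=50, u=0.045, s_eff=0.15)
        sample = mc_click_times(tc, reps=2000, seed=3)
        mte = exact_mfpt(build_rates(tc))
        assert sample.censored == 0
        assert abs(sample.mean - mte) < 3 * sample.se

    def test_jump_chain_equals_per_step(self):
        tc = TwoClassParams(N=50, u=0.045, s_eff=0.15)
        a = mc_click_times(tc, reps=1500, seed=5, jump_chain=True)
        b = mc_click_times(tc, reps=1500, seed=6, jump_chain=False)
        z = abs(a.mean - b.mean) / np.hypot(a.se, b.se)
        assert z < 3.0

    def test_seed_determinism(self):
        tc = TwoClassParams(N=40, u=0.05, s_eff=0.2)
        a = mc_click_times(tc, reps=200, seed=11)
        b = mc_click_times(tc, reps=200, seed=11)
        np.testing.assert_array_equal(a.times, b.times)

    def test_censoring_when_absorption_blocked(self):
        # u = 0 starting from the top: no route to n = 0
        tc = TwoClassParams(N=20, u=0.0, s_eff=0.2)
        sample = mc_click_times(tc, n0=20, reps=10, seed=1, max_steps=5000)
        assert sample.censored == 10
        assert sample.n == 0
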