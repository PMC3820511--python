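"""WKB analytics: action, QSDs, click rates, scaling form."""

import math
import warnings

import numpy as np
import pytest
from scipy.integrate import quad

from ratchet import (
    RegimeWarning,
    TwoClassParams,
    build_rates,
    exact_mfpt,
    haigh_factor,
    qsd_eigen,
    scaling_form,
    total_variation,
    wkb_action,
    wkb_mte,
    wkb_mte_simplified,
    wkb_qsd,
)
from ratchet.wkb import action_derivative


@pytest.fixture
def tc300():
    return TwoClassParams(N=300, u=0.03, s_eff=0.1)


class TestAction:
    def test_derivative_vanishes_at_fixed_point(self, tc300):
        assert action_derivative(tc300.x_star, tc300) == pytest.approx(0.0, abs=1e-14)

    def test_action_is_minimal_at_fixed_point(self, tc300):
        # strictly decreasing below x*, strictly increasing above
        grid = np.linspace(0.01, 1.0, 100)
        S = wkb_action(tc300, grid)
        below = grid < tc300.x_star
        assert np.all(np.diff(S[below]) < 0)
        assert np.all(np.diff(S[~below][1:]) > 0)
        assert wkb_action(tc300, [tc300.x_star])[0] == pytest.approx(0.0, abs=1e-14)

    def test_closed_form_matches_quadrature(self, tc300):
        grid = np.linspace(0.02, 0.99, 100)
        closed = wkb_action(tc300, grid)
        quadr = wkb_action(tc300, grid, method="quad")
        assert np.max(np.abs(closed - quadr)) < 1e-10

    def test_degenerate_slope_case(self):
        # u + s_eff = 1 hits the b = 0 branch of the antiderivative
        tc = TwoClassParams(N=50, u=0.4, s_eff=0.6)
        grid = np.linspace(0.05, 0.9, 20)
        closed = wkb_action(tc, grid)
        direct = np.array(
            [quad(action_derivative, tc.x_star, x, args=(tc,), epsabs=1e-13)[0]
             for x in grid]
        )
        assert np.max(np.abs(closed - direct)) < 1e-10

    def test_no_metastable_state_rejected(self):
        tc = TwoClassParams(N=50, u=0.3, s_eff=0.2)  # u >= s_eff
        with pytest.raises(ValueError, match="metastable"):
            wkb_action(tc, [0.5])


class TestQSD:
    def test_leading_order_peaks_at_fixed_point(self, tc300):
        table = wkb_qsd(tc300, order="leading")
        assert table.mode() == round(tc300.N * tc300.x_star)
        assert table.mass.sum() == pytest.approx(1.0, abs=1e-12)

    def test_prefactor_qsd_close_to_eigen_oracle(self, tc300):
        pref = wkb_qsd(tc300, order="prefactor")
        _, eig = qsd_eigen(build_rates(tc300))
        assert total_variation(pref, eig) < 0.05

    def test_prefactor_correction_improves_on_leading(self, tc300):
        # the 1/N correction helps, especially in the non-Gaussian tails
        _, eig = qsd_eigen(build_rates(tc300))
        tv_lead = total_variation(wkb_qsd(tc300, "leading"), eig)
        tv_pref = total_variation(wkb_qsd(tc300, "prefactor"), eig)
        assert tv_pref < tv_lead

    def test_out_of_regime_warns(self):
        tc = TwoClassParams(N=30, u=0.09, s_eff=0.1)  # x* = 0.1, near boundary
        with pytest.warns(RegimeWarning):
            table = wkb_qsd(tc, order="prefactor")
        assert not table.flags["in_regime"]


class TestMTE:
    def test_log_rate_matches_exact_solution(self, tc300):
        res = wkb_mte(tc300)
        mte_exact = exact_mfpt(build_rates(tc300))
        assert abs(math.log(res.mte) - math.log(mte_exact)) / math.log(
            mte_exact
        ) < 0.02

    def test_leading_order_is_exponentially_accurate_only(self):
        # the leading-order rate ratio drifts from 1 with N while the
        # log-rates of the matched solution converge
        ratios, log_errors = [], []
        for N in (100, 200, 400):
            tc = TwoClassParams(N=N, u=0.03, s_eff=0.1)
            res = wkb_mte(tc)
            mte_exact = exact_mfpt(build_rates(tc))
            ratios.append(res.extras["rate_leading"] * mte_exact)
            log_errors.append(
                abs(math.log(res.mte) - math.log(mte_exact)) / math.log(mte_exact)
            )
        assert abs(ratios[2] - 1.0) > abs(ratios[0] - 1.0)  # prefactor matters
        assert log_errors[2] < log_errors[0]  # exponent converges

    def test_mte_increases_with_population_size(self):
        a = wkb_mte(TwoClassParams(N=100, u=0.03, s_eff=0.1))
        b = wkb_mte(TwoClassParams(N=200, u=0.03, s_eff=0.1))
        assert b.mte > a.mte

    def test_deterministic(self, tc300):
        a, b = wkb_mte(tc300), wkb_mte(tc300)
        assert a.mte == b.mte and a.extras == b.extras


class TestSimplified:
    def test_agrees_with_full_in_asymptotic_regime(self):
        # small s_eff at fixed N s_eff = 30 and lam0 = 0.3
        tc = TwoClassParams(N=12000, u=0.3 * 0.0025, s_eff=0.0025)
        res = wkb_mte_simplified(tc)
        assert abs(res.extras["deviation_vs_full"]) < 0.05

    def test_validity_boundary_documented(self):
        # at N s_eff ~ 2 the closed form is far from the matched solution
        tc = TwoClassParams(N=800, u=0.3 * 0.0025, s_eff=0.0025)
        with pytest.warns(RegimeWarning):
            res = wkb_mte_simplified(tc)
        assert abs(res.extras["deviation_vs_full"]) > 0.05

    def test_selection_sets_the_timescale(self):
        # at fixed (N s_eff, lam0) the MTE in generations scales as 1/s_eff
        a = wkb_mte_simplified(TwoClassParams(N=600, u=0.015, s_eff=0.05))
        b = wkb_mte_simplified(TwoClassParams(N=1200, u=0.0075, s_eff=0.025))
        assert b.mte / a.mte == pytest.approx(2.0, rel=1e-12)


class TestScalingForm:
    def test_reconstruction_identity(self):
        tc = TwoClassParams(N=500, u=0.02, s_eff=0.08)
        parts = scaling_form(tc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RegimeWarning)
            res = wkb_mte_simplified(tc)
        assert parts["prefactor"] * math.exp(parts["exponent"]) == res.mte

    def test_haigh_factor_decreasing(self):
        grid = np.linspace(0.01, 0.6, 20)
        values = [haigh_factor(l0) for l0 in grid]
        assert np.all(np.diff(values) < 0)

    def test_haigh_factor_small_lam0_limit(self):
        # finite positive limit 1 as lam0 -> 0; passes through the classical
        # ad hoc range 0.5-0.6 around lam0 ~ 0.25
        seq = [haigh_factor(l0) for l0 in (0.1, 0.01, 0.001, 1e-6)]
        assert np.all(np.diff(seq) > 0)
        assert seq[-1] == pytest.approx(1.0, abs=1e-4)
        assert 0.5 < haigh_factor(0.25) < 0.6
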