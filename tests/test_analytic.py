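"""Analytic inheritance models: closed forms, expansions, exact sums, oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitopart import (
    BetaNetworkParams,
    DivisionParams,
    GeneticParams,
    GrowthParams,
    ModelSpec,
    PlacementParams,
    binomial_null,
    brute_force_enumeration,
    closed_form_copy_number,
    closed_form_heteroplasmy,
    exact_moments_sum,
    fit_beta,
    joint_moments,
    moments_random,
    moments_repulsive,
    run_ensemble,
    taylor_first_order,
    taylor_second_order,
)
from mitopart.division import _var_se


class TestBinomialNull:
    def test_symmetric_division(self):
        pred = binomial_null(100, 0.5, 0.5)
        assert pred.V_N == pytest.approx(25.0)
        assert pred.Vp_h == pytest.approx(0.01)
        assert pred.E_N == pytest.approx(50.0)

    def test_asymmetric_division(self):
        pred = binomial_null(100, 0.5, 0.1)
        assert pred.V_N == pytest.approx(9.0)
        assert pred.Vp_h == pytest.approx(0.09)

    def test_near_deterministic_inheritance_vanishes(self):
        pred = binomial_null(100, 0.5, 1.0 - 1e-9)
        assert pred.V_N == pytest.approx(0.0, abs=1e-6)
        assert pred.Vp_h == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("h,p_c", [(0.0, 0.5), (1.0, 0.5), (0.5, 0.0), (0.5, 1.0)])
    def test_boundary_parameters_rejected(self, h, p_c):
        with pytest.raises(ValueError):
            binomial_null(100, h, p_c)


class TestFitBeta:
    def test_uniform_distribution(self):
        bp = fit_beta(0.5, 1.0 / 12.0)
        assert bp.alpha == pytest.approx(1.0, abs=1e-12)
        assert bp.beta == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_shape_two(self):
        bp = fit_beta(0.5, 0.05)
        assert bp.alpha == pytest.approx(2.0, abs=1e-12)
        assert bp.beta == pytest.approx(2.0, abs=1e-12)

    def test_infeasible_variance(self):
        with pytest.raises(ValueError):
            fit_beta(0.5, 0.3)

    @given(
        E_U=st.floats(0.01, 0.99),
        frac=st.floats(0.01, 0.99),
    )
    @settings(max_examples=200, derandomize=True)
    def test_roundtrip(self, E_U, frac):
        V_U = frac * E_U * (1.0 - E_U)
        bp = fit_beta(E_U, V_U)
        assert bp.E_U == pytest.approx(E_U, abs=1e-12)
        assert bp.V_U == pytest.approx(V_U, abs=1e-12)


class TestMomentsRandom:
    def test_degenerate_u_reduces_to_binomial(self):
        spec = ModelSpec(N0=100, h=0.5, p=1.0, q=0.0, p_c=0.5, beta_params=None)
        cm = moments_random(spec)
        assert cm.V_Wn == pytest.approx(50 * 0.25)
        assert cm.cov_WnMn == 0.0

    def test_shared_u_covariance(self):
        # w_n = m_n = 50, V(U) = 0.01 -> Cov(W_n, M_n) = 25
        bp = fit_beta(0.5, 0.01)
        spec = ModelSpec(N0=100, h=0.5, p=1.0, q=1.0, p_c=0.5, beta_params=bp)
        cm = moments_random(spec)
        assert cm.cov_WnMn == pytest.approx(25.0)

    def test_single_trial_is_bernoulli(self):
        bp = fit_beta(0.4, 0.02)
        spec = ModelSpec(N0=2, h=0.5, p=1.0, q=0.0, p_c=0.4, beta_params=bp)
        cm = moments_random(spec)  # w_n = 1
        assert cm.V_Wn == pytest.approx(0.4 * 0.6)


class TestMomentsRepulsive:
    def test_all_spaces_filled_is_deterministic(self):
        # degenerate U at p_c = 0.5, spaces_total = 40 -> d = 20 = w_n + m_n
        spec = ModelSpec(N0=20, h=0.5, p=1.0, q=1.0, p_c=0.5,
                         mode="repulsive", spaces_total=40)
        cm = moments_repulsive(spec)
        assert cm.E_Wn == pytest.approx(10.0)
        assert cm.V_Wn == pytest.approx(0.0, abs=1e-12)
        assert cm.cov_WnMn == pytest.approx(0.0, abs=1e-12)

    def test_partial_draw_hypergeometric_mean(self):
        # degenerate U at 0.5, spaces_total = 16 -> d = 8 of 20 networked
        spec = ModelSpec(N0=20, h=0.5, p=1.0, q=1.0, p_c=0.5,
                         mode="repulsive", spaces_total=16)
        cm = moments_repulsive(spec)
        assert cm.E_Wn == pytest.approx(8 * 10 / 20)

    def test_against_monte_carlo_oracle(self):
        bp = fit_beta(0.5, 0.05)
        spec = ModelSpec(N0=10, h=0.5, p=1.0, q=1.0, p_c=0.5, beta_params=bp,
                         mode="repulsive", spaces_total=10)
        cm = moments_repulsive(spec)
        rng = np.random.default_rng(7)
        n = 1_000_000
        u = rng.beta(bp.alpha, bp.beta, size=n)
        d = np.minimum(np.floor(u * 10).astype(int), 10)
        wn = rng.hypergeometric(5, 5, d)
        mn = d - wn
        assert cm.E_Wn == pytest.approx(wn.mean(), abs=3 * wn.std() / math.sqrt(n))
        assert cm.V_Wn == pytest.approx(wn.var(), abs=3 * _var_se(wn.astype(float)))
        assert cm.cov_WnMn == pytest.approx(np.cov(wn, mn)[0, 1], abs=0.01)

    def test_requires_spaces(self):
        with pytest.raises(ValueError):
            ModelSpec(N0=10, h=0.5, p=1, q=1, mode="repulsive")


class TestTaylorFirstOrder:
    def test_recovers_binomial_null(self):
        spec = ModelSpec(N0=100, h=0.5, p=0.0, q=0.0, p_c=0.3, beta_params=None)
        pred = taylor_first_order(moments_random(spec), 0.5)
        assert pred.Vp_h == pytest.approx((1 - 0.3) / (0.3 * 100), abs=1e-12)

    def test_matches_closed_form_heteroplasmy(self, rng):
        for _ in range(20):
            N0 = int(rng.integers(10, 1500))
            h = rng.uniform(0.05, 0.95)
            p, q = rng.uniform(0, 1, 2)
            p_c = rng.uniform(0.05, 0.95)
            bp = fit_beta(p_c, rng.uniform(1e-5, 0.5 * p_c * (1 - p_c)))
            spec = ModelSpec(N0=N0, h=h, p=p, q=q, p_c=p_c, beta_params=bp)
            pred = taylor_first_order(moments_random(spec), h)
            assert pred.Vp_h == pytest.approx(closed_form_heteroplasmy(spec), abs=1e-10)

    def test_negative_covariance_coefficient(self):
        """Holding variances fixed, decreasing Cov(W, M) increases V(h)."""
        from mitopart.analytic import ComponentMoments

        base = dict(E_Wn=25, V_Wn=10, E_Wc=0, V_Wc=0, E_Mn=25, V_Mn=10,
                    E_Mc=0, V_Mc=0)
        covs = [5.0, 0.0, -5.0]
        vhs = [taylor_first_order(ComponentMoments(**base, cov_WnMn=c), 0.5).V_h
               for c in covs]
        assert vhs[0] < vhs[1] < vhs[2]


class TestClosedForms:
    def test_no_network_reduces_to_binomial(self):
        spec = ModelSpec(N0=100, h=0.5, p=0.0, q=0.0, p_c=0.5,
                         beta_params=fit_beta(0.5, 0.01))
        assert closed_form_copy_number(spec) == pytest.approx(25.0)
        assert closed_form_heteroplasmy(spec) == pytest.approx(0.01)

    def test_copy_number_arithmetic(self):
        # kappa = 1: V(N) = 25 + 100*99*0.01 = 124
        spec = ModelSpec(N0=100, h=0.5, p=1.0, q=1.0, p_c=0.5,
                         beta_params=fit_beta(0.5, 0.01))
        assert closed_form_copy_number(spec) == pytest.approx(124.0)

    def test_maximum_variance_case(self):
        # (p, q) = (1, 0): V'(h) = 1/N0 + 4 V(U) (h(1-h) - h/N0) = 0.0198
        spec = ModelSpec(N0=100, h=0.5, p=1.0, q=0.0, p_c=0.5,
                         beta_params=fit_beta(0.5, 0.01))
        assert closed_form_heteroplasmy(spec) == pytest.approx(0.0198)

    def test_unbiased_inclusion_prediction(self):
        # p = q at p_c = 1/2: V'(h) = 1/N0 - 4 p V(U) / N0
        N0, p, V_U = 200, 0.7, 0.008
        spec = ModelSpec(N0=N0, h=0.3, p=p, q=p, p_c=0.5,
                         beta_params=fit_beta(0.5, V_U))
        assert closed_form_heteroplasmy(spec) == pytest.approx(
            1 / N0 - 4 * p * V_U / N0, abs=1e-12
        )

    def test_bias_growth_in_inclusion_difference(self):
        """V'(h) strictly increases with (p - q)^2 at large N0."""
        bp = fit_beta(0.5, 0.01)
        diffs = np.linspace(0.0, 1.0, 6)
        vals = [
            closed_form_heteroplasmy(
                ModelSpec(N0=1000, h=0.5, p=0.5 + d / 2, q=0.5 - d / 2, p_c=0.5,
                          beta_params=bp)
            )
            for d in diffs
        ]
        assert np.all(np.diff(vals) > 0)


class TestExactSum:
    def test_null_mode_copy_number(self):
        spec = ModelSpec(N0=100, h=0.5, p=0.0, q=0.0, p_c=0.3, mode="null")
        pred = exact_moments_sum(spec, 64, check_convergence=False)
        assert pred.V_N == pytest.approx(100 * 0.3 * 0.7, abs=1e-9)

    def test_genotype_exchange_symmetry(self):
        bp = BetaNetworkParams(3.0, 3.0)
        spec = ModelSpec(N0=50, h=0.5, p=0.7, q=0.7, p_c=0.5, beta_params=bp)
        pred = exact_moments_sum(spec, 64, check_convergence=False)
        assert pred.E_h == pytest.approx(0.5, abs=1e-9)

    def test_matches_enumeration_oracle(self):
        bp = fit_beta(0.5, 0.05)
        spec = ModelSpec(N0=6, h=0.5, p=1.0, q=0.5, p_c=0.5, beta_params=bp)
        a = exact_moments_sum(spec, 64, check_convergence=False)
        b = brute_force_enumeration(spec, 64)
        for attr in ("E_N", "V_N", "E_h", "V_h"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr), abs=1e-9)

    def test_zero_atom_mass_reported(self):
        spec = ModelSpec(N0=4, h=0.5, p=0.0, q=0.0, p_c=0.5, mode="null")
        pred = exact_moments_sum(spec, 64, check_convergence=False)
        assert pred.extras["p_zero"] == pytest.approx(0.5**4, abs=1e-12)

    def test_refuses_oversize(self):
        with pytest.raises(ValueError):
            exact_moments_sum(ModelSpec(N0=6000, h=0.5, p=0, q=0, mode="null"))


class TestEnumeration:
    def test_two_molecule_deterministic_network(self):
        # N0=2, p=q=1, U degenerate at 0.5: each molecule inherited w.p. 1/2
        spec = ModelSpec(N0=2, h=0.5, p=1.0, q=1.0, p_c=0.5, beta_params=None)
        pred = brute_force_enumeration(spec, 64)
        assert pred.E_N == pytest.approx(1.0, abs=1e-12)

    def test_two_coin_flips(self):
        spec = ModelSpec(N0=2, h=0.5, p=0.0, q=0.0, p_c=0.5, beta_params=None)
        pred = brute_force_enumeration(spec, 64)
        assert pred.V_N == pytest.approx(0.5, abs=1e-12)
        assert pred.extras["p_zero"] == pytest.approx(0.25, abs=1e-12)

    def test_refuses_large_populations(self):
        with pytest.raises(ValueError):
            brute_force_enumeration(ModelSpec(N0=13, h=0.5, p=0, q=0, mode="null"))


class TestTaylorSecondOrder:
    def test_close_to_exact_for_binomial_null(self):
        spec = ModelSpec(N0=100, h=0.5, p=0.0, q=0.0, p_c=0.5, mode="null")
        t2 = taylor_second_order(joint_moments(spec), 0.5)
        ex = exact_moments_sum(spec, 64, check_convergence=False)
        assert t2.Vp_h == pytest.approx(ex.Vp_h, rel=0.05)

    def test_compensatory_diagonal_term(self):
        """On the p = q diagonal the second-order correction is positive,
        opposing the first-order -4 p V(U)/N0 shift."""
        bp = fit_beta(0.5, 0.01)
        spec = ModelSpec(N0=100, h=0.5, p=0.8, q=0.8, p_c=0.5, beta_params=bp)
        t1 = taylor_first_order(moments_random(spec), 0.5)
        t2 = taylor_second_order(joint_moments(spec), 0.5)
        assert t1.Vp_h < 0.01  # first order dips below the null on the diagonal
        assert t2.Vp_h > t1.Vp_h

    def test_correction_scales_as_inverse_square_copy_number(self):
        devs = {}
        for N0 in (10, 100):
            spec = ModelSpec(N0=N0, h=0.5, p=0.0, q=0.0, p_c=0.5, mode="null")
            t1 = taylor_first_order(moments_random(
                ModelSpec(N0=N0, h=0.5, p=0.0, q=0.0, p_c=0.5, beta_params=None)), 0.5)
            t2 = taylor_second_order(joint_moments(spec), 0.5)
            devs[N0] = abs(t2.Vp_h - t1.Vp_h)
        # O(1/N0^2): two orders of magnitude over a tenfold N0 increase
        ratio = devs[10] / devs[100]
        assert 30 < ratio < 300


class TestTaylorFailureModes:
    def test_asymmetric_division_underestimates_heteroplasmy_variance(self):
        """At p_c = 0.1 the first-order expansion falls short of the exact sum."""
        bp = fit_beta(0.1, 0.005)
        spec = ModelSpec(N0=100, h=0.5, p=1.0, q=0.0, p_c=0.1, beta_params=bp)
        t1 = taylor_first_order(moments_random(spec), 0.5)
        ex = exact_moments_sum(spec, 128, check_convergence=False)
        assert ex.V_h > t1.V_h


class TestMomentFidelity:
    def test_component_moments_match_simulation(self, rng):
        """Theory (with the sim-fitted Beta) reproduces simulated W/M moments."""
        summary, samples = run_ensemble(
            GrowthParams(s=16), GeneticParams(100, 0.5, 1.0, 0.5),
            PlacementParams(), None, DivisionParams(180.0),
            n_reps=20_000, rng=rng, return_samples=True,
        )
        bp = fit_beta(summary.E_U, summary.V_U)
        cm = moments_random(
            ModelSpec(N0=100, h=0.5, p=1.0, q=0.5, p_c=0.5, beta_params=bp)
        )
        n = len(samples)
        W = samples["W"].to_numpy(float)
        M = samples["M"].to_numpy(float)
        assert cm.E_W == pytest.approx(W.mean(), abs=3.5 * W.std() / math.sqrt(n))
        assert cm.E_M == pytest.approx(M.mean(), abs=3.5 * M.std() / math.sqrt(n))
        assert cm.V_W == pytest.approx(W.var(ddof=1), abs=3.5 * _var_se(W))
        assert cm.V_M == pytest.approx(M.var(ddof=1), abs=3.5 * _var_se(M))
        # covariance SE approximated via the delta method on products
        prod = (W - W.mean()) * (M - M.mean())
        assert cm.cov_WM == pytest.approx(
            np.cov(W, M)[0, 1], abs=3.5 * prod.std() / math.sqrt(n)
        )
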