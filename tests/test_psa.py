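"""Monte Carlo sensitivity analysis: priors, propagation, CEAC, CE plane."""

import numpy as np
import pytest
from scipy import stats

from asthmaecon import (
    StrategyDistributions,
    StrategyParams,
    UtilityModel,
    ceac,
    ce_plane_summary,
    datasets,
    dirichlet_from_counts,
    fit_gamma_from_moments,
    run_psa,
)
from asthmaecon.psa import PSAResult, deterministic_delta


def _strategy(label="S", costs=(100.0, 50.0, 10.0), probs=(0.2, 0.3, 0.5),
              basis="medication"):
    um = UtilityModel()
    return StrategyParams(
        label=label,
        state_costs=costs,
        state_probs=probs,
        state_utilities=tuple(float(u) for u in um.state_utilities()),
        cost_basis=basis,
        prob_tol=1e-6,
    )


class TestGammaFit:
    def test_round_numbers(self):
        d = fit_gamma_from_moments(100.0, 10.0)
        assert d.shape == pytest.approx(100.0)
        assert d.scale == pytest.approx(1.0)

    def test_study_inpatient_medication_shape(self):
        d = fit_gamma_from_moments(1982.34, 1863.04)
        assert d.shape == pytest.approx((1982.34 / 1863.04) ** 2, rel=1e-12)
        assert d.shape == pytest.approx(1.132, abs=5e-3)

    def test_moment_round_trip_exact(self):
        """Analytic mean/variance of the fit equal the inputs exactly."""
        for mean, sd in [(1.0, 0.3), (5291.53, 900.0), (0.02, 0.5)]:
            d = fit_gamma_from_moments(mean, sd)
            assert d.shape * d.scale == pytest.approx(mean, rel=1e-12)
            assert d.shape * d.scale**2 == pytest.approx(sd**2, rel=1e-12)

    def test_sampled_mean_matches_input(self):
        d = fit_gamma_from_moments(1982.34, 1863.04)
        draws = d.sample(np.random.default_rng(7), 1_000_000)
        assert draws.mean() == pytest.approx(1982.34, rel=0.01)

    def test_nonpositive_moments_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma_from_moments(0.0, 1.0)
        with pytest.raises(ValueError):
            fit_gamma_from_moments(1.0, -1.0)


class TestDirichlet:
    def test_marginal_means_are_visit_shares(self):
        d = dirichlet_from_counts((8, 8, 30))
        draws = d.sample(np.random.default_rng(0), 200_000)
        assert draws.mean(axis=0) == pytest.approx((0.1739, 0.1739, 0.6522), abs=2e-3)
        assert np.allclose(draws.sum(axis=1), 1.0)

    def test_uniform_simplex(self):
        d = dirichlet_from_counts((1, 1, 1))
        draws = d.sample(np.random.default_rng(1), 100_000)
        assert draws.mean(axis=0) == pytest.approx((1 / 3,) * 3, abs=5e-3)

    def test_marginal_sd_matches_beta_closed_form(self):
        """Each marginal is Beta(c_i, total - c_i); sds agree within 2%."""
        counts = (22, 47, 275)
        total = sum(counts)
        d = dirichlet_from_counts(counts)
        draws = d.sample(np.random.default_rng(2), 100_000)
        for i, c in enumerate(counts):
            expect = stats.beta(c, total - c).std()
            assert draws[:, i].std() == pytest.approx(expect, rel=0.02)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError, match="zero count"):
            dirichlet_from_counts((0, 1, 2))

    def test_beta_mode_draws_stay_on_simplex(self):
        s = _strategy(probs=tuple(datasets.study_probabilities("A1")))
        d = StrategyDistributions.from_params(
            s, counts=(8, 8, 30), prob_mode="beta"
        )
        draws = d.prob_dist.sample(np.random.default_rng(3), 10_000)
        assert np.allclose(draws.sum(axis=1), 1.0)
        assert draws.mean(axis=0) == pytest.approx((0.1739, 0.1739, 0.6522), abs=0.01)


class TestRunPSA:
    def test_degenerate_distributions_reproduce_base_case(self):
        ref, alt = _strategy("r"), _strategy("a", costs=(120.0, 60.0, 20.0))
        dr = StrategyDistributions.from_params(ref, vary_costs=False, vary_probs=False)
        da = StrategyDistributions.from_params(alt, vary_costs=False, vary_probs=False)
        res = run_psa(dr, da, n=200, seed=5)
        dc, du = deterministic_delta(ref, alt)
        assert np.allclose(res.delta_cost, dc)
        assert np.allclose(res.delta_utility, du)

    def test_same_seed_bit_identical(self):
        strategies = {s.label: s for s in datasets.study_strategies("medication")}
        def dists(lab):
            return StrategyDistributions.from_params(
                strategies[lab],
                cost_sds=datasets.STATE_COST_SDS["medication"][lab],
                counts=datasets.VISIT_COUNTS[lab],
            )
        r1 = run_psa(dists("A"), dists("B"), n=500, seed=11)
        r2 = run_psa(dists("A"), dists("B"), n=500, seed=11)
        assert np.array_equal(r1.draws, r2.draws)
        r3 = run_psa(dists("A"), dists("B"), n=500, seed=12)
        assert not np.array_equal(r1.draws, r3.draws)

    def test_mean_incremental_utility_near_base_case(self):
        """At n = 1000 the A-vs-B utility gain is near the deterministic 0.47."""
        strategies = {s.label: s for s in datasets.study_strategies("medication")}
        def dists(lab):
            return StrategyDistributions.from_params(
                strategies[lab],
                cost_sds=datasets.STATE_COST_SDS["medication"][lab],
                counts=datasets.VISIT_COUNTS[lab],
            )
        res = run_psa(dists("A"), dists("B"), n=1000, seed=0)
        du = res.delta_utility
        mc_err = 3 * du.std() / np.sqrt(len(du))
        assert abs(du.mean() - 0.47) < mc_err + 0.01

    def test_mean_error_shrinks_with_n(self):
        """Root-n convergence of the draw mean to the deterministic dC."""
        strategies = {s.label: s for s in datasets.study_strategies("ics")}
        def dists(lab):
            return StrategyDistributions.from_params(
                strategies[lab],
                cost_sds=datasets.STATE_COST_SDS["ics"][lab],
                counts=datasets.VISIT_COUNTS[lab],
            )
        dc, _ = deterministic_delta(strategies["A"], strategies["B"])
        errs = {}
        for n in (200, 20_000):
            reps = [
                abs(run_psa(dists("A"), dists("B"), n=n, seed=s).delta_cost.mean() - dc)
                for s in range(5)
            ]
            errs[n] = np.mean(reps)
        assert errs[20_000] < errs[200]

    def test_parameter_streams_stable_under_extension(self):
        """Fixing one parameter does not reshuffle the draws of the others."""
        s = _strategy()
        full = StrategyDistributions.from_params(s, cv=0.3, counts=(5, 5, 10))
        fixed_probs = StrategyDistributions.from_params(s, cv=0.3, counts=None)
        base = _strategy("base")
        dr = StrategyDistributions.from_params(base, vary_costs=False)
        r_full = run_psa(dr, full, n=100, seed=3)
        r_fixed = run_psa(dr, fixed_probs, n=100, seed=3)
        # cost draws shared; only the probability vector changed
        assert not np.array_equal(r_full.delta_cost, r_fixed.delta_cost)
        # re-running the full setup reproduces it exactly
        assert np.array_equal(r_full.draws, run_psa(dr, full, n=100, seed=3).draws)

    def test_mismatched_basis_rejected(self):
        r = StrategyDistributions.from_params(_strategy("r", basis="ics"))
        a = StrategyDistributions.from_params(_strategy("a", basis="medication"))
        with pytest.raises(ValueError, match="cost basis"):
            run_psa(r, a, n=10, seed=0)


class TestCEAC:
    def test_two_point_hand_example(self):
        res = PSAResult("r", "a", np.array([-1.0, 1.0]), np.array([0.1, 0.1]),
                        seed=0, n_iterations=2)
        grid, prob = ceac(res, [5.0])
        assert prob[0] == pytest.approx(0.5)

    def test_endpoints_match_quadrant_fractions(self):
        rng = np.random.default_rng(8)
        dc = rng.normal(100, 500, 2000)
        du = rng.normal(0.1, 0.3, 2000)
        res = PSAResult("r", "a", dc, du, seed=0, n_iterations=2000)
        _, p0 = ceac(res, [0.0])
        assert p0[0] == pytest.approx((dc < 0).mean())
        _, pinf = ceac(res, [1e12])
        assert pinf[0] == pytest.approx((du > 0).mean(), abs=1e-3)

    def test_monotone_when_all_gains_positive(self):
        rng = np.random.default_rng(9)
        dc = rng.normal(100, 500, 1000)
        du = np.abs(rng.normal(0.2, 0.1, 1000))
        res = PSAResult("r", "a", dc, du, seed=0, n_iterations=1000)
        _, prob = ceac(res, np.linspace(0, 1e5, 50))
        assert np.all(np.diff(prob) >= 0)

    def test_empty_grid_rejected(self):
        res = PSAResult("r", "a", np.zeros(3), np.zeros(3), seed=0, n_iterations=3)
        with pytest.raises(ValueError, match="empty WTP grid"):
            ceac(res, [])


class TestCEPlane:
    def test_normal_cloud_coverage(self):
        """The 95% normal-theory ellipse covers ~95% of normal draws."""
        rng = np.random.default_rng(10)
        cov = np.array([[4.0, 1.5], [1.5, 2.0]])
        xy = rng.multivariate_normal([10.0, 0.5], cov, size=10_000)
        res = PSAResult("r", "a", xy[:, 0], xy[:, 1], seed=0, n_iterations=10_000)
        summary = ce_plane_summary(res, confidence=0.95)
        assert summary.inside_fraction == pytest.approx(0.95, abs=0.01)

    def test_quadrant_shares_partition(self):
        rng = np.random.default_rng(11)
        res = PSAResult("r", "a", rng.normal(size=500), rng.normal(size=500),
                        seed=0, n_iterations=500)
        shares = ce_plane_summary(res).quadrant_shares
        assert sum(shares.values()) == pytest.approx(1.0)

    def test_degenerate_cloud(self):
        res = PSAResult("r", "a", np.full(10, 3.0), np.full(10, 0.2),
                        seed=0, n_iterations=10)
        summary = ce_plane_summary(res)
        assert summary.degenerate
        assert summary.inside_fraction == 1.0

    def test_too_few_draws_rejected(self):
        res = PSAResult("r", "a", np.zeros(2), np.zeros(2), seed=0, n_iterations=2)
        with pytest.raises(ValueError, match="at least 3"):
            ce_plane_summary(res)
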