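"""Unit and oracle tests for the three distance estimators."""

import warnings

import numpy as np
import pytest

from parityclock import (
    ContractError,
    EstimationError,
    GammaPrior,
    GammaRates,
    GridSpec,
    ParityProblem,
    bootstrap_sd,
    fit_conditional,
    fit_gamma_map,
    fit_mle,
    fit_nb_prior,
    sample_rates,
    simulate_counts,
    solve_site_rate,
)
from parityclock.estimators import _map_objective, _map_score, estimate
from parityclock.model import _site_loglik_terms


class TestSolveSiteRate:
    @pytest.mark.parametrize("p", [0.01, 0.1, 0.5, 2.0])
    def test_zero_count_odd_parity_closed_form(self, p):
        # maximising -lam + log(1 - e^{-2 lam p}) gives lam = log(1+2p)/(2p)
        assert solve_site_rate(0, 1, p) == pytest.approx(
            np.log(1.0 + 2.0 * p) / (2.0 * p), rel=1e-9
        )

    def test_even_parity_negligible_distance_recovers_poisson_mle(self):
        assert solve_site_rate(5, 0, 1e-8) == pytest.approx(5.0, abs=1e-4)

    @pytest.mark.parametrize("x, z, p", [(3, 1, 0.1), (7, 0, 0.25), (1, 1, 0.4)])
    def test_matches_fine_grid_argmax(self, x, z, p):
        lam_grid = np.arange(1e-4, 50.0, 1e-4)
        ll = _site_loglik_terms(np.array([x]), np.array([z]), lam_grid, p)
        lam_best = lam_grid[np.argmax(ll)]
        assert solve_site_rate(x, z, p) == pytest.approx(lam_best, abs=2e-4)

    def test_rejects_non_positive_p(self):
        with pytest.raises(ContractError):
            solve_site_rate(3, 0, 0.0)

    def test_even_parity_zero_count_boundary(self):
        assert solve_site_rate(0, 0, 0.3) == 0.0


class TestFitMle:
    def test_all_even_parity_hits_lower_boundary(self):
        prob = ParityProblem([3, 5, 2], [0, 0, 0])
        est = fit_mle(prob)
        assert est.boundary_hit
        assert est.p_hat == pytest.approx(GridSpec().p_min, rel=1e-6)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(EstimationError):
            fit_mle(ParityProblem([0, 0], [0, 1]))

    def test_single_site_matches_2d_brute_force(self):
        # joint maximisation over (p, lambda) on a fine 2-D grid
        prob = ParityProblem([4], [1])
        est = fit_mle(prob, GridSpec(1e-3, 1.0, 200))
        ps = np.arange(1e-3, 1.0 + 1e-9, 1e-3)
        lams = np.arange(1e-3, 10.0, 1e-3)
        best = (-np.inf, None, None)
        for p in ps:
            ll = _site_loglik_terms(np.array([4]), np.array([1]), lams, p)
            j = int(np.argmax(ll))
            if ll[j] > best[0]:
                best = (ll[j], p, lams[j])
        assert est.p_hat == pytest.approx(best[1], abs=1e-3)
        assert est.lambda_hat[0] == pytest.approx(best[2], abs=1e-3)

    def test_stationarity_identities_at_interior_optimum(self, large_problem):
        problem, _, _ = large_problem
        est = fit_mle(problem)
        assert not est.boundary_hit
        # first normal equation: rates sum to the count total
        assert est.diagnostics["rate_sum_gap"] < 1e-3
        assert abs(est.lambda_hat.sum() - problem.counts.sum()) / problem.counts.sum() < 1e-3
        # score in p vanishes (scaled by the count total)
        assert abs(est.diagnostics["p_score"]) / problem.counts.sum() < 1e-4

    def test_recovery_within_bootstrap_bands(self):
        """Over replicates at n=2000, the MLE stays within 3 empirical SDs."""
        p_true = 0.05
        rng = np.random.default_rng(123)
        estimates = []
        for _ in range(50):
            lam = sample_rates(GammaRates(), 2000, rng)
            prob = simulate_counts(lam, p_true, rng)
            estimates.append(fit_mle(prob).p_hat)
        estimates = np.array(estimates)
        sd = estimates.std(ddof=1)
        coverage = np.mean(np.abs(estimates - p_true) <= 3 * sd)
        assert coverage >= 0.9


class TestFitConditional:
    def test_no_mismatches_gives_zero_distance(self):
        est = fit_conditional(ParityProblem([1, 2, 3], [0, 0, 0]))
        assert est.p_hat == 0.0
        assert est.converged

    def test_unit_counts_closed_form(self):
        x = np.ones(100, dtype=int)
        z = np.zeros(100, dtype=int)
        z[:10] = 1
        est = fit_conditional(ParityProblem(x, z))
        assert est.p_hat == pytest.approx(0.1, abs=1e-9)

    def test_double_counts_closed_form(self):
        x = np.full(100, 2)
        z = np.zeros(100, dtype=int)
        z[:18] = 1
        est = fit_conditional(ParityProblem(x, z))
        assert est.p_hat == pytest.approx((1.0 - np.sqrt(0.64)) / 2.0, abs=1e-9)

    def test_saturated_parity_clamps_below_half(self):
        x = np.ones(20, dtype=int)
        z = np.ones(20, dtype=int)
        with pytest.warns(RuntimeWarning):
            est = fit_conditional(ParityProblem(x, z))
        assert est.boundary_hit
        assert not est.converged
        assert est.p_hat < 0.5

    def test_score_is_non_increasing_in_p(self, small_problem):
        xu, mult = np.unique(small_problem.counts, return_counts=True)
        ps = np.linspace(0.0, 0.499, 200)
        lhs = np.array([np.sum(mult * (1 - 2 * p) ** xu) for p in ps])
        assert np.all(np.diff(lhs) <= 1e-12)


class TestFitNbPrior:
    def test_recovers_generating_hyperparameters(self):
        # Gamma-Poisson mixture draws are marginally Negative Binomial
        rng = np.random.default_rng(31)
        lam = rng.gamma(shape=0.23, scale=1.0 / 0.164, size=15629)
        counts = rng.poisson(lam)
        prior = fit_nb_prior(counts)
        assert prior.alpha == pytest.approx(0.23, rel=0.15)
        assert prior.beta == pytest.approx(0.164, rel=0.15)
        assert not prior.underdispersed

    def test_underdispersed_counts_fall_back(self):
        counts = np.full(1000, 5)
        counts[0] = 6  # tiny jitter: variance << mean
        with pytest.warns(RuntimeWarning):
            prior = fit_nb_prior(counts)
        assert prior.underdispersed
        assert prior.mean == pytest.approx(counts.mean(), rel=1e-6)

    def test_poisson_limit_preserves_mean(self):
        rng = np.random.default_rng(77)
        counts = rng.poisson(2.0, size=10_000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prior = fit_nb_prior(counts)
        assert prior.mean == pytest.approx(2.0, rel=0.05)

    def test_constant_counts_rejected(self):
        with pytest.raises(ContractError):
            fit_nb_prior(np.full(10, 3))


class TestFitGammaMap:
    PRIOR = GammaPrior(alpha=0.23, beta=0.164)

    def test_no_mismatches_gives_zero_distance(self):
        est = fit_gamma_map(ParityProblem([2, 5], [0, 0]), self.PRIOR)
        assert est.p_hat == 0.0

    def test_matches_1d_grid_maximisation_at_boundary(self):
        # a lone odd-parity zero-count site drags the optimum to the
        # upper boundary: the grid argmax and the fit must agree there
        prob = ParityProblem([3, 0], [0, 1])
        est = fit_gamma_map(prob, self.PRIOR)
        ps = np.arange(1e-6, 20.0, 1e-4)
        xu = np.array([3.0, 0.0])
        zu = np.array([0, 1])
        mult = np.array([1.0, 1.0])
        objs = np.array([_map_objective(p, xu, zu, mult, 0.23, 0.164) for p in ps])
        p_grid = ps[int(np.argmax(objs))]
        assert est.p_hat == pytest.approx(p_grid, abs=1e-4 + 20.0 * 1e-6)
        assert est.boundary_hit and not est.converged

    def test_matches_1d_grid_maximisation_interior(self):
        prob = ParityProblem([3, 0, 2, 1], [1, 0, 0, 0])
        est = fit_gamma_map(prob, self.PRIOR)
        ps = np.arange(1e-6, 20.0, 1e-4)
        xu = np.array([3.0, 0.0, 2.0, 1.0])
        zu = np.array([1, 0, 0, 0])
        mult = np.ones(4)
        objs = np.array([_map_objective(p, xu, zu, mult, 0.23, 0.164) for p in ps])
        p_grid = ps[int(np.argmax(objs))]
        assert not est.boundary_hit
        assert est.p_hat == pytest.approx(p_grid, abs=1e-4)
        # stationarity residual of the score equation at the optimum
        assert abs(_map_score(est.p_hat, xu, zu, mult, 0.23, 0.164)) < 1e-6

    def test_recovery_on_large_instance(self, large_problem):
        problem, lam, p_true = large_problem
        est = fit_gamma_map(problem, self.PRIOR)
        from parityclock import crb_p

        sd = np.sqrt(crb_p(np.maximum(lam, 1e-9), p_true))
        assert est.p_hat == pytest.approx(p_true, abs=4 * sd)
        assert est.converged


class TestDispatchAndBootstrap:
    def test_unknown_method_rejected(self, small_problem):
        with pytest.raises(ContractError):
            estimate(small_problem, method="beast")

    @pytest.mark.parametrize("method", ["mle", "conditional", "gamma_map"])
    def test_dispatch_smoke(self, small_problem, method):
        est = estimate(small_problem, method=method)
        assert est.method == method
        assert est.p_hat >= 0

    def test_bootstrap_single_site_is_degenerate(self):
        prob = ParityProblem([3], [0])
        sd = bootstrap_sd(prob, method="conditional", B=10, seed=0)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_bootstrap_deterministic_under_seed(self, small_problem):
        a = bootstrap_sd(small_problem, method="conditional", B=25, seed=5)
        b = bootstrap_sd(small_problem, method="conditional", B=25, seed=5)
        assert a == b
        assert a > 0

    def test_bootstrap_requires_two_resamples(self, small_problem):
        with pytest.raises(ContractError):
            bootstrap_sd(small_problem, B=1)
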