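"""Dose transform, logistic curves, log posterior, sampler and posterior
functionals, cross-checked against brute-force and quadrature oracles."""

import numpy as np
import pytest

import r2dt
from r2dt.errors import ConfigError
from r2dt.model import (
    ModelParams,
    PriorSpec,
    TrialData,
    center_log_dose,
    dose_response_probs,
    expected_utilities,
    log_posterior,
    posterior_expected_utility,
    posterior_tail_probs,
    prob_efficacy,
    prob_toxicity,
    sample_posterior,
)

from _oracles import brute_log_posterior, quadrature_posterior_mean_eff, quadrature_tail_prob_eff
from conftest import FAST_MCMC


class TestDoseGrid:
    def test_default_grid_covariates(self, grid):
        assert grid.centered_log[0] == pytest.approx(-0.5037, abs=2e-4)
        assert grid.centered_log[-1] == pytest.approx(0.4126, abs=2e-4)
        assert grid.centered_log.sum() == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_pair(self):
        g = center_log_dose((10.0, 10.0 * np.e))
        assert g.centered_log == pytest.approx([-0.5, 0.5])

    @pytest.mark.parametrize("doses", [(10.0,), (0.0, 10.0), (30.0, 20.0), (20.0, 20.0)])
    def test_invalid_grids_rejected(self, doses):
        with pytest.raises(ConfigError):
            center_log_dose(doses)


class TestCurves:
    def test_null_params_give_half(self):
        theta = ModelParams(0, 0, 0, 0, 0)
        assert prob_efficacy(theta, 0.7) == pytest.approx(0.5)
        assert prob_toxicity(theta, -1.3) == pytest.approx(0.5)

    def test_linear_efficacy_value(self):
        theta = ModelParams(0, 1, 0, 0, 0)
        assert prob_efficacy(theta, 0.4126) == pytest.approx(0.6017, abs=1e-4)

    def test_negative_curvature_gives_interior_maximum(self):
        theta = ModelParams(0.0, 1.0, -2.0, 0.0, 1.0)
        fd = np.linspace(-2, 2, 401)
        pe = prob_efficacy(theta.as_array(), fd)
        argmax = fd[np.argmax(pe)]
        assert -2 < argmax < 2  # vertex of the quadratic: b1/(2*|b2|) = 0.25
        assert argmax == pytest.approx(0.25, abs=0.02)

    def test_toxicity_monotone_in_dose(self, grid):
        theta = ModelParams(0.2, 0.5, -0.3, -1.0, 1.5)
        pt = prob_toxicity(theta.as_array(), grid.centered_log)
        assert np.all(np.diff(pt) > 0)

    def test_probabilities_strictly_interior(self, grid):
        pe, pt = dose_response_probs(np.array([[12.0, -8, 3, -12.0, 8]]), grid)
        assert np.all((pe > 0) & (pe < 1)) and np.all((pt > 0) & (pt < 1))


class TestLogPosterior:
    def test_empty_data_is_log_prior(self, prior, grid):
        theta = ModelParams(*prior.mean)
        lp = log_posterior(theta, TrialData(), prior, grid)
        expected = float(
            -np.log(prior.sd_arr).sum() - 2.5 * np.log(2 * np.pi)
        )
        assert lp == pytest.approx(expected)

    def test_single_patient_adds_two_log_halves(self, prior, grid):
        # With theta = 0 every probability is 1/2, and the middle of a
        # symmetric two-dose grid has covariate 0.
        g = center_log_dose((10.0, 10.0 * np.e))
        theta = ModelParams(0, 0, 0, 0, 0)
        base = log_posterior(theta, TrialData(), prior, g)
        data = TrialData(np.array([0]), np.array([1]), np.array([0]))
        lp = log_posterior(theta, data, prior, g)
        assert lp - base == pytest.approx(2 * np.log(0.5))

    def test_matches_brute_force_on_random_datasets(self, prior, grid, rng):
        for _ in range(5):
            n = int(rng.integers(1, 20))
            data = TrialData(
                rng.integers(0, 4, n), rng.integers(0, 2, n), rng.integers(0, 2, n)
            )
            theta = rng.normal(0, 1.5, 5)
            got = log_posterior(theta, data, prior, grid)
            want = brute_log_posterior(
                theta, data.dose_index, data.y_eff, data.y_tox,
                grid.centered_log, prior.mean, prior.sd,
            )
            assert got == pytest.approx(want, abs=1e-9)

    def test_patient_order_irrelevant(self, prior, grid, rng):
        n = 12
        idx, ye, yt = rng.integers(0, 4, n), rng.integers(0, 2, n), rng.integers(0, 2, n)
        perm = rng.permutation(n)
        theta = rng.normal(size=5)
        lp1 = log_posterior(theta, TrialData(idx, ye, yt), prior, grid)
        lp2 = log_posterior(theta, TrialData(idx[perm], ye[perm], yt[perm]), prior, grid)
        assert lp1 == pytest.approx(lp2, abs=1e-12)


class TestSampler:
    def test_same_seed_same_draws(self, prior, grid):
        data = TrialData(np.array([0, 0, 1]), np.array([1, 0, 1]), np.array([0, 0, 1]))
        d1 = sample_posterior(data, prior, grid, n_draws=200, seed=42, **{k: v for k, v in FAST_MCMC.items() if k != "n_draws"})
        d2 = sample_posterior(data, prior, grid, n_draws=200, seed=42, **{k: v for k, v in FAST_MCMC.items() if k != "n_draws"})
        assert np.array_equal(d1.params, d2.params)
        d3 = sample_posterior(data, prior, grid, n_draws=200, seed=43)
        assert not np.array_equal(d1.params, d3.params)

    def test_prior_recovery_with_no_data(self, prior, grid):
        draws = sample_posterior(
            TrialData(), prior, grid, n_draws=4000, seed=7, warmup=600, thin=5
        )
        x = draws.params
        # batch-means standard error to account for chain autocorrelation
        nb = 40
        batches = x[: (len(x) // nb) * nb].reshape(nb, -1, 5).mean(axis=1)
        se = batches.std(axis=0, ddof=1) / np.sqrt(nb)
        assert np.all(np.abs(x.mean(0) - prior.mean_arr) < 3.5 * se + 1e-9)
        assert x.std(0) == pytest.approx(prior.sd_arr, rel=0.15)

    def test_posterior_mean_matches_quadrature_oracle(self, grid, rng):
        # Restricted model: free efficacy intercept and slope; the quadratic
        # term is pinned by a near-degenerate prior and the toxicity block is
        # independent of the efficacy probabilities.
        prior = PriorSpec(mean=(0.0, 1.0, 0.0, -1.0, 1.0), sd=(2.0, 2.0, 1e-3, 2.0, 2.0))
        n = 24
        idx = rng.integers(0, 4, n)
        ye = rng.integers(0, 2, n)
        data = TrialData(idx, ye, rng.integers(0, 2, n))
        draws = sample_posterior(data, prior, grid, n_draws=4000, seed=3, warmup=600, thin=5)
        pe, _ = draws.probs(grid)
        oracle = quadrature_posterior_mean_eff(
            idx, ye, grid.centered_log, (0.0, 1.0), (2.0, 2.0)
        )
        assert np.max(np.abs(pe.mean(0) - oracle)) < 0.01

    def test_tail_prob_matches_quadrature_oracle(self, grid, rng):
        prior = PriorSpec(mean=(0.0, 1.0, 0.0, -1.0, 1.0), sd=(2.0, 2.0, 1e-3, 2.0, 2.0))
        n = 18
        idx = rng.integers(0, 4, n)
        ye = rng.integers(0, 2, n)
        data = TrialData(idx, ye, rng.integers(0, 2, n))
        draws = sample_posterior(data, prior, grid, n_draws=6000, seed=5, warmup=600, thin=10)
        got = posterior_tail_probs(draws, grid)["pr_eff_above"]
        want = quadrature_tail_prob_eff(
            idx, ye, grid.centered_log, (0.0, 1.0), (2.0, 2.0), threshold=0.5
        )
        assert np.max(np.abs(got - want)) < 0.02

    def test_laplace_close_to_mcmc_on_moderate_data(self, prior, grid, rng):
        n = 30
        data = TrialData(rng.integers(0, 4, n), rng.integers(0, 2, n), rng.integers(0, 2, n))
        d_mcmc = sample_posterior(data, prior, grid, n_draws=3000, seed=1, warmup=600, thin=4)
        d_lap = sample_posterior(data, prior, grid, n_draws=3000, seed=1, method="laplace")
        pe_m, _ = d_mcmc.probs(grid)
        pe_l, _ = d_lap.probs(grid)
        assert np.max(np.abs(pe_m.mean(0) - pe_l.mean(0))) < 0.05

    def test_n_draws_validated(self, prior, grid):
        with pytest.raises(ConfigError):
            sample_posterior(TrialData(), prior, grid, n_draws=0)


class TestPosteriorFunctionals:
    def _point_draws(self, pe, pt, grid):
        # Degenerate draw matrix whose dose-response equals (pe, pt) at every
        # dose: intercept-only parameter vectors.
        from scipy.special import logit

        theta = np.array([[logit(pe), 0, 0, logit(pt), 0]])
        return r2dt.PosteriorDraws(params=theta, provenance={})

    def test_degenerate_draws_equal_pointwise_utility(self, grid, rd_utility):
        draws = self._point_draws(0.85, 0.15, grid)
        got = posterior_expected_utility(draws, grid, 3, rd_utility)
        assert got == pytest.approx(float(rd_utility(0.85, 0.15)), abs=1e-12)
        assert round(got, 2) == 0.88

    def test_matches_brute_force_average(self, prior, grid, rd_utility, rng):
        params = prior.mean_arr + rng.normal(0, 0.5, (100, 5))
        draws = r2dt.PosteriorDraws(params=params, provenance={})
        fast = expected_utilities(draws, grid, rd_utility)
        for j in range(grid.k):
            slow = np.mean(
                [
                    rd_utility(
                        prob_efficacy(ModelParams.from_array(p), grid.centered_log[j]),
                        prob_toxicity(ModelParams.from_array(p), grid.centered_log[j]),
                    )
                    for p in params
                ]
            )
            assert fast[j] == pytest.approx(slow, abs=1e-12)

    def test_jensen_gap_in_concave_region(self, grid, rd_utility, rng):
        # In the all-gains region both marginals are concave, so expected
        # utility cannot exceed utility at the expected probabilities.
        from scipy.special import logit

        pe = rng.uniform(0.55, 0.95, 400)
        pt = rng.uniform(0.05, 0.30, 400)
        params = np.column_stack(
            [logit(pe), np.zeros(400), np.zeros(400), logit(pt), np.zeros(400)]
        )
        draws = r2dt.PosteriorDraws(params=params, provenance={})
        eu = posterior_expected_utility(draws, grid, 0, rd_utility)
        assert eu <= float(rd_utility(pe.mean(), pt.mean())) + 1e-9

    def test_tail_probs_two_point(self, grid, rd_utility):
        from scipy.special import logit

        params = np.array(
            [[logit(0.9), 0, 0, logit(0.1), 0], [logit(0.2), 0, 0, logit(0.6), 0]]
        )
        draws = r2dt.PosteriorDraws(params=params, provenance={})
        t = posterior_tail_probs(draws, grid, dose_index=0, utility=rd_utility, u_ref=0.58)
        # one draw clearly above the contour, one clearly below
        assert t["pr_utility_below"] == pytest.approx(0.5)
        assert t["pr_eff_above"] == pytest.approx(0.5)
        high = r2dt.PosteriorDraws(params=params[:1], provenance={})
        assert posterior_tail_probs(high, grid, 0, utility=rd_utility, u_ref=0.58)[
            "pr_utility_below"
        ] == 0.0
        low = r2dt.PosteriorDraws(params=params[1:], provenance={})
        assert posterior_tail_probs(low, grid, 0, utility=rd_utility, u_ref=0.58)[
            "pr_utility_below"
        ] == 1.0
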