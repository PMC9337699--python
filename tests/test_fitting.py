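"""Grid posteriors, marginal likelihoods, credible regions, informative prior."""

import math

import numpy as np
import pytest
from scipy.special import betaln, logsumexp

from jartask.fitting import (
    InformativePrior,
    ParamGrid,
    Prior,
    build_informative_prior,
    calibrate_sigma,
    counts_from_trials,
    default_grid,
    fit_pilot_posteriors,
    fit_posterior,
    flat_prior,
    mle_and_credible,
    posterior_from_counts,
    posterior_mass_near,
    rho_recovery_mse,
    sample_params_from_prior,
    simulate_class_counts,
    trial_log_likelihood,
)
from jartask.cohort import generate_pilot
from jartask.observers import MODELS, ObserverParams, response_prob
from jartask.task import HIGH, LOW, TrialRecord, rho_io, sample_block_trials
from jartask.observers import simulate_responses


def responded_block(blocks, name="HA", model="noisy_bayes_set_rho", seed=3, **kw):
    params = ObserverParams(model=model, **(kw or {"a": 0.2}))
    stim = sample_block_trials(blocks[name], seed)
    return simulate_responses(params, stim, blocks[name], seed + 1)


class TestTrialLogLikelihood:
    def test_guess_closed_form(self, blocks):
        p = ObserverParams(model="guess", p_guess=0.7)
        t = TrialRecord("s", "HA", 0, HIGH, 2, (1, -1), response=HIGH)
        assert trial_log_likelihood(p, t, blocks["HA"]) == pytest.approx(math.log(0.7))
        t_low = TrialRecord("s", "HA", 0, HIGH, 2, (1, -1), response=LOW)
        assert trial_log_likelihood(p, t_low, blocks["HA"]) == pytest.approx(
            math.log(0.3)
        )

    def test_impossible_observation_floored(self, blocks):
        p = ObserverParams(model="rare_ball", p_rare=1.0, p_no=1.0)
        t = TrialRecord("s", "HA", 0, HIGH, 5, (1, -1, -1, -1, -1), response=LOW)
        assert trial_log_likelihood(p, t, blocks["HA"]) == pytest.approx(
            math.log(1e-10)
        )


class TestPosterior:
    def test_zero_trials_returns_prior(self, blocks):
        prior = flat_prior("guess")
        post = fit_posterior("guess", [], blocks["HA"], prior)
        assert np.allclose(post.mass, prior.mass)
        assert post.log_marginal == pytest.approx(0.0)

    def test_normalized(self, blocks):
        post = fit_posterior(
            "noisy_bayes", responded_block(blocks), blocks["HA"]
        )
        assert post.mass.sum() == pytest.approx(1.0, abs=1e-10)

    def test_single_cell_grid(self, blocks):
        grid = ParamGrid((("p_guess", np.array([0.6])),))
        prior = flat_prior("guess", grid)
        trials = responded_block(blocks, model="guess", p_guess=0.6)
        post = fit_posterior("guess", trials, blocks["HA"], prior)
        assert post.mass.sum() == pytest.approx(1.0)
        k = sum(t.response == HIGH for t in trials)
        expected = k * math.log(0.6) + (42 - k) * math.log(0.4)
        assert post.log_marginal == pytest.approx(expected)

    def test_reorder_invariance(self, blocks):
        trials = responded_block(blocks)
        post1 = fit_posterior("noisy_bayes", trials, blocks["HA"])
        post2 = fit_posterior("noisy_bayes", trials[::-1], blocks["HA"])
        assert np.allclose(post1.log_posterior, post2.log_posterior)

    @pytest.mark.parametrize("model", ["noisy_bayes_set_rho", "guess", "rare_ball"])
    def test_marginal_matches_dense_loop_oracle(self, blocks, model):
        """Grid log-marginal equals an independently coded per-trial,
        per-cell likelihood summation on a coarse grid."""
        trials = responded_block(blocks, model="noisy_bayes_set_rho", seed=8)
        block = blocks["HA"]
        coarse = {
            "noisy_bayes_set_rho": ParamGrid((("a", np.linspace(0.0, 1.0, 9)),)),
            "guess": ParamGrid((("p_guess", np.linspace(0.05, 0.95, 7)),)),
            "rare_ball": ParamGrid(
                (("p_rare", np.linspace(0.5, 1.0, 6)), ("p_no", np.linspace(0.5, 1.0, 6)))
            ),
        }[model]
        prior = flat_prior(model, coarse)
        post = fit_posterior(model, trials, block, prior)
        # oracle: explicit double loop over cells and trials
        cells = coarse.cell_params()
        n_cells = coarse.n_cells
        loglik = np.zeros(n_cells)
        for i in range(n_cells):
            params = ObserverParams(
                model=model, **{k: (v[i] if k != "theta" else int(v[i])) for k, v in cells.items()}
            )
            for t in trials:
                p = response_prob(params, t, block)
                p = min(max(p, 1e-10), 1 - 1e-10)
                loglik[i] += math.log(p if t.response == HIGH else 1 - p)
        oracle = logsumexp(loglik - math.log(n_cells))
        assert post.log_marginal == pytest.approx(oracle, abs=1e-6)

    def test_guess_marginal_matches_beta_integral(self, blocks):
        """Flat-prior guess marginal ~ the Beta integral
        B(k+1, N-k+1) = int p^k (1-p)^(N-k) dp (trial-ordered likelihood)."""
        trials = responded_block(blocks, model="guess", p_guess=0.65, seed=10)
        post = fit_posterior("guess", trials, blocks["HA"])
        k = sum(t.response == HIGH for t in trials)
        analytic = betaln(k + 1, 42 - k + 1)
        # discrete-node quadrature at step 0.01 on a 42-trial likelihood
        assert post.log_marginal == pytest.approx(analytic, abs=0.02)

    def test_grid_refinement_converges(self, blocks):
        trials = responded_block(blocks, model="guess", p_guess=0.6, seed=11)
        base = fit_posterior(
            "guess",
            trials,
            blocks["HA"],
            flat_prior("guess", ParamGrid((("p_guess", np.linspace(0.0, 1.0, 101)),))),
        )
        fine = fit_posterior(
            "guess",
            trials,
            blocks["HA"],
            flat_prior("guess", ParamGrid((("p_guess", np.linspace(0.0, 1.0, 201)),))),
        )
        assert base.log_marginal == pytest.approx(fine.log_marginal, abs=0.01)


class TestMleAndCredible:
    def test_delta_posterior_single_cell(self):
        grid = default_grid("guess")
        mass = np.zeros(grid.n_cells)
        mass[37] = 1.0
        post = _posterior_from_mass("guess", grid, mass)
        fit = mle_and_credible(post)
        assert fit.credible_mask.sum() == 1
        assert fit.mle["p_guess"] == pytest.approx(grid.axis("p_guess")[37])

    def test_uniform_posterior_covers_95_percent(self):
        grid = default_grid("guess")
        mass = np.full(grid.n_cells, 1.0 / grid.n_cells)
        fit = mle_and_credible(_posterior_from_mass("guess", grid, mass))
        assert fit.credible_mask.sum() >= 0.95 * grid.n_cells

    def test_coverage_over_synthetic_datasets(self, blocks):
        """True parameters drawn from the fitting prior fall inside the 95%
        highest-density region in at least 80% of synthetic blocks, for
        every model (Bayesian coverage self-consistency)."""
        block = blocks["HA"]
        n_rep = 100
        for model in MODELS:
            prior = flat_prior(model)
            rng = np.random.default_rng(17)
            truths = sample_params_from_prior(prior, rng, n_rep)
            cells = prior.grid.cell_params()
            hits = 0
            for truth in truths:
                counts = simulate_class_counts(truth, block, rng)
                post = posterior_from_counts(model, counts, block, prior)
                fit = mle_and_credible(post)
                mask = np.ones(prior.grid.n_cells, dtype=bool)
                for name in prior.grid.names:
                    mask &= np.isclose(cells[name], getattr(truth, name))
                (idx,) = np.where(mask)
                hits += bool(fit.credible_mask[idx[0]])
            assert hits / n_rep >= 0.8, model


def _posterior_from_mass(model, grid, mass):
    from jartask.fitting import PosteriorGrid

    with np.errstate(divide="ignore"):
        logm = np.log(mass)
    return PosteriorGrid(
        model=model,
        grid=grid,
        log_prior=np.full(grid.n_cells, -math.log(grid.n_cells)),
        log_likelihood=logm,
        log_posterior=logm,
        log_marginal=0.0,
    )


@pytest.fixture(scope="module")
def pilot_posts(blocks):
    pilot = generate_pilot(10)
    return fit_pilot_posteriors(pilot, blocks["HA"])


class TestInformativePrior:
    def test_positive_and_normalized(self, blocks, pilot_posts):
        info = build_informative_prior(pilot_posts, blocks["HA"], sigma=8.0)
        for m, prior in info.priors.items():
            assert prior.mass.sum() == pytest.approx(1.0)
            assert np.all(prior.mass > 0), m

    def test_smoothing_constants_by_symmetry(self, blocks, pilot_posts):
        info = build_informative_prior(pilot_posts, blocks["HA"], sigma=8.0)
        assert (info.c, info.L) == (2.0, 1.0)  # asymmetric
        sym_posts = fit_pilot_posteriors(generate_pilot(6), blocks["ES"])
        info_sym = build_informative_prior(sym_posts, blocks["ES"], sigma=8.0)
        assert (info_sym.c, info_sym.L) == (5.0, 2.0)  # symmetric

    def test_large_c_limit_flattens_a_marginal(self, blocks, pilot_posts):
        info = build_informative_prior(pilot_posts, blocks["HA"], sigma=8.0, c=1e9, L=1.0)
        assert np.allclose(info.a_marginal, info.a_marginal[0])

    def test_rho_filter_centered_at_argmax(self, blocks, pilot_posts):
        info = build_informative_prior(pilot_posts, blocks["HA"], sigma=0.5)
        rho_vals = info.priors["noisy_bayes"].grid.axis("rho")
        peak = rho_vals[np.argmax(info.rho_marginal)]
        assert abs(peak - info.mu) <= 1.0  # tight filter pulls mass to mu

    def test_requires_posteriors(self, blocks):
        with pytest.raises(ValueError):
            build_informative_prior([], blocks["HA"], sigma=8.0)

    def test_calibration_meets_mse_target(self, blocks, pilot_posts):
        sigma, info = calibrate_sigma(
            pilot_posts, blocks["HA"], seed=5, n_datasets=40
        )
        mse = rho_recovery_mse(
            info.priors["noisy_bayes"], blocks["HA"], 40, np.random.default_rng(6)
        )
        assert mse < 1.0


class TestPosteriorMassNear:
    def test_whole_grid_is_mass_one(self, blocks):
        post = fit_posterior("guess", responded_block(blocks, model="guess", p_guess=0.5, seed=2), blocks["HA"])
        assert posterior_mass_near(post, {"p_guess": 0.5}, radius=1.0) == pytest.approx(1.0)
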