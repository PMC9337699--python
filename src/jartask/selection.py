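"""Bayes-factor model comparison and selection.

The marginal likelihood of each model is the prior-weighted sum of its
per-cell likelihoods on the fitting grid.  Every alternative model is
compared to the free-rho Noisy Bayesian baseline through the log Bayes
factor log m(alt) - log m(baseline); the alternative with the largest
positive log BF is selected, and the baseline is kept when no alternative
is positive.  |log BF| > 1 is flagged as strong evidence.

``model_recovery_study`` re-runs the identifiability protocol: synthetic
datasets are generated from each accepted model with parameters drawn from
its fitting prior (informative for Bayesian models, flat for heuristics)
and pushed through the same selection rule, yielding a confusion matrix per
block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .fitting import (
    Prior,
    counts_from_trials,
    flat_prior,
    log_prob_tables,
    posterior_from_counts,
    sample_params_from_prior,
    simulate_class_counts,
)
from .observers import MODELS, ObserverParams, class_response_probs
from .task import HIGH, BlockConfig

BASELINE_MODEL = "noisy_bayes"
#: Tie-break order for alternatives (order of declaration).
ALTERNATIVE_MODELS = (
    "noisy_bayes_set_rho",
    "prior_bayes",
    "variable_rare",
    "rare_ball",
    "guess",
)
STRONG_EVIDENCE_LOG_BF = 1.0


@dataclass
class ModelComparisonResult:
    subject_id: str
    block: str
    log_bf: dict
    selected_model: str
    strong_evidence: bool
    log_marginals: dict
    cross_validation_accuracy: float | None = None


class BlockFitter:
    """Precomputed log-likelihood tables for all six models on one block.

    Fitting a dataset then reduces to two matrix products per model, which
    makes the 100-datasets-per-model recovery protocol cheap.
    """

    def __init__(
        self,
        block: BlockConfig,
        priors: dict[str, Prior] | None = None,
        noise_scaling: str = "trial",
    ):
        self.block = block
        self.priors = priors or {m: flat_prior(m) for m in MODELS}
        self.noise_scaling = noise_scaling
        self.tables = {
            m: log_prob_tables(
                m, block, self.priors[m].grid, noise_scaling=noise_scaling
            )
            for m in MODELS
        }

    def log_marginals_batch(self, counts_batch: np.ndarray) -> dict[str, np.ndarray]:
        """Log marginal likelihood per model for a (B, classes, 2) batch."""
        ch = counts_batch[:, :, 0].T  # (classes, B)
        cl = counts_batch[:, :, 1].T
        out = {}
        for m in MODELS:
            log_ph, log_pl = self.tables[m]
            ll = log_ph @ ch + log_pl @ cl  # (cells, B)
            ll += self.priors[m].log_mass[:, None]
            out[m] = logsumexp(ll, axis=0)
        return out

    def posterior(self, counts: np.ndarray, model: str):
        return posterior_from_counts(
            model,
            counts,
            self.block,
            self.priors[model],
            tables=self.tables[model],
        )


def log_marginal_likelihood(
    model: str,
    trials,
    block: BlockConfig,
    prior: Prior | None = None,
    noise_scaling: str = "trial",
) -> float:
    """Grid-quadrature log marginal likelihood of one subject-block."""
    post = posterior_from_counts(
        model,
        counts_from_trials(trials, block.sample_lengths),
        block,
        prior or flat_prior(model),
        noise_scaling=noise_scaling,
    )
    return post.log_marginal


def log_bayes_factor(
    alt_model: str,
    trials,
    block: BlockConfig,
    priors: dict[str, Prior] | None = None,
) -> float:
    """log m(alt) - log m(noisy_bayes); positive favors the alternative."""
    priors = priors or {m: flat_prior(m) for m in (alt_model, BASELINE_MODEL)}
    alt = log_marginal_likelihood(alt_model, trials, block, priors[alt_model])
    base = log_marginal_likelihood(BASELINE_MODEL, trials, block, priors[BASELINE_MODEL])
    return alt - base


def _select_from_marginals(log_marginals: dict[str, float]) -> tuple[str, dict, bool]:
    base = log_marginals[BASELINE_MODEL]
    log_bf = {m: log_marginals[m] - base for m in ALTERNATIVE_MODELS}
    best, best_val = BASELINE_MODEL, 0.0
    for m in ALTERNATIVE_MODELS:  # declaration order breaks exact ties
        if log_bf[m] > 0 and log_bf[m] > best_val:
            best, best_val = m, log_bf[m]
    if best == BASELINE_MODEL:
        strong = all(log_bf[m] < -STRONG_EVIDENCE_LOG_BF for m in ALTERNATIVE_MODELS)
    else:
        strong = log_bf[best] > STRONG_EVIDENCE_LOG_BF
    return best, log_bf, strong


def select_model(
    trials,
    block: BlockConfig,
    priors: dict[str, Prior] | None = None,
    subject_id: str = "",
    fitter: BlockFitter | None = None,
) -> ModelComparisonResult:
    """Fit all six models to one subject-block and apply the selection rule."""
    fitter = fitter or BlockFitter(block, priors)
    counts = counts_from_trials(trials, block.sample_lengths)
    marginals = {
        m: float(v[0]) for m, v in fitter.log_marginals_batch(counts[None]).items()
    }
    selected, log_bf, strong = _select_from_marginals(marginals)
    return ModelComparisonResult(
        subject_id=subject_id,
        block=block.name,
        log_bf=log_bf,
        selected_model=selected,
        strong_evidence=strong,
        log_marginals=marginals,
    )


@dataclass
class RecoveryResult:
    """Identifiability study output for one block.

    ``confusion`` tabulates the full six-way selection rule;
    ``vs_baseline_fraction`` is the pairwise criterion — the fraction of an
    alternative model's datasets whose log Bayes factor against the Noisy
    Bayesian baseline is positive, which is how identifiability of the
    alternatives is defined.
    """

    block: str
    n_datasets: int
    confusion: np.ndarray  # rows: generating model, cols: selected model
    vs_baseline_fraction: dict = field(default_factory=dict)
    models: tuple = MODELS

    @property
    def identification_fraction(self) -> dict:
        return {
            m: float(self.confusion[i, i]) for i, m in enumerate(self.models)
        }


def model_recovery_study(
    block: BlockConfig,
    priors: dict[str, Prior],
    n_datasets: int,
    seed,
    models=MODELS,
    noise_scaling: str = "trial",
) -> RecoveryResult:
    """Simulate ``n_datasets`` response sets per generating model (parameters
    drawn from that model's fitting prior), run Bayes-factor selection on
    each, and tabulate the confusion matrix."""
    rng = np.random.default_rng(seed)
    fitter = BlockFitter(block, priors, noise_scaling)
    confusion = np.zeros((len(models), len(models)))
    vs_baseline = {}
    col = {m: j for j, m in enumerate(MODELS)}
    for i, gen in enumerate(models):
        truths = sample_params_from_prior(priors[gen], rng, n_datasets)
        batch = np.stack(
            [
                simulate_class_counts(t, block, rng, noise_scaling=noise_scaling)
                for t in truths
            ]
        )
        marginals = fitter.log_marginals_batch(batch)
        for d in range(n_datasets):
            sel, _, _ = _select_from_marginals({m: marginals[m][d] for m in MODELS})
            confusion[i, col[sel]] += 1
        if gen != BASELINE_MODEL:
            vs_baseline[gen] = float(
                np.mean(marginals[gen] > marginals[BASELINE_MODEL])
            )
    confusion /= n_datasets
    return RecoveryResult(
        block=block.name,
        n_datasets=n_datasets,
        confusion=confusion,
        vs_baseline_fraction=vs_baseline,
    )


def cross_validate(
    trials,
    block: BlockConfig,
    model: str,
    prior: Prior | None = None,
    seed=0,
    n_folds: int = 10,
    scoring: str = "map",
    noise_scaling: str = "trial",
) -> float:
    """10-fold 90/10 cross-validated response-prediction accuracy.

    Folds are contiguous chunks of a seed-shuffled trial order.  The model
    is refit on the training trials, its MLE parameters predict the
    most-probable response on each held-out trial, and accuracies are
    averaged over folds.  ``scoring="prob"`` scores the probability assigned
    to the observed response instead of the 0/1 match.
    """
    trials = list(trials)
    if len(trials) < n_folds:
        raise ValueError(f"need at least {n_folds} trials for {n_folds}-fold CV")
    prior = prior or flat_prior(model)
    tables = log_prob_tables(model, block, prior.grid, noise_scaling=noise_scaling)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trials))
    folds = np.array_split(order, n_folds)
    accs = []
    for fold in folds:
        held = set(int(i) for i in fold)
        train = [t for i, t in enumerate(trials) if i not in held]
        test = [trials[i] for i in held]
        counts = counts_from_trials(train, block.sample_lengths)
        post = posterior_from_counts(
            model, counts, block, prior, tables=tables
        )
        mle = ObserverParams(model=model, **prior.grid.params_at(int(np.argmax(post.mass))))
        n_arr = np.array([t.n for t in test])
        k_arr = np.array([t.rare_count for t in test])
        p_high = class_response_probs(mle, block, n_arr, k_arr, noise_scaling)
        obs_high = np.array([t.response == HIGH for t in test])
        if scoring == "map":
            pred_high = p_high >= 0.5
            accs.append(float(np.mean(pred_high == obs_high)))
        elif scoring == "prob":
            accs.append(float(np.mean(np.where(obs_high, p_high, 1.0 - p_high))))
        else:
            raise ValueError(f"unknown scoring {scoring!r}")
    return float(np.mean(accs))
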