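"""Psychometric decomposition of choice errors into bias, noise and variance.

Per subject-block, the fraction of high-jar responses is related to the
trial's true LLR (computed by the ideal observer) through a three-parameter
logistic

    p(high | LLR) = alpha + (1 - 2 alpha) / (1 + exp(-beta (LLR - phi))),

fit by Bernoulli maximum likelihood on per-trial outcomes (a least-squares
fit to binned proportions is available as an option).  The decomposition:

* bias  = phi, the LLR of indifference, clipped to [-10, 10]; positive
  values mean more low-jar choices (an accentuated choice asymmetry),
* noise = 1/|beta|, the inverse psychometric slope,
* variance v = (1/x) sum_i n_i |P_obs,i - p_fit,i| over the x distinct LLR
  values, the weighted mean absolute residual: choice variability tied to
  specific observation patterns rather than to the LLR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import ranksums, spearmanr, ttest_ind

from .task import HIGH, BlockConfig, llr_from_count

BIAS_BOUND = 10.0
_BOUNDS = [(0.0, 0.5), (1e-3, 50.0), (-20.0, 20.0)]  # alpha, beta, phi


@dataclass
class PsychometricFit:
    alpha: float
    beta: float
    phi: float
    bias: float
    noise: float
    variance_v: float
    variance_v_normalized: float
    n_per_llr: dict
    log_likelihood: float
    boundary: bool = False  # fit pinned at a parameter bound (degenerate data)

    def curve(self, llr):
        return _logistic(np.asarray(llr, dtype=float), self.alpha, self.beta, self.phi)


def _logistic(llr, alpha, beta, phi):
    return alpha + (1.0 - 2.0 * alpha) * expit(beta * (llr - phi))


def trial_llrs(trials, block: BlockConfig) -> np.ndarray:
    return np.array([llr_from_count(block, t.n, t.rare_count) for t in trials])


def _neg_log_lik(theta, llr, y):
    p = np.clip(_logistic(llr, *theta), 1e-12, 1.0 - 1e-12)
    return -float(np.sum(np.where(y, np.log(p), np.log1p(-p))))


def fit_psychometric(
    trials,
    block: BlockConfig,
    seed=0,
    n_restarts: int = 10,
    criterion: str = "bernoulli",
) -> PsychometricFit:
    """Fit the three-parameter logistic to one subject-block.

    ``criterion="bernoulli"`` (default) maximizes the per-trial Bernoulli
    likelihood; ``"lsq"`` minimizes squared error on per-LLR proportions.
    """
    trials = [t for t in trials if t.response is not None]
    llr = trial_llrs(trials, block)
    y = np.array([t.response == HIGH for t in trials])
    levels = np.unique(np.round(llr, 9))
    if len(levels) < 3:
        raise ValueError("need responses at >= 3 distinct LLR values")
    llr_r = np.round(llr, 9)
    p_obs = np.array([y[llr_r == v].mean() for v in levels])
    n_i = np.array([(llr_r == v).sum() for v in levels])

    if criterion == "bernoulli":
        objective = lambda th: _neg_log_lik(th, llr, y)
    elif criterion == "lsq":
        objective = lambda th: float(
            np.sum(n_i * (p_obs - _logistic(levels, *th)) ** 2)
        )
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    rng = np.random.default_rng(seed)
    starts = [(0.02, 1.0, 0.0)]
    for _ in range(n_restarts - 1):
        starts.append(
            (
                rng.uniform(0.0, 0.2),
                np.exp(rng.uniform(np.log(0.05), np.log(20.0))),
                rng.uniform(-5.0, 5.0),
            )
        )
    best = None
    for x0 in starts:
        res = minimize(objective, x0, method="L-BFGS-B", bounds=_BOUNDS)
        if best is None or res.fun < best.fun:
            best = res
    alpha, beta, phi = (float(v) for v in best.x)
    p_fit = _logistic(levels, alpha, beta, phi)
    v = float(np.sum(n_i * np.abs(p_obs - p_fit)) / len(levels))
    v_norm = float(np.sum(n_i * np.abs(p_obs - p_fit)) / n_i.sum())
    boundary = bool(
        y.all()
        or (~y).all()
        or np.isclose(beta, _BOUNDS[1][1])
        or np.isclose(abs(phi), _BOUNDS[2][1])
    )
    return PsychometricFit(
        alpha=alpha,
        beta=beta,
        phi=phi,
        bias=float(np.clip(phi, -BIAS_BOUND, BIAS_BOUND)),
        noise=1.0 / abs(beta),
        variance_v=v,
        variance_v_normalized=v_norm,
        n_per_llr={float(v_): int(n_) for v_, n_ in zip(levels, n_i)},
        log_likelihood=-_neg_log_lik((alpha, beta, phi), llr, y),
        boundary=boundary,
    )


def bias_noise_variance(fit: PsychometricFit) -> tuple[float, float, float]:
    """(bias, noise, variance) triple from a fitted psychometric function."""
    return fit.bias, fit.noise, fit.variance_v


def bootstrap_mean_ci(values, n_boot: int = 1000, seed=0, level: float = 0.95):
    """Uniform bootstrap mean and percentile confidence interval."""
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [50 * (1 - level), 100 - 50 * (1 - level)])
    return float(means.mean()), (float(lo), float(hi))


#: Strategy groups by selected model.
GROUPS = {
    "noisy_bayes_set_rho": "nearly_ideal",
    "noisy_bayes": "mistuned_bayesian",
    "prior_bayes": "mistuned_bayesian",
    "variable_rare": "heuristic",
    "rare_ball": "heuristic",
    "guess": "heuristic",
}


def group_summaries(
    fits: dict,
    assignments: dict,
    metrics=("bias", "variance_v", "noise"),
    n_boot: int = 1000,
    seed=0,
):
    """Per-strategy-group medians, bootstrap means/CIs and pairwise tests.

    ``fits`` maps subject id -> PsychometricFit; ``assignments`` maps
    subject id -> selected model tag.  Groups with no members are omitted.
    Rank-sum (Wilcoxon) and Welch t-tests compare each group to the
    nearly-ideal reference; Spearman correlations relate metric pairs.
    """
    by_group: dict[str, list] = {}
    for sid, fit in fits.items():
        if sid not in assignments:
            continue
        g = GROUPS[assignments[sid]]
        by_group.setdefault(g, []).append(fit)
    out = {}
    for g, members in by_group.items():
        entry = {"n": len(members)}
        for metric in metrics:
            vals = np.array([getattr(f, metric) for f in members])
            mean, ci = bootstrap_mean_ci(vals, n_boot=n_boot, seed=seed)
            entry[metric] = {
                "median": float(np.median(vals)),
                "boot_mean": mean,
                "boot_ci": ci,
            }
        out[g] = entry
    ref = by_group.get("nearly_ideal")
    if ref:
        for g, members in by_group.items():
            if g == "nearly_ideal":
                continue
            tests = {}
            for metric in metrics:
                a = np.array([getattr(f, metric) for f in members])
                b = np.array([getattr(f, metric) for f in ref])
                tests[metric] = {
                    "ranksum_p": float(ranksums(a, b).pvalue),
                    "welch_p": float(ttest_ind(a, b, equal_var=False).pvalue),
                }
            out[g]["vs_nearly_ideal"] = tests
    if len(metrics) >= 2:
        all_fits = [f for fs in by_group.values() for f in fs]
        if len(all_fits) > 2:
            a = np.array([getattr(f, metrics[0]) for f in all_fits])
            b = np.array([getattr(f, metrics[1]) for f in all_fits])
            rho, p = spearmanr(a, b)
            out["correlation"] = {
                f"{metrics[0]}_vs_{metrics[1]}": {"rho": float(rho), "p": float(p)}
            }
    return out
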