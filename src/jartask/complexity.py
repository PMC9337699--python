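"""Strategy-complexity analysis.

Three complementary measures:

* **Mutual information** (bits) between the trial observation — the
  unordered class (rare count |xi|, sample length n) — and the response,
  estimated by the plug-in formula on the empirical joint (only observed
  cells enter the sum).  A variant conditions the observation on the
  previous response as a source of task-irrelevant information.

* **Rate-distortion accuracy bound**: the maximum expected accuracy
  V* = max_pi sum_c p(c) sum_r pi(r|c) Q(c, r) over stochastic policies
  pi(r|c) whose mutual information with the observation equals a fixed
  budget C, where Q(c, high) = 1/(1 + exp(-z_n)) is the ideal observer's
  probability that "high" is correct for class c.  Solved by SLSQP with an
  equality constraint and random multistart.

* **Algorithmic complexity**: operation counts (arithmetic, write, store,
  read) per strategy plus a constant reflexive cost.  Bayesian strategies
  scale with the sample length n (n multiplications and n-1 additions);
  heuristic strategies are n-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .task import BlockConfig, class_probabilities, llr_from_count, trial_classes

_TIE_TOL = 1e-12


# ---------------------------------------------------------------------------
# Empirical mutual information
# ---------------------------------------------------------------------------


def _plugin_mi(joint: dict, n_total: int, obs_of, resp_of) -> float:
    """Plug-in MI (log2) from a sparse joint count dict.

    ``obs_of``/``resp_of`` extract the conditioning observation and the
    response symbol from a joint key; only observed cells enter the sums.
    """
    p_obs: dict = {}
    p_resp: dict = {}
    for key, c in joint.items():
        p_obs[obs_of(key)] = p_obs.get(obs_of(key), 0) + c
        p_resp[resp_of(key)] = p_resp.get(resp_of(key), 0) + c
    mi = 0.0
    for key, c in joint.items():
        p_joint = c / n_total
        po = p_obs[obs_of(key)] / n_total
        pr = p_resp[resp_of(key)] / n_total
        mi += p_joint * np.log2(p_joint / (po * pr))
    return float(mi)


def empirical_mi(trials, include_prev: bool = False) -> float:
    """Plug-in MI (bits) between observation class and response.

    With ``include_prev`` the previous response within the trial sequence
    joins the conditioning variable; the first trial (no predecessor) is
    dropped.
    """
    trials = sorted(
        (t for t in trials if t.response is not None), key=lambda t: t.trial_index
    )
    if not trials:
        raise ValueError("no responded trials")
    joint: dict = {}
    if include_prev:
        for prev, t in zip(trials[:-1], trials[1:]):
            key = ((t.n, t.rare_count, prev.response), t.response)
            joint[key] = joint.get(key, 0) + 1
        n_total = len(trials) - 1
    else:
        for t in trials:
            key = ((t.n, t.rare_count), t.response)
            joint[key] = joint.get(key, 0) + 1
        n_total = len(trials)
    if n_total == 0:
        return 0.0
    return _plugin_mi(joint, n_total, obs_of=lambda k: k[0], resp_of=lambda k: k[1])


def accuracy(trials) -> float:
    """Fraction of responded trials where the response matches the jar."""
    done = [t for t in trials if t.response is not None]
    return float(np.mean([t.response == t.jar for t in done]))


def bootstrap_mi_accuracy(
    trials, n_boot: int = 1000, seed=0, include_prev: bool = False
):
    """Bootstrap distributions of MI and accuracy over trial resamples."""
    trials = [t for t in trials if t.response is not None]
    rng = np.random.default_rng(seed)
    mi = np.empty(n_boot)
    acc = np.empty(n_boot)
    n = len(trials)
    for b in range(n_boot):
        resample = [trials[i] for i in rng.integers(n, size=n)]
        mi[b] = empirical_mi(resample, include_prev=include_prev)
        acc[b] = accuracy(resample)
    return mi, acc


# ---------------------------------------------------------------------------
# Rate-distortion accuracy bound
# ---------------------------------------------------------------------------


def ideal_policy(block: BlockConfig) -> np.ndarray:
    """pi(high | class) of the ideal observer: threshold on the rare count
    with the zero-LLR tie split 50/50."""
    classes = trial_classes(block.sample_lengths)
    pi = np.empty(len(classes))
    for i, (n, k) in enumerate(classes):
        z = llr_from_count(block, n, k)
        pi[i] = 1.0 if z > _TIE_TOL else (0.0 if z < -_TIE_TOL else 0.5)
    return pi


def value_q(block: BlockConfig) -> np.ndarray:
    """Q(class, r): probability that response r is correct, from the ideal
    LLR; column 0 is high, column 1 is low."""
    classes = trial_classes(block.sample_lengths)
    z = np.array([llr_from_count(block, n, k) for n, k in classes])
    q_high = 1.0 / (1.0 + np.exp(-z))
    return np.column_stack([q_high, 1.0 - q_high])


def policy_value(pi: np.ndarray, p_class: np.ndarray, q: np.ndarray) -> float:
    """Expected accuracy V_pi of a stochastic policy."""
    return float(np.sum(p_class * (pi * q[:, 0] + (1.0 - pi) * q[:, 1])))


def policy_mi(pi: np.ndarray, p_class: np.ndarray) -> float:
    """MI (bits) between class and response induced by a policy."""
    p_high = float(np.sum(p_class * pi))
    mi = 0.0
    for w, p in zip(p_class, pi):
        for pr, marg in ((p, p_high), (1.0 - p, 1.0 - p_high)):
            if pr > 0 and marg > 0:
                mi += w * pr * np.log2(pr / marg)
    return float(mi)


def ideal_policy_stats(block: BlockConfig) -> tuple[float, float]:
    """(MI, accuracy) of the ideal step policy, from mass functions."""
    p_class = class_probabilities(block, block.sample_lengths)
    pi = ideal_policy(block)
    return policy_mi(pi, p_class), policy_value(pi, p_class, value_q(block))


def accuracy_bound(
    block: BlockConfig,
    mi_budget: float,
    seed=0,
    n_starts: int = 20,
    tol: float = 1e-6,
) -> float:
    """Maximum accuracy V* over policies with MI equal to ``mi_budget``."""
    p_class = class_probabilities(block, block.sample_lengths)
    q = value_q(block)
    pi_ideal = ideal_policy(block)
    mi_ideal = policy_mi(pi_ideal, p_class)
    if mi_budget < 0 or mi_budget > mi_ideal + 1e-9:
        raise ValueError(
            f"MI budget {mi_budget} outside feasible range [0, {mi_ideal:.4f}]"
        )
    if abs(mi_budget - mi_ideal) < 1e-12:
        return policy_value(pi_ideal, p_class, q)

    n = len(p_class)
    rng = np.random.default_rng(seed)
    best_const = max(
        policy_value(np.zeros(n), p_class, q), policy_value(np.ones(n), p_class, q)
    )
    if mi_budget == 0.0:
        return best_const

    def neg_value(pi):
        return -policy_value(pi, p_class, q)

    def mi_gap(pi):
        return policy_mi(np.clip(pi, 0.0, 1.0), p_class) - mi_budget

    best = -np.inf
    frac = mi_budget / mi_ideal
    for s in range(n_starts):
        if s == 0:
            x0 = frac * pi_ideal + (1 - frac) * 0.5
        else:
            blend = rng.uniform(0.2, 1.0) * frac
            x0 = np.clip(
                blend * pi_ideal + (1 - blend) * 0.5 + rng.normal(0, 0.05, n),
                0.01,
                0.99,
            )
        res = minimize(
            neg_value,
            x0,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * n,
            constraints=[{"type": "eq", "fun": mi_gap}],
            options={"maxiter": 300, "ftol": 1e-10},
        )
        if abs(mi_gap(res.x)) < 10 * tol and -res.fun > best:
            best = -res.fun
    if not np.isfinite(best):
        raise RuntimeError("constrained policy optimization failed to converge")
    return float(max(best, best_const if mi_budget <= 1e-9 else best))


def bound_curve(block: BlockConfig, budgets=None, seed=0) -> np.ndarray:
    """(C, V*) pairs over a grid of MI budgets up to the ideal policy MI."""
    mi_ideal, _ = ideal_policy_stats(block)
    if budgets is None:
        budgets = np.linspace(0.0, mi_ideal, 9)
    return np.array([[c, accuracy_bound(block, c, seed=seed)] for c in budgets])


# ---------------------------------------------------------------------------
# Algorithmic complexity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OperationCounts:
    arithmetic: int
    write: int
    store: int
    read: int
    c_reflex: float = 0.0

    @property
    def total(self) -> float:
        return self.c_reflex + self.arithmetic + self.write + self.store + self.read


def algorithmic_complexity(model: str, n: int, c_reflex: float = 0.0) -> OperationCounts:
    """Per-trial operation counts for one strategy at sample length n.

    Heuristics are n-independent; Bayesian strategies multiply each of the
    n ball weights and sum them (n - 1 additions), with extra reads/stores
    for their free parameters.
    """
    if model == "guess":  # read and store P_guess
        return OperationCounts(0, 0, 1, 1, c_reflex)
    if model == "rare_ball":  # presence test (max), read response prob, store 2 params
        return OperationCounts(1, 0, 2, 1, c_reflex)
    if model == "variable_rare":  # + count rare balls, store threshold theta
        return OperationCounts(2, 0, 3, 1, c_reflex)
    if model == "noisy_bayes_set_rho":  # n multiplications, n-1 additions
        return OperationCounts(2 * n - 1, 0, 0, 0, c_reflex)
    if model == "noisy_bayes":  # + read and store rho
        return OperationCounts(2 * n - 1, 0, 1, 1, c_reflex)
    if model == "prior_bayes":  # + read and store the prior as well
        return OperationCounts(2 * n - 1, 0, 2, 2, c_reflex)
    raise ValueError(f"unknown model tag {model!r}")


def mean_complexity(model: str, sample_lengths=(2, 5, 10), c_reflex: float = 0.0) -> float:
    """Mean total operation count across the design's sample lengths."""
    return float(
        np.mean([algorithmic_complexity(model, n, c_reflex).total for n in sample_lengths])
    )


@dataclass
class ComplexityResult:
    """Per subject-block strategy-complexity summary."""

    subject_id: str
    block: str
    mi_bits: float
    mi_with_prev_bits: float
    accuracy: float
    mi_boot_mean: float
    accuracy_boot_mean: float
    bound_value: float | None = None
    algorithmic: float | None = None


def subject_complexity(
    trials,
    block: BlockConfig,
    subject_id: str = "",
    selected_model: str | None = None,
    n_boot: int = 1000,
    seed=0,
    compute_bound: bool = False,
) -> ComplexityResult:
    """MI, accuracy and bootstrap means for one subject-block; optionally
    the accuracy bound evaluated at the subject's bootstrap-mean MI."""
    mi = empirical_mi(trials)
    mi_prev = empirical_mi(trials, include_prev=True)
    acc = accuracy(trials)
    mi_b, acc_b = bootstrap_mi_accuracy(trials, n_boot=n_boot, seed=seed)
    bound = None
    if compute_bound:
        mi_ideal, _ = ideal_policy_stats(block)
        bound = accuracy_bound(block, min(float(mi_b.mean()), mi_ideal), seed=seed)
    algo = (
        mean_complexity(selected_model, block.sample_lengths)
        if selected_model
        else None
    )
    return ComplexityResult(
        subject_id=subject_id,
        block=block.name,
        mi_bits=mi,
        mi_with_prev_bits=mi_prev,
        accuracy=acc,
        mi_boot_mean=float(mi_b.mean()),
        accuracy_boot_mean=float(acc_b.mean()),
        bound_value=bound,
        algorithmic=algo,
    )
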