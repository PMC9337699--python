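"""The six fitted observer models.

Three are Bayesian: they form a (possibly mistuned) weighted evidence total
m = z0 + rho*k - (n - k) for a sample with k rare balls out of n, corrupt it
with zero-mean Gaussian noise of standard deviation a, and respond "high"
when the noisy total is positive.  The closed-form probability of a high
response is therefore

    P(high) = 1/2 [1 + erf(m / sqrt(2 a^2))],

with the a = 0 limit degenerating to the sign rule (ties split 50/50).

* noisy_bayes          free rho and a
* noisy_bayes_set_rho  rho fixed to the ideal observer's rho_IO; free a
* prior_bayes          rho = rho_IO, free prior log-odds z0 and a

Three are heuristic: they map the observed ball pattern to a response
probability without reference to likelihoods.

* variable_rare  respond high with prob P_rare when >= theta rare balls are
                 seen, otherwise low with prob P_no
* rare_ball      variable_rare with theta fixed at 1
* guess          respond high with a fixed probability P_guess

Heuristic response probabilities ignore the sample length at fixed rare
count, which is what decouples them from the LLR and generates
observation-specific choice "variance".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .task import HIGH, LOW, BlockConfig, TrialRecord, rho_io

BAYESIAN_MODELS = ("noisy_bayes", "noisy_bayes_set_rho", "prior_bayes")
HEURISTIC_MODELS = ("variable_rare", "rare_ball", "guess")
MODELS = BAYESIAN_MODELS + HEURISTIC_MODELS

#: Free-parameter count per model tag.
N_FREE_PARAMS = {
    "noisy_bayes": 2,
    "noisy_bayes_set_rho": 1,
    "prior_bayes": 2,
    "variable_rare": 3,
    "rare_ball": 2,
    "guess": 1,
}

_MODEL_FIELDS = {
    "noisy_bayes": ("rho", "a"),
    "noisy_bayes_set_rho": ("a",),
    "prior_bayes": ("a", "z0"),
    "variable_rare": ("theta", "p_rare", "p_no"),
    "rare_ball": ("p_rare", "p_no"),
    "guess": ("p_guess",),
}


@dataclass(frozen=True)
class ObserverParams:
    """Tagged parameter set for one observer model.

    Only the fields belonging to ``model`` may be set (see _MODEL_FIELDS);
    everything else must stay None.
    """

    model: str
    rho: float | None = None
    a: float | None = None
    z0: float | None = None
    theta: int | None = None
    p_rare: float | None = None
    p_no: float | None = None
    p_guess: float | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model tag {self.model!r}")
        allowed = _MODEL_FIELDS[self.model]
        for name in ("rho", "a", "z0", "theta", "p_rare", "p_no", "p_guess"):
            val = getattr(self, name)
            if name in allowed:
                if val is None:
                    raise ValueError(f"{self.model} requires parameter {name}")
            elif val is not None:
                raise ValueError(f"{self.model} does not use parameter {name}")
        if self.a is not None and self.a < 0:
            raise ValueError("noise standard deviation a must be >= 0")
        if self.rho is not None and self.rho <= 0:
            raise ValueError("rare-ball weight rho must be > 0")
        if self.theta is not None and (self.theta < 1 or int(self.theta) != self.theta):
            raise ValueError("theta must be a positive integer")
        for name in ("p_rare", "p_no", "p_guess"):
            val = getattr(self, name)
            if val is not None and not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    def as_dict(self) -> dict:
        d = {"model": self.model}
        d.update({k: getattr(self, k) for k in _MODEL_FIELDS[self.model]})
        return d


def gaussian_sign_prob(m, a):
    """P(m + N(0, a^2) > 0); vectorized, with the a = 0 step/tie limit."""
    m = np.asarray(m, dtype=float)
    a = np.asarray(a, dtype=float)
    step = np.where(m > 0, 1.0, np.where(m < 0, 0.0, 0.5))
    with np.errstate(divide="ignore", invalid="ignore"):
        smooth = 0.5 * (1.0 + erf(m / (np.sqrt(2.0) * a)))
    return np.where(a > 0, smooth, step)


def bayes_mean_belief(
    model: str,
    rho: float | None,
    z0: float,
    block: BlockConfig,
    n,
    k,
):
    """Rescaled mean belief m = z0 + rho*k - (n-k) for a Bayesian model."""
    if model in ("noisy_bayes_set_rho", "prior_bayes"):
        rho = rho_io(block)
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return z0 + rho * k - (n - k)


def bayes_response_prob(
    params: ObserverParams,
    trial: TrialRecord,
    block: BlockConfig,
    noise_scaling: str = "trial",
) -> float:
    """Closed-form P(high) for the Bayesian models on one trial.

    ``noise_scaling="trial"`` uses variance a^2 at the trial level (the
    fitted likelihood); ``"per_ball"`` accumulates n independent noise terms
    for a trial variance of n a^2.
    """
    if params.model not in BAYESIAN_MODELS:
        raise ValueError(f"{params.model} is not a Bayesian model")
    z0 = params.z0 if params.model == "prior_bayes" else 0.0
    m = bayes_mean_belief(params.model, params.rho, z0, block, trial.n, trial.rare_count)
    a = params.a
    if noise_scaling == "per_ball":
        a = a * math.sqrt(trial.n)
    elif noise_scaling != "trial":
        raise ValueError(f"unknown noise_scaling {noise_scaling!r}")
    return float(gaussian_sign_prob(m, a))


def heuristic_response_prob(params: ObserverParams, trial: TrialRecord) -> float:
    """P(high) for the pattern-based heuristic models on one trial."""
    if params.model not in HEURISTIC_MODELS:
        raise ValueError(f"{params.model} is not a heuristic model")
    if params.model == "guess":
        return params.p_guess
    theta = 1 if params.model == "rare_ball" else params.theta
    if trial.rare_count >= theta:
        return params.p_rare
    return 1.0 - params.p_no


def response_prob(
    params: ObserverParams,
    trial: TrialRecord,
    block: BlockConfig,
    noise_scaling: str = "trial",
) -> float:
    """P(high) under any of the six models."""
    if params.model in BAYESIAN_MODELS:
        return bayes_response_prob(params, trial, block, noise_scaling)
    return heuristic_response_prob(params, trial)


def class_response_probs(
    params: ObserverParams,
    block: BlockConfig,
    n_arr: np.ndarray,
    k_arr: np.ndarray,
    noise_scaling: str = "trial",
) -> np.ndarray:
    """Vectorized P(high) over observation classes (n, rare_count)."""
    n_arr = np.asarray(n_arr)
    k_arr = np.asarray(k_arr)
    if params.model in BAYESIAN_MODELS:
        z0 = params.z0 if params.model == "prior_bayes" else 0.0
        m = bayes_mean_belief(params.model, params.rho, z0, block, n_arr, k_arr)
        a = np.asarray(params.a, dtype=float)
        if noise_scaling == "per_ball":
            a = a * np.sqrt(n_arr.astype(float))
        return gaussian_sign_prob(m, np.broadcast_to(a, m.shape))
    if params.model == "guess":
        return np.full(n_arr.shape, params.p_guess, dtype=float)
    theta = 1 if params.model == "rare_ball" else params.theta
    return np.where(k_arr >= theta, params.p_rare, 1.0 - params.p_no)


def simulate_responses(
    params: ObserverParams,
    trials: list[TrialRecord],
    block: BlockConfig,
    seed,
    noise_scaling: str = "trial",
) -> list[TrialRecord]:
    """Fill in stochastic responses for a list of stimulus-only trials."""
    rng = np.random.default_rng(seed)
    out = []
    for t in trials:
        if t.response is not None:
            raise ValueError("trials already carry responses")
        p = response_prob(params, t, block, noise_scaling)
        r = HIGH if rng.random() < p else LOW
        out.append(
            TrialRecord(
                subject_id=t.subject_id,
                block=t.block,
                trial_index=t.trial_index,
                jar=t.jar,
                n=t.n,
                sample=t.sample,
                response=r,
                segment=t.segment,
            )
        )
    return out
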