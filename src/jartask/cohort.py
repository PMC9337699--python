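"""Synthetic cohorts emulating the study design.

Each simulated subject is assigned one of the six observer strategies and a
parameter set drawn from configurable distributions, then runs a full
session: a 24-trial control pre-test, the four test blocks (42 trials each)
in randomized order, and 12 control trials interspersed between consecutive
test blocks (60 control trials in total).  Exclusion mirrors the study: a
subject must respond correctly on at least 80% of the pre-test control
trials, and subjects scoring 50% or less on two or more of the interspersed
control mini-blocks are flagged inattentive.

Truth labels (assigned strategy and parameters) are kept separate from the
trial table so that fitting code never sees them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .observers import MODELS, ObserverParams, simulate_responses
from .task import (
    TEST_BLOCK_NAMES,
    BlockConfig,
    TrialRecord,
    sample_block_trials,
    study_blocks,
)

PRETEST_TRIALS = 24
INTERSPERSED_TRIALS = 12
N_INTERSPERSED = 3


def _uniform(lo: float, hi: float):
    return lambda rng: float(rng.uniform(lo, hi))


def _choice(values):
    vals = list(values)
    return lambda rng: vals[rng.integers(len(vals))]


#: Default per-model parameter distributions: spans of the qualitatively
#: reported fitted ranges; every entry can be overridden in CohortConfig.
DEFAULT_PARAM_DISTRIBUTIONS = {
    "noisy_bayes": {"a": _uniform(0.0, 1.0), "rho": _uniform(1.0, 24.16)},
    "noisy_bayes_set_rho": {"a": _uniform(0.0, 1.0)},
    "prior_bayes": {"a": _uniform(0.0, 1.0), "z0": _uniform(-3.0, 0.0)},
    "variable_rare": {
        "theta": _choice((1, 2, 3)),
        "p_rare": _uniform(0.5, 1.0),
        "p_no": _uniform(0.5, 1.0),
    },
    "rare_ball": {"p_rare": _uniform(0.5, 1.0), "p_no": _uniform(0.5, 1.0)},
    "guess": {"p_guess": _uniform(0.5, 1.0)},
}

#: Study-preset distributions: narrower, low-noise ranges that mimic the
#: qualitative pattern of the reported subject fits (nearly ideal subjects
#: with small noise, mistuned Bayesians underweighting the rare ball or
#: leaning toward the low jar, heuristics with probabilities above chance).
STUDY_PRESET_PARAM_DISTRIBUTIONS = {
    "noisy_bayes": {"a": _uniform(0.05, 0.5), "rho": _uniform(1.0, 8.0)},
    "noisy_bayes_set_rho": {"a": _uniform(0.05, 0.4)},
    "prior_bayes": {"a": _uniform(0.05, 0.5), "z0": _uniform(-3.0, -0.5)},
    "variable_rare": {
        "theta": _choice((1, 2, 3)),
        "p_rare": _uniform(0.6, 0.95),
        "p_no": _uniform(0.6, 0.95),
    },
    "rare_ball": {"p_rare": _uniform(0.6, 0.95), "p_no": _uniform(0.6, 0.95)},
    "guess": {"p_guess": _uniform(0.35, 0.65)},
}

#: Strategy mix loosely following the reported best-fit model shares.
STUDY_PRESET_STRATEGY_MIX = {
    "noisy_bayes": 0.20,
    "noisy_bayes_set_rho": 0.25,
    "prior_bayes": 0.20,
    "variable_rare": 0.15,
    "rare_ball": 0.10,
    "guess": 0.10,
}


@dataclass
class CohortConfig:
    """Configuration for one synthetic cohort."""

    n_subjects: int = 24
    strategy_mix: dict = field(
        default_factory=lambda: {m: 1.0 / len(MODELS) for m in MODELS}
    )
    parameter_distributions: dict = field(
        default_factory=lambda: {
            m: dict(d) for m, d in DEFAULT_PARAM_DISTRIBUTIONS.items()
        }
    )
    blocks: dict = field(default_factory=study_blocks)
    seed: int = 0
    noise_scaling: str = "trial"
    #: "own": the assigned strategy answers every segment, control included.
    #: "ideal": control segments are answered by a low-noise set-rho observer,
    #: mirroring the fact that every retained human subject passed the easy
    #: control pre-test even when using a heuristic on the test blocks.
    control_strategy: str = "own"

    def __post_init__(self) -> None:
        if not self.strategy_mix:
            raise ValueError("strategy_mix must not be empty")
        total = sum(self.strategy_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"strategy_mix sums to {total}, expected 1")
        for tag in self.strategy_mix:
            if tag not in MODELS:
                raise ValueError(f"unknown model tag {tag!r} in strategy_mix")


def study_preset_config(n_subjects: int = 198, seed: int = 0) -> CohortConfig:
    """Cohort preset mimicking the study's fitted strategy composition."""
    return CohortConfig(
        n_subjects=n_subjects,
        strategy_mix=dict(STUDY_PRESET_STRATEGY_MIX),
        parameter_distributions={
            m: dict(d) for m, d in STUDY_PRESET_PARAM_DISTRIBUTIONS.items()
        },
        seed=seed,
        control_strategy="ideal",
    )


@dataclass
class SubjectSession:
    """One simulated subject's full session plus truth labels."""

    subject_id: str
    true_model: str
    true_params: ObserverParams
    trials: list  # TrialRecord, in presentation order
    block_order: tuple
    excluded: bool = False
    exclusion_reason: str | None = None


def sample_observer_params(model: str, dists: dict, rng) -> ObserverParams:
    draws = {name: fn(rng) for name, fn in dists[model].items()}
    return ObserverParams(model=model, **draws)


def _control_block(blocks: dict, n_trials: int) -> BlockConfig:
    ct = blocks["CT"]
    return BlockConfig(
        ct.name, ct.h_plus, ct.h_minus, n_trials=n_trials,
        sample_lengths=ct.sample_lengths, prior_high=ct.prior_high,
    )


#: Strategy answering control segments under control_strategy="ideal".
CONTROL_IDEAL_PARAMS = ObserverParams(model="noisy_bayes_set_rho", a=0.1)


def generate_subject(
    subject_id: str,
    model: str,
    params: ObserverParams,
    blocks: dict,
    rng,
    noise_scaling: str = "trial",
    control_params: ObserverParams | None = None,
) -> SubjectSession:
    """Build one session: pre-test, randomized test blocks, interspersed
    control trials, responded to by the subject's strategy (optionally a
    separate one on control segments)."""
    perm = rng.permutation(len(TEST_BLOCK_NAMES))
    order = tuple(TEST_BLOCK_NAMES[i] for i in perm)
    segments: list[tuple[str, BlockConfig]] = [
        ("pretest", _control_block(blocks, PRETEST_TRIALS))
    ]
    for i, name in enumerate(order):
        segments.append((f"test:{name}", blocks[name]))
        if i < len(order) - 1:
            segments.append(
                (f"control{i + 1}", _control_block(blocks, INTERSPERSED_TRIALS))
            )
    trials: list[TrialRecord] = []
    offset = 0
    for segment, block in segments:
        stim = sample_block_trials(block, rng, subject_id=subject_id, segment=segment)
        seg_params = params
        if control_params is not None and block.name == "CT":
            seg_params = control_params
        answered = simulate_responses(seg_params, stim, block, rng, noise_scaling)
        for t in answered:
            t.trial_index += offset
            trials.append(t)
        offset += len(answered)
    return SubjectSession(
        subject_id=subject_id,
        true_model=model,
        true_params=params,
        trials=trials,
        block_order=order,
    )


def generate_cohort(config: CohortConfig) -> list[SubjectSession]:
    """Generate a full cohort; reproducible from config.seed."""
    rng = np.random.default_rng(config.seed)
    tags = sorted(config.strategy_mix)
    weights = np.array([config.strategy_mix[t] for t in tags])
    weights = weights / weights.sum()
    control_params = (
        CONTROL_IDEAL_PARAMS if config.control_strategy == "ideal" else None
    )
    sessions = []
    for i in range(config.n_subjects):
        model = tags[rng.choice(len(tags), p=weights)]
        params = sample_observer_params(model, config.parameter_distributions, rng)
        sessions.append(
            generate_subject(
                f"S{i:03d}",
                model,
                params,
                config.blocks,
                rng,
                config.noise_scaling,
                control_params=control_params,
            )
        )
    return apply_exclusions(sessions)


def generate_pilot(n_pilot: int = 20, config: CohortConfig | None = None):
    """Pilot cohort used to build the informative prior (default 20
    subjects from the study preset distributions)."""
    if config is None:
        config = study_preset_config(n_subjects=n_pilot, seed=20)
    else:
        config = replace(config, n_subjects=n_pilot)
    return generate_cohort(config)


def _segment_accuracy(trials: list[TrialRecord], segment: str) -> tuple[int, int]:
    seg = [t for t in trials if t.segment == segment]
    correct = sum(1 for t in seg if t.response == t.jar)
    return correct, len(seg)


def apply_exclusions(sessions: list[SubjectSession]) -> list[SubjectSession]:
    """Flag pre-test failures (< 80% correct on 24 pre-test control trials)
    and inattentive subjects (<= 50% on >= 2 interspersed control blocks)."""
    for s in sessions:
        pre_correct, pre_n = _segment_accuracy(s.trials, "pretest")
        if pre_n == 0:
            raise ValueError(f"{s.subject_id}: no pre-test control trials")
        if pre_correct / pre_n < 0.8:
            s.excluded = True
            s.exclusion_reason = "pretest"
            continue
        low_blocks = 0
        for i in range(1, N_INTERSPERSED + 1):
            c, n = _segment_accuracy(s.trials, f"control{i}")
            if n == 0:
                raise ValueError(f"{s.subject_id}: missing control{i} trials")
            if c / n <= 0.5:
                low_blocks += 1
        if low_blocks >= 2:
            s.excluded = True
            s.exclusion_reason = "inattentive"
        else:
            s.excluded = False
            s.exclusion_reason = None
    return sessions


def block_trials(session: SubjectSession, block_name: str) -> list[TrialRecord]:
    """All trials of one block; control pools pre-test and interspersed."""
    if block_name == "CT":
        return [t for t in session.trials if t.block == "CT"]
    return [t for t in session.trials if t.block == block_name]
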