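"""Task environment and ideal observer for the jar-discrimination task.

Two jars, equally likely a priori, differ in the fraction of "rare"-colored
balls they contain (h+ for the high jar, h- for the low jar, 0 < h- < h+).
On each trial the observer sees a sample of n balls drawn i.i.d. from one jar
and reports which jar produced it.  The ideal observer accumulates the
log-likelihood ratio (LLR)

    z_n = z_0 + sum_j Psi(xi_j),   Psi(+1) = log(h+/h-),
                                   Psi(-1) = log((1-h+)/(1-h-)),

and responds "high" when z_n > 0, "low" when z_n < 0, and at random when
z_n = 0.  When the jars are asymmetric (h+ + h- < 1) the rare ball carries
more evidence per observation than the common ball, which produces a choice
asymmetry in favor of the low jar even for the ideal observer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

HIGH = "high"
LOW = "low"

__all__ = [
    "HIGH",
    "LOW",
    "BlockConfig",
    "TrialRecord",
    "BeliefState",
    "STUDY_BLOCKS",
    "study_blocks",
    "rho_io",
    "belief_increment",
    "ideal_belief",
    "ideal_choice",
    "rare_ball_threshold",
    "ideal_response_probabilities",
    "sample_block_trials",
    "trial_classes",
    "class_index",
    "class_probabilities",
]


@dataclass(frozen=True)
class BlockConfig:
    """Jar composition and trial design for one task condition.

    ``h_plus``/``h_minus`` are the rare-ball fractions of the high and low
    jar.  ``n_trials`` must divide evenly over jar x sample-length cells so
    the design is balanced.
    """

    name: str
    h_plus: float
    h_minus: float
    n_trials: int = 42
    sample_lengths: tuple[int, ...] = (2, 5, 10)
    prior_high: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.h_minus < self.h_plus <= 1.0):
            raise ValueError(
                f"require 0 < h_minus < h_plus <= 1, got "
                f"h_plus={self.h_plus}, h_minus={self.h_minus}"
            )
        if self.h_plus == self.h_minus:
            raise ValueError("h_plus == h_minus carries no evidence")
        if self.h_plus < 1.0 and math.isclose(self.h_plus, self.h_minus):
            raise ValueError("degenerate jars: h_plus ~ h_minus")
        if any(h in (0.0,) for h in (self.h_minus,)) or self.h_plus == 0.0:
            raise ValueError("degenerate jar composition")
        if not self.sample_lengths:
            raise ValueError("need at least one sample length")
        cells = 2 * len(self.sample_lengths)
        if self.n_trials % cells:
            raise ValueError(
                f"n_trials={self.n_trials} not divisible by "
                f"2 x |sample_lengths| = {cells}"
            )
        if not (0.0 < self.prior_high < 1.0):
            raise ValueError("prior_high must lie in (0, 1)")

    @property
    def symmetric(self) -> bool:
        return math.isclose(self.h_plus, 1.0 - self.h_minus)

    @property
    def asymmetric(self) -> bool:
        return self.h_plus + self.h_minus < 1.0 and not self.symmetric

    def jar_fraction(self, jar: str) -> float:
        return self.h_plus if jar == HIGH else self.h_minus


def study_blocks(control_trials: int = 60) -> dict[str, BlockConfig]:
    """The five study conditions keyed by block tag.

    Control (CT) is symmetric and easy; the four test blocks cross difficulty
    (hard/easy) with evidence symmetry.  The control block's trial count
    defaults to the 60 pooled control trials (24 pre-test + 3 x 12
    interspersed).
    """
    return {
        "CT": BlockConfig("CT", 0.9, 0.1, n_trials=control_trials),
        "HA": BlockConfig("HA", 0.2, 0.1),
        "HS": BlockConfig("HS", 0.55, 0.45),
        "EA": BlockConfig("EA", 0.4, 0.1),
        "ES": BlockConfig("ES", 0.7, 0.3),
    }


STUDY_BLOCKS = study_blocks()
TEST_BLOCK_NAMES = ("HA", "HS", "EA", "ES")


@dataclass
class TrialRecord:
    """One trial: the ball sample shown and (optionally) the response."""

    subject_id: str
    block: str
    trial_index: int
    jar: str
    n: int
    sample: tuple[int, ...]
    response: str | None = None
    segment: str = "test"

    def __post_init__(self) -> None:
        if len(self.sample) != self.n:
            raise ValueError("sample length does not match n")
        if any(x not in (-1, 1) for x in self.sample):
            raise ValueError("sample entries must be +1 (rare) or -1 (common)")
        if self.jar not in (HIGH, LOW):
            raise ValueError(f"unknown jar label {self.jar!r}")
        if self.response not in (HIGH, LOW, None):
            raise ValueError(f"unknown response label {self.response!r}")

    @property
    def rare_count(self) -> int:
        return sum(1 for x in self.sample if x == 1)


@dataclass(frozen=True)
class BeliefState:
    """Log-likelihood ratio (natural log) with its prior log-odds."""

    z: float
    z0: float = 0.0


def belief_increment(block: BlockConfig, ball: int) -> float:
    """LLR increment Psi(ball) for a single rare (+1) or common (-1) ball."""
    if ball == 1:
        return math.log(block.h_plus / block.h_minus)
    if ball == -1:
        if block.h_plus >= 1.0:
            raise ValueError("h_plus = 1 gives infinite evidence for a common ball")
        return math.log((1.0 - block.h_plus) / (1.0 - block.h_minus))
    raise ValueError(f"ball must be +1 or -1, got {ball}")


def ideal_belief(block: BlockConfig, sample, z0: float = 0.0) -> BeliefState:
    """Posterior LLR after an ordered (but order-irrelevant) ball sample."""
    sample = tuple(sample)
    k = sum(1 for x in sample if x == 1)
    if k + sum(1 for x in sample if x == -1) != len(sample):
        raise ValueError("sample entries must be +1 or -1")
    z = z0 + llr_from_count(block, len(sample), k)
    return BeliefState(z=z, z0=z0)


def llr_from_count(block: BlockConfig, n: int, k: int) -> float:
    """Ideal LLR of a sample with k rare balls out of n."""
    if n == 0:
        return 0.0
    return k * belief_increment(block, 1) + (n - k) * belief_increment(block, -1)


_TIE_TOL = 1e-12


def ideal_choice(belief: BeliefState, rng: np.random.Generator) -> str:
    """Sign rule on the LLR; ties (to float tolerance) get a fair coin."""
    z = belief.z
    if not math.isfinite(z):
        raise ValueError("belief must be finite")
    if z > _TIE_TOL:
        return HIGH
    if z < -_TIE_TOL:
        return LOW
    return HIGH if rng.random() < 0.5 else LOW


def rare_ball_threshold(block: BlockConfig, n: int) -> float:
    """Minimum rare-ball count B that triggers a high response at length n.

    If some count gives an LLR of exactly zero (symmetric jars, even n) the
    half-integer convention B = n/2 is reported; the tie bin is split
    downstream.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for k in range(n + 1):
        z = llr_from_count(block, n, k)
        if abs(z) <= _TIE_TOL:
            return k  # boundary count: z == 0 exactly (k == n/2 when symmetric)
        if z > 0:
            return float(k)
    return float(n + 1)  # no count suffices (h_plus, h_minus both > 1/2 cannot occur)


def ideal_response_probabilities(block: BlockConfig, n: int) -> dict:
    """Exact ideal-observer response probabilities at sample length n.

    Returns conditional P(response | jar) via binomial tails above the
    rare-ball threshold (splitting the mass of a zero-LLR count evenly) and
    the marginal over jars mixed with the prior.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ks = np.arange(n + 1)
    z = np.array([llr_from_count(block, n, int(k)) for k in ks])
    w_high = np.where(z > _TIE_TOL, 1.0, np.where(z < -_TIE_TOL, 0.0, 0.5))
    out: dict = {}
    for jar, h in ((HIGH, block.h_plus), (LOW, block.h_minus)):
        pmf = binom.pmf(ks, n, h)
        p_high = float(np.sum(pmf * w_high))
        out[(HIGH, jar)] = p_high
        out[(LOW, jar)] = 1.0 - p_high
    p = block.prior_high
    out[HIGH] = p * out[(HIGH, HIGH)] + (1 - p) * out[(HIGH, LOW)]
    out[LOW] = 1.0 - out[HIGH]
    return out


def sample_block_trials(
    block: BlockConfig,
    seed,
    subject_id: str = "sim",
    segment: str = "test",
) -> list[TrialRecord]:
    """Draw a balanced, shuffled block of stimulus-only trials.

    Each (jar, sample length) cell appears exactly n_trials / (2 x lengths)
    times; within a trial each ball is rare with the drawn jar's fraction.
    Fully reproducible from ``seed`` (an int or a Generator).
    """
    rng = np.random.default_rng(seed)
    per_cell = block.n_trials // (2 * len(block.sample_lengths))
    cells = [
        (jar, n)
        for jar in (HIGH, LOW)
        for n in block.sample_lengths
        for _ in range(per_cell)
    ]
    order = rng.permutation(len(cells))
    trials = []
    for idx, cell_i in enumerate(order):
        jar, n = cells[cell_i]
        h = block.jar_fraction(jar)
        balls = tuple(1 if u < h else -1 for u in rng.random(n))
        trials.append(
            TrialRecord(
                subject_id=subject_id,
                block=block.name,
                trial_index=idx,
                jar=jar,
                n=n,
                sample=balls,
                segment=segment,
            )
        )
    return trials


def rho_io(block: BlockConfig) -> float:
    """The ideal observer's rare-ball weight after normalizing the common-
    ball weight to -1: |log(h+/h-) / log((1-h+)/(1-h-))|."""
    return abs(belief_increment(block, 1) / belief_increment(block, -1))


def trial_classes(sample_lengths=(2, 5, 10)) -> list[tuple[int, int]]:
    """All unordered observation classes (n, rare_count) for the design."""
    return [(n, k) for n in sample_lengths for k in range(n + 1)]


def class_index(sample_lengths=(2, 5, 10)) -> dict[tuple[int, int], int]:
    return {c: i for i, c in enumerate(trial_classes(sample_lengths))}


def class_probabilities(block: BlockConfig, sample_lengths=(2, 5, 10)) -> np.ndarray:
    """p(class) under equal length sampling and the jar prior."""
    classes = trial_classes(sample_lengths)
    p = np.zeros(len(classes))
    for i, (n, k) in enumerate(classes):
        p[i] = (
            block.prior_high * binom.pmf(k, n, block.h_plus)
            + (1 - block.prior_high) * binom.pmf(k, n, block.h_minus)
        ) / len(sample_lengths)
    return p
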