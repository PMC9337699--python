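"""Mutual information, the rate-distortion bound, operation counts."""

import math

import numpy as np
import pytest

from jartask.complexity import (
    ComplexityResult,
    accuracy,
    accuracy_bound,
    algorithmic_complexity,
    bootstrap_mi_accuracy,
    empirical_mi,
    ideal_policy,
    ideal_policy_stats,
    mean_complexity,
    policy_mi,
    policy_value,
    subject_complexity,
    value_q,
)
from jartask.observers import MODELS, ObserverParams, simulate_responses
from jartask.task import HIGH, LOW, TrialRecord, class_probabilities, sample_block_trials


def simulate(blocks, name, model, seed, **params):
    p = ObserverParams(model=model, **params)
    stim = sample_block_trials(blocks[name], seed)
    return simulate_responses(p, stim, blocks[name], seed + 1)


def oracle_mi(trials):
    """Independent plug-in MI oracle: explicit dictionary sums, log2."""
    joint, p_obs, p_r = {}, {}, {}
    n = len(trials)
    for t in trials:
        o = (t.n, t.rare_count)
        joint[(o, t.response)] = joint.get((o, t.response), 0) + 1
        p_obs[o] = p_obs.get(o, 0) + 1
        p_r[t.response] = p_r.get(t.response, 0) + 1
    mi = 0.0
    for (o, r), c in joint.items():
        mi += (c / n) * math.log2((c / n) / ((p_obs[o] / n) * (p_r[r] / n)))
    return mi


class TestEmpiricalMI:
    def test_constant_response_zero(self, blocks):
        trials = simulate(blocks, "HA", "guess", 1, p_guess=1.0)
        assert empirical_mi(trials) == 0.0

    def test_deterministic_policy_equals_response_entropy(self, blocks):
        """When the response is a function of the observation class, MI
        equals the empirical response entropy."""
        trials = simulate(blocks, "HA", "rare_ball", 2, p_rare=1.0, p_no=1.0)
        p_high = np.mean([t.response == HIGH for t in trials])
        h = 0.0
        for p in (p_high, 1 - p_high):
            if p > 0:
                h -= p * math.log2(p)
        assert empirical_mi(trials) == pytest.approx(h, abs=1e-12)

    @pytest.mark.parametrize("model,params", [
        ("noisy_bayes", {"rho": 4.0, "a": 0.5}),
        ("variable_rare", {"theta": 2, "p_rare": 0.85, "p_no": 0.7}),
    ])
    def test_matches_independent_oracle(self, blocks, model, params):
        trials = simulate(blocks, "EA", model, 3, **params)
        assert empirical_mi(trials) == pytest.approx(oracle_mi(trials), abs=1e-12)

    def test_bounded_by_response_entropy(self, blocks):
        for seed in range(3):
            trials = simulate(blocks, "HA", "noisy_bayes", 5 + seed, rho=3.0, a=0.4)
            p = np.mean([t.response == HIGH for t in trials])
            h = -sum(q * math.log2(q) for q in (p, 1 - p) if q > 0)
            mi = empirical_mi(trials)
            assert 0.0 <= mi <= h + 1e-12

    def test_with_previous_response_conditioning(self, blocks):
        trials = simulate(blocks, "HA", "noisy_bayes_set_rho", 6, a=0.3)
        mi = empirical_mi(trials)
        mi_prev = empirical_mi(trials, include_prev=True)
        assert mi_prev >= 0.0
        # richer conditioning cannot reduce the plug-in estimate much
        assert mi_prev >= mi - 0.2


class TestBootstrap:
    def test_constant_dataset_zero_width(self, blocks):
        trials = simulate(blocks, "HA", "guess", 7, p_guess=1.0)
        mi, acc = bootstrap_mi_accuracy(trials, n_boot=50, seed=0)
        assert np.ptp(mi) == 0.0

    def test_seed_determinism(self, blocks):
        trials = simulate(blocks, "EA", "noisy_bayes", 8, rho=3.0, a=0.3)
        a1 = bootstrap_mi_accuracy(trials, n_boot=30, seed=5)
        a2 = bootstrap_mi_accuracy(trials, n_boot=30, seed=5)
        assert np.array_equal(a1[0], a2[0]) and np.array_equal(a1[1], a2[1])

    def test_plugin_bias_direction_on_independent_data(self, blocks):
        """Bootstrap mean MI exceeds the plug-in MI on independent data
        (both are upward-biased; resampling adds spurious dependence)."""
        diffs = []
        for seed in range(4):
            trials = simulate(blocks, "HA", "guess", 30 + seed, p_guess=0.5)
            mi, _ = bootstrap_mi_accuracy(trials, n_boot=200, seed=seed)
            diffs.append(mi.mean() - empirical_mi(trials))
        assert np.mean(diffs) > 0


class TestAccuracyBound:
    def test_endpoint_ideal_policy(self, blocks):
        for name in ("HA", "ES"):
            mi_ideal, acc_ideal = ideal_policy_stats(blocks[name])
            assert accuracy_bound(blocks[name], mi_ideal) == pytest.approx(acc_ideal)

    def test_zero_budget_best_constant_policy(self, blocks):
        """V*(0) equals the better of the two constant policies in closed
        form."""
        block = blocks["HA"]
        p_c = class_probabilities(block)
        q = value_q(block)
        expected = max(float(p_c @ q[:, 0]), float(p_c @ q[:, 1]))
        assert accuracy_bound(block, 0.0) == pytest.approx(expected)

    def test_monotone_in_budget(self, blocks):
        block = blocks["EA"]
        mi_ideal, _ = ideal_policy_stats(block)
        budgets = np.linspace(0.0, mi_ideal, 5)
        vals = [accuracy_bound(block, c, seed=2, n_starts=8) for c in budgets]
        for lo, hi in zip(vals, vals[1:]):
            assert hi >= lo - 1e-4

    def test_infeasible_budget_rejected(self, blocks):
        mi_ideal, _ = ideal_policy_stats(blocks["HA"])
        with pytest.raises(ValueError):
            accuracy_bound(blocks["HA"], mi_ideal + 0.5)
        with pytest.raises(ValueError):
            accuracy_bound(blocks["HA"], -0.1)

    def test_large_sample_subject_below_bound(self, blocks):
        """A simulated observer's asymptotic (MI, accuracy) lies on or
        below the bound curve."""
        block = blocks["EA"]
        p = ObserverParams(model="noisy_bayes", rho=2.0, a=0.4)
        big = type(block)(block.name, block.h_plus, block.h_minus, n_trials=30000)
        trials = simulate_responses(p, sample_block_trials(big, 9), block, 10)
        mi = empirical_mi(trials)
        acc = accuracy(trials)
        assert acc <= accuracy_bound(block, mi, seed=3) + 0.01


class TestIdealPolicy:
    def test_matches_large_sample_simulation(self, blocks):
        """Mass-function MI/accuracy of the ideal policy agree with a large
        empirical simulation."""
        block = blocks["HA"]
        mi_pmf, acc_pmf = ideal_policy_stats(block)
        p = ObserverParams(model="noisy_bayes_set_rho", a=0.0)
        big = type(block)(block.name, block.h_plus, block.h_minus, n_trials=30000)
        trials = simulate_responses(p, sample_block_trials(big, 11), block, 12)
        assert empirical_mi(trials) == pytest.approx(mi_pmf, abs=0.03)
        assert accuracy(trials) == pytest.approx(acc_pmf, abs=0.02)

    def test_policy_rows_valid(self, blocks):
        pi = ideal_policy(blocks["EA"])
        assert np.all((pi >= 0) & (pi <= 1))


class TestAlgorithmicComplexity:
    def test_guess_reads_and_stores_one_parameter(self):
        c = algorithmic_complexity("guess", 5)
        assert (c.arithmetic, c.store, c.read) == (0, 1, 1)
        assert c.total == 2

    def test_bayesian_scales_with_n(self):
        for model in ("noisy_bayes", "noisy_bayes_set_rho", "prior_bayes"):
            assert (
                algorithmic_complexity(model, 10).total
                > algorithmic_complexity(model, 2).total
            )

    def test_heuristics_n_independent(self):
        for model in ("guess", "rare_ball", "variable_rare"):
            totals = {algorithmic_complexity(model, n).total for n in (2, 5, 10)}
            assert len(totals) == 1

    def test_bayesian_mean_exceeds_every_heuristic(self):
        bayes = [mean_complexity(m) for m in ("noisy_bayes", "noisy_bayes_set_rho", "prior_bayes")]
        heur = [mean_complexity(m) for m in ("guess", "rare_ball", "variable_rare")]
        assert min(bayes) > max(heur)

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError):
            algorithmic_complexity("windowing", 5)

    def test_reflex_constant_additive(self):
        base = algorithmic_complexity("rare_ball", 5).total
        assert algorithmic_complexity("rare_ball", 5, c_reflex=3.0).total == base + 3.0


class TestSubjectComplexity:
    def test_summary_fields(self, blocks):
        trials = simulate(blocks, "HA", "rare_ball", 13, p_rare=0.9, p_no=0.85)
        res = subject_complexity(
            trials, blocks["HA"], subject_id="s", selected_model="rare_ball",
            n_boot=50, seed=1,
        )
        assert isinstance(res, ComplexityResult)
        assert res.mi_bits >= 0 and 0 <= res.accuracy <= 1
        assert res.algorithmic == mean_complexity("rare_ball")
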