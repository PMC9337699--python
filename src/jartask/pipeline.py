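"""End-to-end orchestration of the analysis.

``run_pipeline`` executes the full flow on a synthetic or user-supplied
cohort: generation (optional) -> exclusions -> informative-prior
construction from a pilot -> per subject-block model fits and Bayes-factor
selection -> cross-validation -> psychometric decomposition -> strategy
complexity -> summary tables.  Every stage is seeded from the run seed and
the output directory receives CSV tables plus a JSON manifest recording the
configuration and seeds, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .cohort import CohortConfig, block_trials, generate_cohort, generate_pilot
from .complexity import subject_complexity
from .fitting import (
    counts_from_trials,
    flat_priors,
    informative_priors_for_blocks,
    mle_and_credible,
)
from .observers import MODELS
from .psychometrics import GROUPS, fit_psychometric, group_summaries
from .selection import BlockFitter, cross_validate, model_recovery_study, select_model
from .task import TEST_BLOCK_NAMES, study_blocks

log = logging.getLogger("jartask")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "results"
    seed: int = 0
    cohort: CohortConfig | None = None
    trials_path: str | None = None  # user-supplied cohort instead
    blocks: dict = field(default_factory=study_blocks)
    prior_source: str = "informative"  # "flat" | "informative"
    n_pilot: int = 20
    n_boot: int = 1000
    recovery_datasets: int = 0  # 0 skips the model-recovery study
    block_subset: tuple | None = None
    calibration_datasets: int = 100

    def digest(self) -> str:
        payload = {
            "seed": self.seed,
            "prior_source": self.prior_source,
            "n_pilot": self.n_pilot,
            "n_boot": self.n_boot,
            "recovery_datasets": self.recovery_datasets,
            "blocks": sorted(self.blocks),
            "cohort_seed": self.cohort.seed if self.cohort else None,
            "n_subjects": self.cohort.n_subjects if self.cohort else None,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def build_priors(config: RunConfig) -> dict:
    """Per-block, per-model fitting priors (flat or pilot-informed)."""
    if config.prior_source == "flat":
        return {name: flat_priors() for name in config.blocks}
    pilot = generate_pilot(config.n_pilot, config.cohort)
    infos = informative_priors_for_blocks(
        pilot, config.blocks, seed=config.seed + 1000,
        n_datasets=config.calibration_datasets,
    )
    return {name: info.priors for name, info in infos.items()}


def analysis_blocks(config: RunConfig):
    names = config.block_subset or (("CT",) + TEST_BLOCK_NAMES)
    return {n: config.blocks[n] for n in names if n in config.blocks}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the result bundle (also written
    to config.out_dir as CSV/JSON)."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.trials_path:
        sessions = io.sessions_from_files(config.trials_path)
        log.info("loaded %d subjects from %s", len(sessions), config.trials_path)
    else:
        cohort_cfg = config.cohort or CohortConfig(seed=config.seed)
        sessions = generate_cohort(cohort_cfg)
        io.write_sessions(sessions, out)
        log.info("generated cohort of %d subjects", len(sessions))
    retained = [s for s in sessions if not s.excluded]
    log.info("retained %d/%d subjects after exclusions", len(retained), len(sessions))

    priors = build_priors(config)
    blocks = analysis_blocks(config)

    fit_rows, sel_rows, psych_rows, cx_rows = [], [], [], []
    recovery_frames = []
    for name, block in blocks.items():
        t_block = time.time()
        fitter = BlockFitter(block, priors[name])
        sel_by_subject = {}
        fits_by_subject = {}
        for s in retained:
            trials = block_trials(s, name)
            if not trials:
                continue
            try:
                result = select_model(
                    trials, block, subject_id=s.subject_id, fitter=fitter
                )
                result.cross_validation_accuracy = cross_validate(
                    trials,
                    block,
                    result.selected_model,
                    prior=priors[name][result.selected_model],
                    seed=config.seed,
                )
                sel_by_subject[s.subject_id] = result.selected_model
                counts = counts_from_trials(trials, block.sample_lengths)
                for m in MODELS:
                    post = fitter.posterior(counts, m)
                    summary = mle_and_credible(post)
                    fit_rows.append(
                        {
                            "subject_id": s.subject_id,
                            "block": name,
                            "model": m,
                            "log_marginal": post.log_marginal,
                            **{f"mle_{k}": v for k, v in summary.mle.items()},
                        }
                    )
                sel_rows.append(
                    {
                        "subject_id": s.subject_id,
                        "block": name,
                        "selected_model": result.selected_model,
                        "group": GROUPS[result.selected_model],
                        "strong_evidence": result.strong_evidence,
                        "cv_accuracy": result.cross_validation_accuracy,
                        **{f"log_bf_{m}": v for m, v in result.log_bf.items()},
                    }
                )
                pf = fit_psychometric(trials, block, seed=config.seed)
                fits_by_subject[s.subject_id] = pf
                psych_rows.append(
                    {
                        "subject_id": s.subject_id,
                        "block": name,
                        "alpha": pf.alpha,
                        "beta": pf.beta,
                        "phi": pf.phi,
                        "bias": pf.bias,
                        "noise": pf.noise,
                        "variance_v": pf.variance_v,
                        "boundary": pf.boundary,
                    }
                )
                cx = subject_complexity(
                    trials,
                    block,
                    subject_id=s.subject_id,
                    selected_model=result.selected_model,
                    n_boot=config.n_boot,
                    seed=config.seed,
                )
                cx_rows.append(
                    {
                        "subject_id": s.subject_id,
                        "block": name,
                        "mi_bits": cx.mi_bits,
                        "mi_with_prev_bits": cx.mi_with_prev_bits,
                        "accuracy": cx.accuracy,
                        "mi_boot_mean": cx.mi_boot_mean,
                        "accuracy_boot_mean": cx.accuracy_boot_mean,
                        "algorithmic_complexity": cx.algorithmic,
                    }
                )
            except Exception:
                log.exception(
                    "subject %s block %s failed; continuing", s.subject_id, name
                )
        if config.recovery_datasets:
            rec = model_recovery_study(
                block, priors[name], config.recovery_datasets, seed=config.seed + 7
            )
            df = pd.DataFrame(rec.confusion, index=list(MODELS), columns=list(MODELS))
            df.insert(0, "generating_model", df.index)
            df.insert(0, "block", name)
            recovery_frames.append(df)
        log.info("block %s done in %.1fs", name, time.time() - t_block)

    bundle = {
        "fits": pd.DataFrame(fit_rows),
        "selection": pd.DataFrame(sel_rows),
        "psychometrics": pd.DataFrame(psych_rows),
        "complexity": pd.DataFrame(cx_rows),
    }
    if recovery_frames:
        bundle["recovery"] = pd.concat(recovery_frames, ignore_index=True)
    write_tables(bundle, out)

    manifest = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "n_subjects": len(sessions),
        "n_retained": len(retained),
        "blocks": sorted(blocks),
        "prior_source": config.prior_source,
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle


def write_tables(bundle: dict, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.items():
        if isinstance(df, pd.DataFrame):
            df.to_csv(out_dir / f"{name}.csv", index=False)


def group_summary_tables(bundle: dict, n_boot: int = 1000, seed: int = 0) -> dict:
    """Per-block strategy-group summaries from a result bundle."""
    psych = bundle["psychometrics"]
    sel = bundle["selection"]
    out = {}
    for name in psych["block"].unique():
        pf = psych[psych["block"] == name].set_index("subject_id")
        sf = sel[sel["block"] == name].set_index("subject_id")

        class _Row:
            def __init__(self, row):
                self.bias = row["bias"]
                self.noise = row["noise"]
                self.variance_v = row["variance_v"]

        fits = {sid: _Row(row) for sid, row in pf.iterrows()}
        assignments = {sid: sf.loc[sid, "selected_model"] for sid in pf.index if sid in sf.index}
        out[name] = group_summaries(fits, assignments, n_boot=n_boot, seed=seed)
    return out
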