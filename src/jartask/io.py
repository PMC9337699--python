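"""CSV and config round-trips.

Trial tables are plain UTF-8 CSV with a header, one row per trial and the
ball sample serialized as a string of R (rare) / C (common) characters in
presentation order.  Trial indices are 0-based.  Block and cohort configs
use YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .cohort import SubjectSession
from .observers import ObserverParams
from .task import BlockConfig, TrialRecord

TRIAL_COLUMNS = [
    "subject_id",
    "block",
    "segment",
    "trial_index",
    "jar",
    "n",
    "sample",
    "rare_count",
    "response",
]


def sample_to_string(sample) -> str:
    return "".join("R" if x == 1 else "C" for x in sample)


def string_to_sample(s: str) -> tuple[int, ...]:
    if not set(s) <= {"R", "C"}:
        raise ValueError(f"sample string {s!r} contains characters other than R/C")
    return tuple(1 if ch == "R" else -1 for ch in s)


def trials_to_frame(trials) -> pd.DataFrame:
    rows = [
        {
            "subject_id": t.subject_id,
            "block": t.block,
            "segment": t.segment,
            "trial_index": t.trial_index,
            "jar": t.jar,
            "n": t.n,
            "sample": sample_to_string(t.sample),
            "rare_count": t.rare_count,
            "response": t.response if t.response is not None else "none",
        }
        for t in trials
    ]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    trials = []
    has_response = "response" in df.columns
    for i, row in enumerate(df.itertuples(index=False)):
        sample = string_to_sample(str(row.sample))
        if len(sample) != int(row.n):
            raise ValueError(
                f"row {i}: sample length {len(sample)} != n column {row.n}"
            )
        response = None
        if has_response:
            r = str(row.response)
            response = None if r in ("none", "nan", "") else r
        trials.append(
            TrialRecord(
                subject_id=str(row.subject_id),
                block=str(row.block),
                trial_index=int(row.trial_index),
                jar=str(row.jar),
                n=int(row.n),
                sample=sample,
                response=response,
                segment=str(getattr(row, "segment", "test")),
            )
        )
    return trials


def write_trials(trials, path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def read_trials(path) -> list[TrialRecord]:
    df = pd.read_csv(path, dtype={"sample": str})
    missing = {"subject_id", "block", "trial_index", "jar", "n", "sample"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return frame_to_trials(df)


def sessions_to_trials(sessions) -> list[TrialRecord]:
    return [t for s in sessions for t in s.trials]


def subjects_to_frame(sessions) -> pd.DataFrame:
    """Truth-label table, kept separate from the trials so fitting code
    cannot see it."""
    rows = [
        {
            "subject_id": s.subject_id,
            "true_model": s.true_model,
            "true_params": json.dumps(s.true_params.as_dict()),
            "block_order": "|".join(s.block_order),
            "excluded": s.excluded,
            "exclusion_reason": s.exclusion_reason or "",
        }
        for s in sessions
    ]
    return pd.DataFrame(rows)


def write_sessions(sessions, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_trials(sessions_to_trials(sessions), out_dir / "trials.csv")
    subjects_to_frame(sessions).to_csv(out_dir / "subjects.csv", index=False)


def sessions_from_files(trials_path, subjects_path=None) -> list[SubjectSession]:
    trials = read_trials(trials_path)
    by_subject: dict[str, list] = {}
    for t in trials:
        by_subject.setdefault(t.subject_id, []).append(t)
    meta = {}
    if subjects_path is not None:
        df = pd.read_csv(subjects_path)
        for row in df.itertuples(index=False):
            params = json.loads(row.true_params)
            model = params.pop("model")
            meta[str(row.subject_id)] = dict(
                true_model=model,
                true_params=ObserverParams(model=model, **params),
                block_order=tuple(str(row.block_order).split("|")),
                excluded=bool(row.excluded),
                exclusion_reason=str(row.exclusion_reason) or None,
            )
    sessions = []
    for sid, ts in by_subject.items():
        ts.sort(key=lambda t: t.trial_index)
        m = meta.get(
            sid,
            dict(
                true_model="unknown",
                true_params=None,
                block_order=(),
                excluded=False,
                exclusion_reason=None,
            ),
        )
        sessions.append(SubjectSession(subject_id=sid, trials=ts, **m))
    return sessions


def block_config_to_dict(block: BlockConfig) -> dict:
    return {
        "name": block.name,
        "h_plus": block.h_plus,
        "h_minus": block.h_minus,
        "n_trials": block.n_trials,
        "sample_lengths": list(block.sample_lengths),
        "prior_high": block.prior_high,
    }


def block_config_from_dict(d: dict) -> BlockConfig:
    return BlockConfig(
        name=d["name"],
        h_plus=float(d["h_plus"]),
        h_minus=float(d["h_minus"]),
        n_trials=int(d.get("n_trials", 42)),
        sample_lengths=tuple(d.get("sample_lengths", (2, 5, 10))),
        prior_high=float(d.get("prior_high", 0.5)),
    )


def write_blocks(blocks: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {name: block_config_to_dict(b) for name, b in blocks.items()}, fh
        )


def read_blocks(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {name: block_config_from_dict(d) for name, d in raw.items()}
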