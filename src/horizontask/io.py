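"""Session log serialization.

One CSV per session, one row per choice, with a JSON sidecar holding the
task configuration and seed.  All files are UTF-8 with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .task import ChoiceRecord, Session, TaskConfig, TrialRecord

__all__ = ["write_session_csv", "read_session_csv", "write_sessions", "read_sessions"]

CSV_COLUMNS = [
    "session_id", "animal_id", "feedback", "trial_id", "horizon",
    "choice_index", "side_chosen", "chosen_outcome", "unchosen_outcome",
    "obs_left", "obs_right", "true_mean_left", "true_mean_right",
]


def write_session_csv(session: Session, path) -> None:
    session.validate()
    rows = []
    for t in session.trials:
        for ch in t.choices:
            rows.append({
                "session_id": session.session_id,
                "animal_id": session.animal_id,
                "feedback": session.feedback,
                "trial_id": t.trial_id,
                "horizon": t.horizon,
                "choice_index": ch.choice_index,
                "side_chosen": ch.chosen_side,
                "chosen_outcome": ch.chosen_outcome,
                "unchosen_outcome": "" if ch.unchosen_outcome is None else ch.unchosen_outcome,
                "obs_left": ";".join(str(v) for v in t.obs_values_left),
                "obs_right": ";".join(str(v) for v in t.obs_values_right),
                "true_mean_left": t.true_mean_left,
                "true_mean_right": t.true_mean_right,
            })
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(
        path, index=False, encoding="utf-8", float_format="%.17g"
    )
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(json.dumps({"config": session.config.to_dict()}, indent=2))


def read_session_csv(path, config: TaskConfig | None = None) -> Session:
    """Load a session CSV (config from the JSON sidecar unless supplied)."""
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip",
                     dtype={"unchosen_outcome": "Int64"})
    if df.empty:
        raise ValueError(f"{path}: empty session file")
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if config is None:
        sidecar = Path(path).with_suffix(".json")
        if sidecar.exists():
            config = TaskConfig.from_dict(json.loads(sidecar.read_text())["config"])
        else:
            config = TaskConfig()
    if df["session_id"].nunique() != 1 or df["animal_id"].nunique() != 1:
        raise ValueError(f"{path}: multiple sessions/animals in one file")
    if df["feedback"].nunique() != 1:
        raise ValueError(f"{path}: mixed feedback conditions in one session")
    feedback = df["feedback"].iloc[0]
    if feedback != config.feedback:
        raise ValueError(
            f"{path}: feedback '{feedback}' does not match config '{config.feedback}'"
        )
    if feedback == "partial" and df["unchosen_outcome"].notna().any():
        raise ValueError(f"{path}: partial-feedback session contains unchosen outcomes")

    trials = []
    for tid, grp in df.groupby("trial_id", sort=True):
        grp = grp.sort_values("choice_index")
        first = grp.iloc[0]
        choices = [
            ChoiceRecord(
                choice_index=int(r.choice_index),
                chosen_side=str(r.side_chosen),
                chosen_outcome=int(r.chosen_outcome),
                unchosen_outcome=None if pd.isna(r.unchosen_outcome) else int(r.unchosen_outcome),
            )
            for r in grp.itertuples()
        ]
        trials.append(TrialRecord(
            trial_id=int(tid),
            horizon=int(first.horizon),
            feedback=feedback,
            true_mean_left=float(first.true_mean_left),
            true_mean_right=float(first.true_mean_right),
            obs_values_left=[int(v) for v in str(first.obs_left).split(";")],
            obs_values_right=[int(v) for v in str(first.obs_right).split(";")],
            choices=choices,
        ))
    session = Session(
        session_id=str(df["session_id"].iloc[0]),
        animal_id=str(df["animal_id"].iloc[0]),
        config=config,
        trials=trials,
    )
    session.validate()
    return session


def write_sessions(sessions, out_dir) -> list:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in sessions:
        p = out_dir / f"{s.session_id}.csv"
        write_session_csv(s, p)
        paths.append(p)
    return paths


def read_sessions(paths_or_dir) -> list:
    p = Path(paths_or_dir) if isinstance(paths_or_dir, (str, Path)) else None
    if p is not None and p.is_dir():
        paths = sorted(p.glob("*.csv"))
    elif p is not None:
        paths = [p]
    else:
        paths = [Path(x) for x in paths_or_dir]
    if not paths:
        raise FileNotFoundError("no session CSV files found")
    return [read_session_csv(path) for path in paths]
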