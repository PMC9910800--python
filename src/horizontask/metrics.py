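"""Descriptive behavioral statistics for horizon-task sessions.

Accuracy is model-defined: a choice is correct when the chosen side has the
strictly higher expected value according to the ideal observer at that
moment (observation-phase beliefs for first choices; beliefs including all
feedback revealed so far for later choices).  Exact EV ties are excluded
from the denominator.  Group-level tests follow the study's convention of
one-sample t-tests over session-level values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .observer import ObserverConfig, summaries_from_counts, _stream_counts

__all__ = [
    "accuracy_table",
    "session_ttest",
    "within_horizon_trend",
    "repetition_table",
    "psychometric",
]


def _choice_frame(sessions, observer: ObserverConfig) -> pd.DataFrame:
    """One row per choice with model EVs, correctness and repetition flags."""
    rows, counts = [], []
    for session in sessions:
        session.validate()
        cfg = session.config
        for trial in session.trials:
            streams = _stream_counts(trial, observer)
            prev_side = None
            for k, choice in enumerate(trial.choices):
                counts_a, _, counts_c = streams[k]
                use = counts_a if k == 0 else counts_c
                counts.append(use["L"])
                counts.append(use["R"])
                rows.append({
                    "session_id": session.session_id,
                    "animal_id": session.animal_id,
                    "feedback": session.feedback,
                    "trial_id": trial.trial_id,
                    "horizon": "long" if trial.horizon == cfg.horizon_long else "short",
                    "choice_index": choice.choice_index,
                    "chose_right": choice.chosen_side == "R",
                    "repeat": None if prev_side is None else choice.chosen_side == prev_side,
                })
                prev_side = choice.chosen_side
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    ev, _ = summaries_from_counts(np.stack(counts), observer)
    ev_l, ev_r = ev[0::2], ev[1::2]
    df["ev_diff"] = ev_r - ev_l
    chose_right = df["chose_right"].to_numpy()
    # EV ties are excluded from accuracy scoring, not credited half; the
    # threshold treats sub-1e-6 gaps (distinct evidence with numerically
    # equal expected value) as ties
    tie = np.abs(df["ev_diff"].to_numpy()) < 1e-6
    df["correct"] = np.where(chose_right, df["ev_diff"] > 0, df["ev_diff"] < 0)
    df["tie"] = tie
    return df


def accuracy_table(sessions, observer: ObserverConfig) -> pd.DataFrame:
    """Accuracy per (feedback, horizon, choice_index): session means averaged.

    Returns columns feedback, horizon, choice_index, accuracy, n_sessions.
    """
    df = _choice_frame(sessions, observer)
    df = df[~df["tie"]]
    per_sess = (
        df.groupby(["feedback", "horizon", "choice_index", "session_id"])["correct"]
        .mean()
        .reset_index()
    )
    out = (
        per_sess.groupby(["feedback", "horizon", "choice_index"])["correct"]
        .agg(accuracy="mean", n_sessions="size")
        .reset_index()
    )
    return out


def session_ttest(per_session_values, null_mean: float):
    """Two-sided one-sample t-test of session values against a null mean.

    Returns (t, dof, p).  With zero variance across sessions the statistic is
    undefined; the degenerate case is reported as t=0, p=1 when every value
    equals the null and as t=+/-inf, p=0 otherwise.
    """
    v = np.asarray(per_session_values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 sessions")
    dof = v.size - 1
    if v.std(ddof=1) == 0:
        if v[0] == null_mean:
            return 0.0, dof, 1.0
        return float(np.sign(v[0] - null_mean)) * np.inf, dof, 0.0
    t, p = stats.ttest_1samp(v, null_mean)
    return float(t), dof, float(p)


def within_horizon_trend(sessions, observer: ObserverConfig,
                         quantity: str = "accuracy"):
    """Per-session slope of a quantity over long-horizon choice position.

    For every session, both the choice index (1-4 for accuracy, 2-4 for
    repetition) and the per-index session means of the quantity are z-scored
    and the OLS slope recorded; a one-sample t-test of the slopes against 0
    gives the group-level trend.  Sessions where the quantity is constant
    have an undefined slope and are dropped (reported in ``n_dropped``).
    """
    if quantity not in ("accuracy", "repetition"):
        raise ValueError("quantity must be 'accuracy' or 'repetition'")
    df = _choice_frame(sessions, observer)
    df = df[df["horizon"] == "long"]
    if quantity == "accuracy":
        df = df[~df["tie"]]
        col = "correct"
    else:
        df = df[df["choice_index"] >= 2]
        col = "repeat"
    per = (
        df.groupby(["session_id", "choice_index"])[col].mean().reset_index()
    )
    slopes = []
    n_dropped = 0
    for sid, grp in per.groupby("session_id"):
        x = grp["choice_index"].to_numpy(dtype=float)
        y = grp[col].to_numpy(dtype=float)
        if len(x) < 2 or y.std() == 0 or x.std() == 0:
            n_dropped += 1
            continue
        zx = (x - x.mean()) / x.std()
        zy = (y - y.mean()) / y.std()
        slopes.append(float(zx @ zy / (zx @ zx)))
    result = {"slopes": np.array(slopes), "n_dropped": n_dropped}
    if len(slopes) >= 2:
        t, dof, p = session_ttest(slopes, 0.0)
        result.update(t=t, dof=dof, p=p)
    else:
        result.update(t=None, dof=None, p=None, degenerate=True)
    return result


def repetition_table(sessions, observer: ObserverConfig) -> pd.DataFrame:
    """P(repeat previous choice) per feedback and long-horizon choice index."""
    df = _choice_frame(sessions, observer)
    df = df[(df["horizon"] == "long") & (df["choice_index"] >= 2)]
    per_sess = (
        df.groupby(["feedback", "choice_index", "session_id"])["repeat"]
        .mean()
        .reset_index()
    )
    return (
        per_sess.groupby(["feedback", "choice_index"])["repeat"]
        .agg(repetition="mean", n_sessions="size")
        .reset_index()
    )


def psychometric(sessions, observer: ObserverConfig, n_bins: int = 11) -> pd.DataFrame:
    """P(choose right) on first choices, binned by the model EV difference.

    Bin edges are symmetric about zero and span the observed |EV difference|.
    Empty bins are reported with NaN probability, not zero.
    """
    df = _choice_frame(sessions, observer)
    df = df[df["choice_index"] == 1]
    lim = float(np.abs(df["ev_diff"]).max()) + 1e-9
    edges = np.linspace(-lim, lim, n_bins + 1)
    which = pd.cut(df["ev_diff"], edges, include_lowest=True)
    grouped = df.groupby(which, observed=False)["chose_right"]
    n = grouped.size()
    k = grouped.sum()
    p = k / n
    se = np.sqrt(p * (1 - p) / n)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({
        "bin_center": centers,
        "n": n.to_numpy(),
        "p_right": p.to_numpy(),
        "se": se.to_numpy(),
    })
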