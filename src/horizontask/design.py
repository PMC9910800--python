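"""Regressor construction for the two logistic choice models.

First choices (one per trial) are modelled as

    P(right) = sigmoid(b_SB + b_RB*RB + b_horizon*H + b_EV*EV + b_U*U
                       + b_EVxH*EV*H + b_UxH*U*H)

where EV and U are right-minus-left differences of the observer's expected
value and uncertainty from the observation phase, H codes the horizon
(+1 short, -1 long) and RB codes the previous completed trial's last choice
(+1 right, -1 left, 0 if none).  The ``info_count`` variant replaces U by the
right-minus-left count of informative observations.

Subsequent choices (choices 2-4 in long-horizon trials) are modelled as

    P(right) = sigmoid(b_SB + b_RB*RB + b_dChosen*dChosen
                       + b_baselineEV*baselineEV + b_dEVchosen*dEVchosen
                       + b_baselineU*baselineU + b_dUchosen*dUchosen
                       + b_dEVunchosen*dEVunchosen + b_dUunchosen*dUunchosen)

where baseline* are observation-phase right-minus-left differences,
d*chosen are the change of those differences due to outcomes of own choices,
and d*unchosen the further change due to counterfactual outcomes (identically
zero under partial feedback).  dChosen is the signed right-minus-left choice
count so far within the trial; RB codes the previous choice within the trial.

Both simulators and design builders call the same regressor functions, so the
model formula exists in exactly one place.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .observer import ObserverConfig, summaries_from_counts, _stream_counts
from .task import Session

__all__ = [
    "FIRST_CHOICE_COLUMNS",
    "SUBSEQUENT_COLUMNS",
    "GROUP_COLUMNS",
    "first_choice_regressors",
    "subsequent_regressors",
    "build_first_choice_design",
    "build_subsequent_choice_design",
]

FIRST_CHOICE_COLUMNS = ["SB", "RB", "horizon", "EV", "U", "EVxhorizon", "Uxhorizon"]
SUBSEQUENT_COLUMNS = [
    "SB",
    "RB",
    "dChosen",
    "baselineEV",
    "dEVchosen",
    "baselineU",
    "dUchosen",
    "dEVunchosen",
    "dUunchosen",
]
GROUP_COLUMNS = ["animal_id", "session_id", "feedback", "choice_kind"]

HORIZON_CODE = {"short": 1.0, "long": -1.0}
SIDE_CODE = {"R": 1.0, "L": -1.0}


def first_choice_regressors(ev_diff, u_diff, rb, horizon_sign):
    """Eq-style first-choice regressor dict (right-minus-left convention)."""
    return {
        "SB": 1.0,
        "RB": rb,
        "horizon": horizon_sign,
        "EV": ev_diff,
        "U": u_diff,
        "EVxhorizon": ev_diff * horizon_sign,
        "Uxhorizon": u_diff * horizon_sign,
    }


def subsequent_regressors(
    baseline_ev,
    baseline_u,
    ev_b_diff,
    u_b_diff,
    ev_c_diff,
    u_c_diff,
    delta_chosen,
    rb,
):
    """Subsequent-choice regressors from stream summaries.

    ``*_b`` values are right-minus-left EV/U including own-choice feedback
    (stream b); ``*_c`` additionally include counterfactual feedback
    (stream c).
    """
    return {
        "SB": 1.0,
        "RB": rb,
        "dChosen": delta_chosen,
        "baselineEV": baseline_ev,
        "dEVchosen": ev_b_diff - baseline_ev,
        "baselineU": baseline_u,
        "dUchosen": u_b_diff - baseline_u,
        "dEVunchosen": ev_c_diff - ev_b_diff,
        "dUunchosen": u_c_diff - u_b_diff,
    }


def _horizon_sign(trial, config) -> float:
    if trial.horizon == config.horizon_short:
        return HORIZON_CODE["short"]
    if trial.horizon == config.horizon_long:
        return HORIZON_CODE["long"]
    raise ValueError(f"trial {trial.trial_id}: unknown horizon {trial.horizon}")


def _batch_summaries(counts_rows, observer: ObserverConfig):
    if not counts_rows:
        return np.zeros(0), np.zeros(0)
    ev, u = summaries_from_counts(np.stack(counts_rows), observer)
    return ev, u


def build_first_choice_design(
    sessions, observer: ObserverConfig, variant: str = "uncertainty"
) -> pd.DataFrame:
    """One row per first choice, with Eq-4-style regressors.

    ``variant='info_count'`` replaces the uncertainty difference by the
    right-minus-left count of informative observations (and uses it in the
    horizon interaction).
    """
    if variant not in ("uncertainty", "info_count"):
        raise ValueError("variant must be 'uncertainty' or 'info_count'")
    rows, counts = [], []
    for session in sessions:
        session.validate()
        prev_last_side = None
        for trial in session.trials:
            if not trial.choices:
                raise ValueError(
                    f"session {session.session_id} trial {trial.trial_id}: "
                    "no choices; beliefs/design need completed trials"
                )
            rb = SIDE_CODE.get(prev_last_side, 0.0)
            counts.append(observer.observation_counts(trial.obs_values_left))
            counts.append(observer.observation_counts(trial.obs_values_right))
            rows.append(
                {
                    "animal_id": session.animal_id,
                    "session_id": session.session_id,
                    "feedback": session.feedback,
                    "choice_kind": "first",
                    "trial_id": trial.trial_id,
                    "response": 1 if trial.choices[0].chosen_side == "R" else 0,
                    "rb": rb,
                    "h": _horizon_sign(trial, session.config),
                    "n_info_diff": float(
                        len(trial.obs_values_right) - len(trial.obs_values_left)
                    ),
                }
            )
            prev_last_side = trial.choices[-1].chosen_side
    ev, u = _batch_summaries(counts, observer)
    ev_diff = ev[1::2] - ev[0::2]
    u_diff = u[1::2] - u[0::2]
    out = []
    for i, row in enumerate(rows):
        ud = row["n_info_diff"] if variant == "info_count" else u_diff[i]
        reg = first_choice_regressors(ev_diff[i], ud, row["rb"], row["h"])
        rec = {k: row[k] for k in GROUP_COLUMNS + ["trial_id", "response"]}
        rec.update(reg)
        out.append(rec)
    df = pd.DataFrame(out, columns=GROUP_COLUMNS + ["trial_id", "response"] + FIRST_CHOICE_COLUMNS)
    if not np.isfinite(df[FIRST_CHOICE_COLUMNS].to_numpy()).all():
        raise ValueError("non-finite regressor value in first-choice design")
    return df


def build_subsequent_choice_design(sessions, observer: ObserverConfig) -> pd.DataFrame:
    """One row per choice 2..4 of each long-horizon trial."""
    rows, counts = [], []
    for session in sessions:
        session.validate()
        cfg = session.config
        for trial in session.trials:
            if trial.horizon != cfg.horizon_long or len(trial.choices) < 2:
                continue
            streams = _stream_counts(trial, observer)
            n_right = 0
            prev_side = None
            for k, choice in enumerate(trial.choices):
                if k > 0:
                    counts_a, counts_b, counts_c = streams[k]
                    for cdict in (counts_a, counts_b, counts_c):
                        counts.append(cdict["L"])
                        counts.append(cdict["R"])
                    rows.append(
                        {
                            "animal_id": session.animal_id,
                            "session_id": session.session_id,
                            "feedback": session.feedback,
                            "choice_kind": "subsequent",
                            "trial_id": trial.trial_id,
                            "choice_index": choice.choice_index,
                            "response": 1 if choice.chosen_side == "R" else 0,
                            "rb": SIDE_CODE[prev_side],
                            "dchosen": float(n_right - (k - n_right)),
                        }
                    )
                n_right += choice.chosen_side == "R"
                prev_side = choice.chosen_side
    ev, u = _batch_summaries(counts, observer)
    # per design row, six summaries in order aL aR bL bR cL cR
    ev = ev.reshape(-1, 6)
    u = u.reshape(-1, 6)
    out = []
    for i, row in enumerate(rows):
        reg = subsequent_regressors(
            baseline_ev=ev[i, 1] - ev[i, 0],
            baseline_u=u[i, 1] - u[i, 0],
            ev_b_diff=ev[i, 3] - ev[i, 2],
            u_b_diff=u[i, 3] - u[i, 2],
            ev_c_diff=ev[i, 5] - ev[i, 4],
            u_c_diff=u[i, 5] - u[i, 4],
            delta_chosen=row["dchosen"],
            rb=row["rb"],
        )
        rec = {
            k: row[k]
            for k in GROUP_COLUMNS + ["trial_id", "choice_index", "response"]
        }
        rec.update(reg)
        out.append(rec)
    df = pd.DataFrame(
        out,
        columns=GROUP_COLUMNS
        + ["trial_id", "choice_index", "response"]
        + SUBSEQUENT_COLUMNS,
    )
    if len(df):
        partial = df["feedback"] == "partial"
        if not np.allclose(df.loc[partial, ["dEVunchosen", "dUunchosen"]], 0.0):
            raise AssertionError("counterfactual regressors nonzero under partial feedback")
        if not np.isfinite(df[SUBSEQUENT_COLUMNS].to_numpy()).all():
            raise ValueError("non-finite regressor value in subsequent-choice design")
    return df
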