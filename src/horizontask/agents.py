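"""Choice-generating agents: the generative inverse of the two choice models.

An agent carries one coefficient vector per choice model (first choices;
subsequent long-horizon choices).  At every choice point it computes the same
regressors the design builder would, passes the linear predictor through a
logistic, optionally mixes in a lapse (uniform random choice), samples a
side, and then observes outcomes according to the session's feedback
condition before the next choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .design import (
    FIRST_CHOICE_COLUMNS,
    SUBSEQUENT_COLUMNS,
    SIDE_CODE,
    _horizon_sign,
    first_choice_regressors,
    subsequent_regressors,
)
from .observer import ObserverConfig, summaries_from_counts
from .task import ChoiceRecord, Session, TaskConfig, TrialRecord, sample_outcome

__all__ = ["AgentParams", "simulate_agent", "simulate_session", "study_agent_params"]


@dataclass
class AgentParams:
    """Ground-truth coefficients for a simulated animal.

    ``first`` must supply every first-choice coefficient, ``subsequent``
    every subsequent-choice coefficient; ``lapse_rate`` is the probability of
    an unconditionally random choice.
    """

    first: dict
    subsequent: dict
    lapse_rate: float = 0.0

    def __post_init__(self):
        missing = set(FIRST_CHOICE_COLUMNS) - set(self.first)
        if missing:
            raise ValueError(f"first-choice coefficients missing: {sorted(missing)}")
        missing = set(SUBSEQUENT_COLUMNS) - set(self.subsequent)
        if missing:
            raise ValueError(f"subsequent-choice coefficients missing: {sorted(missing)}")
        vals = list(self.first.values()) + list(self.subsequent.values())
        if not np.all(np.isfinite(vals)):
            raise ValueError("coefficients must be finite")
        if not (0.0 <= self.lapse_rate < 0.5):
            raise ValueError("lapse_rate must be in [0, 0.5)")


def _p_right(regressors: dict, coef: dict, lapse: float) -> float:
    eta = sum(coef[k] * regressors[k] for k in coef)
    p = expit(eta)
    return (1.0 - lapse) * p + 0.5 * lapse


def simulate_agent(
    session_trials,
    params: AgentParams,
    config: TaskConfig,
    observer: ObserverConfig,
    rng_seed: int,
):
    """Fill in the choices of a generated session (in place copy returned).

    Both sides' outcomes are drawn every choice; the unchosen outcome is
    recorded -- and enters the agent's beliefs -- only under complete
    feedback.
    """
    rng = np.random.default_rng(rng_seed)
    complete = config.feedback == "complete"
    out = []
    prev_trial_last_side = None
    for trial in session_trials:
        if trial.choices:
            raise ValueError("session already contains choices")
        counts = {
            "L": observer.observation_counts(trial.obs_values_left),
            "R": observer.observation_counts(trial.obs_values_right),
        }
        counts_b = {s: counts[s].copy() for s in "LR"}  # own-choice stream
        ev, u = summaries_from_counts(np.stack([counts["L"], counts["R"]]), observer)
        baseline_ev, baseline_u = ev[1] - ev[0], u[1] - u[0]
        choices = []
        n_right = 0
        prev_side = None
        for k in range(trial.horizon):
            if k == 0:
                reg = first_choice_regressors(
                    baseline_ev,
                    baseline_u,
                    SIDE_CODE.get(prev_trial_last_side, 0.0),
                    _horizon_sign(trial, config),
                )
                p = _p_right(reg, params.first, params.lapse_rate)
            else:
                evc, uc = summaries_from_counts(
                    np.stack([counts_b["L"], counts_b["R"], counts["L"], counts["R"]]),
                    observer,
                )
                reg = subsequent_regressors(
                    baseline_ev=baseline_ev,
                    baseline_u=baseline_u,
                    ev_b_diff=evc[1] - evc[0],
                    u_b_diff=uc[1] - uc[0],
                    ev_c_diff=evc[3] - evc[2],
                    u_c_diff=uc[3] - uc[2],
                    delta_chosen=float(n_right - (k - n_right)),
                    rb=SIDE_CODE[prev_side],
                )
                p = _p_right(reg, params.subsequent, params.lapse_rate)
            side = "R" if rng.random() < p else "L"
            other = "L" if side == "R" else "R"
            mu = {"L": trial.true_mean_left, "R": trial.true_mean_right}
            outcome = sample_outcome(mu[side], config, rng)
            alt = sample_outcome(mu[other], config, rng)
            choices.append(
                ChoiceRecord(
                    choice_index=k + 1,
                    chosen_side=side,
                    chosen_outcome=outcome,
                    unchosen_outcome=alt if complete else None,
                )
            )
            idx = observer.support_index([outcome])[0]
            counts_b[side][idx] += 1.0
            counts[side][idx] += 1.0
            if complete:
                aidx = observer.support_index([alt])[0]
                counts[other][aidx] += 1.0
            n_right += side == "R"
            prev_side = side
        out.append(
            TrialRecord(
                trial_id=trial.trial_id,
                horizon=trial.horizon,
                feedback=trial.feedback,
                true_mean_left=trial.true_mean_left,
                true_mean_right=trial.true_mean_right,
                obs_values_left=list(trial.obs_values_left),
                obs_values_right=list(trial.obs_values_right),
                choices=choices,
            )
        )
        prev_trial_last_side = choices[-1].chosen_side
    return out


def simulate_session(
    session_id: str,
    animal_id: str,
    config: TaskConfig,
    params: AgentParams,
    observer: ObserverConfig,
    rng_seed: int,
) -> Session:
    """Generate and play out one full session."""
    from .task import generate_session

    trials = generate_session(config, rng_seed)
    played = simulate_agent(trials, params, config, observer, rng_seed + 1)
    return Session(session_id=session_id, animal_id=animal_id, config=config, trials=played)


def study_agent_params(feedback: str) -> AgentParams:
    """Study-like generative coefficients for one feedback condition.

    The values encode the qualitative behavioral pattern of the task:
    stronger reliance on expected value under complete than partial feedback;
    within partial feedback a weaker EV effect in the long horizon (a positive
    EV-by-horizon interaction, i.e. more random exploration when information
    is useful and choice-contingent); mild risk aversion; a repetition bias
    that is stronger under partial feedback; sensitivity to chosen-outcome
    updates in both conditions and to counterfactual updates only where they
    exist (complete feedback).
    """
    if feedback == "partial":
        first = {"SB": 0.0, "RB": 0.3, "horizon": 0.0, "EV": 0.8, "U": -0.1,
                 "EVxhorizon": 0.25, "Uxhorizon": 0.0}
        subsequent = {"SB": 0.0, "RB": 0.8, "dChosen": 0.3, "baselineEV": 0.6,
                      "dEVchosen": 0.6, "baselineU": -0.1, "dUchosen": 0.0,
                      "dEVunchosen": 0.0, "dUunchosen": 0.0}
    elif feedback == "complete":
        first = {"SB": 0.0, "RB": 0.3, "horizon": 0.0, "EV": 1.2, "U": -0.1,
                 "EVxhorizon": 0.0, "Uxhorizon": 0.0}
        subsequent = {"SB": 0.0, "RB": 0.5, "dChosen": 0.3, "baselineEV": 0.9,
                      "dEVchosen": 0.6, "baselineU": -0.1, "dUchosen": 0.0,
                      "dEVunchosen": 0.5, "dUunchosen": 0.0}
    else:
        raise ValueError("feedback must be 'partial' or 'complete'")
    return AgentParams(first=first, subsequent=subsequent)
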