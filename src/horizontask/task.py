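"""Horizon-task structure and session generation.

A session is a sequence of two-option trials.  Each option pays integer juice
drops (0-10) drawn from a Gaussian with a fixed per-trial mean in [3, 7] and
SD 1.5.  Every trial opens with an observation phase of 4 informative samples
split 2/2 or 3/1 between the sides, then the animal makes 1 (short horizon)
or 4 (long horizon) choices.  Horizon alternates in blocks of 5 trials; the
feedback condition (partial: chosen outcome only; complete: both outcomes) is
fixed for a whole session.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = [
    "TaskConfig",
    "ChoiceRecord",
    "TrialRecord",
    "Session",
    "generate_session",
    "sample_outcome",
    "mirror_trial",
    "mirror_session",
]

FEEDBACK_CONDITIONS = ("partial", "complete")


@dataclass
class TaskConfig:
    """Generative parameters of the task; defaults are the study's values."""

    outcome_sd: float = 1.5
    mean_low: float = 3.0
    mean_high: float = 7.0
    outcome_min: int = 0
    outcome_max: int = 10
    n_observations: int = 4
    block_length: int = 5
    horizon_short: int = 1
    horizon_long: int = 4
    feedback: str = "partial"
    trials_per_session: int = 150
    seed: Optional[int] = None

    def __post_init__(self):
        if self.outcome_min >= self.outcome_max:
            raise ValueError("outcome_min must be < outcome_max")
        if not (self.mean_low >= self.outcome_min and self.mean_high <= self.outcome_max):
            raise ValueError("mean range must lie inside the outcome range")
        if self.mean_low >= self.mean_high:
            raise ValueError("mean_low must be < mean_high")
        if self.n_observations < 2:
            raise ValueError("need >= 2 observations so each side gets >= 1")
        if self.horizon_short >= self.horizon_long:
            raise ValueError("horizon_short must be < horizon_long")
        if self.outcome_sd <= 0:
            raise ValueError("outcome_sd must be positive")
        if self.feedback not in FEEDBACK_CONDITIONS:
            raise ValueError(f"feedback must be one of {FEEDBACK_CONDITIONS}")
        period = 2 * self.block_length
        if self.trials_per_session <= 0 or self.trials_per_session % period:
            raise ValueError(
                "trials_per_session must be a positive multiple of "
                f"2*block_length={period} so horizons alternate in whole "
                "blocks and the information-split balance is exact"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        return cls(**d)


@dataclass
class ChoiceRecord:
    choice_index: int                      # 1-based position within the trial
    chosen_side: str                       # 'L' or 'R'
    chosen_outcome: int
    unchosen_outcome: Optional[int] = None  # present iff complete feedback

    def __post_init__(self):
        if self.chosen_side not in ("L", "R"):
            raise ValueError("chosen_side must be 'L' or 'R'")


@dataclass
class TrialRecord:
    trial_id: int
    horizon: int
    feedback: str
    true_mean_left: float
    true_mean_right: float
    obs_values_left: list
    obs_values_right: list
    choices: list = field(default_factory=list)

    def validate(self, config: TaskConfig) -> None:
        n_obs = len(self.obs_values_left) + len(self.obs_values_right)
        if n_obs != config.n_observations:
            raise ValueError(f"trial {self.trial_id}: {n_obs} observations")
        if not self.obs_values_left or not self.obs_values_right:
            raise ValueError(f"trial {self.trial_id}: a side has no observation")
        if len(self.choices) > self.horizon:
            raise ValueError(f"trial {self.trial_id}: more choices than horizon")
        for v in list(self.obs_values_left) + list(self.obs_values_right):
            if not (config.outcome_min <= v <= config.outcome_max):
                raise ValueError(f"trial {self.trial_id}: outcome {v} out of range")
        for ch in self.choices:
            has_cf = ch.unchosen_outcome is not None
            if has_cf != (self.feedback == "complete"):
                raise ValueError(
                    f"trial {self.trial_id}: unchosen_outcome must be present "
                    "iff feedback is complete"
                )


@dataclass
class Session:
    """One testing session: metadata plus its trials."""

    session_id: str
    animal_id: str
    config: TaskConfig
    trials: list

    @property
    def feedback(self) -> str:
        return self.config.feedback

    def validate(self) -> None:
        for t in self.trials:
            if t.feedback != self.config.feedback:
                raise ValueError("mixed feedback conditions in one session")
            t.validate(self.config)


def sample_outcome(mean: float, config: TaskConfig, rng: np.random.Generator,
                   raw: bool = False) -> float:
    """One outcome: Gaussian(mean, outcome_sd), rounded half-up, clamped.

    With ``raw=True`` the pre-rounding Gaussian draw is returned (used to
    verify the generative SD).
    """
    x = rng.normal(mean, config.outcome_sd)
    if raw:
        return x
    return int(np.clip(np.floor(x + 0.5), config.outcome_min, config.outcome_max))


def _draw_distinct_means(config: TaskConfig, rng: np.random.Generator):
    # resample until the two means are distinguishable (one 0.05 grid step)
    while True:
        lo, hi = config.mean_low, config.mean_high
        m = rng.uniform(lo, hi, size=2)
        if abs(m[0] - m[1]) >= 0.05:
            return float(m[0]), float(m[1])


def generate_session(config: TaskConfig, rng_seed: int) -> list:
    """Generate the trials of one session (choices left empty).

    Horizon labels alternate in runs of exactly ``block_length``; exactly half
    the trials get a 2/2 informative split and half a 3/1 split (the 3-side
    randomized), assigned by shuffling a balanced label vector.
    """
    config.__post_init__()  # re-validate in case fields were mutated
    rng = np.random.default_rng(rng_seed)
    n = config.trials_per_session

    n_blocks = n // config.block_length
    start_long = bool(rng.integers(2))
    horizons = []
    for b in range(n_blocks):
        is_long = (b % 2 == 0) == start_long
        h = config.horizon_long if is_long else config.horizon_short
        horizons.extend([h] * config.block_length)

    equal_split = np.zeros(n, dtype=bool)
    equal_split[: n // 2] = True
    rng.shuffle(equal_split)

    k = config.n_observations
    trials = []
    for i in range(n):
        mu_l, mu_r = _draw_distinct_means(config, rng)
        if equal_split[i]:
            n_left = k // 2
        else:
            n_left = (k - 1) if rng.integers(2) else 1  # 3/1 for k=4
        obs_l = [sample_outcome(mu_l, config, rng) for _ in range(n_left)]
        obs_r = [sample_outcome(mu_r, config, rng) for _ in range(k - n_left)]
        trials.append(
            TrialRecord(
                trial_id=i,
                horizon=horizons[i],
                feedback=config.feedback,
                true_mean_left=mu_l,
                true_mean_right=mu_r,
                obs_values_left=obs_l,
                obs_values_right=obs_r,
            )
        )
    return trials


def mirror_trial(trial: TrialRecord) -> TrialRecord:
    """Swap the two sides of a trial (options, observations and choices)."""
    return TrialRecord(
        trial_id=trial.trial_id,
        horizon=trial.horizon,
        feedback=trial.feedback,
        true_mean_left=trial.true_mean_right,
        true_mean_right=trial.true_mean_left,
        obs_values_left=list(trial.obs_values_right),
        obs_values_right=list(trial.obs_values_left),
        choices=[
            ChoiceRecord(
                choice_index=c.choice_index,
                chosen_side="R" if c.chosen_side == "L" else "L",
                chosen_outcome=c.chosen_outcome,
                unchosen_outcome=c.unchosen_outcome,
            )
            for c in trial.choices
        ],
    )


def mirror_session(session: Session) -> Session:
    return Session(
        session_id=session.session_id,
        animal_id=session.animal_id,
        config=session.config,
        trials=[mirror_trial(t) for t in session.trials],
    )
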