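"""Ideal Bayesian observer for the horizon task.

Each option pays out integer juice drops drawn from a Gaussian with unknown
mean and known SD.  The observer maintains a discretized posterior over
candidate means, mixes it into a posterior predictive over the next outcome,
and summarises that predictive by its mean (expected value, EV) and variance
(uncertainty, U).  Only outcomes actually revealed on screen enter the
computation; the observer knows nothing about horizon or feedback condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .task import TrialRecord

__all__ = [
    "ObserverConfig",
    "BeliefState",
    "outcome_likelihood",
    "posterior_over_means",
    "predictive_next_outcome",
    "belief_summary",
    "belief_state",
    "belief_trajectory",
]


class ObserverConfig:
    """Discretization of the observer's inference problem.

    Parameters
    ----------
    mean_grid:
        Ordered candidate means ``mu_j`` (drops).  Defaults to a 0.05-step
        grid spanning the full 0-10 outcome range: the observer is not told
        the generative mean range and reasons over everything the screen
        could show.
    sigma:
        Known outcome SD (drops).
    outcome_support:
        Ordered outcome values the screen can display (integer drops 0-10
        by default).
    prior:
        Prior probability over ``mean_grid``; uniform by default.
    """

    def __init__(
        self,
        mean_grid: np.ndarray | None = None,
        sigma: float = 1.5,
        outcome_support: np.ndarray | None = None,
        prior: np.ndarray | None = None,
    ):
        if mean_grid is None:
            mean_grid = np.round(np.arange(0.0, 10.0001, 0.05), 10)
        self.mean_grid = np.asarray(mean_grid, dtype=float)
        if self.mean_grid.ndim != 1 or np.any(np.diff(self.mean_grid) <= 0):
            raise ValueError("mean_grid must be 1-D and strictly increasing")
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        self.sigma = float(sigma)
        if outcome_support is None:
            outcome_support = np.arange(0, 11)
        self.outcome_support = np.asarray(outcome_support, dtype=float)
        if self.outcome_support.ndim != 1 or np.any(np.diff(self.outcome_support) <= 0):
            raise ValueError("outcome_support must be 1-D and strictly increasing")
        if prior is None:
            prior = np.full(self.mean_grid.size, 1.0 / self.mean_grid.size)
        self.prior = np.asarray(prior, dtype=float)
        if self.prior.shape != self.mean_grid.shape:
            raise ValueError("prior must match mean_grid shape")
        if abs(self.prior.sum() - 1.0) > 1e-12:
            raise ValueError("prior must sum to 1 within 1e-12")

        # likelihood matrix P(x | mu): Gaussian kernel at the support points,
        # normalized over x for each mu so every column is a distribution
        x = self.outcome_support[:, None]
        mu = self.mean_grid[None, :]
        logk = -0.5 * ((x - mu) / self.sigma) ** 2
        logk -= logsumexp(logk, axis=0, keepdims=True)
        self._log_lik = logk                      # (n_x, n_mu)
        self._lik = np.exp(logk)
        self._log_prior = np.log(self.prior)

    def support_index(self, outcomes) -> np.ndarray:
        """Map outcome values onto support indices, rejecting foreign values."""
        obs = np.atleast_1d(np.asarray(outcomes, dtype=float))
        idx = np.searchsorted(self.outcome_support, obs)
        idx = np.clip(idx, 0, self.outcome_support.size - 1)
        if not np.allclose(self.outcome_support[idx], obs, atol=1e-9):
            bad = obs[~np.isclose(self.outcome_support[idx], obs, atol=1e-9)]
            raise ValueError(f"outcome(s) {bad.tolist()} not in outcome_support")
        return idx

    def observation_counts(self, outcomes) -> np.ndarray:
        """Multiplicity of each support value among `outcomes` (order-free)."""
        counts = np.zeros(self.outcome_support.size)
        if len(outcomes):
            np.add.at(counts, self.support_index(outcomes), 1.0)
        return counts


@dataclass(frozen=True)
class BeliefState:
    """Posterior beliefs about one option at one moment."""

    posterior: np.ndarray          # P(mu | observations) over mean_grid
    predictive: np.ndarray         # P(next outcome) over outcome_support
    expected_value: float          # EV: mean of the predictive (drops)
    uncertainty: float             # U: variance of the predictive (drops^2)
    n_observations: int = 0


def outcome_likelihood(x: float, mu: float, config: ObserverConfig) -> float:
    """P(outcome x | candidate mean mu) under the discretized Gaussian."""
    xi = int(config.support_index([x])[0])
    j = np.searchsorted(config.mean_grid, mu)
    j = min(j, config.mean_grid.size - 1)
    if not np.isclose(config.mean_grid[j], mu, atol=1e-9):
        raise ValueError(f"mu={mu} not in mean_grid")
    return float(config._lik[xi, j])


def _log_posterior_from_counts(counts: np.ndarray, config: ObserverConfig) -> np.ndarray:
    # counts: (..., n_x); i.i.d. likelihood factorizes over observations so
    # only the outcome multiplicities matter
    logpost = config._log_prior + counts @ config._log_lik
    norm = logsumexp(logpost, axis=-1, keepdims=True)
    if not np.all(np.isfinite(norm)):
        raise FloatingPointError("posterior has no mass; check prior/likelihood")
    return logpost - norm


def posterior_from_counts(counts: np.ndarray, config: ObserverConfig) -> np.ndarray:
    """Batched posterior over means from outcome-count vectors (log-space)."""
    return np.exp(_log_posterior_from_counts(np.asarray(counts, dtype=float), config))


def posterior_over_means(observations, config: ObserverConfig) -> np.ndarray:
    """Posterior over candidate means given observed outcomes.

    Computed in log space (prior plus summed log-likelihoods, renormalized
    with a logsumexp) so long observation lists cannot underflow.  An empty
    observation list returns the prior.
    """
    return posterior_from_counts(config.observation_counts(observations), config)


def predictive_next_outcome(posterior: np.ndarray, config: ObserverConfig) -> np.ndarray:
    """Posterior predictive P(next outcome) = sum_j P(x | mu_j) P(mu_j | data)."""
    posterior = np.asarray(posterior, dtype=float)
    pred = posterior @ config._lik.T
    s = pred.sum(axis=-1, keepdims=True)
    if np.any(np.abs(s - 1.0) > 1e-8):
        raise ValueError("posterior is not normalized")
    return pred / s


def belief_summary(predictive: np.ndarray, config: ObserverConfig) -> tuple:
    """(expected value, uncertainty) = (mean, variance) of the predictive."""
    x = config.outcome_support
    predictive = np.asarray(predictive, dtype=float)
    ev = predictive @ x
    u = predictive @ (x**2) - ev**2
    return ev, np.maximum(u, 0.0)


def belief_state(observations, config: ObserverConfig) -> BeliefState:
    """Full belief bundle (posterior, predictive, EV, U) for one option."""
    post = posterior_over_means(observations, config)
    pred = predictive_next_outcome(post, config)
    ev, u = belief_summary(pred, config)
    return BeliefState(post, pred, float(ev), float(u), len(observations))


def _stream_counts(trial: TrialRecord, config: ObserverConfig):
    """Outcome-count vectors for belief streams at every choice point.

    For choice k (1-based) the streams contain, per side:

    - ``a`` (baseline): the informative observation phase only;
    - ``b`` (chosen-only): baseline plus outcomes of own choices 1..k-1;
    - ``c`` (full): stream b plus counterfactual outcomes revealed under
      complete feedback.  Under partial feedback b and c coincide.

    Nothing revealed at or after choice k leaks into the choice-k streams.
    """
    base = {
        "L": config.observation_counts(trial.obs_values_left),
        "R": config.observation_counts(trial.obs_values_right),
    }
    complete = trial.feedback == "complete"
    b = {s: base[s].copy() for s in "LR"}
    c = {s: base[s].copy() for s in "LR"}
    out = []
    for choice in trial.choices:
        out.append(
            (
                {s: base[s].copy() for s in "LR"},
                {s: b[s].copy() for s in "LR"},
                {s: c[s].copy() for s in "LR"},
            )
        )
        side = choice.chosen_side
        other = "R" if side == "L" else "L"
        idx = config.support_index([choice.chosen_outcome])[0]
        b[side][idx] += 1.0
        c[side][idx] += 1.0
        if complete:
            if choice.unchosen_outcome is None:
                raise ValueError("complete-feedback choice lacks unchosen_outcome")
            uidx = config.support_index([choice.unchosen_outcome])[0]
            c[other][uidx] += 1.0
    return out


def belief_trajectory(trial: TrialRecord, config: ObserverConfig):
    """Per-choice beliefs for both options along a completed trial.

    Returns a list (one entry per choice made) of dicts keyed by stream
    ('a', 'b', 'c'); each stream maps side 'L'/'R' to a :class:`BeliefState`.
    """
    if not trial.choices:
        raise ValueError("trial has no choices; simulate it first")
    out = []
    for counts_a, counts_b, counts_c in _stream_counts(trial, config):
        entry = {}
        for name, counts in (("a", counts_a), ("b", counts_b), ("c", counts_c)):
            entry[name] = {
                side: _state_from_counts(counts[side], config) for side in "LR"
            }
        out.append(entry)
    return out


def _state_from_counts(counts: np.ndarray, config: ObserverConfig) -> BeliefState:
    post = posterior_from_counts(counts, config)
    pred = predictive_next_outcome(post, config)
    ev, u = belief_summary(pred, config)
    return BeliefState(post, pred, float(ev), float(u), int(counts.sum()))


def summaries_from_counts(counts: np.ndarray, config: ObserverConfig):
    """Batched (EV, U) straight from outcome-count vectors.

    The workhorse for design building and agent simulation: one matmul per
    call instead of one per belief.
    """
    post = posterior_from_counts(counts, config)
    pred = post @ config._lik.T
    pred /= pred.sum(axis=-1, keepdims=True)
    return belief_summary(pred, config)
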