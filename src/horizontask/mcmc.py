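"""Adaptive Hamiltonian Monte Carlo.

A compact HMC implementation used by the hierarchical logistic fit: jittered
leapfrog trajectories, dual-averaging step-size adaptation, and a diagonal
mass matrix estimated during a warmup window.  The target is supplied as a
single callable returning the log density and its gradient; the hierarchical
models here use a non-centered parameterization, which keeps their posteriors
close to Gaussian and well inside this sampler's comfort zone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["sample_hmc", "HMCResult"]

DIVERGENCE_THRESHOLD = 1000.0  # energy error treated as a divergence


@dataclass
class HMCResult:
    draws: np.ndarray          # (n_chains, n_samples, dim)
    accept_rate: np.ndarray    # per chain
    n_divergent: np.ndarray    # per chain
    step_size: np.ndarray      # per chain, post-adaptation


def _leapfrog(logp_grad, q, p, eps, n_steps, inv_mass):
    lp, grad = logp_grad(q)
    p = p + 0.5 * eps * grad
    for i in range(n_steps):
        q = q + eps * inv_mass * p
        lp, grad = logp_grad(q)
        if not np.isfinite(lp):
            return q, p, -np.inf
        p = p + (eps if i < n_steps - 1 else 0.5 * eps) * grad
    return q, p, lp


class _DualAveraging:
    """Nesterov dual averaging of log step size (standard HMC constants)."""

    def __init__(self, eps0, target):
        self.mu = np.log(10 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.m = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, alpha):
        self.m += 1
        w = 1.0 / (self.m + self.t0)
        self.h_bar = (1 - w) * self.h_bar + w * (self.target - alpha)
        self.log_eps = self.mu - np.sqrt(self.m) / self.gamma * self.h_bar
        wk = self.m ** (-self.kappa)
        self.log_eps_bar = wk * self.log_eps + (1 - wk) * self.log_eps_bar
        return np.exp(self.log_eps)

    @property
    def adapted(self):
        return np.exp(self.log_eps_bar)


def _one_chain(logp_grad, q0, n_warmup, n_samples, rng, target_accept,
               path_length, max_leapfrog):
    dim = q0.size
    q = q0.copy()
    lp, _ = logp_grad(q)
    if not np.isfinite(lp):
        raise ValueError("non-finite log density at the initial point")
    inv_mass = np.ones(dim)
    sqrt_mass = np.ones(dim)

    eps = 0.1
    da = _DualAveraging(eps, target_accept)
    mass_window = []
    # warmup phases: [0, w1) step-size only; [w1, w2) also collect draws for
    # the diagonal mass estimate; [w2, n_warmup) re-adapt step size under the
    # new metric with a fresh dual-averaging state
    w1, w2 = int(0.3 * n_warmup), int(0.7 * n_warmup)
    draws = np.empty((n_samples, dim))
    n_div = 0

    total = n_warmup + n_samples
    for it in range(total):
        warming = it < n_warmup
        p = rng.standard_normal(dim) * sqrt_mass
        h0 = -lp + 0.5 * np.sum(inv_mass * p * p)
        n_steps = max(1, min(max_leapfrog,
                             int(round(path_length / eps * rng.uniform(0.7, 1.3)))))
        q_new, p_new, lp_new = _leapfrog(logp_grad, q, p, eps, n_steps, inv_mass)
        h1 = -lp_new + 0.5 * np.sum(inv_mass * p_new * p_new)
        d_energy = h1 - h0
        if not np.isfinite(d_energy) or d_energy > DIVERGENCE_THRESHOLD:
            alpha = 0.0
            n_div += not warming
        else:
            alpha = min(1.0, np.exp(-d_energy))
            if rng.random() < alpha:
                q, lp = q_new, lp_new
        if warming:
            eps = da.update(alpha)
            if w1 <= it < w2:
                mass_window.append(q.copy())
            if it == w2 - 1 and len(mass_window) >= 10:
                var = np.var(np.asarray(mass_window), axis=0)
                n = len(mass_window)
                inv_mass = (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))
                sqrt_mass = 1.0 / np.sqrt(inv_mass)
                eps = max(da.adapted / 10.0, 1e-4)  # conservative restart
                da = _DualAveraging(eps, target_accept)
            if it == n_warmup - 1:
                eps = da.adapted
        else:
            draws[it - n_warmup] = q
    return draws, n_div, eps


def sample_hmc(
    logp_grad,
    x0: np.ndarray,
    n_chains: int = 2,
    n_warmup: int = 300,
    n_samples: int = 300,
    seed: int = 0,
    target_accept: float = 0.8,
    path_length: float = 1.2,
    max_leapfrog: int = 32,
    jitter: float = 0.05,
) -> HMCResult:
    """Run `n_chains` independent HMC chains from jittered copies of `x0`."""
    rng = np.random.default_rng(seed)
    dim = np.asarray(x0, dtype=float).size
    all_draws = np.empty((n_chains, n_samples, dim))
    n_div = np.zeros(n_chains, dtype=int)
    steps = np.zeros(n_chains)
    accept = np.zeros(n_chains)
    for c in range(n_chains):
        chain_rng = np.random.default_rng(rng.integers(2**31 - 1))
        q0 = np.asarray(x0, dtype=float) + jitter * chain_rng.standard_normal(dim)
        draws, div, eps = _one_chain(
            logp_grad, q0, n_warmup, n_samples, chain_rng,
            target_accept, path_length, max_leapfrog,
        )
        all_draws[c] = draws
        n_div[c] = div
        steps[c] = eps
        moved = np.any(np.diff(draws, axis=0) != 0, axis=1)
        accept[c] = moved.mean() if len(moved) else 0.0
    return HMCResult(all_draws, accept, n_div, steps)
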