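"""Hierarchical Bayesian logistic regression for choice data.

The model mirrors the study's fitting strategy: every regressor gets a fixed
effect for each animal-by-condition cell, and testing sessions are random
effects -- for each animal and each regressor, session-level coefficients are
drawn from their own Gaussian centered on that animal's cell-level fixed
effect.  The likelihood is Bernoulli-logit.  Sampling uses the package's HMC
with a non-centered parameterization:

    b_session = beta[animal, condition] + tau[animal] * z_session,
    z ~ N(0, 1),  beta ~ Student-t(3, 0, 2.5),  tau ~ half-Student-t(3, 0, 2.5)

Priors are weakly informative; inference is meant to be likelihood-dominated.
Significance follows the posterior-count convention: the one-sided p-value of
an effect is the fraction of posterior draws on the wrong side of zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import arviz as az
import numpy as np
from scipy.special import expit
import pandas as pd

from .mcmc import sample_hmc

__all__ = [
    "FitConfig",
    "FitResult",
    "fit",
    "one_sided_p",
    "p_string",
    "contrast",
    "condition_contrast",
]


@dataclass
class FitConfig:
    n_chains: int = 12
    n_warmup: int = 1000
    n_samples: int = 1000
    prior_scale: float = 2.5       # Student-t scale, fixed effects
    prior_df: float = 3.0
    tau_scale: float = 2.5         # half-Student-t scale, random-effect SDs
    tau_df: float = 3.0
    hierarchical: bool = True      # False: pooled fixed-effects-only model
    seed: int = 0
    target_accept: float = 0.8
    rhat_threshold: float = 1.05
    ess_threshold: float = 400.0

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2")
        if self.n_warmup <= 0 or self.n_samples <= 0:
            raise ValueError("iteration counts must be positive")


@dataclass
class FitResult:
    coef_names: list
    animals: list
    conditions: list
    cells: list                    # [(animal, condition), ...]
    beta: np.ndarray               # (chains, draws, n_cells, p)
    tau: Optional[np.ndarray]      # (chains, draws, n_animals, p)
    session_index: pd.DataFrame    # session_id, animal_id, feedback, n_rows
    diagnostics: pd.DataFrame      # parameter, rhat, ess
    n_divergent: int
    flags: list = field(default_factory=list)
    config: Optional[FitConfig] = None

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def cell_draws(self, coef: str, animal: str, condition: str) -> np.ndarray:
        """Flat posterior draws of one coefficient in one cell."""
        ci = self._cell_index(animal, condition)
        p = self.coef_names.index(coef)
        return self.beta[:, :, ci, p].reshape(-1)

    def group_draws(self, coef: str, condition: Optional[str] = None,
                    animals: Optional[list] = None) -> np.ndarray:
        """Per-draw average of a coefficient over animals (and conditions).

        This is the group-level estimate: averaging the cell posteriors
        across animals within a condition, or across everything when no
        condition is given.
        """
        animals = animals or self.animals
        conditions = [condition] if condition else self.conditions
        cells = [(a, c) for a in animals for c in conditions
                 if (a, c) in self.cells]
        if not cells:
            raise KeyError(f"no cells match condition={condition}")
        p = self.coef_names.index(coef)
        idx = [self.cells.index(cell) for cell in cells]
        return self.beta[:, :, idx, p].mean(axis=2).reshape(-1)

    def tau_draws(self, coef: str, animal: str) -> np.ndarray:
        if self.tau is None:
            raise ValueError("non-hierarchical fit has no random-effect SDs")
        ai = self.animals.index(animal)
        p = self.coef_names.index(coef)
        return self.tau[:, :, ai, p].reshape(-1)

    def _cell_index(self, animal: str, condition: str) -> int:
        try:
            return self.cells.index((animal, condition))
        except ValueError:
            raise KeyError(f"no cell ({animal}, {condition}) in fit") from None

    def summary(self) -> pd.DataFrame:
        """Posterior summaries per cell and per condition-level group."""
        rows = []
        diag = self.diagnostics.set_index("parameter")
        for p, coef in enumerate(self.coef_names):
            for ci, (a, c) in enumerate(self.cells):
                d = self.beta[:, :, ci, p].reshape(-1)
                name = f"beta[{a},{c},{coef}]"
                rows.append(_summary_row(coef, f"{a}:{c}", d,
                                         diag.loc[name] if name in diag.index else None))
            for c in self.conditions:
                d = self.group_draws(coef, condition=c)
                rows.append(_summary_row(coef, f"group:{c}", d, None))
            rows.append(_summary_row(coef, "group", self.group_draws(coef), None))
        return pd.DataFrame(rows)

    def draws_frame(self) -> pd.DataFrame:
        """All fixed-effect draws in long format (for persistence)."""
        ch, dr, nc, p = self.beta.shape
        recs = []
        for ci, (a, c) in enumerate(self.cells):
            for pi, coef in enumerate(self.coef_names):
                recs.append(pd.DataFrame({
                    "chain": np.repeat(np.arange(ch), dr),
                    "draw": np.tile(np.arange(dr), ch),
                    "animal_id": a, "feedback": c, "coefficient": coef,
                    "value": self.beta[:, :, ci, pi].reshape(-1),
                }))
        return pd.concat(recs, ignore_index=True)


def _summary_row(coef, cell, draws, diag_row):
    q = np.quantile(draws, [0.025, 0.975])
    return {
        "coefficient": coef, "cell": cell,
        "mean": draws.mean(), "sd": draws.std(ddof=1),
        "q2.5": q[0], "q97.5": q[1],
        "p_greater": one_sided_p(draws, "greater"),
        "p_smaller": one_sided_p(draws, "smaller"),
        "rhat": None if diag_row is None else diag_row["rhat"],
        "ess": None if diag_row is None else diag_row["ess"],
    }


def one_sided_p(draws: np.ndarray, direction: str) -> float:
    """Posterior-count one-sided p: fraction of draws on the null side of 0.

    ``direction='greater'`` tests effect > 0, so p = #(draws <= 0)/N; draws
    exactly at zero count against the hypothesis (conservative).  A returned
    0.0 means no draw crossed; report it as "< 1/N" (see :func:`p_string`).
    """
    draws = np.asarray(draws)
    if draws.size == 0:
        raise ValueError("empty draws")
    if direction == "greater":
        return float(np.mean(draws <= 0))
    if direction == "smaller":
        return float(np.mean(draws >= 0))
    raise ValueError("direction must be 'greater' or 'smaller'")


def p_string(p: float, n_draws: int) -> str:
    return f"< 1/{n_draws}" if p == 0.0 else f"{p:.6g}"


def contrast(fit: FitResult, weights: dict, coef: str):
    """Per-draw weighted combination of cell posteriors.

    `weights` maps (animal, condition) tuples to weights.  Returns the draw
    vector; test it with :func:`one_sided_p`.
    """
    p = fit.coef_names.index(coef)
    out = None
    for cell, w in weights.items():
        ci = fit._cell_index(*cell)
        term = w * fit.beta[:, :, ci, p]
        out = term if out is None else out + term
    if out is None:
        raise ValueError("empty contrast")
    return out.reshape(-1)


def condition_contrast(fit: FitResult, coef: str, cond_a: str, cond_b: str):
    """Animal-averaged condition difference (cond_a minus cond_b)."""
    w = {}
    na = sum(1 for a, c in fit.cells if c == cond_a)
    nb = sum(1 for a, c in fit.cells if c == cond_b)
    if na == 0 or nb == 0:
        raise KeyError(f"conditions {cond_a}/{cond_b} not both present")
    for a, c in fit.cells:
        if c == cond_a:
            w[(a, c)] = 1.0 / na
        elif c == cond_b:
            w[(a, c)] = -1.0 / nb
    return contrast(fit, w, coef)


# ---------------------------------------------------------------------------
# model internals


def _t_logpdf_grad(x, df, scale):
    # Student-t log density (up to constant) and gradient
    lp = -0.5 * (df + 1) * np.log1p(x * x / (df * scale * scale))
    g = -(df + 1) * x / (df * scale * scale + x * x)
    return lp.sum(), g


def _validate_design(df: pd.DataFrame, columns: list):
    need = {"response", "animal_id", "session_id", "feedback"} | set(columns)
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"design is missing columns: {sorted(missing)}")
    X = df[columns].to_numpy(dtype=float)
    y = df["response"].to_numpy()
    if not np.isfinite(X).all():
        raise ValueError("non-finite regressor values in design")
    if not np.isin(y, [0, 1]).all():
        raise ValueError("response must be binary 0/1")
    for j, name in enumerate(columns):
        col = X[:, j]
        if np.ptp(col) == 0 and not (name == "SB" or np.all(col == 1.0)):
            raise ValueError(
                f"column '{name}' is constant ({col[0]:g}); remove it "
                "before fitting (non-identifiable)"
            )
        if name != "SB" and np.ptp(col) > 0:
            pos, neg = col[y == 1], col[y == 0]
            if len(pos) and len(neg) and (pos.min() > neg.max() or pos.max() < neg.min()):
                raise ValueError(f"column '{name}' perfectly separates the responses")
    return X, y.astype(float)


def _ridge_logistic(X, y, lam=1.0, n_iter=25):
    """Newton-ridge logistic fit used only to initialize the chains."""
    p = X.shape[1]
    b = np.zeros(p)
    for _ in range(n_iter):
        eta = X @ b
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-6)
        H = (X * w[:, None]).T @ X + lam * np.eye(p)
        g = X.T @ (y - mu) - lam * b
        step = np.linalg.solve(H, g)
        b = b + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return b


def fit(design: pd.DataFrame, columns: list, config: FitConfig) -> FitResult:
    """Fit the hierarchical logistic model to a design-matrix frame.

    `design` needs one row per choice with a binary ``response``, the
    regressor columns, and grouping columns ``animal_id``, ``session_id``
    and ``feedback``.  Sessions are nested in animal-by-condition cells.
    """
    X_all, y_all = _validate_design(design, columns)
    df = design.reset_index(drop=True)
    order = df.sort_values(["animal_id", "feedback", "session_id"],
                           kind="stable").index.to_numpy()
    X = X_all[order]
    y = y_all[order]
    g = df.loc[order, ["animal_id", "feedback", "session_id"]]

    sess_keys, sess_idx = np.unique(
        g[["animal_id", "feedback", "session_id"]].astype(str).agg("\x00".join, axis=1),
        return_inverse=True,
    )
    sess_table = (
        g.assign(_k=sess_idx)
        .groupby("_k", sort=True)
        .agg(animal_id=("animal_id", "first"), feedback=("feedback", "first"),
             session_id=("session_id", "first"), n_rows=("session_id", "size"))
        .reset_index(drop=True)
    )
    S = len(sess_table)
    animals = sorted(sess_table["animal_id"].unique())
    conditions = sorted(sess_table["feedback"].unique())
    cells = [(a, c) for a in animals for c in conditions
             if ((sess_table["animal_id"] == a) & (sess_table["feedback"] == c)).any()]
    cell_of_sess = np.array([
        cells.index((a, c))
        for a, c in zip(sess_table["animal_id"], sess_table["feedback"])
    ])
    animal_of_sess = np.array([animals.index(a) for a in sess_table["animal_id"]])
    if config.hierarchical:
        per_cell = sess_table.groupby(["animal_id", "feedback"]).size()
        if (per_cell < 2).any():
            bad = per_cell[per_cell < 2].index.tolist()
            raise ValueError(f"hierarchical fit needs >= 2 sessions per cell; got {bad}")

    # rows must be contiguous per session for reduceat
    sort2 = np.argsort(sess_idx, kind="stable")
    X, y, sess_idx = X[sort2], y[sort2], sess_idx[sort2]
    starts = np.searchsorted(sess_idx, np.arange(S))

    C, p, A = len(cells), len(columns), len(animals)
    nb, nt = C * p, A * p
    hier = config.hierarchical
    dim = nb + (nt + S * p if hier else 0)

    df_b, s_b = config.prior_df, config.prior_scale
    df_t, s_t = config.tau_df, config.tau_scale

    def logp_grad(theta):
        # warmup excursions can overflow exp(log_tau); the leapfrog rejects
        # non-finite energies, so silence the transient warnings here
        with np.errstate(over="ignore", invalid="ignore"):
            return _logp_grad_inner(theta)

    def _logp_grad_inner(theta):
        beta = theta[:nb].reshape(C, p)
        if hier:
            log_tau = theta[nb:nb + nt].reshape(A, p)
            z = theta[nb + nt:].reshape(S, p)
            tau = np.exp(log_tau)
            b_sess = beta[cell_of_sess] + tau[animal_of_sess] * z
        else:
            b_sess = beta[cell_of_sess]
        eta = np.einsum("ij,ij->i", X, b_sess[sess_idx])
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        r = y - expit(eta)
        G = np.add.reduceat(X * r[:, None], starts, axis=0)  # (S, p)

        lp_beta, g_beta_prior = _t_logpdf_grad(beta, df_b, s_b)
        grad_beta = np.zeros((C, p))
        np.add.at(grad_beta, cell_of_sess, G)
        grad_beta += g_beta_prior
        lp = ll + lp_beta

        if hier:
            lp_tau_val = -0.5 * (df_t + 1) * np.log1p(tau**2 / (df_t * s_t**2))
            lp += float(lp_tau_val.sum() + log_tau.sum())   # + Jacobian
            lp += float(-0.5 * (z * z).sum())
            grad_z = tau[animal_of_sess] * G - z
            gz_tau = np.zeros((A, p))
            np.add.at(gz_tau, animal_of_sess, G * z)
            dlp_dtau = -(df_t + 1) * tau / (df_t * s_t**2 + tau**2)
            grad_lt = (gz_tau + dlp_dtau) * tau + 1.0
            grad = np.concatenate([grad_beta.ravel(), grad_lt.ravel(), grad_z.ravel()])
        else:
            grad = grad_beta.ravel()
        return lp, grad

    # initialize fixed effects at a per-cell ridge-logistic solution
    beta0 = np.zeros((C, p))
    for ci in range(C):
        rows = np.isin(sess_idx, np.where(cell_of_sess == ci)[0])
        if rows.sum() > p:
            beta0[ci] = _ridge_logistic(X[rows], y[rows])
    if hier:
        x0 = np.concatenate([
            beta0.ravel(),
            np.full(nt, np.log(0.3)),
            np.zeros(S * p),
        ])
    else:
        x0 = beta0.ravel()

    res = sample_hmc(
        logp_grad, x0,
        n_chains=config.n_chains, n_warmup=config.n_warmup,
        n_samples=config.n_samples, seed=config.seed,
        target_accept=config.target_accept,
    )
    ch, dr = res.draws.shape[:2]
    beta_draws = res.draws[:, :, :nb].reshape(ch, dr, C, p)
    tau_draws = (
        np.exp(res.draws[:, :, nb:nb + nt].reshape(ch, dr, A, p)) if hier else None
    )

    posterior = {"beta": beta_draws}
    if hier:
        posterior["tau"] = tau_draws
    idata = az.from_dict(posterior=posterior)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    diag_rows = []
    for pi, coef in enumerate(columns):
        for ci, (a, c) in enumerate(cells):
            diag_rows.append({
                "parameter": f"beta[{a},{c},{coef}]",
                "rhat": float(rhat["beta"][ci, pi]),
                "ess": float(ess["beta"][ci, pi]),
            })
        if hier:
            for ai, a in enumerate(animals):
                diag_rows.append({
                    "parameter": f"tau[{a},{coef}]",
                    "rhat": float(rhat["tau"][ai, pi]),
                    "ess": float(ess["tau"][ai, pi]),
                })
    diagnostics = pd.DataFrame(diag_rows)

    flags = []
    worst = diagnostics["rhat"].max()
    if worst > config.rhat_threshold:
        bad = diagnostics.loc[diagnostics["rhat"].idxmax(), "parameter"]
        flags.append(f"rhat {worst:.3f} > {config.rhat_threshold} at {bad}")
    if (diagnostics["ess"] < config.ess_threshold).any():
        flags.append(
            f"min ESS {diagnostics['ess'].min():.0f} < {config.ess_threshold:.0f}"
        )
    ndiv = int(res.n_divergent.sum())
    if ndiv:
        flags.append(f"{ndiv} divergent transitions")

    return FitResult(
        coef_names=list(columns), animals=animals, conditions=conditions,
        cells=cells, beta=beta_draws, tau=tau_draws,
        session_index=sess_table, diagnostics=diagnostics,
        n_divergent=ndiv, flags=flags, config=config,
    )
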