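"""End-to-end orchestration: simulate -> beliefs -> designs -> fit -> metrics.

Every run writes its outputs plus a ``manifest.json`` recording configs,
seeds, software version, per-stage row counts and timing, so deterministic
stages can be reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agents import AgentParams, simulate_session, study_agent_params
from .design import (
    FIRST_CHOICE_COLUMNS,
    SUBSEQUENT_COLUMNS,
    build_first_choice_design,
    build_subsequent_choice_design,
)
from .hierfit import FitConfig, fit, one_sided_p
from .io import read_sessions, write_sessions
from .metrics import accuracy_table, repetition_table, within_horizon_trend
from .observer import ObserverConfig, belief_trajectory
from .task import TaskConfig

__all__ = ["simulate_dataset", "run_pipeline", "run_recovery", "beliefs_frame"]

DEFAULT_ANIMALS = ["M", "S", "E"]
DEFAULT_SESSIONS_PER_CONDITION = 13


def _params_from_dict(d: dict) -> AgentParams:
    return AgentParams(first=d["first"], subsequent=d["subsequent"],
                       lapse_rate=d.get("lapse_rate", 0.0))


def simulate_dataset(
    seed: int,
    conditions=("partial", "complete"),
    animals=DEFAULT_ANIMALS,
    n_sessions: int = DEFAULT_SESSIONS_PER_CONDITION,
    trials_per_session: int = 150,
    agent_params: dict | None = None,
    observer: ObserverConfig | None = None,
) -> list:
    """Simulate the study's dataset layout: animals x conditions x sessions.

    ``agent_params`` maps condition -> AgentParams (defaults to the
    study-like agent).  Seeds for each session are derived deterministically
    from `seed`.
    """
    observer = observer or ObserverConfig()
    rng = np.random.default_rng(seed)
    sessions = []
    for cond in conditions:
        params = (agent_params or {}).get(cond) or study_agent_params(cond)
        cfg = TaskConfig(feedback=cond, trials_per_session=trials_per_session)
        for animal in animals:
            for k in range(n_sessions):
                sid = f"{animal}_{cond}_{k:02d}"
                sessions.append(
                    simulate_session(
                        sid, animal, cfg, params, observer,
                        rng_seed=int(rng.integers(2**31 - 2)),
                    )
                )
    return sessions


def beliefs_frame(sessions, observer: ObserverConfig) -> pd.DataFrame:
    """Tidy per-choice EV/U trajectories (streams a/b/c, both sides)."""
    rows = []
    for session in sessions:
        for trial in session.trials:
            for k, entry in enumerate(belief_trajectory(trial, observer)):
                for stream, sides in entry.items():
                    for side, bs in sides.items():
                        rows.append({
                            "session_id": session.session_id,
                            "trial_id": trial.trial_id,
                            "choice_index": k + 1,
                            "side": side,
                            "stream": stream,
                            "EV": bs.expected_value,
                            "U": bs.uncertainty,
                            "n_obs": bs.n_observations,
                        })
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict, out_dir, seed: int = 0) -> dict:
    """Run all stages; returns the manifest (also written to disk).

    `config` keys (all optional): ``simulate`` (dataset settings or false to
    load ``sessions`` paths), ``fit`` (MCMC settings), ``variant``
    (first-choice design variant).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    observer = ObserverConfig()
    manifest = {"version": __version__, "seed": seed, "config": config, "stages": {}}

    def stage(name):
        t0 = time.time()

        def done(**info):
            manifest["stages"][name] = {"seconds": round(time.time() - t0, 3), **info}

        return done

    d = stage("sessions")
    sim_cfg = config.get("simulate", {})
    if sim_cfg is False or "sessions" in config:
        sessions = read_sessions(config["sessions"])
    else:
        ap = {
            c: _params_from_dict(v) for c, v in sim_cfg.get("agent_params", {}).items()
        } or None
        sessions = simulate_dataset(
            seed=seed,
            conditions=tuple(sim_cfg.get("conditions", ("partial", "complete"))),
            animals=sim_cfg.get("animals", DEFAULT_ANIMALS),
            n_sessions=sim_cfg.get("n_sessions", DEFAULT_SESSIONS_PER_CONDITION),
            trials_per_session=sim_cfg.get("trials_per_session", 150),
            agent_params=ap,
            observer=observer,
        )
        write_sessions(sessions, out / "sessions")
    d(n_sessions=len(sessions), n_trials=sum(len(s.trials) for s in sessions))

    d = stage("designs")
    first = build_first_choice_design(
        sessions, observer, variant=config.get("variant", "uncertainty")
    )
    first.to_csv(out / "design_first.csv", index=False)
    subs = build_subsequent_choice_design(sessions, observer)
    subs.to_csv(out / "design_subsequent.csv", index=False)
    _write_design_schema(out, config.get("variant", "uncertainty"))
    d(first_rows=len(first), subsequent_rows=len(subs))

    fit_cfg_d = config.get("fit", {})
    fit_cfg = FitConfig(
        n_chains=fit_cfg_d.get("n_chains", 2),
        n_warmup=fit_cfg_d.get("n_warmup", 300),
        n_samples=fit_cfg_d.get("n_samples", 250),
        seed=seed + 1,
    )
    d = stage("fit_first")
    fit_first = fit(first, FIRST_CHOICE_COLUMNS, fit_cfg)
    fit_first.summary().to_csv(out / "fit_first_summary.csv", index=False)
    (out / "fit_first.json").write_text(_fit_json(fit_first))
    d(n_draws=fit_first.n_draws, flags=fit_first.flags)

    d = stage("fit_subsequent")
    cols = list(SUBSEQUENT_COLUMNS)
    if (subs["feedback"] == "partial").all():
        cols = [c for c in cols if c not in ("dEVunchosen", "dUunchosen")]
    fit_sub = fit(subs, cols, replace(fit_cfg, seed=seed + 2))
    fit_sub.summary().to_csv(out / "fit_subsequent_summary.csv", index=False)
    (out / "fit_subsequent.json").write_text(_fit_json(fit_sub))
    d(n_draws=fit_sub.n_draws, flags=fit_sub.flags)

    d = stage("metrics")
    acc = accuracy_table(sessions, observer)
    acc.to_csv(out / "accuracy.csv", index=False)
    rep = repetition_table(sessions, observer)
    rep.to_csv(out / "repetition.csv", index=False)
    trend = within_horizon_trend(sessions, observer, "accuracy")
    (out / "metrics.json").write_text(json.dumps({
        "accuracy_trend": {
            "t": trend["t"], "dof": trend["dof"], "p": trend["p"],
            "n_sessions": int(len(trend["slopes"])),
            "n_dropped": trend["n_dropped"],
        },
    }, indent=2))
    d(accuracy_rows=len(acc), repetition_rows=len(rep))

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.csv")) if p.is_file()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _write_design_schema(out: Path, variant: str) -> None:
    (out / "design_schema.json").write_text(json.dumps({
        "variant": variant,
        "coding": {
            "response": "1 = right option chosen",
            "horizon": "+1 short, -1 long",
            "RB": "+1 previous choice right, -1 left, 0 none",
            "differences": "right minus left",
        },
        "first_choice_columns": FIRST_CHOICE_COLUMNS,
        "subsequent_columns": SUBSEQUENT_COLUMNS,
    }, indent=2))


def _fit_json(fr) -> str:
    s = fr.summary()
    return json.dumps({
        "flags": fr.flags,
        "n_divergent": fr.n_divergent,
        "n_draws": fr.n_draws,
        "summary": s.to_dict(orient="records"),
    }, indent=2, default=lambda o: None if pd.isna(o) else o)


def run_recovery(
    seed: int,
    truth: dict | None = None,
    n_sessions: int = DEFAULT_SESSIONS_PER_CONDITION,
    trials_per_session: int = 150,
    fit_config: FitConfig | None = None,
    conditions=("partial", "complete"),
) -> dict:
    """Simulate with known first-choice coefficients, refit, and tabulate.

    Returns a report dict with per-(condition, coefficient) truth, posterior
    mean, 95% interval, coverage indicator, and the study's two headline
    contrasts (complete-partial on EV; the short-long EV gap per condition,
    which is twice the EV-by-horizon coefficient).
    """
    observer = ObserverConfig()
    truth = truth or {c: study_agent_params(c) for c in conditions}
    sessions = simulate_dataset(
        seed=seed, conditions=conditions, n_sessions=n_sessions,
        trials_per_session=trials_per_session,
        agent_params=truth, observer=observer,
    )
    design = build_first_choice_design(sessions, observer)
    fc = fit_config or FitConfig(n_chains=2, n_warmup=300, n_samples=250, seed=seed)
    res = fit(design, FIRST_CHOICE_COLUMNS, fc)
    report = {"coefficients": [], "contrasts": {}, "flags": res.flags}
    for cond in conditions:
        for coef in FIRST_CHOICE_COLUMNS:
            d = res.group_draws(coef, condition=cond)
            lo, hi = np.quantile(d, [0.025, 0.975])
            tv = truth[cond].first[coef]
            report["coefficients"].append({
                "condition": cond, "coefficient": coef, "truth": tv,
                "posterior_mean": float(d.mean()), "q2.5": float(lo),
                "q97.5": float(hi), "bias": float(d.mean() - tv),
                "covered": bool(lo <= tv <= hi),
            })
    if set(conditions) == {"partial", "complete"}:
        from .hierfit import condition_contrast

        ev_gap = condition_contrast(res, "EV", "complete", "partial")
        report["contrasts"]["EV_complete_minus_partial"] = {
            "mean": float(ev_gap.mean()),
            "p_greater": one_sided_p(ev_gap, "greater"),
        }
    for cond in conditions:
        d = 2.0 * res.group_draws("EVxhorizon", condition=cond)
        report["contrasts"][f"EV_short_minus_long_{cond}"] = {
            "mean": float(d.mean()),
            "p_greater": one_sided_p(d, "greater"),
        }
    report["fit"] = res
    return report
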