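"""Hierarchical logistic fit: posterior-count p-values, contrasts, oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from horizontask import (
    AgentParams,
    FitConfig,
    ObserverConfig,
    TaskConfig,
    build_first_choice_design,
    condition_contrast,
    contrast,
    fit,
    one_sided_p,
    p_string,
    simulate_session,
    study_agent_params,
)
from horizontask.design import FIRST_CHOICE_COLUMNS


class TestOneSidedP:
    def test_direct_count(self):
        assert one_sided_p(np.array([-1.0, 1.0, 1.0, 1.0]), "greater") == 0.25

    def test_symmetric_draws(self):
        rng = np.random.default_rng(0)
        d = rng.standard_normal(20000)
        assert one_sided_p(d, "greater") == pytest.approx(0.5, abs=0.02)
        assert one_sided_p(d, "smaller") == pytest.approx(0.5, abs=0.02)

    def test_boundary_reported_below_resolution(self):
        d = np.abs(np.random.default_rng(1).standard_normal(12000)) + 0.01
        p = one_sided_p(d, "greater")
        assert p == 0.0
        assert p_string(p, d.size) == "< 1/12000"

    def test_zero_draws_count_against_hypothesis(self):
        assert one_sided_p(np.array([0.0, 1.0]), "greater") == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            one_sided_p(np.array([]), "greater")


def _null_design(n_sessions=2, n_trials=40, seed=0):
    observer = ObserverConfig()
    null = AgentParams(
        first={k: 0.0 for k in FIRST_CHOICE_COLUMNS},
        subsequent={"SB": 0, "RB": 0, "dChosen": 0, "baselineEV": 0,
                    "dEVchosen": 0, "baselineU": 0, "dUchosen": 0,
                    "dEVunchosen": 0, "dUunchosen": 0},
    )
    sessions = []
    for ai, a in enumerate(("M", "S", "E")):
        cfg = TaskConfig(feedback="partial", trials_per_session=n_trials)
        for k in range(n_sessions):
            sessions.append(
                simulate_session(f"{a}{k}", a, cfg, null, observer,
                                 seed * 1000 + ai * 100 + k)
            )
    return build_first_choice_design(sessions, observer)


@pytest.fixture(scope="module")
def null_fit():
    design = _null_design()
    return fit(design, FIRST_CHOICE_COLUMNS,
               FitConfig(n_chains=2, n_warmup=250, n_samples=200, seed=3))


class TestFit:
    def test_null_recovery_intervals_cover_zero(self, null_fit):
        for coef in FIRST_CHOICE_COLUMNS:
            d = null_fit.group_draws(coef)
            lo, hi = np.quantile(d, [0.025, 0.975])
            assert lo <= 0.0 <= hi, coef

    def test_draw_count_and_diagnostics_reported(self, null_fit):
        cfg = null_fit.config
        assert null_fit.n_draws == cfg.n_chains * cfg.n_samples
        assert (null_fit.diagnostics["rhat"] > 0).all()
        betas = null_fit.diagnostics[
            null_fit.diagnostics["parameter"].str.startswith("beta")
        ]
        assert len(betas) == len(FIRST_CHOICE_COLUMNS) * 3  # 3 animal cells

    def test_summary_schema(self, null_fit):
        s = null_fit.summary()
        for col in ("coefficient", "cell", "mean", "sd", "q2.5", "q97.5",
                    "p_greater", "p_smaller"):
            assert col in s.columns

    def test_contrast_identity_and_average(self, null_fit):
        d_cell = null_fit.cell_draws("EV", "M", "partial")
        d_contrast = contrast(null_fit, {("M", "partial"): 1.0}, "EV")
        assert np.array_equal(d_cell, d_contrast)
        with pytest.raises(KeyError):
            contrast(null_fit, {("X", "partial"): 1.0}, "EV")

    def test_constant_column_rejected(self, null_fit):
        design = _null_design(n_sessions=2, n_trials=20, seed=5)
        design["dead"] = 3.14
        with pytest.raises(ValueError, match="'dead'"):
            fit(design, FIRST_CHOICE_COLUMNS + ["dead"],
                FitConfig(n_chains=2, n_warmup=50, n_samples=50, seed=0))

    def test_perfect_separation_rejected(self):
        design = _null_design(n_sessions=2, n_trials=20, seed=6)
        design["sep"] = np.where(design["response"] == 1, 1.0, -1.0)
        design.loc[design.index[0], "sep"] = -0.5  # keep it non-constant per class
        with pytest.raises(ValueError, match="separates"):
            fit(design, ["SB", "sep"],
                FitConfig(n_chains=2, n_warmup=50, n_samples=50, seed=0))

    def test_too_few_sessions_per_cell_rejected(self):
        design = _null_design(n_sessions=1, n_trials=20, seed=7)
        with pytest.raises(ValueError, match="2 sessions"):
            fit(design, FIRST_CHOICE_COLUMNS,
                FitConfig(n_chains=2, n_warmup=50, n_samples=50, seed=0))

    def test_determinism_under_fixed_seed(self):
        design = _null_design(n_sessions=2, n_trials=20, seed=8)
        cfg = FitConfig(n_chains=2, n_warmup=60, n_samples=40, seed=11)
        a = fit(design, ["SB", "EV"], cfg)
        b = fit(design, ["SB", "EV"], cfg)
        assert np.array_equal(a.beta, b.beta)


class TestSingleSessionReduction:
    def test_posterior_matches_penalized_ml(self):
        """Non-hierarchical single-session posterior vs an independent
        ridge-penalized ML logistic fit (statsmodels)."""
        observer = ObserverConfig()
        cfg = TaskConfig(feedback="partial", trials_per_session=500)
        s = simulate_session("one", "M", cfg, study_agent_params("partial"),
                             observer, 3)
        design = build_first_choice_design([s], observer)
        res = fit(design, FIRST_CHOICE_COLUMNS,
                  FitConfig(n_chains=2, n_warmup=300, n_samples=300, seed=1,
                            hierarchical=False))
        X = design[FIRST_CHOICE_COLUMNS].to_numpy()
        y = design["response"].to_numpy()
        ml = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
            alpha=1e-4, L1_wt=0.0
        )
        for i, coef in enumerate(FIRST_CHOICE_COLUMNS):
            post_mean = res.cell_draws(coef, "M", "partial").mean()
            assert abs(post_mean - ml.params[i]) < 0.05, coef


def test_animal_relabeling_preserves_group_average():
    """Group averages are invariant to animal labels up to MC error."""
    design = _null_design(n_sessions=2, n_trials=30, seed=12)
    relabeled = design.copy()
    relabeled["animal_id"] = relabeled["animal_id"].map(
        {"M": "Z1", "S": "Z2", "E": "Z3"}
    )
    cfg = FitConfig(n_chains=2, n_warmup=200, n_samples=150, seed=2)
    a = fit(design, ["SB", "EV", "RB"], cfg)
    b = fit(relabeled, ["SB", "EV", "RB"], cfg)
    for coef in ("SB", "EV", "RB"):
        da, db = a.group_draws(coef), b.group_draws(coef)
        pooled_se = np.sqrt(da.var() / 50 + db.var() / 50)  # generous ESS guess
        assert abs(da.mean() - db.mean()) < 5 * pooled_se + 0.05
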