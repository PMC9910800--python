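"""Behavioral metrics: accuracy, t-tests, trends, repetition, psychometrics."""

import numpy as np
import pytest

from horizontask import (
    AgentParams,
    TaskConfig,
    accuracy_table,
    mirror_session,
    psychometric,
    repetition_table,
    session_ttest,
    simulate_session,
    study_agent_params,
    within_horizon_trend,
)
from horizontask.design import FIRST_CHOICE_COLUMNS, SUBSEQUENT_COLUMNS


def flat_agent(**overrides):
    first = {k: 0.0 for k in FIRST_CHOICE_COLUMNS}
    subsequent = {k: 0.0 for k in SUBSEQUENT_COLUMNS}
    for k, v in overrides.items():
        (first if k in first else subsequent)[k] = v
        if k in first and k in subsequent:
            subsequent[k] = v
    return AgentParams(first=first, subsequent=subsequent)


@pytest.fixture(scope="module")
def coinflip_sessions(observer):
    cfg = TaskConfig(trials_per_session=100)
    agent = flat_agent()
    return [
        simulate_session(f"c{k}", "A", cfg, agent, observer, 200 + k)
        for k in range(10)
    ]


class TestSessionTtest:
    def test_hand_computed_example(self):
        t, dof, p = session_ttest([0.6, 0.7, 0.8], 0.5)
        assert t == pytest.approx(2 * np.sqrt(3), abs=1e-10)  # 3.4641016...
        assert dof == 2

    def test_values_at_null(self):
        t, dof, p = session_ttest([0.5, 0.5, 0.5, 0.5], 0.5)
        assert (t, p) == (0.0, 1.0)
        assert dof == 3

    def test_zero_variance_off_null_is_degenerate(self):
        t, dof, p = session_ttest([0.7, 0.7], 0.5)
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_dof_shape(self):
        vals = np.random.default_rng(0).uniform(0.4, 0.9, size=41)
        _, dof, _ = session_ttest(vals, 0.5)
        assert dof == 40

    def test_too_few_sessions(self):
        with pytest.raises(ValueError):
            session_ttest([0.6], 0.5)


class TestAccuracy:
    def test_coinflip_accuracy_near_half(self, observer, coinflip_sessions):
        acc = accuracy_table(coinflip_sessions, observer)
        n_choices = sum(
            len(t.choices) for s in coinflip_sessions for t in s.trials
        )
        overall = acc["accuracy"].mean()
        assert abs(overall - 0.5) < 3 * np.sqrt(0.25 / n_choices) * np.sqrt(len(acc))

    def test_value_guided_agent_above_chance(self, observer):
        cfg = TaskConfig(trials_per_session=50)
        agent = flat_agent(EV=0.8, baselineEV=0.8, dEVchosen=0.8)
        sessions = [
            simulate_session(f"v{k}", "A", cfg, agent, observer, 300 + k)
            for k in range(8)
        ]
        acc = accuracy_table(sessions, observer)
        first = acc[acc["choice_index"] == 1]
        per_sess = []
        from horizontask.metrics import _choice_frame

        df = _choice_frame(sessions, observer)
        df = df[(df["choice_index"] == 1) & ~df["tie"]]
        per_sess = df.groupby("session_id")["correct"].mean().tolist()
        t, dof, p = session_ttest(per_sess, 0.5)
        assert t > 0 and p / 2 < 0.01  # one-sided above chance
        assert (first["accuracy"] > 0.5).all()

    def test_accuracy_invariant_under_mirroring(self, observer, coinflip_sessions):
        acc = accuracy_table(coinflip_sessions, observer)
        accm = accuracy_table(
            [mirror_session(s) for s in coinflip_sessions], observer
        )
        assert np.allclose(acc["accuracy"], accm["accuracy"])


class TestTrend:
    def test_study_like_agent_accuracy_rises_within_horizon(self, observer):
        """An agent that learns from chosen outcomes and commits to its pick
        becomes more accurate across the long horizon."""
        cfg = TaskConfig(trials_per_session=60)
        agent = study_agent_params("partial")
        sessions = [
            simulate_session(f"l{k}", "A", cfg, agent, observer, 800 + k)
            for k in range(12)
        ]
        res = within_horizon_trend(sessions, observer, "accuracy")
        assert res["t"] > 0 and res["p"] / 2 < 0.05

    def test_constant_quantity_dropped(self, observer):
        cfg = TaskConfig(trials_per_session=30)
        greedy = flat_agent(RB=80.0)  # repeats forever: repetition constant 1
        sessions = [
            simulate_session(f"g{k}", "A", cfg, greedy, observer, 500 + k)
            for k in range(3)
        ]
        res = within_horizon_trend(sessions, observer, "repetition")
        assert res["n_dropped"] == 3
        assert res.get("degenerate", False) or res["t"] is None

    def test_unknown_quantity_rejected(self, observer, coinflip_sessions):
        with pytest.raises(ValueError):
            within_horizon_trend(coinflip_sessions, observer, "speed")


class TestRepetition:
    def test_huge_repetition_bias(self, observer):
        cfg = TaskConfig(trials_per_session=30)
        s = simulate_session("r", "A", cfg, flat_agent(RB=80.0), observer, 0)
        rep = repetition_table([s], observer)
        assert np.allclose(rep["repetition"], 1.0)

    def test_coinflip_repetition_near_half(self, observer, coinflip_sessions):
        rep = repetition_table(coinflip_sessions, observer)
        assert abs(rep["repetition"].mean() - 0.5) < 0.06

    def test_partial_repetition_exceeds_complete(self, observer):
        sessions = []
        for cond in ("partial", "complete"):
            cfg = TaskConfig(feedback=cond, trials_per_session=60)
            rb = 1.2 if cond == "partial" else 0.3
            agent = flat_agent(RB=rb)
            sessions += [
                simulate_session(f"{cond}{k}", "A", cfg, agent, observer, 600 + k)
                for k in range(6)
            ]
        rep = repetition_table(sessions, observer)
        by_cond = rep.groupby("feedback")["repetition"].mean()
        assert by_cond["partial"] > by_cond["complete"]


@pytest.fixture(scope="module")
def value_sessions(observer):
    cfg = TaskConfig(trials_per_session=150)
    agent = flat_agent(EV=1.0)
    return [
        simulate_session(f"p{k}", "A", cfg, agent, observer, 700 + k)
        for k in range(10)
    ]


class TestPsychometric:
    def test_monotone_in_ev_difference(self, observer, value_sessions):
        curve = psychometric(value_sessions, observer, n_bins=9)
        filled = curve.dropna(subset=["p_right"])
        slope = np.polyfit(filled["bin_center"], filled["p_right"], 1)[0]
        assert slope > 0
        # ends of the curve bracket chance level
        assert filled["p_right"].iloc[0] < 0.5 < filled["p_right"].iloc[-1]

    def test_mirror_antisymmetry(self, observer, value_sessions):
        curve = psychometric(value_sessions, observer, n_bins=9)
        curvem = psychometric(
            [mirror_session(s) for s in value_sessions], observer, n_bins=9
        )
        a = curve["p_right"].to_numpy()
        b = curvem["p_right"].to_numpy()[::-1]
        mask = ~np.isnan(a) & ~np.isnan(b)
        assert np.allclose(a[mask], 1 - b[mask], atol=1e-12)

    def test_empty_bins_reported_missing(self, observer, value_sessions):
        curve = psychometric(value_sessions, observer, n_bins=41)
        assert curve["p_right"].isna().any()
        assert not (curve.loc[curve["n"] == 0, "p_right"] == 0).any()
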