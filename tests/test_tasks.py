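"""Schedules, stimuli, and dataset generators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metadelegate.ddm import DDMParams
from metadelegate.metacog import MetacogParams
from metadelegate.delegation import DelegationParams
from metadelegate.tasks import (
    AgentSpec,
    TaskConfig,
    default_agents,
    generate_dot_stimulus,
    generate_schedule,
    simulate_delegation_dataset,
    simulate_forced_choice_dataset,
)


class TestConfig:
    def test_default_counts_match_design(self):
        cfg = TaskConfig()
        assert cfg.trials_per_condition == 120
        assert cfg.n_trials == 240
        deleg = TaskConfig(experiment_variant="delegation")
        assert deleg.n_trials == 480

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="even"):
            TaskConfig(difficulty_levels=(2, 3))
        with pytest.raises(ValueError, match="increasing"):
            TaskConfig(difficulty_levels=(4, 2))
        with pytest.raises(ValueError, match="divide"):
            TaskConfig(block_size=7)
        with pytest.raises(ValueError, match="expert accuracy"):
            TaskConfig(experiment_variant="delegation", expert_levels=(0.4,))


class TestSchedule:
    def test_exact_cell_counts_and_reproducibility(self):
        cfg = TaskConfig()
        s1 = generate_schedule(cfg, seed=5)
        s2 = generate_schedule(cfg, seed=5)
        pd.testing.assert_frame_equal(s1, s2)
        counts = s1.groupby(["condition", "c"]).size()
        assert (counts == 10).all()
        assert len(counts) == 24

    def test_block_run_constraint(self):
        cfg = TaskConfig()
        for seed in range(10):
            s = generate_schedule(cfg, seed=seed)
            blocks = s.groupby("block_index")["condition"].first()
            runs = (blocks != blocks.shift()).cumsum()
            assert blocks.groupby(runs).size().max() <= 3

    def test_degenerate_single_cell(self):
        cfg = TaskConfig(difficulty_levels=(4,), conditions=("Self",),
                         n_trials_per_level=5, block_size=5)
        s = generate_schedule(cfg, seed=0)
        assert len(s) == 5
        assert (s["c"] == 4).all()

    def test_delegation_cells_cross_expert_levels(self):
        s = generate_schedule(TaskConfig(experiment_variant="delegation"), seed=2)
        counts = s.groupby(["condition", "expert_level", "c"]).size()
        assert (counts == 10).all()
        assert len(s) == 480


class TestStimulus:
    @pytest.mark.parametrize("c", [2, 24])
    def test_dot_counts(self, c):
        lay = generate_dot_stimulus(c, seed=1)
        assert {len(lay.left_dots), len(lay.right_dots)} == {50, 50 + c}

    def test_containment_and_reproducibility(self):
        a = generate_dot_stimulus(8, seed=3)
        b = generate_dot_stimulus(8, seed=3)
        np.testing.assert_array_equal(a.left_dots, b.left_dots)
        for dots in (a.left_dots, a.right_dots):
            assert (np.linalg.norm(dots, axis=1) <= a.circle_radius).all()

    def test_invalid_difference(self):
        with pytest.raises(ValueError):
            generate_dot_stimulus(0, seed=0)


class TestForcedChoiceDataset:
    def test_columns_and_invariants(self, small_forced_choice, small_config):
        df = small_forced_choice
        assert len(df) == small_config.n_trials * 6
        assert df["confidence"].isin([50, 60, 70, 80, 90, 100]).all()
        assert (df["rt_decision"] > 0).all()
        assert df["choice"].isin(["left", "right"]).all()
        assert (df["accuracy"] == (df["choice"] == df["correct_side"])).all()

    def test_strong_drift_gives_ceiling_accuracy(self):
        strong = DDMParams(B0=1.0, h=0.0, v0=2.0, v1=2.0, ndt=0.2, t_max=4.0)
        agents = {"s0": {c: AgentSpec(ddm=strong, metacog=MetacogParams())
                         for c in ("Self", "Group")}}
        cfg = TaskConfig(difficulty_levels=(8, 16, 24), n_trials_per_level=10,
                         block_size=10)
        df = simulate_forced_choice_dataset(agents, cfg, seed=0)
        assert df["accuracy"].mean() > 0.97

    def test_missing_condition_params_error(self, small_config):
        agents = {"s0": {"Self": AgentSpec(ddm=DDMParams(t_max=4.0),
                                           metacog=MetacogParams())}}
        with pytest.raises(ValueError, match="lacks condition"):
            simulate_forced_choice_dataset(agents, small_config, seed=0)

    @settings(max_examples=5, deadline=None, derandomize=True)
    @given(
        v1=st.floats(0.2, 1.0), sig=st.floats(1.0, 3.0),
        ma=st.floats(-0.3, 0.3), seed=st.integers(0, 100),
    )
    def test_table_invariants_over_random_agents(self, v1, sig, ma, seed):
        ddm_p = DDMParams(v1=v1, t_max=5.0)
        mc_p = MetacogParams(sigma_sens=sig, m_add=ma)
        agents = {"s0": {c: AgentSpec(ddm=ddm_p, metacog=mc_p)
                         for c in ("Self", "Group")}}
        cfg = TaskConfig(difficulty_levels=(4, 16), n_trials_per_level=5,
                         block_size=5)
        df = simulate_forced_choice_dataset(agents, cfg, seed=seed)
        assert df["confidence"].between(50, 100).all()
        assert (df["rt_decision"] > 0).all()
        assert df["accuracy"].isin([0, 1]).all()


class TestDelegationDataset:
    @staticmethod
    def _agents(alpha, link=3.0, n=2):
        dp = DelegationParams(variant="constant", alpha_phi=alpha,
                              link_scale=link)
        return {
            f"s{i}": {c: AgentSpec(ddm=DDMParams(t_max=5.0),
                                   metacog=MetacogParams(), delegation=dp)
                      for c in ("Self", "Group")}
            for i in range(n)
        }

    def test_delegate_rows_have_expert_and_no_confidence(self):
        cfg = TaskConfig(experiment_variant="delegation",
                         difficulty_levels=(4, 16), n_trials_per_level=5,
                         block_size=10)
        df = simulate_delegation_dataset(self._agents(0.2), cfg, seed=1)
        assert df["confidence"].isna().all()
        deleg = df[df["choice"] == "delegate"]
        assert len(deleg) > 0
        assert deleg["expert_level"].notna().all()

    def test_preference_extremes(self):
        cfg = TaskConfig(experiment_variant="delegation",
                         difficulty_levels=(4, 16), n_trials_per_level=5,
                         block_size=10)
        never = simulate_delegation_dataset(
            self._agents(-np.inf, link=np.inf), cfg, seed=2)
        assert (never["choice"] != "delegate").all()
        always = simulate_delegation_dataset(
            self._agents(np.inf, link=np.inf), cfg, seed=3)
        assert (always["choice"] == "delegate").all()

    def test_realized_expert_accuracy_converges(self):
        cfg = TaskConfig(experiment_variant="delegation",
                         difficulty_levels=(4, 16), n_trials_per_level=50,
                         block_size=10, expert_levels=(0.9,))
        df = simulate_delegation_dataset(
            self._agents(np.inf, link=np.inf, n=10), cfg, seed=4)
        deleg = df[df["choice"] == "delegate"]
        n = len(deleg)
        assert n == 2000
        se = np.sqrt(0.9 * 0.1 / n)
        assert deleg["accuracy"].mean() == pytest.approx(0.9, abs=3 * se)

    def test_requires_expert_levels(self):
        cfg = TaskConfig(difficulty_levels=(4,), n_trials_per_level=10,
                         block_size=10)
        with pytest.raises(ValueError, match="expert_levels"):
            simulate_delegation_dataset(self._agents(0.0), cfg, seed=0)


def test_default_agents_group_shift():
    agents = default_agents(3, rng=np.random.default_rng(0),
                            group_shift={"m_add": -0.2, "B0": 0.3})
    for per_cond in agents.values():
        assert (per_cond["Group"].metacog.m_add
                == pytest.approx(per_cond["Self"].metacog.m_add - 0.2))
        assert (per_cond["Group"].ddm.B0
                == pytest.approx(per_cond["Self"].ddm.B0 + 0.3))
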