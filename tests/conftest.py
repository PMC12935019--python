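import numpy as np
import pandas as pd
import pytest

from metadelegate.ddm import DDMParams
from metadelegate.metacog import MetacogParams
from metadelegate.delegation import DelegationParams
from metadelegate.tasks import (
    AgentSpec, TaskConfig, default_agents, simulate_forced_choice_dataset,
)


@pytest.fixture(scope="session")
def small_config():
    """Six difficulty levels, 5 trials per level: quick but structured."""
    return TaskConfig(difficulty_levels=(2, 4, 8, 12, 16, 24),
                      n_trials_per_level=5, block_size=5)


@pytest.fixture(scope="session")
def small_forced_choice(small_config):
    """Forced-choice dataset from 6 agents with identical Self/Group params."""
    agents = default_agents(6, rng=np.random.default_rng(7))
    return simulate_forced_choice_dataset(agents, small_config, seed=21)


@pytest.fixture(scope="session")
def metacog_trials():
    """1200 trials from known metacognitive parameters (for recovery)."""
    from metadelegate.metacog import simulate_confidence_trials

    rng = np.random.default_rng(3)
    levels = np.arange(2, 25, 2)
    c = np.repeat(levels, 100).astype(float)
    sides = np.where(rng.random(c.size) < 0.5, "left", "right")
    params = MetacogParams(sigma_sens=2.0, bias_sens=0.0, sigma_meta=0.05,
                           m_mult=0.8, m_add=0.0)
    df = simulate_confidence_trials(params, c, sides, rng)
    df["c"] = c
    df["correct_side"] = sides
    df["condition"] = "Self"
    return params, df


def make_iv_dataset(b_conf, J=20, n_per=36, seed=5):
    """Trial table from the IV model's own two-stage generative process."""
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(J):
        a_c = 0.3 * rng.standard_normal()
        a_y = 0.3 * rng.standard_normal()
        c = rng.choice(np.arange(2, 25, 2), n_per)
        cond = rng.integers(2, size=n_per)
        for i in range(n_per):
            rows.append((f"s{j:02d}", int(c[i]), cond[i], a_c, a_y))
    df = pd.DataFrame(rows, columns=["subject_id", "c", "cond_bin",
                                     "a_c", "a_y"])
    df["condition"] = np.where(df.cond_bin == 1, "Group", "Self")
    z1 = (df.c - df.c.mean()) / df.c.std()
    mu_c = df.a_c + 0.5 * z1 - 0.3 * df.cond_bin
    df["confidence_iv"] = mu_c + 0.4 * rng.standard_t(5, len(df))
    eta = df.a_y + b_conf * mu_c
    y = rng.random(len(df)) < 1 / (1 + np.exp(-eta))
    df["choice"] = np.where(y, "delegate", "left")
    df["expert_level"] = 0.9
    return df


def make_delegation_aggregates(
    true_alpha=-1.0, true_beta=0.0, true_link=3.0, J=40, n=10,
    expert=0.9, seed=42, alpha_sd=0.3,
):
    """Synthetic per-level aggregates from the delegation model itself."""
    rng = np.random.default_rng(seed)
    levels = np.arange(2, 25, 2)
    rows = []
    for j in range(J):
        a_j = true_alpha + alpha_sd * rng.standard_normal()
        b_j = abs(true_beta + 0.2 * rng.standard_normal()) if true_beta else 0.0
        conf = np.clip(
            0.55 + 0.35 * (np.log(levels) / np.log(24))
            + 0.03 * rng.standard_normal(levels.size), 0.5, 1.0)
        phi = a_j - b_j * conf
        p = 1.0 / (1.0 + np.exp(-true_link * (expert - conf + phi)))
        k = rng.binomial(n, p)
        for i, c in enumerate(levels):
            rows.append(dict(
                subject_id=f"s{j:02d}", condition="Group", expert_level=expert,
                c=int(c), mean_confidence_self=conf[i],
                delegation_proportion=k[i] / n, n_trials=n))
    return pd.DataFrame(rows)
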