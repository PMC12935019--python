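"""Task schedules, dot stimuli, and synthetic behavioral datasets.

Emulates a two-alternative dot-magnitude judgment task: two circles, one with
50 dots and one with 50 + c (c in {2, 4, ..., 24}), judged under Self or
Group responsibility conditions presented in pseudo-randomly intermixed
blocks of 10 trials, with confidence reports on {50, 60, ..., 100}.  Variants
cover limited (700 ms) and unlimited display, trial/summary feedback, a
stakes manipulation (Low = 15 vs High = 60 points, mirroring 15 x 4 group
payoffs), and a delegation task that adds experts with 70% or 90% accuracy.

Datasets are produced by composing the DDM (choice and RT), the
metacognitive model (confidence), and the delegation model (delegate/lead),
per agent and condition, from ground-truth parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from metadelegate.ddm import DDMParams, simulate_ddm_trials
from metadelegate.metacog import MetacogParams, simulate_confidence_trials
from metadelegate.delegation import DelegationParams, delegation_preference

__all__ = [
    "TaskConfig",
    "StimulusLayout",
    "AgentSpec",
    "generate_schedule",
    "generate_dot_stimulus",
    "simulate_forced_choice_dataset",
    "simulate_delegation_dataset",
    "default_agents",
    "TRIAL_TABLE_COLUMNS",
]

TRIAL_TABLE_COLUMNS = [
    "subject_id", "trial_index", "block_index", "condition", "c",
    "correct_side", "expert_level", "choice", "accuracy", "confidence",
    "rt_decision", "rt_initiation", "feedback_shown",
]

_VARIANTS = ("limited", "unlimited", "feedback", "stakes", "delegation")


@dataclass(frozen=True)
class TaskConfig:
    """Design parameters of one experiment variant.

    Defaults reproduce the printed task structure: 10 trials per difficulty
    level and condition, 12 levels (c = 2..24 step 2), blocks of 10 with no
    more than three consecutive blocks of one condition, 700 ms display for
    the limited variant, 15 points per correct choice (60 for the high-stakes
    condition), and expert accuracies {0.7, 0.9} in the delegation task.
    """

    experiment_variant: str = "limited"
    n_trials_per_level: int = 10
    difficulty_levels: tuple = tuple(range(2, 25, 2))
    conditions: tuple = ("Self", "Group")
    block_size: int = 10
    max_consecutive_same_blocks: int = 3
    display_ms: float | None = 700.0
    expert_levels: tuple = ()
    reward_points: Mapping[str, float] | None = None
    confidence_scale: tuple = (50, 60, 70, 80, 90, 100)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment_variant not in _VARIANTS:
            raise ValueError(f"unknown variant {self.experiment_variant!r}")
        lv = self.difficulty_levels
        if not all(x % 2 == 0 and x >= 2 for x in lv):
            raise ValueError("difficulty levels must be even and >= 2")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError("difficulty levels must be strictly increasing")
        if self.experiment_variant == "delegation" and not self.expert_levels:
            object.__setattr__(self, "expert_levels", (0.7, 0.9))
        for e in self.expert_levels:
            if not 0.5 < e <= 1.0:
                raise ValueError(f"expert accuracy must be in (0.5, 1], got {e}")
        if self.trials_per_condition % self.block_size != 0:
            raise ValueError(
                f"block size {self.block_size} does not divide the "
                f"{self.trials_per_condition} trials per condition"
            )
        if self.reward_points is None:
            pts = ({"Low": 15.0, "High": 60.0}
                   if self.experiment_variant == "stakes"
                   else {c: 15.0 for c in self.conditions})
            object.__setattr__(self, "reward_points", pts)

    @property
    def trials_per_condition(self) -> int:
        n = self.n_trials_per_level * len(self.difficulty_levels)
        if self.experiment_variant == "delegation":
            n *= len(self.expert_levels)
        return n

    @property
    def n_trials(self) -> int:
        return self.trials_per_condition * len(self.conditions)


@dataclass(frozen=True)
class StimulusLayout:
    """Dot coordinates for one trial; one circle holds 50 dots, the other
    50 + c.  Geometry (7.7 cm circles, 0.2 cm dots) is kept for fidelity but
    unused by any model."""

    left_dots: np.ndarray
    right_dots: np.ndarray
    circle_radius: float = 3.85
    dot_radius: float = 0.1


def _uniform_disk(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    th = 2 * np.pi * rng.random(n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def generate_dot_stimulus(
    c: int,
    seed: int,
    correct_side: str | None = None,
    circle_radius: float = 3.85,
) -> StimulusLayout:
    """Uniform dot placement inside each circle; the side with 50 + c dots is
    the correct side (random if not given)."""
    if c <= 0:
        raise ValueError("dot difference c must be positive")
    rng = np.random.default_rng(seed)
    if correct_side is None:
        correct_side = "left" if rng.random() < 0.5 else "right"
    n_left = 50 + c if correct_side == "left" else 50
    n_right = 50 + c if correct_side == "right" else 50
    return StimulusLayout(
        left_dots=_uniform_disk(n_left, circle_radius, rng),
        right_dots=_uniform_disk(n_right, circle_radius, rng),
        circle_radius=circle_radius,
    )


def _condition_block_order(
    labels: Sequence[str],
    n_blocks_each: int,
    max_run: int,
    rng: np.random.Generator,
    max_tries: int = 10_000,
) -> list:
    """Rejection-sample a block ordering with no run longer than max_run."""
    seq = np.repeat(list(labels), n_blocks_each)
    for _ in range(max_tries):
        rng.shuffle(seq)
        run, longest = 1, 1
        for a, b in zip(seq, seq[1:]):
            run = run + 1 if a == b else 1
            longest = max(longest, run)
        if longest <= max_run:
            return list(seq)
    raise RuntimeError("could not satisfy the consecutive-block constraint")


def generate_schedule(config: TaskConfig, seed: int | None = None) -> pd.DataFrame:
    """Trial schedule satisfying the design counts and block constraints.

    Per condition there are exactly ``n_trials_per_level`` trials at each
    difficulty level (crossed with each expert level in the delegation
    variant); trials are chunked into condition blocks of ``block_size``
    pseudo-randomly intermixed so that no more than
    ``max_consecutive_same_blocks`` consecutive blocks share a condition.
    The correct side is assigned independently per trial.  Deterministic
    given the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    per_cond = {}
    for cond in config.conditions:
        cells = []
        experts = config.expert_levels or (np.nan,)
        for e in experts:
            for c in config.difficulty_levels:
                cells += [(c, e)] * config.n_trials_per_level
        cells = np.array(cells, dtype=float)
        rng.shuffle(cells)
        per_cond[cond] = cells

    n_blocks_each = config.trials_per_condition // config.block_size
    order = _condition_block_order(
        config.conditions, n_blocks_each, config.max_consecutive_same_blocks, rng
    )

    rows = []
    cursor = {cond: 0 for cond in config.conditions}
    trial_index = 0
    for block_index, cond in enumerate(order):
        i = cursor[cond]
        chunk = per_cond[cond][i : i + config.block_size]
        cursor[cond] = i + config.block_size
        for c, e in chunk:
            rows.append(
                {
                    "trial_index": trial_index,
                    "block_index": block_index,
                    "condition": cond,
                    "c": int(c),
                    "correct_side": "left" if rng.random() < 0.5 else "right",
                    "expert_level": e,
                }
            )
            trial_index += 1
    return pd.DataFrame(rows)


@dataclass
class AgentSpec:
    """Ground-truth generative parameters of one agent in one condition."""

    ddm: DDMParams
    metacog: MetacogParams
    delegation: DelegationParams | None = None


def default_agents(
    n_subjects: int,
    conditions: Sequence[str] = ("Self", "Group"),
    rng: np.random.Generator | None = None,
    group_shift: Mapping[str, float] | None = None,
) -> dict:
    """Population of agents with mild parameter variability.

    ``group_shift`` optionally perturbs named parameters in the Group
    condition (e.g. ``{"m_add": -0.2}`` for responsibility-induced
    underconfidence); Self and Group otherwise share each agent's draw.
    """
    rng = rng or np.random.default_rng(0)
    agents = {}
    for s in range(n_subjects):
        base_ddm = DDMParams(
            B0=float(np.clip(1.2 + 0.1 * rng.standard_normal(), 0.6, 2.5)),
            l=0.1, h=0.05,
            v0=float(0.1 + 0.05 * rng.standard_normal()),
            v1=float(np.clip(0.5 + 0.08 * rng.standard_normal(), 0.1, 1.5)),
            x0=0.0,
            ndt=float(np.clip(0.3 + 0.03 * rng.standard_normal(), 0.15, 0.6)),
            t_max=8.0,
        )
        base_mc = MetacogParams(
            sigma_sens=float(np.clip(2.0 + 0.2 * rng.standard_normal(), 1.0, 4.0)),
            bias_sens=0.0,
            sigma_meta=0.08,
            m_mult=1.0,
            m_add=0.0,
        )
        spec = {}
        for cond in conditions:
            ddm_p, mc_p = base_ddm, base_mc
            if cond == "Group" and group_shift:
                ddm_kw = {k: v for k, v in group_shift.items()
                          if k in DDMParams.__dataclass_fields__}
                mc_kw = {k: v for k, v in group_shift.items()
                         if k in MetacogParams.__dataclass_fields__}
                if ddm_kw:
                    from dataclasses import replace
                    ddm_p = replace(base_ddm, **{
                        k: getattr(base_ddm, k) + v for k, v in ddm_kw.items()})
                if mc_kw:
                    from dataclasses import replace
                    mc_p = replace(base_mc, **{
                        k: getattr(base_mc, k) + v for k, v in mc_kw.items()})
            spec[cond] = AgentSpec(ddm=ddm_p, metacog=mc_p)
        agents[f"s{s:03d}"] = spec
    return agents


def _coupled_decision_values(
    mc: MetacogParams, mu: np.ndarray, choice_sign: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sensory samples truncated to the side of the externally given choice,
    so confidence conditions on the same latent evidence that produced it."""
    m0 = mu + mc.bias_sens
    a = np.where(choice_sign > 0, 0.0, -np.inf)
    b = np.where(choice_sign > 0, np.inf, 0.0)
    az = (a - m0) / mc.sigma_sens
    bz = (b - m0) / mc.sigma_sens
    u = rng.random(mu.size)
    return stats.truncnorm.ppf(u, az, bz, loc=m0, scale=mc.sigma_sens)


def simulate_forced_choice_dataset(
    agents: Mapping[str, Mapping[str, AgentSpec]],
    config: TaskConfig,
    seed: int = 0,
    coupling: str = "coupled",
    dt: float = 2e-3,
) -> pd.DataFrame:
    """Full synthetic forced-choice dataset: DDM choice/RT plus model-based
    confidence for every scheduled trial of every agent.

    ``coupling="coupled"`` (default) draws the metacognitive sensory sample
    from the side of the DDM choice, so choice and confidence share one
    evidence channel; ``"independent"`` draws it unconditionally.
    """
    if coupling not in ("coupled", "independent"):
        raise ValueError("coupling must be 'coupled' or 'independent'")
    root = np.random.default_rng(seed)
    frames = []
    feedback = config.experiment_variant == "feedback"
    for subject_id, per_cond in agents.items():
        sched = generate_schedule(config, seed=int(root.integers(2**31)))
        rng = np.random.default_rng(int(root.integers(2**31)))
        for cond in config.conditions:
            if cond not in per_cond:
                raise ValueError(f"agent {subject_id} lacks condition {cond!r}")
            spec = per_cond[cond]
            sub = sched[sched["condition"] == cond].copy()
            s = np.where(sub["correct_side"].to_numpy() == "left", 1.0, -1.0)
            resp, rt = simulate_ddm_trials(
                spec.ddm, sub["c"].to_numpy(float), rng, dt=dt, direction=s
            )
            mu = s * np.log(sub["c"].to_numpy(float))
            if coupling == "coupled":
                y = _coupled_decision_values(spec.metacog, mu, resp, rng)
            else:
                y = None
            conf = simulate_confidence_trials(
                spec.metacog, sub["c"].to_numpy(float), s, rng, y=y
            )
            sub["choice"] = np.where(resp > 0, "left", "right")
            sub["accuracy"] = (resp == s).astype(int)
            sub["confidence"] = conf["confidence"].to_numpy()
            sub["rt_decision"] = rt
            sub["rt_initiation"] = rng.lognormal(np.log(0.4), 0.3, len(sub))
            sub["feedback_shown"] = feedback
            sub["subject_id"] = subject_id
            frames.append(sub)
    out = pd.concat(frames, ignore_index=True)
    return out[TRIAL_TABLE_COLUMNS]


def simulate_delegation_dataset(
    agents: Mapping[str, Mapping[str, AgentSpec]],
    config: TaskConfig,
    seed: int = 0,
    dt: float = 2e-3,
) -> pd.DataFrame:
    """Synthetic delegation-task dataset.

    On each trial the agent forms an internal confidence from the
    metacognitive model, compares the delegate value (the expert's accuracy)
    with the lead value (own confidence) plus the delegation preference, and
    delegates with probability ``logistic(link_scale * Delta)``.  Delegated
    trials resolve by a Bernoulli draw at the expert's accuracy; led trials
    run through the agent's DDM.  Confidence is not elicited in this task
    (the confidence column is empty), matching the design.
    """
    if not config.expert_levels:
        raise ValueError("delegation requires nonempty expert_levels")
    root = np.random.default_rng(seed)
    frames = []
    for subject_id, per_cond in agents.items():
        sched = generate_schedule(config, seed=int(root.integers(2**31)))
        rng = np.random.default_rng(int(root.integers(2**31)))
        for cond in config.conditions:
            spec = per_cond[cond]
            if spec.delegation is None:
                raise ValueError(f"agent {subject_id} lacks DelegationParams")
            dp = spec.delegation
            sub = sched[sched["condition"] == cond].copy()
            cvals = sub["c"].to_numpy(float)
            s = np.where(sub["correct_side"].to_numpy() == "left", 1.0, -1.0)
            conf = simulate_confidence_trials(spec.metacog, cvals, s, rng)
            c_ind = conf["conf_continuous"].to_numpy()
            expert = sub["expert_level"].to_numpy(float)
            phi = delegation_preference(dp, c_ind, expert)
            delta = expert - c_ind + phi
            if np.isfinite(dp.link_scale):
                p_del = 1.0 / (1.0 + np.exp(-dp.link_scale * delta))
            else:
                p_del = (delta > 0).astype(float)
            delegated = rng.random(len(sub)) < p_del

            resp, rt = simulate_ddm_trials(spec.ddm, cvals, rng, dt=dt,
                                           direction=s)
            choice = np.where(resp > 0, "left", "right").astype(object)
            accuracy = (resp == s).astype(float)
            exp_correct = rng.random(len(sub)) < expert
            choice[delegated] = "delegate"
            accuracy[delegated] = exp_correct[delegated].astype(float)
            rt = np.where(delegated, rng.lognormal(np.log(0.8), 0.4, len(sub)), rt)

            sub["choice"] = choice
            sub["accuracy"] = accuracy
            sub["confidence"] = np.nan
            sub["rt_decision"] = rt
            sub["rt_initiation"] = rng.lognormal(np.log(0.4), 0.3, len(sub))
            sub["feedback_shown"] = False
            sub["subject_id"] = subject_id
            frames.append(sub)
    out = pd.concat(frames, ignore_index=True)
    return out[TRIAL_TABLE_COLUMNS]
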