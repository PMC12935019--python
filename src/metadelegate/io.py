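"""CSV/YAML/JSON plumbing, schema validation, and the end-to-end pipeline.

The trial table travels as a flat UTF-8 comma-separated file with a fixed
header (see ``TRIAL_TABLE_COLUMNS``); RTs are written in seconds with six
decimals, missing values as empty fields, so identical configs and seeds
produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from metadelegate.tasks import TRIAL_TABLE_COLUMNS, TaskConfig

__all__ = [
    "read_trial_table",
    "write_trial_table",
    "read_task_config",
    "write_task_config",
    "RunManifest",
    "run_pipeline",
]

log = logging.getLogger("metadelegate")

_VALID_CONFIDENCE = {50, 60, 70, 80, 90, 100}
_VALID_CHOICE = {"left", "right", "delegate"}


class SchemaError(ValueError):
    """A trial table violated the documented schema."""


def write_trial_table(df: pd.DataFrame, path) -> None:
    """Write a trial table CSV with fixed numeric precision."""
    out = df.copy()
    for col in ("rt_decision", "rt_initiation"):
        out[col] = out[col].map(
            lambda v: "" if pd.isna(v) else f"{v:.6f}"
        )
    for col in ("confidence", "expert_level", "accuracy"):
        out[col] = out[col].map(
            lambda v: "" if pd.isna(v) else (f"{v:g}")
        )
    out[TRIAL_TABLE_COLUMNS].to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a trial table CSV.

    Schema violations are reported with (1-based, header-exclusive) row
    numbers.  Checks: required columns; confidence on the six-bin scale when
    present; positive decision RTs; delegate choices only on trials with an
    expert available.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: empty trial table")
    missing = set(TRIAL_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")

    problems = []

    conf = df["confidence"]
    bad = conf.notna() & ~conf.isin(list(_VALID_CONFIDENCE))
    for i in df.index[bad][:5]:
        problems.append(f"row {i + 1}: confidence {conf[i]!r} not on the 50..100 scale")

    rt = pd.to_numeric(df["rt_decision"], errors="coerce")
    bad = df["rt_decision"].notna() & ~(rt > 0)
    for i in df.index[bad][:5]:
        problems.append(f"row {i + 1}: rt_decision must be positive")

    bad = ~df["choice"].isin(_VALID_CHOICE)
    for i in df.index[bad][:5]:
        problems.append(f"row {i + 1}: unknown choice {df['choice'][i]!r}")

    deleg = df["choice"] == "delegate"
    bad = deleg & df["expert_level"].isna()
    for i in df.index[bad][:5]:
        problems.append(f"row {i + 1}: delegate choice without expert_level")

    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems))
    return df


def write_task_config(config: TaskConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["difficulty_levels"] = list(d["difficulty_levels"])
    d["conditions"] = list(d["conditions"])
    d["expert_levels"] = list(d["expert_levels"])
    d["confidence_scale"] = list(d["confidence_scale"])
    d["reward_points"] = dict(d["reward_points"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_task_config(path) -> TaskConfig:
    d = yaml.safe_load(Path(path).read_text())
    for key in ("difficulty_levels", "conditions", "expert_levels",
                "confidence_scale"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return TaskConfig(**d)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_hash: str
    seed: int
    package_version: str
    stages: dict = field(default_factory=dict)  # name -> {path, seconds}

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def run_pipeline(
    config: TaskConfig,
    seed: int,
    out_dir,
    n_subjects: int = 8,
    reduced: bool = True,
) -> RunManifest:
    """Simulate, fit, and analyze one synthetic study end to end.

    Stages: simulate forced-choice and delegation datasets; fit the
    metacognitive model and the DDM to one subject; fit the constant-variant
    delegation model; run the condition-on-confidence regression.  With
    ``reduced=True`` (default) fits use desk-scale optimizer and sampler
    settings.  All artifacts and a manifest land under ``out_dir``; any
    stage failure raises with a stage-tagged message.
    """
    from metadelegate import __version__
    from metadelegate.tasks import (
        default_agents, simulate_forced_choice_dataset, simulate_delegation_dataset,
    )
    from metadelegate.ddm import CollapsingBoundDDM
    from metadelegate.metacog import MetacogModel
    from metadelegate.delegation import (
        DelegationModel, DelegationParams, build_level_aggregates,
    )
    from metadelegate.inference import HierarchicalRegression

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_bytes = json.dumps(dataclasses.asdict(config), sort_keys=True,
                           default=str).encode()
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_bytes).hexdigest()[:16],
        seed=seed,
        package_version=__version__,
    )

    def stage(name):
        t0 = time.time()
        log.info("stage %s started (seed %d)", name, seed)

        def done(path):
            manifest.stages[name] = {
                "path": str(path), "seconds": round(time.time() - t0, 2),
            }
            log.info("stage %s finished in %.1fs", name, time.time() - t0)

        return done

    try:
        done = stage("simulate")
        rng = np.random.default_rng(seed)
        agents = default_agents(n_subjects, rng=rng, group_shift={"m_add": -0.15})
        fc = simulate_forced_choice_dataset(agents, config, seed=seed)
        fc_path = out_dir / "forced_choice.csv"
        write_trial_table(fc, fc_path)

        deleg_cfg = TaskConfig(experiment_variant="delegation",
                               difficulty_levels=config.difficulty_levels,
                               n_trials_per_level=config.n_trials_per_level)
        for sid in agents:
            for cond in agents[sid]:
                agents[sid][cond].delegation = DelegationParams(
                    variant="constant", alpha_phi=-0.1, link_scale=3.0)
        dl = simulate_delegation_dataset(agents, deleg_cfg, seed=seed + 1)
        dl_path = out_dir / "delegation.csv"
        write_trial_table(dl, dl_path)
        done(fc_path)
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'simulate' failed: {e}") from e

    try:
        done = stage("fit_metacog")
        first = fc[fc["subject_id"] == sorted(fc["subject_id"].unique())[0]]
        mc_fit = MetacogModel(n_starts=2 if reduced else 4, seed=seed).fit(
            first, condition="Self")
        mc_path = out_dir / "metacog_self.json"
        mc_path.write_text(json.dumps(
            dataclasses.asdict(mc_fit.params_), indent=2))
        done(mc_path)
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'fit_metacog' failed: {e}") from e

    try:
        done = stage("fit_ddm")
        ddm_kw = (dict(maxiter=3, popsize=6, polish_maxiter=150,
                       profile_l=(0.1,), profile_h=(0.0, 0.1))
                  if reduced else {})
        ddm_fit = CollapsingBoundDDM(seed=seed, **ddm_kw).fit(
            first, condition="Self")
        ddm_path = out_dir / "ddm_self.json"
        d = dataclasses.asdict(ddm_fit.params_)
        d["loglik"] = ddm_fit.loglik_
        d["converged"] = ddm_fit.converged_
        ddm_path.write_text(json.dumps(d, indent=2))
        done(ddm_path)
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'fit_ddm' failed: {e}") from e

    try:
        done = stage("fit_delegation")
        agg = build_level_aggregates(fc, dl)
        stratum = agg[(agg["condition"] == "Group")
                      & (agg["expert_level"] == 0.9)]
        kw = dict(n_steps=2000, n_burn=1000, thin=4) if reduced else {}
        del_fit = DelegationModel(variant="constant", seed=seed, **kw).fit(stratum)
        del_path = out_dir / "delegation_fit.json"
        del_path.write_text(del_fit.summary_.to_json(indent=2))
        done(del_path)
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'fit_delegation' failed: {e}") from e

    try:
        done = stage("regress_confidence")
        kw = (dict(chains=1, draws_per_chain=500, n_steps=1200, n_burn=800)
              if reduced else {})
        reg = HierarchicalRegression(equation_id=2, seed=seed, **kw).fit(fc)
        reg_path = out_dir / "regression_eq2.json"
        reg_path.write_text(json.dumps({
            t: {"point": e.point, "ci95": list(e.ci95), "pmcmc": e.pmcmc}
            for t, e in reg.effects_.items()}, indent=2))
        done(reg_path)
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'regress_confidence' failed: {e}") from e

    manifest.to_json(out_dir / "manifest.json")
    return manifest
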