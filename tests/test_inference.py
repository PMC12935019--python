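"""Regression layer: P_MCMC, hierarchical recovery, IV, sensitivity identities."""

import numpy as np
import pandas as pd
import pytest

from metadelegate.ddm import DDMParams
from metadelegate.metacog import MetacogParams
from metadelegate.inference import (
    EQUATION_SPECS,
    HierarchicalRegression,
    IVRegression,
    attach_iv_confidence,
    build_change_scores,
    build_design,
    parameter_swap_effect,
    pmcmc,
)

REDUCED = dict(chains=1, draws_per_chain=800, n_steps=1500, n_burn=900)


class TestPmcmc:
    def test_exact_counts(self):
        assert pmcmc(np.ones(200)) == 0.0
        assert pmcmc(np.array([1.0, 1, 1, -1] * 50)) == pytest.approx(0.25)

    def test_symmetric_posterior(self):
        rng = np.random.default_rng(0)
        d = rng.standard_normal(20_000)
        assert pmcmc(d) == pytest.approx(0.5, abs=0.02)

    def test_direction_override_and_warning(self):
        d = np.array([1.0] * 150 + [-1.0] * 50)
        assert pmcmc(d, "positive") == pytest.approx(0.25)
        assert pmcmc(d, "negative") == pytest.approx(0.75)
        with pytest.warns(UserWarning, match="100 draws"):
            pmcmc(np.ones(10))


class TestDesign:
    def test_battery_is_complete_and_typed(self):
        assert set(EQUATION_SPECS) == set(range(1, 13))
        for spec in EQUATION_SPECS.values():
            assert "Difficulty" not in spec.subject_varying

    def test_simulation_type_contrast_design(self, small_forced_choice):
        # biased-vs-unbiased simulation contrast: SimType dummy-coded with
        # the first (alphabetical) level as reference
        df = small_forced_choice.copy()
        half = len(df) // 2
        df["sim_type"] = ["biased"] * half + ["unbiased"] * (len(df) - half)
        y, X, terms, _, varying = build_design(df, EQUATION_SPECS[7])
        sim = X[:, terms.index("SimType")]
        assert set(np.unique(sim)) == {0.0, 1.0}
        assert terms.index("SimType") in varying

    def test_change_score_aggregation(self, small_forced_choice):
        # delegation frame: Group delegates strictly more than Self
        fc = small_forced_choice
        rows = []
        for sid in fc["subject_id"].unique():
            for cond, p in (("Self", 0.2), ("Group", 0.6)):
                for c in (4, 16):
                    for i in range(10):
                        rows.append((sid, cond, c, 0.9,
                                     "delegate" if i < p * 10 else "left"))
        dl = pd.DataFrame(rows, columns=["subject_id", "condition", "c",
                                         "expert_level", "choice"])
        out = build_change_scores(fc, dl, expert_level=0.9)
        assert {"delegation_change", "confidence_change"} <= set(out.columns)
        assert np.allclose(out["delegation_change"], 0.4)

    def test_condition_coding_and_standardization(self, small_forced_choice):
        y, X, terms, subj, varying = build_design(
            small_forced_choice, EQUATION_SPECS[2])
        cond = X[:, terms.index("Condition")]
        assert set(np.unique(cond)) == {0.0, 1.0}
        diff = X[:, terms.index("Difficulty")]
        assert diff.mean() == pytest.approx(0.0, abs=1e-9)
        assert diff.std() == pytest.approx(1.0, rel=1e-9)
        assert y.std() == pytest.approx(1.0, rel=1e-6)


def _simulate_logistic_glmm(n_subj=12, n_per=120, b_diff=1.0, b_cond=0.0,
                            seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(n_subj):
        a_j = 0.3 * rng.standard_normal()
        c = rng.choice(np.arange(2, 25, 2), n_per)
        cond = rng.integers(2, size=n_per)
        z = (c - c.mean()) / c.std()
        eta = 0.5 + a_j + b_diff * z + b_cond * cond
        y = rng.random(n_per) < 1 / (1 + np.exp(-eta))
        for i in range(n_per):
            rows.append((f"s{j:02d}", int(c[i]),
                         "Group" if cond[i] else "Self", int(y[i]), i))
    return pd.DataFrame(rows, columns=["subject_id", "c", "condition",
                                       "accuracy", "trial_index"])


class TestHierarchicalRegression:
    def test_logistic_recovery(self):
        df = _simulate_logistic_glmm(b_diff=1.0, b_cond=0.0, seed=1)
        fit = HierarchicalRegression(equation_id=1, seed=0, **REDUCED).fit(df)
        eff = fit.effect("Difficulty")
        assert eff.ci95[0] <= 1.0 <= eff.ci95[1]
        cond = fit.effect("Condition")
        assert cond.ci95[0] <= 0.0 <= cond.ci95[1]

    def test_gaussian_condition_shift_detected(self, small_forced_choice):
        df = small_forced_choice.copy()
        # inject a -0.4 SD confidence shift in Group rows
        shift = np.where(df["condition"] == "Group", -8.0, 0.0)
        df["confidence"] = np.clip(
            (df["confidence"] + shift).round(-1), 50, 100)
        fit = HierarchicalRegression(equation_id=2, seed=1, **REDUCED).fit(df)
        eff = fit.effect("Condition")
        assert eff.point < 0
        assert eff.ci95[1] < 0  # CI excludes zero

    def test_missing_columns_raise(self):
        with pytest.raises((ValueError, KeyError)):
            HierarchicalRegression(equation_id=1).fit(
                pd.DataFrame({"subject_id": ["a"]}))


class TestIV:
    @staticmethod
    def _generate(b_conf, J=20, n_per=36, seed=5):
        from tests.conftest import make_iv_dataset

        return make_iv_dataset(b_conf, J=J, n_per=n_per, seed=seed)

    def test_recovers_negative_confidence_effect(self):
        df = self._generate(b_conf=-0.7)
        fit = IVRegression(n_steps=3000, n_burn=1500, seed=0).fit(df, 0.9)
        eff = fit.effects_["beta_conf"]
        assert eff.ci95[0] <= -0.7 <= eff.ci95[1]
        assert eff.point < 0

    def test_null_confidence_effect_covered(self):
        df = self._generate(b_conf=0.0, seed=6)
        fit = IVRegression(n_steps=3000, n_burn=1500, seed=1).fit(df, 0.9)
        eff = fit.effects_["beta_conf"]
        assert eff.ci95[0] <= 0.0 <= eff.ci95[1]

    def test_zero_variance_instrument_rejected(self):
        df = self._generate(b_conf=-0.5)
        df["condition"] = "Self"
        with pytest.raises(ValueError, match="instrument"):
            IVRegression().fit(df, 0.9)

    def test_attach_confidence_merges_cell_means(self, small_forced_choice):
        deleg = small_forced_choice[["subject_id", "condition", "c"]].copy()
        deleg["choice"] = "left"
        deleg["expert_level"] = 0.9
        out = attach_iv_confidence(deleg, small_forced_choice)
        assert out["confidence_iv"].notna().all()


class TestParameterSwap:
    """Boundary identities of the sensitivity analysis (metacog simulator;
    the DDM and delegation simulators are exercised in the acceptance suite)."""

    SELF = MetacogParams(sigma_sens=2.0, sigma_meta=0.08)
    GROUP = MetacogParams(sigma_sens=2.0, sigma_meta=0.08, m_add=-0.45)

    def test_all_swap_reproduces_full_effect(self):
        all_fields = tuple(
            f.name for f in __import__("dataclasses").fields(MetacogParams))
        eff = parameter_swap_effect(self.SELF, self.GROUP, all_fields,
                                    "metacog", n_subjects=10, seed=0)
        assert eff.point < 0
        assert eff.ci95[1] < 0

    def test_no_swap_gives_null_effect(self):
        eff = parameter_swap_effect(self.SELF, self.GROUP, (), "metacog",
                                    n_subjects=10, seed=0)
        assert eff.ci95[0] <= 0.0 <= eff.ci95[1]

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            parameter_swap_effect(self.SELF, self.GROUP, ("nope",), "metacog")
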