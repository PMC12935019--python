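"""Delegation model: preference variants, action rule, DIC, optimality, LOO."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metadelegate.delegation import (
    DelegationModel,
    DelegationParams,
    delegation_drive,
    delegation_preference,
    delegation_probability,
    dic,
    expected_final_accuracy,
    loo_accuracy_prediction,
)
from tests.conftest import make_delegation_aggregates


class TestPreference:
    def test_constant_variant(self):
        p = DelegationParams(variant="constant", alpha_phi=-0.3)
        for conf in (0.5, 0.75, 1.0):
            assert delegation_preference(p, conf, 0.9) == pytest.approx(-0.3)

    def test_confidence_dependent_variant(self):
        p = DelegationParams(variant="conf_self", beta_phi_mag=2.0)
        assert delegation_preference(p, 0.8, 0.9) == pytest.approx(-1.6)

    def test_combined_variant(self):
        p = DelegationParams(variant="combined", alpha_phi=0.5, beta_phi_mag=1.0)
        assert delegation_preference(p, 0.9, 0.9) == pytest.approx(-0.4)

    def test_out_of_range_confidence_rejected(self):
        p = DelegationParams()
        with pytest.raises(ValueError):
            delegation_preference(p, 0.3, 0.9)
        with pytest.raises(ValueError):
            delegation_preference(p, 0.8, 1.2)

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValueError):
            DelegationParams(beta_phi_mag=-1.0)


class TestDrive:
    def test_value_maximizing_delegation(self):
        delta, action = delegation_drive(0.7, 0.9, 0.0)
        assert delta == pytest.approx(0.2)
        assert action == "delegate"

    def test_tie_resolves_to_lead(self):
        delta, action = delegation_drive(0.9, 0.7, 0.2)
        assert delta == pytest.approx(0.0)
        assert action == "lead"

    def test_dominant_lead_preference(self):
        for conf in (0.5, 0.9, 1.0):
            _, action = delegation_drive(conf, 0.9, -10.0)
            assert action == "lead"


class TestProbability:
    def test_midpoint_and_direct_value(self):
        p = DelegationParams(variant="constant", alpha_phi=0.0, link_scale=10.0)
        assert delegation_probability(0.9, p, 0.9) == pytest.approx(0.5)
        # Delta = 0.2 at slope 10 -> logistic(2)
        assert delegation_probability(0.7, p, 0.9) == pytest.approx(
            1 / (1 + np.exp(-2.0)), rel=1e-9)

    def test_hard_step_limit(self):
        p = DelegationParams(variant="constant", alpha_phi=0.0,
                             link_scale=np.inf)
        assert delegation_probability(0.7, p, 0.9) == 1.0
        assert delegation_probability(0.95, p, 0.9) == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        alpha=st.floats(-2, 2), beta=st.floats(0, 3), link=st.floats(0.5, 30),
        expert=st.sampled_from([0.7, 0.9]),
    )
    def test_monotone_in_confidence_and_expert(self, alpha, beta, link, expert):
        p = DelegationParams(variant="combined", alpha_phi=alpha,
                             beta_phi_mag=beta, link_scale=link)
        conf = np.linspace(0.5, 1.0, 11)
        probs = delegation_probability(conf, p, expert)
        assert np.all(np.diff(probs) <= 1e-12)
        assert np.all(
            delegation_probability(conf, p, 0.9)
            >= delegation_probability(conf, p, 0.7) - 1e-12)


class TestDIC:
    def test_degenerate_posterior(self):
        val, p_d = dic(np.array([7.0, 7.0, 7.0]), 7.0)
        assert p_d == 0.0
        assert val == 7.0

    def test_arithmetic(self):
        # draws with variance 4 and deviance-at-mean 10 -> pD 2, DIC 14
        draws = np.array([8.0, 12.0, 8.0, 12.0])
        val, p_d = dic(draws, 10.0)
        assert p_d == pytest.approx(2.0)
        assert val == pytest.approx(14.0)

    def test_needs_two_draws(self):
        with pytest.raises(ValueError):
            dic(np.array([3.0]), 3.0)


class TestHierarchicalFit:
    def test_recovers_population_constant_preference(self):
        agg = make_delegation_aggregates(true_alpha=-1.0, true_link=3.0, J=40)
        fit = DelegationModel(variant="constant", n_steps=6000, n_burn=3000,
                              thin=6, seed=1).fit(agg)
        lo, hi = fit.summary_.loc["alpha_phi", ["ci_low", "ci_high"]]
        assert lo <= -1.0 <= hi
        assert fit.pd_ > 0

    def test_all_lead_data_concentrates_negative(self):
        agg = make_delegation_aggregates(J=10, seed=3)
        agg["delegation_proportion"] = 0.0
        fit = DelegationModel(variant="constant", n_steps=3000, n_burn=1500,
                              seed=2).fit(agg)
        assert (fit.posterior_["alpha_phi"] < 0).mean() > 0.97

    def test_seed_reproducibility(self):
        agg = make_delegation_aggregates(J=8, seed=5)
        kw = dict(variant="constant", n_steps=1500, n_burn=800, seed=7)
        a = DelegationModel(**kw).fit(agg)
        b = DelegationModel(**kw).fit(agg)
        pd.testing.assert_frame_equal(a.summary_, b.summary_)
        assert a.dic_ == b.dic_

    def test_rejects_mixed_strata(self):
        agg = make_delegation_aggregates(J=4)
        other = agg.copy()
        other["expert_level"] = 0.7
        with pytest.raises(ValueError, match="stratum"):
            DelegationModel().fit(pd.concat([agg, other]))


class TestFinalAccuracy:
    conf = np.array([0.55, 0.65, 0.75, 0.85, 0.95])

    def test_boundary_policies(self):
        acc = self.conf  # calibrated confidence
        always_lead = expected_final_accuracy(-10.0, self.conf, acc, 0.9)
        assert always_lead == pytest.approx(acc.mean())
        always_delegate = expected_final_accuracy(10.0, self.conf, acc, 0.9)
        assert always_delegate == pytest.approx(0.9)

    def test_neutral_preference_is_optimal_under_calibration(self):
        acc = self.conf
        best = expected_final_accuracy(0.0, self.conf, acc, 0.8)
        assert best == pytest.approx(np.maximum(self.conf, 0.8).mean())
        for phi in (-0.5, -0.1, 0.1, 0.5):
            assert expected_final_accuracy(phi, self.conf, acc, 0.8) <= best + 1e-12

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), phi=st.floats(-1, 1),
           expert=st.sampled_from([0.7, 0.9]))
    def test_neutral_optimality_over_random_profiles(self, seed, phi, expert):
        rng = np.random.default_rng(seed)
        conf = np.sort(rng.uniform(0.5, 1.0, 12))
        assert (expected_final_accuracy(phi, conf, conf, expert)
                <= expected_final_accuracy(0.0, conf, conf, expert) + 1e-12)


class TestLeaveOneOut:
    def test_exact_linear_relation(self):
        phi = np.linspace(0.1, 1.0, 10)
        acc = 0.9 - 0.2 * phi
        preds, r = loo_accuracy_prediction(phi, acc)
        assert preds.size == 10
        assert r == pytest.approx(1.0)

    def test_independent_features_show_no_positive_skill(self):
        # out-of-sample correlation under the null is biased negative (the
        # prediction is close to the left-out mean), never reliably positive
        rs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            phi = rng.uniform(0, 1, 100)
            acc = 0.8 + 0.02 * rng.standard_normal(100)
            _, r = loo_accuracy_prediction(phi, acc)
            rs.append(r)
        assert np.mean(rs) < 0.2

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            loo_accuracy_prediction(np.ones(5), np.linspace(0.7, 0.9, 5))
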