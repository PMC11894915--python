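"""Unit and property tests for the net-benefit calculus."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbvoi import (
    ConfusionCounts,
    PopulationScale,
    Strategy,
    ThetaTriplet,
    Threshold,
    ValidationSample,
    decision_curve,
    enb_current_plugin,
    net_benefit,
    scale_to_population,
)

probs = st.floats(0.0, 1.0, allow_nan=False)
inner_probs = st.floats(0.01, 0.99, allow_nan=False)


class TestThreshold:
    @pytest.mark.parametrize("z", [0.0, 1.0, -0.1, 1.2, float("nan")])
    def test_invalid_rejected(self, z):
        with pytest.raises(ValueError):
            Threshold(z)

    def test_omega_is_odds_of_z(self):
        assert Threshold(0.02).omega == pytest.approx(0.02 / 0.98)
        assert Threshold(0.5).omega == 1.0


class TestNetBenefit:
    def test_treat_none_is_zero(self):
        theta = ThetaTriplet(0.3, 0.7, 0.8)
        assert net_benefit(Strategy.TREAT_NONE, theta, Threshold(0.13)) == 0.0

    def test_treat_all_zero_when_prevalence_equals_threshold(self):
        z = 0.17
        theta = ThetaTriplet(z, 0.6, 0.6)
        assert net_benefit(Strategy.TREAT_ALL, theta, Threshold(z)) == pytest.approx(
            0.0, abs=1e-15
        )

    def test_model_nb_hand_value(self):
        theta = ThetaTriplet(0.10, 0.80, 0.90)
        # 0.08 - 0.9 * 0.1 * (1/9) = 0.07
        assert net_benefit(Strategy.USE_MODEL, theta, Threshold(0.10)) == pytest.approx(
            0.07
        )

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            net_benefit(5, ThetaTriplet(0.1, 0.5, 0.5), Threshold(0.1))

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(p=probs, se=probs, sp=probs, z=inner_probs)
    def test_treat_all_minus_model_identity(self, p, se, sp, z):
        """NB(all) - NB(model) == prev*(1-sens) - (1-prev)*spec*omega."""
        thr = Threshold(z)
        theta = ThetaTriplet(p, se, sp)
        lhs = net_benefit(Strategy.TREAT_ALL, theta, thr) - net_benefit(
            Strategy.USE_MODEL, theta, thr
        )
        rhs = p * (1 - se) - (1 - p) * sp * thr.omega
        assert lhs == pytest.approx(rhs, abs=1e-12)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(p=inner_probs, se=inner_probs, sp=inner_probs, z=inner_probs,
           component=st.sampled_from(["prevalence", "sensitivity", "specificity"]))
    def test_linearity_in_each_component(self, p, se, sp, z, component):
        """Second finite difference along each theta axis is zero."""
        thr = Threshold(z)
        base = {"prevalence": p, "sensitivity": se, "specificity": sp}
        h = min(base[component], 1 - base[component]) / 2
        vals = []
        for delta in (-h, 0.0, h):
            theta = ThetaTriplet(**{**base, component: base[component] + delta})
            vals.append(net_benefit(Strategy.USE_MODEL, theta, thr))
        assert vals[0] + vals[2] - 2 * vals[1] == pytest.approx(0.0, abs=1e-12)


class TestEnbCurrentPlugin:
    def test_case_study_means_prefer_model(self):
        theta = ThetaTriplet(0.086, 42 / 45, 148 / 459)
        best, _ = enb_current_plugin(theta, Threshold(0.02))
        assert best is Strategy.USE_MODEL

    def test_symmetric_point_ties_to_treat_none(self):
        best, value = enb_current_plugin(ThetaTriplet(0.5, 0.5, 0.5), Threshold(0.5))
        assert best is Strategy.TREAT_NONE
        assert value == 0.0

    def test_prevalence_one_ties_to_model(self):
        best, value = enb_current_plugin(ThetaTriplet(1.0, 1.0, 0.3), Threshold(0.2))
        assert best is Strategy.USE_MODEL
        assert value == 1.0

    def test_zero_total_counts_rejected(self):
        with pytest.raises(ValueError):
            enb_current_plugin(ConfusionCounts(0, 0, 0, 0), Threshold(0.1))

    def test_counts_and_theta_agree(self, pilot_sample, thr02):
        counts = pilot_sample.counts_at(thr02)
        best_c, val_c = enb_current_plugin(counts, thr02)
        best_t, val_t = enb_current_plugin(counts.to_theta(), thr02)
        assert best_c is best_t
        assert val_c == pytest.approx(val_t, abs=1e-12)


class TestPopulationScaling:
    def test_zero_scales_to_zero(self):
        scale = PopulationScale(800_000)
        assert scale_to_population(0.0, Threshold(0.3), scale) == 0.0

    def test_case_study_tp_and_fp_units(self):
        thr = Threshold(0.02)
        tp = scale_to_population(0.00101, thr, PopulationScale(800_000, "true_positive"))
        fp = scale_to_population(0.00125, thr, PopulationScale(800_000, "false_positive"))
        assert tp == pytest.approx(808, abs=1)
        assert fp == pytest.approx(49_000, abs=10)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(v=st.floats(0, 1, allow_nan=False), z=inner_probs,
           k=st.floats(0, 1e7, allow_nan=False))
    def test_fp_tp_ratio_is_inverse_odds(self, v, z, k):
        thr = Threshold(z)
        tp = scale_to_population(v, thr, PopulationScale(k, "true_positive"))
        fp = scale_to_population(v, thr, PopulationScale(k, "false_positive"))
        if tp > 0:
            assert fp / tp == pytest.approx((1 - z) / z, rel=1e-12)

    def test_negative_voi_rejected(self):
        with pytest.raises(ValueError):
            scale_to_population(-0.1, Threshold(0.3), PopulationScale(100))


class TestValidationSample:
    def test_boundary_risk_classified_positive(self):
        s = ValidationSample(risks=[0.02, 0.0199], outcomes=[1, 1])
        c = s.counts_at(Threshold(0.02))
        assert (c.n_tp, c.n_fn) == (1, 1)

    def test_out_of_range_risk_reports_row(self):
        with pytest.raises(ValueError, match="row 2"):
            ValidationSample(risks=[0.5, 1.2], outcomes=[0, 1])

    def test_nonbinary_outcome_reports_row(self):
        with pytest.raises(ValueError, match="row 3"):
            ValidationSample(risks=[0.5, 0.5, 0.5], outcomes=[0, 1, 2])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ValidationSample(risks=[], outcomes=[])

    def test_csv_round_trip(self, pilot_sample, tmp_path):
        path = tmp_path / "sample.csv"
        pilot_sample.to_csv(path)
        back = ValidationSample.from_csv(path)
        np.testing.assert_allclose(back.risks, pilot_sample.risks)
        np.testing.assert_array_equal(back.outcomes, pilot_sample.outcomes)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("risk,label\n0.5,1\n")
        with pytest.raises(ValueError, match="outcome"):
            ValidationSample.from_csv(path)


class TestDecisionCurve:
    def test_fixture_model_nb_at_002(self, pilot_sample):
        table = decision_curve(pilot_sample, [0.02])
        expected = 41 / 500 - (310 / 500) * (0.02 / 0.98)
        assert table["nb_model"][0] == pytest.approx(expected, abs=1e-12)
        assert table["nb_none"][0] == 0.0

    def test_treat_all_matches_plugin_prevalence(self, pilot_sample):
        table = decision_curve(pilot_sample, [0.05])
        prev = pilot_sample.prevalence
        omega = 0.05 / 0.95
        assert table["nb_all"][0] == pytest.approx(prev - (1 - prev) * omega, abs=1e-12)

    def test_no_events_sample_cannot_benefit(self):
        s = ValidationSample(risks=[0.4, 0.6, 0.1], outcomes=[0, 0, 0])
        table = decision_curve(s, [0.3])
        assert table["nb_model"][0] <= 0
        assert table["nb_all"][0] < 0

    def test_consistent_with_net_benefit_at_plugin_theta(self, pilot_sample):
        thr = Threshold(0.02)
        theta = pilot_sample.counts_at(thr).to_theta()
        table = decision_curve(pilot_sample, [thr])
        assert table["nb_model"][0] == pytest.approx(
            net_benefit(Strategy.USE_MODEL, theta, thr), abs=1e-12
        )
        assert table["nb_all"][0] == pytest.approx(
            net_benefit(Strategy.TREAT_ALL, theta, thr), abs=1e-12
        )

    def test_empty_thresholds_rejected(self, pilot_sample):
        with pytest.raises(ValueError):
            decision_curve(pilot_sample, [])
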