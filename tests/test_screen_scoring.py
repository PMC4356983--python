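"""Ratiometric readouts, deviation scores, classification, t-tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pmtraffic.errors import (
    ContractViolationError,
    DegenerateControlError,
    ParameterError,
)
from pmtraffic.screen_scoring import (
    ENHANCER,
    INHIBITOR,
    NEUTRAL,
    READOUTS,
    ConditionSummary,
    ImageSummary,
    cell_traffic_efficiency,
    classify_condition,
    compare_condition,
    condition_summary,
    deviation_score,
    image_summary,
    score_screen,
)
from test_quality_control import make_cell


def ratio_cell(surface, total, **kwargs):
    return make_cell(
        integrated_surface=float(surface),
        integrated_total=float(total),
        mean_total=float(total) / 200,
        **kwargs,
    )


class TestCellTrafficEfficiency:
    def test_half(self):
        assert cell_traffic_efficiency(ratio_cell(50, 100)) == pytest.approx(0.5)

    def test_scale_invariance(self):
        a = cell_traffic_efficiency(ratio_cell(50, 100))
        b = cell_traffic_efficiency(ratio_cell(150, 300))
        assert a == pytest.approx(b)

    def test_zero_surface_mutant_like(self):
        assert cell_traffic_efficiency(ratio_cell(0, 100)) == 0.0

    def test_zero_total_contract_violation(self):
        with pytest.raises(ContractViolationError):
            cell_traffic_efficiency(ratio_cell(0, 0))


class TestImageSummary:
    def test_odd_median(self):
        cells = [ratio_cell(r * 100, 100) for r in (0.2, 0.4, 0.9)]
        summary = image_summary(cells, "A01", 1, "c")
        assert summary.median_traffic_efficiency == pytest.approx(0.4)

    def test_even_median_averages_middle_pair(self):
        cells = [ratio_cell(r * 100, 100) for r in (0.2, 0.4)]
        summary = image_summary(cells, "A01", 1, "c")
        assert summary.median_traffic_efficiency == pytest.approx(0.3)

    def test_flagged_cells_excluded(self):
        good = ratio_cell(40, 100)
        bad = ratio_cell(90, 100)
        bad.qc_flags.add("saturated")
        summary = image_summary([good, bad], "A01", 1, "c")
        assert summary.n_cells == 1
        assert summary.median_traffic_efficiency == pytest.approx(0.4)

    def test_no_passing_cells_returns_none(self):
        bad = ratio_cell(10, 100)
        bad.qc_flags.add("low_expression")
        assert image_summary([bad], "A01", 1, "c") is None

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=25))
    def test_median_matches_sort_based_oracle(self, ratios):
        cells = [ratio_cell(r * 1000, 1000) for r in ratios]
        summary = image_summary(cells, "A01", 1, "c")
        ordered = sorted(ratios)
        n = len(ordered)
        oracle = (
            ordered[n // 2] if n % 2 else (ordered[n // 2 - 1] + ordered[n // 2]) / 2.0
        )
        assert summary.median_traffic_efficiency == pytest.approx(oracle, abs=1e-12)


def summaries_from(values, condition="test"):
    return [
        ImageSummary(
            well="A01",
            field=i + 1,
            condition=condition,
            median_traffic_efficiency=v,
            median_total=v * 1000,
            median_surface=v * 500,
            n_cells=30,
        )
        for i, v in enumerate(values)
    ]


class TestConditionSummary:
    def test_mean_of_image_medians(self):
        summary = condition_summary(summaries_from([0.3, 0.5]), "test")
        assert summary.mean["traffic_efficiency"] == pytest.approx(0.4)

    def test_sem_formula(self):
        # sd of {0.40, 0.50, 0.60} is 0.1, so sem = 0.1/sqrt(3)
        summary = condition_summary(summaries_from([0.40, 0.50, 0.60]), "test")
        assert summary.mean["traffic_efficiency"] == pytest.approx(0.50)
        assert summary.sem["traffic_efficiency"] == pytest.approx(
            0.05773502691896257, abs=1e-12
        )

    def test_single_image_sem_undefined(self):
        summary = condition_summary(summaries_from([0.5]), "test")
        assert summary.sem["traffic_efficiency"] is None
        assert summary.n_images == 1

    def test_median_aggregation_switch(self):
        summary = condition_summary(summaries_from([0.1, 0.2, 0.9]), "test", aggregation="median")
        assert summary.mean["traffic_efficiency"] == pytest.approx(0.2)

    def test_failed_images_excluded(self):
        images = summaries_from([0.3, 0.5, 0.9])
        images[2].qc_status = "out_of_focus"
        summary = condition_summary(images, "test")
        assert summary.n_images == 2
        assert summary.mean["traffic_efficiency"] == pytest.approx(0.4)


class TestDeviationScore:
    def _neg(self, values=(0.40, 0.50, 0.60)):
        return condition_summary(summaries_from(list(values), "neg"), "neg")

    def test_equal_means_zero(self):
        test = condition_summary(summaries_from([0.40, 0.50, 0.60], "t"), "t")
        assert deviation_score(test, self._neg()) == pytest.approx(0.0, abs=1e-12)

    def test_effect_of_twice_sem_scores_exactly_one(self):
        neg = self._neg()
        sem = neg.sem["traffic_efficiency"]
        shifted = [v + 2 * sem for v in (0.40, 0.50, 0.60)]
        test = condition_summary(summaries_from(shifted, "t"), "t")
        assert deviation_score(test, neg, k=2.0) == pytest.approx(1.0, abs=1e-12)

    def test_hand_evaluated_example(self):
        # (0.70 - 0.50) / (2 * 0.1/sqrt(3))
        test = condition_summary(summaries_from([0.60, 0.70, 0.80], "t"), "t")
        assert deviation_score(test, self._neg(), k=2.0) == pytest.approx(
            1.7320508075688772, abs=1e-12
        )

    def test_zero_sem_degenerate_control(self):
        neg = condition_summary(summaries_from([0.5, 0.5, 0.5], "neg"), "neg")
        test = condition_summary(summaries_from([0.6, 0.7], "t"), "t")
        with pytest.raises(DegenerateControlError):
            deviation_score(test, neg)

    def test_undefined_sem_degenerate_control(self):
        neg = condition_summary(summaries_from([0.5], "neg"), "neg")
        test = condition_summary(summaries_from([0.6, 0.7], "t"), "t")
        with pytest.raises(DegenerateControlError):
            deviation_score(test, neg)

    def test_antisymmetry_for_equal_spread_groups(self):
        # same sd in both groups -> swapping test and control negates the score
        a = condition_summary(summaries_from([0.40, 0.50, 0.60], "a"), "a")
        b = condition_summary(summaries_from([0.45, 0.55, 0.65], "b"), "b")
        assert deviation_score(a, b) == pytest.approx(-deviation_score(b, a), abs=1e-12)


class TestClassify:
    def test_enhancer(self):
        assert classify_condition(1.5) == ENHANCER

    def test_inhibitor(self):
        assert classify_condition(-1.2) == INHIBITOR

    def test_exact_plus_one_neutral(self):
        assert classify_condition(1.0) == NEUTRAL

    def test_exact_minus_one_neutral(self):
        assert classify_condition(-1.0) == NEUTRAL

    def test_non_finite_rejected(self):
        with pytest.raises(ParameterError):
            classify_condition(float("nan"))

    @settings(max_examples=100, deadline=None)
    @given(st.floats(min_value=-10, max_value=10))
    def test_classification_consistent_with_thresholds(self, score):
        label = classify_condition(score)
        if score > 1:
            assert label == ENHANCER
        elif score < -1:
            assert label == INHIBITOR
        else:
            assert label == NEUTRAL


class TestCompareCondition:
    def test_identical_groups_p_one(self):
        assert compare_condition([0.4, 0.5, 0.6], [0.4, 0.5, 0.6]) == pytest.approx(1.0)

    def test_matches_closed_form_pooled_t(self):
        # independent oracle: pooled-variance formula + t CDF, evaluated here
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
            len(a) + len(b) - 2
        )
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert abs(t) == pytest.approx(3.6742346141747673, abs=1e-10)
        p_oracle = 2 * stats.t.sf(abs(t), len(a) + len(b) - 2)
        assert p_oracle == pytest.approx(0.021311641128756713, abs=1e-10)
        assert compare_condition(a, b) == pytest.approx(p_oracle, abs=1e-10)

    def test_agrees_with_permutation_test(self, rng):
        # Monte-Carlo permutation oracle on a moderate-effect fixture
        a = rng.normal(0.0, 1.0, 12)
        b = rng.normal(0.8, 1.0, 12)
        p_t = compare_condition(a, b)
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        n_perm, hits = 20000, 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if abs(perm[:12].mean() - perm[12:].mean()) >= obs:
                hits += 1
        p_perm = hits / n_perm
        mc_err = 3 * math.sqrt(max(p_perm, 1e-4) * (1 - p_perm) / n_perm)
        assert abs(p_t - p_perm) <= mc_err + 0.02

    def test_too_small_groups_rejected(self):
        with pytest.raises(ParameterError):
            compare_condition([0.1], [0.2, 0.3])

    def test_welch_flag(self):
        a, b = [1.0, 2.0, 3.0, 9.0], [4.0, 5.0, 6.0]
        assert compare_condition(a, b, welch=True) != compare_condition(a, b, welch=False)


class TestScoreScreen:
    def _images(self):
        return (
            summaries_from([0.40, 0.50, 0.60], "neg")
            + summaries_from([0.60, 0.70, 0.80], "up")
            + summaries_from([0.41, 0.49, 0.58], "flat")
            + summaries_from([0.9], "lonely")
        )

    def test_hits_and_exclusions(self):
        summaries, hits, excluded = score_screen(self._images(), negative_control="neg")
        assert excluded == ["lonely"]
        by_key = {(h.condition, h.readout): h for h in hits}
        up = by_key[("up", "traffic_efficiency")]
        assert up.classification == ENHANCER
        assert up.deviation_score == pytest.approx(1.7320508075688772, abs=1e-12)
        flat = by_key[("flat", "traffic_efficiency")]
        assert flat.classification == NEUTRAL
        assert set(h.readout for h in hits) == set(READOUTS)

    def test_classification_consistency_invariant(self):
        _, hits, _ = score_screen(self._images(), negative_control="neg")
        for h in hits:
            assert h.classification == classify_condition(h.deviation_score)

    def test_missing_negative_control_rejected(self):
        with pytest.raises(DegenerateControlError):
            score_screen(self._images(), negative_control="absent")

    def test_ratio_invariance_per_cell_scaling(self, rng):
        """Scaling each cell's total and surface by a common per-cell factor
        leaves every traffic-efficiency summary unchanged."""
        ratios = rng.uniform(0.1, 0.9, 20)
        factors = rng.uniform(0.5, 5.0, 20)
        base_cells = [ratio_cell(r * 1000, 1000) for r in ratios]
        scaled_cells = [
            ratio_cell(r * 1000 * f, 1000 * f) for r, f in zip(ratios, factors)
        ]
        base = image_summary(base_cells, "A01", 1, "c").median_traffic_efficiency
        scaled = image_summary(scaled_cells, "A01", 1, "c").median_traffic_efficiency
        assert base == pytest.approx(scaled, abs=1e-12)
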