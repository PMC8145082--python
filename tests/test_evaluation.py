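"""Confusion matrices, classification metrics, t tests, and transition analysis."""

import math

import numpy as np
import pytest

from gazedialogue import (
    InteractionTimeline,
    ValidationError,
    accuracy_ttest,
    classification_report,
    confusion_matrix,
    find_transitions,
    qualifying_transitions,
    support_weighted,
    transition_error_analysis,
    transition_table,
)
from gazedialogue.evaluation import ConfusionMatrix, TransitionErrorReport, round_half_away
from gazedialogue.fusion import CLASSES
from tests.conftest import random_timeline, timeline_of


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self, rng):
        t = random_timeline(rng, 100)
        cm = confusion_matrix(t, t)
        assert cm.counts.trace() == 100
        assert cm.total == 100
        assert (cm.counts == np.diag(np.diag(cm.counts))).all()

    def test_small_example(self):
        cm = confusion_matrix(timeline_of(["D", "D", "SG"]), timeline_of(["D", "SG", "SG"]))
        d, sg = CLASSES.index("D"), CLASSES.index("SG")
        assert cm.counts[d, d] == 1
        assert cm.counts[d, sg] == 1
        assert cm.counts[sg, sg] == 1
        assert cm.total == 3

    def test_matches_brute_force_tally(self, rng):
        t = random_timeline(rng, 500)
        p = random_timeline(rng, 500)
        cm = confusion_matrix(t, p)
        tally = {}
        for a, b in zip(t.labels, p.labels):
            tally[(a, b)] = tally.get((a, b), 0) + 1
        for i, ci in enumerate(CLASSES):
            for j, cj in enumerate(CLASSES):
                assert cm.counts[i, j] == tally.get((ci, cj), 0)

    def test_conservation(self, rng):
        t = random_timeline(rng, 300)
        p = random_timeline(rng, 300)
        cm = confusion_matrix(t, p)
        truth_counts = {c: t.labels.count(c) for c in CLASSES}
        pred_counts = {c: p.labels.count(c) for c in CLASSES}
        for i, c in enumerate(CLASSES):
            assert cm.counts[i].sum() == truth_counts[c]
            assert cm.counts[:, i].sum() == pred_counts[c]

    def test_length_mismatch_never_truncates(self):
        with pytest.raises(ValidationError):
            confusion_matrix(timeline_of(["D"] * 3), timeline_of(["D"] * 4))


class TestClassificationReport:
    def test_support_weighted_precision_from_per_class_scores(self):
        # per-class precisions and supports of a 4-class coding evaluation:
        # the weighted score is the support-weighted mean, 0.85 at 2 decimals
        w = support_weighted((0.79, 0.92, 0.64, 0.24), (1189, 2425, 228, 79))
        assert round_half_away(w, 2) == 0.85

    def test_perfect_matrix_scores_one(self):
        cm = ConfusionMatrix(np.diag([10, 20, 5, 5]))
        rep = classification_report(cm)
        assert rep.accuracy == 1.0
        for c in CLASSES:
            assert rep.precision[c] == rep.recall[c] == rep.f1[c] == 1.0
        assert rep.weighted_f1 == 1.0

    def test_two_class_toy_matrix_hand_computed(self):
        # [[8,2],[3,7]] in the first two classes of the 4-class grid
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 0], counts[0, 1], counts[1, 0], counts[1, 1] = 8, 2, 3, 7
        rep = classification_report(ConfusionMatrix(counts))
        first, second = CLASSES[0], CLASSES[1]
        assert rep.recall[first] == pytest.approx(0.8)
        assert rep.precision[first] == pytest.approx(8 / 11)
        assert rep.recall[second] == pytest.approx(0.7)
        assert rep.precision[second] == pytest.approx(7 / 9)
        assert rep.f1[first] == pytest.approx(2 * 0.8 * (8 / 11) / (0.8 + 8 / 11))
        assert rep.accuracy == pytest.approx(0.75)
        assert rep.support[first] == 10

    def test_zero_denominator_conventions(self):
        # one class never predicted and absent from truth: all its metrics 0
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 0] = 5
        counts[1, 0] = 5  # D always predicted as SG+D
        rep = classification_report(ConfusionMatrix(counts))
        assert rep.recall["D"] == 0.0
        assert rep.precision["D"] == 0.0  # never predicted
        assert rep.f1["D"] == 0.0
        assert rep.precision["SG"] == 0.0

    def test_weighted_recall_is_accuracy(self, rng):
        # identity: weighted recall == trace/total, to 12 decimals
        for _ in range(20):
            counts = rng.integers(0, 30, size=(4, 4))
            if counts.sum() == 0 or (counts.sum(axis=1) == 0).any():
                continue
            rep = classification_report(ConfusionMatrix(counts))
            assert rep.weighted_recall == pytest.approx(rep.accuracy, abs=1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            classification_report(ConfusionMatrix(np.zeros((4, 4), dtype=int)))


class TestAccuracyTtest:
    def test_identical_lists_give_t0_p1(self):
        res = accuracy_ttest([0.8, 0.8, 0.8], [0.8, 0.8, 0.8])
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_hand_computed_pooled_t(self):
        # a=(0.8, 0.9), b=(0.6, 0.7): pooled sd^2 = 0.005,
        # t = 0.2 / sqrt(0.005 * (1/2 + 1/2)) = 2.8284..., df = 2
        res = accuracy_ttest([0.8, 0.9], [0.6, 0.7])
        assert res.statistic == pytest.approx(0.2 / math.sqrt(0.005), rel=1e-12)
        assert res.df == 2

    def test_ten_videos_per_condition_gives_df_18(self, rng):
        a = rng.uniform(0.7, 0.9, 10)
        b = rng.uniform(0.7, 0.9, 10)
        assert accuracy_ttest(a, b).df == 18

    def test_swap_negates_t_preserves_p(self, rng):
        a = rng.uniform(0.5, 1.0, 6)
        b = rng.uniform(0.5, 1.0, 6)
        r1 = accuracy_ttest(a, b)
        r2 = accuracy_ttest(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.pvalue == pytest.approx(r2.pvalue)

    def test_zero_variance_unequal_means_flagged_infinite(self):
        res = accuracy_ttest([0.9, 0.9], [0.5, 0.5])
        assert math.isinf(res.statistic) and res.statistic > 0
        assert res.pvalue == 0.0

    def test_welch_flag(self):
        res = accuracy_ttest([0.8, 0.9, 0.7], [0.6, 0.61, 0.59], welch=True)
        assert res.df < 4  # Welch df shrinks under unequal variances


class TestTransitions:
    def test_constant_timeline_has_no_transitions(self):
        assert find_transitions(timeline_of(["D"] * 10)) == []

    def test_single_transition_record(self):
        recs = find_transitions(timeline_of(["D", "D", "SG+D"]))
        assert len(recs) == 1
        r = recs[0]
        assert (r.boundary_index, r.from_class, r.to_class) == (2, "D", "SG+D")
        assert (r.pre_run, r.post_run) == (2, 1)

    def test_pair_counts_match_brute_force_scan(self, rng):
        t = random_timeline(rng, 400)
        table = transition_table(find_transitions(t))
        oracle = {}
        for a, b in zip(t.labels, t.labels[1:]):
            if a != b:
                oracle[(a, b)] = oracle.get((a, b), 0) + 1
        assert table == oracle

    @pytest.mark.parametrize(
        "pre, post, kept",
        [(3, 3, True), (2, 3, False), (3, 2, False), (4, 10, True)],
    )
    def test_flanking_run_filter_inclusive_at_three_windows(self, pre, post, kept):
        labels = ["Other"] * pre + ["D"] * post
        t = timeline_of(labels)
        recs = find_transitions(t)
        kept_recs = qualifying_transitions(recs, t, min_run_seconds=1.5)
        assert (len(kept_recs) == 1) is kept

    def test_qualifying_subset_matches_brute_force(self, rng):
        t = random_timeline(rng, 300)
        recs = find_transitions(t)
        kept = qualifying_transitions(recs, t, 1.5)
        oracle = [r for r in recs if r.pre_run >= 3 and r.post_run >= 3]
        assert kept == oracle


def brute_force_attribution(truth, pred, radius=2):
    """Oracle: scan all (error window, qualifying boundary) pairs."""
    recs = [
        r
        for r in find_transitions(truth)
        if r.pre_run >= 3 and r.post_run >= 3
    ]
    total, attributed = 0, 0
    for w in range(len(truth.labels)):
        if truth.labels[w] == pred.labels[w]:
            continue
        total += 1
        for r in recs:
            early = r.boundary_index - radius <= w < r.boundary_index and pred.labels[w] == r.to_class
            late = r.boundary_index <= w <= r.boundary_index + radius - 1 and pred.labels[w] == r.from_class
            if early or late:
                attributed += 1
                break
    return total, attributed


class TestTransitionErrors:
    def test_perfect_prediction(self, rng):
        t = random_timeline(rng, 50)
        rep = transition_error_analysis(t, t)
        assert rep.total_errors == 0
        assert rep.transition_errors == 0
        assert rep.percentage == 0.0

    def test_one_window_delay_is_attributable(self):
        truth = timeline_of(["D"] * 5 + ["SG"] * 5)
        pred = timeline_of(["D"] * 6 + ["SG"] * 4)  # transition marked 1 window late
        rep = transition_error_analysis(truth, pred)
        assert rep.total_errors == 1
        assert rep.transition_errors == 1

    def test_far_errors_are_not_attributable(self):
        truth = timeline_of(["D"] * 10 + ["SG"] * 10)
        pred = list(truth.labels)
        pred[2] = "SG"  # 8 windows before the boundary
        rep = transition_error_analysis(truth, timeline_of(pred))
        assert rep.total_errors == 1
        assert rep.transition_errors == 0

    def test_wrong_class_near_boundary_is_not_attributable(self):
        truth = timeline_of(["D"] * 5 + ["SG"] * 5)
        pred = list(truth.labels)
        pred[5] = "Other"  # at the boundary but matching neither side
        rep = transition_error_analysis(truth, timeline_of(pred))
        assert rep.transition_errors == 0

    def test_matches_brute_force_attribution(self, rng):
        for _ in range(10):
            truth = random_timeline(rng, 200)
            pred = random_timeline(rng, 200)
            rep = transition_error_analysis(truth, pred)
            total, attributed = brute_force_attribution(truth, pred)
            assert rep.total_errors == total
            assert rep.transition_errors == attributed

    def test_attribution_bound(self, rng):
        # each qualifying boundary absorbs at most 2 early + 2 late windows
        for _ in range(10):
            truth = random_timeline(rng, 200)
            pred = random_timeline(rng, 200, persistence=0.6)
            rep = transition_error_analysis(truth, pred)
            n_qual = len(qualifying_transitions(find_transitions(truth), truth, 1.5))
            assert rep.transition_errors <= min(rep.total_errors, 4 * n_qual)

    def test_percentage_formatting(self):
        rep = TransitionErrorReport(total_errors=272, transition_errors=45)
        assert rep.percentage == 16.5
        rep2 = TransitionErrorReport(total_errors=329, transition_errors=73)
        assert rep2.percentage == 22.2


def test_round_half_away():
    assert round_half_away(16.25, 1) == 16.3
    assert round_half_away(-16.25, 1) == -16.3
    assert round_half_away(0.845, 2) == 0.85
    assert round_half_away(2.5) == 3.0
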