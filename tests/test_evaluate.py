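"""Confusion counting, metric formulas, region-stratified scoring, screening."""

import numpy as np
import pytest

from misscan import (
    HARD_MISSING,
    MODELED,
    SOFT_MISSING,
    ConfusionCounts,
    ScoreTracks,
    evaluate_predictions,
    precision_recall_f1,
    region_stratified_confusion,
    residue_confusion,
    screen_sequences,
)
from misscan.core import LABEL_NAMES, SHORT_REGION_MAX


def brute_confusion(pred, truth, code):
    tp = tn = fp = fn = 0
    for p, t in zip(pred, truth):
        if p == code and t == code:
            tp += 1
        elif p != code and t != code:
            tn += 1
        elif p == code:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn


def brute_membership(vec, length_class):
    """Per-position short/long region membership by direct run scanning."""
    member = [False] * len(vec)
    i = 0
    while i < len(vec):
        if vec[i] == HARD_MISSING:
            j = i
            while j < len(vec) and vec[j] == HARD_MISSING:
                j += 1
            is_short = (j - i) <= SHORT_REGION_MAX
            if (length_class == "short") == is_short:
                for k in range(i, j):
                    member[k] = True
            i = j
        else:
            i += 1
    return member


class TestResidueConfusion:
    def test_perfect_prediction_has_no_errors(self):
        v = np.array([MODELED, HARD_MISSING, SOFT_MISSING], dtype=np.int8)
        counts = residue_confusion(v, v, "modeled")
        assert counts.fp == 0 and counts.fn == 0

    def test_all_modeled_prediction_against_mixed_truth(self):
        pred = np.array([MODELED, MODELED], dtype=np.int8)
        truth = np.array([MODELED, HARD_MISSING], dtype=np.int8)
        counts = residue_confusion(pred, truth, "modeled")
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (1, 1, 0, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            residue_confusion(np.zeros(2, np.int8), np.zeros(3, np.int8), "modeled")

    def test_agrees_with_brute_force_on_random_pairs(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 60))
            pred = rng.integers(0, 3, n).astype(np.int8)
            truth = rng.integers(0, 3, n).astype(np.int8)
            code = int(rng.integers(0, 3))
            counts = residue_confusion(pred, truth, LABEL_NAMES[code])
            assert (counts.tp, counts.tn, counts.fp, counts.fn) == brute_confusion(
                pred, truth, code
            )
            assert counts.total == n


class TestMetricFormulas:
    def test_balanced_half_case(self):
        row = precision_recall_f1(ConfusionCounts("modeled", tp=1, fp=1, fn=1))
        assert (row.precision, row.recall, row.f1) == (0.5, 0.5, 0.5)

    def test_zero_denominator_reported_missing(self):
        row = precision_recall_f1(ConfusionCounts("modeled", tp=0, fp=0, fn=5))
        assert row.precision is None
        assert row.recall == 0.0
        assert row.f1 is None

    def test_direct_arithmetic_example(self):
        row = precision_recall_f1(ConfusionCounts("modeled", tp=3, fp=1, fn=2))
        assert row.precision == pytest.approx(0.75)
        assert row.recall == pytest.approx(0.6)
        assert row.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_f1_between_precision_and_recall(self, rng):
        for _ in range(300):
            counts = ConfusionCounts(
                "modeled",
                tp=int(rng.integers(1, 50)),
                fp=int(rng.integers(0, 50)),
                fn=int(rng.integers(0, 50)),
            )
            row = precision_recall_f1(counts)
            assert min(row.precision, row.recall) - 1e-12 <= row.f1
            assert row.f1 <= max(row.precision, row.recall) + 1e-12


class TestRegionStratified:
    def test_exact_short_run(self):
        vec = np.zeros(20, dtype=np.int8)
        vec[5:13] = HARD_MISSING
        counts = region_stratified_confusion(vec, vec, "short")
        assert (counts.tp, counts.fp, counts.fn) == (8, 0, 0)
        assert counts.tn == 12

    def test_long_truth_split_by_predicted_modeled_residue(self):
        """A 31-residue truth run split into 15+15 predicted runs: every
        predicted position is short under the prediction's own segmentation,
        so the truth-long positions become long-target false negatives."""
        n = 40
        truth = np.zeros(n, dtype=np.int8)
        truth[2:33] = HARD_MISSING  # 31 residues -> long
        pred = truth.copy()
        pred[17] = MODELED  # splits into runs of 15 and 15 -> both short
        long_counts = region_stratified_confusion(pred, truth, "long")
        assert long_counts.tp == 0
        assert long_counts.fn == 31
        short_counts = region_stratified_confusion(pred, truth, "short")
        assert short_counts.fp == 30  # all predicted-short positions are truth-long
        assert short_counts.tp == 0

    def test_no_hard_missing_anywhere(self):
        vec = np.zeros(25, dtype=np.int8)
        counts = region_stratified_confusion(vec, vec, "short")
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (0, 0, 0, 25)

    def test_agrees_with_brute_force_membership(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 200))
            pred = rng.choice([0, 1], size=n, p=[0.6, 0.4]).astype(np.int8)
            truth = rng.choice([0, 1], size=n, p=[0.6, 0.4]).astype(np.int8)
            lclass = "short" if rng.random() < 0.5 else "long"
            counts = region_stratified_confusion(pred, truth, lclass)
            pm = brute_membership(pred, lclass)
            tm = brute_membership(truth, lclass)
            tp = sum(p and t for p, t in zip(pm, tm))
            fp = sum(p and not t for p, t in zip(pm, tm))
            fn = sum(t and not p for p, t in zip(pm, tm))
            tn = n - tp - fp - fn
            assert (counts.tp, counts.fp, counts.fn, counts.tn) == (tp, fp, fn, tn)


class TestEvaluatePredictions:
    def test_report_covers_classes_and_length_classes(self, rng):
        preds = [rng.integers(0, 3, 50).astype(np.int8) for _ in range(5)]
        truths = [rng.integers(0, 3, 50).astype(np.int8) for _ in range(5)]
        report = evaluate_predictions(preds, truths)
        assert list(report["target"]) == [
            "modeled", "hard_missing", "soft_missing", "short", "long",
        ]
        class_rows = report[report["target"].isin(LABEL_NAMES)]
        assert (class_rows[["tp", "tn", "fp", "fn"]].sum(axis=1) == 250).all()


def _screen_entry(seq_id, n, n_high, n_modeled):
    plddt = np.concatenate([np.full(n_high, 90.0), np.full(n - n_high, 50.0)])
    iupred = np.full(n, 0.3)
    pred = np.concatenate(
        [np.full(n_modeled, MODELED), np.full(n - n_modeled, HARD_MISSING)]
    ).astype(np.int8)
    return (seq_id, ScoreTracks(plddt=plddt, iupred=iupred), pred)


class TestScreen:
    def test_boundary_combinations(self):
        entries = [
            _screen_entry("both_high_long", 250, 213, 205),      # selected
            _screen_entry("modeled_ratio_low", 250, 213, 197),   # 0.788 < 0.8
            _screen_entry("plddt_ratio_low", 250, 197, 213),     # 0.788 < 0.8
            _screen_entry("length_boundary", 200, 180, 180),     # 200 is not > 200
            _screen_entry("exact_ratios_201", 201, 161, 161),    # 161/201 > 0.8, selected
            _screen_entry("both_low", 500, 250, 250),            # ratios 0.5
        ]
        results = screen_sequences(entries)
        verdicts = {r.sequence_id: r.selected for r in results}
        assert verdicts == {
            "both_high_long": True,
            "modeled_ratio_low": False,
            "plddt_ratio_low": False,
            "length_boundary": False,
            "exact_ratios_201": True,
            "both_low": False,
        }

    def test_exact_threshold_ratio_selected(self):
        entries = [_screen_entry("exact", 250, 200, 200)]  # both ratios exactly 0.8
        (result,) = screen_sequences(entries)
        assert result.plddt_high_ratio == 0.8
        assert result.selected

    def test_raising_threshold_shrinks_selection(self, rng):
        entries = [
            _screen_entry(f"s{i}", 300, int(rng.integers(150, 300)), int(rng.integers(150, 300)))
            for i in range(30)
        ]
        selected_sets = []
        for threshold in (0.5, 0.7, 0.9):
            chosen = {r.sequence_id for r in screen_sequences(entries, ratio_threshold=threshold)
                      if r.selected}
            selected_sets.append(chosen)
        assert selected_sets[2] <= selected_sets[1] <= selected_sets[0]

    def test_misaligned_entry_rejected(self):
        tracks = ScoreTracks(plddt=np.full(5, 90.0), iupred=np.full(5, 0.2))
        with pytest.raises(ValueError, match="aligned"):
            screen_sequences([("x", tracks, np.zeros(4, np.int8))])
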