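"""Metrics against independent oracles; box matching; daily count series."""

import itertools

import numpy as np
import pytest

import flytrap as ft
from flytrap.evaluate import ConfusionCounts, DailyCount, series_to_frame


def _brute_confusion(labels, preds, positive):
    tp = tn = fp = fn = 0
    for y, p in zip(labels, preds):
        if y == positive and p == positive:
            tp += 1
        elif y == positive:
            fn += 1
        elif p == positive:
            fp += 1
        else:
            tn += 1
    return tp, tn, fp, fn


def _mann_whitney_auc(labels, scores, positive):
    """Pairwise concordance: P(score_pos > score_neg), ties half."""
    pos = [s for y, s in zip(labels, scores) if y == positive]
    neg = [s for y, s in zip(labels, scores) if y != positive]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_hand_tally(self):
        c = ft.confusion(["+", "+", "-", "-"], ["+", "-", "-", "+"],
                         positive="+")
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_perfect_predictions(self):
        y = ["olive_fly", "others", "others"]
        c = ft.confusion(y, y)
        assert c.fp == 0 and c.fn == 0 and c.total == 3

    def test_matches_brute_force_on_random_pairs(self, rng):
        y = rng.choice(["olive_fly", "others"], size=1000)
        p = rng.choice(["olive_fly", "others"], size=1000)
        c = ft.confusion(y, p)
        assert (c.tp, c.tn, c.fp, c.fn) == tuple(
            np.array(_brute_confusion(y, p, "olive_fly"))[[0, 1, 2, 3]])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            ft.confusion(["a"], ["a", "b"])


class TestScalarMetrics:
    def test_printed_formula_arithmetic(self):
        r = ft.scalar_metrics(ConfusionCounts(tp=3, tn=5, fp=1, fn=1))
        assert r.accuracy == 0.8
        assert r.precision == 0.75
        assert r.recall == 0.75
        assert r.f1 == 0.75

    def test_no_false_positives_gives_unit_precision(self):
        r = ft.scalar_metrics(ConfusionCounts(tp=4, tn=2, fp=0, fn=3))
        assert r.precision == 1.0

    def test_zero_denominators_return_zero_with_warning(self):
        with pytest.warns(UserWarning, match="precision"):
            r = ft.scalar_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=2))
        assert r.precision == 0.0 and r.f1 == 0.0

    def test_empty_confusion_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ft.scalar_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_matches_independent_formulas_on_random_tables(self, rng):
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(1, 50, size=4)
            r = ft.scalar_metrics(ConfusionCounts(int(tp), int(tn),
                                                  int(fp), int(fn)))
            n = tp + tn + fp + fn
            prec = tp / (tp + fp)
            rec = tp / (tp + fn)
            assert r.accuracy == (tp + tn) / n
            assert r.precision == prec
            assert r.recall == rec
            assert abs(r.f1 - 2 * prec * rec / (prec + rec)) < 1e-12


class TestRocAuc:
    def test_perfectly_ordered_scores(self):
        y = ["olive_fly"] * 5 + ["others"] * 5
        s = [0.9, 0.8, 0.8, 0.7, 0.6, 0.4, 0.3, 0.2, 0.1, 0.0]
        roc, auc = ft.roc_auc(y, s)
        assert auc == 1.0
        assert roc[0] == (0.0, 0.0) and roc[-1] == (1.0, 1.0)

    def test_curve_monotone(self, rng):
        y = rng.choice(["olive_fly", "others"], size=200)
        s = rng.normal(size=200)
        roc, auc = ft.roc_auc(y, s)
        fpr = [p[0] for p in roc]
        tpr = [p[1] for p in roc]
        assert fpr == sorted(fpr) and tpr == sorted(tpr)
        assert 0.0 <= auc <= 1.0

    def test_label_independent_scores_near_half(self):
        rng = np.random.default_rng(0)
        y = rng.choice(["olive_fly", "others"], size=2000)
        s = rng.normal(size=2000)
        _, auc = ft.roc_auc(y, s)
        assert 0.45 <= auc <= 0.55

    def test_equals_mann_whitney_brute_force(self, rng):
        for _ in range(10):
            y = rng.choice(["olive_fly", "others"], size=50)
            if len(set(y)) < 2:
                continue
            s = rng.normal(size=50).round(1)  # ties on purpose
            _, auc = ft.roc_auc(y, s)
            assert abs(auc - _mann_whitney_auc(y, s, "olive_fly")) < 1e-9

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            ft.roc_auc(["olive_fly"] * 3, [0.1, 0.2, 0.3])


def _optimal_tp(pred, gt, thr):
    """Brute force: best one-to-one matching over all assignments."""
    best = 0
    idx = range(len(gt))
    for k in range(min(len(pred), len(gt)), 0, -1):
        for pred_sub in itertools.permutations(range(len(pred)), k):
            for gt_sub in itertools.combinations(idx, k):
                ok = sum(pred[i].iou(gt[j]) >= thr
                         for i, j in zip(pred_sub, gt_sub))
                best = max(best, ok)
    return best


class TestMatchDetections:
    def test_identical_lists_all_tp(self):
        boxes = [ft.BoundingBox(0, 0, 10, 10), ft.BoundingBox(30, 30, 5, 5)]
        assert ft.match_detections(boxes, list(boxes)) == (2, 0, 0)

    def test_disjoint_lists(self):
        pred = [ft.BoundingBox(0, 0, 5, 5)]
        gt = [ft.BoundingBox(50, 50, 5, 5), ft.BoundingBox(70, 70, 5, 5)]
        assert ft.match_detections(pred, gt) == (0, 1, 2)

    def test_one_to_one_no_double_counting(self):
        gt = [ft.BoundingBox(0, 0, 10, 10)]
        pred = [ft.BoundingBox(0, 0, 10, 10), ft.BoundingBox(1, 1, 10, 10)]
        tp, fp, fn = ft.match_detections(pred, gt)
        assert (tp, fp, fn) == (1, 1, 0)

    def test_greedy_optimal_on_small_instances(self, rng):
        """Greedy matches the exhaustive optimum on random <= 5-box sets."""
        thr = 0.3
        for _ in range(40):
            pred = [ft.BoundingBox(int(x), int(y), int(w), int(h))
                    for x, y, w, h in zip(rng.integers(0, 40, 5),
                                          rng.integers(0, 40, 5),
                                          rng.integers(5, 20, 5),
                                          rng.integers(5, 20, 5))]
            gt = [ft.BoundingBox(int(x), int(y), int(w), int(h))
                  for x, y, w, h in zip(rng.integers(0, 40, 4),
                                        rng.integers(0, 40, 4),
                                        rng.integers(5, 20, 4),
                                        rng.integers(5, 20, 4))]
            tp, _, _ = ft.match_detections(pred, gt, thr)
            optimal = _optimal_tp(pred, gt, thr)
            assert tp <= optimal
            # non-conflicting instances: each pred overlaps <= 1 gt box
            conflicts = any(
                sum(p.iou(g) >= thr for g in gt) > 1 for p in pred)
            if not conflicts:
                assert tp == optimal


class TestDailyCount:
    def test_tally_invariant_enforced(self):
        from datetime import datetime
        with pytest.raises(ValueError, match="ground-truth count"):
            DailyCount(date=datetime(2023, 10, 8), tp=2, fp=0, fn=1,
                       true_count=2)


class TestCountSeries:
    @pytest.fixture(scope="class")
    def series(self, bundle):
        spec = ft.SceneSpec(width=800, height=600, n_olive_flies=2,
                            n_other_flies=2, n_distractors=2, noise_sd=0.0,
                            seed=21, distractor_kinds=("hole", "glyph"))
        seq = ft.generate_sequence(spec, days=4, arrival_rate=0.7)
        return ft.count_series(seq, bundle), seq

    def test_empty_trap_series_all_zero(self, bundle):
        spec = ft.SceneSpec(width=640, height=480, n_olive_flies=0,
                            n_other_flies=0, n_distractors=0, seed=1)
        seq = ft.generate_sequence(spec, days=3)
        series = ft.count_series(seq, bundle)
        for counts in series.values():
            assert all((c.tp, c.fp, c.fn, c.true_count) == (0, 0, 0, 0)
                       for c in counts)

    def test_tp_plus_fn_equals_true_count_everywhere(self, series):
        counts, seq = series
        truth = [sum(e.label == "olive_fly" for e in els)
                 for _, els in seq.days]
        for model_counts in counts.values():
            assert [c.true_count for c in model_counts] == truth
            assert all(c.tp + c.fn == c.true_count for c in model_counts)

    def test_ensemble_fp_bounded_by_both_models(self, series):
        counts, _ = series
        for day in range(len(counts["rf"])):
            assert counts["ensemble"][day].fp <= min(counts["rf"][day].fp,
                                                     counts["svm"][day].fp)

    def test_tidy_frame_columns(self, series):
        frame = series_to_frame(series[0])
        assert set(frame.columns) == {"date", "model", "tp", "fp", "fn",
                                      "true_count"}
        assert len(frame) == 3 * 4
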