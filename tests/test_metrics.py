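"""Detection metrics: matching rules, AP vs brute-force envelope, mAP."""

import numpy as np
import pytest

from kiwidet.metrics import (Detection, PRCurve, average_precision,
                             curve_from_matches, match_detections, mean_ap)


def det(x1, y1, x2, y2, conf, cls=0, img=0):
    return Detection(box=np.array([x1, y1, x2, y2], np.float32),
                     confidence=conf, class_id=cls, image_id=img)


def brute_force_ap(pairs, n_gt):
    """Independent AP oracle: enumerate every ranked prefix, build the
    exact P-R points, take the precision envelope at each of the 101
    recall grid points by exhaustive scan."""
    tps = np.cumsum([tp for _, tp in pairs])
    fps = np.cumsum([not tp for _, tp in pairs])
    recalls = tps / n_gt
    precisions = tps / (tps + fps)
    total = 0.0
    for r in np.linspace(0, 1, 101):
        best = 0.0
        for rec, prec in zip(recalls, precisions):
            if rec >= r - 1e-12:
                best = max(best, prec)
        total += best
    return total / 101


class TestMatching:
    def test_exact_detections_all_tp(self):
        gts = {0: [(np.array([0, 0, 10, 10.]), 0), (np.array([20, 20, 30, 30.]), 0)]}
        dets = [det(0, 0, 10, 10, 1.0), det(20, 20, 30, 30, 1.0)]
        labeled, n_gt = match_detections(dets, gts, 0.5)
        assert [tp for _, tp in labeled] == [True, True]
        assert n_gt == 2

    def test_two_detections_one_gt(self):
        """One-to-one rule: the higher-confidence duplicate wins."""
        gts = {0: [(np.array([0, 0, 10, 10.]), 0)]}
        dets = [det(0, 0, 10, 10, 0.9), det(1, 1, 10, 10, 0.8)]
        labeled, _ = match_detections(dets, gts, 0.5)
        assert [tp for _, tp in labeled] == [True, False]

    def test_precision_recall_worked_example(self):
        """3 gts, 2 dets at IoU 0.6 >= 0.5: TP=2 FP=0 FN=1 -> P=1, R=2/3."""
        g = [(np.array([0, 0, 10, 10.]), 0), (np.array([20, 0, 30, 10.]), 0),
             (np.array([40, 0, 50, 10.]), 0)]
        # shift by 2.5 px -> IoU = 7.5/12.5 = 0.6
        dets = [det(2.5, 0, 12.5, 10, 0.9), det(22.5, 0, 32.5, 10, 0.8)]
        labeled, n_gt = match_detections(dets, {0: g}, 0.5)
        tp = sum(t for _, t in labeled)
        fp = len(labeled) - tp
        assert (tp, fp, n_gt - tp) == (2, 0, 1)
        assert tp / (tp + fp) == 1.0
        assert tp / n_gt == pytest.approx(2 / 3)

    def test_class_mismatch_is_fp(self):
        gts = {0: [(np.array([0, 0, 10, 10.]), 1)]}
        labeled, _ = match_detections([det(0, 0, 10, 10, 0.9, cls=0)], gts, 0.5)
        assert labeled[0][1] is False

    def test_order_invariance_with_distinct_confidences(self, rng):
        g = {0: [(np.array(sorted(rng.uniform(0, 50, 2)) + [60, 60.]), 0)
                 for _ in range(4)]}
        dets = [det(*sorted(rng.uniform(0, 50, 2)), 60, 60, c)
                for c in (0.9, 0.7, 0.5, 0.3)]
        l1, _ = match_detections(dets, g, 0.5)
        l2, _ = match_detections(dets[::-1], g, 0.5)
        assert {(d.confidence, t) for d, t in l1} == {(d.confidence, t) for d, t in l2}


class TestAveragePrecision:
    def test_perfect_ranking_is_one(self):
        c = PRCurve(tuple((1.0 - i * 0.1, True) for i in range(5)), 5)
        assert average_precision(c) == pytest.approx(1.0)

    def test_all_fp_is_zero(self):
        c = PRCurve(((0.9, False), (0.8, False)), 3)
        assert average_precision(c) == 0.0

    def test_zero_ground_truth_is_error(self):
        with pytest.raises(ValueError):
            average_precision(PRCurve(((0.9, True),), 0))

    def test_tp_fp_tp_three_point_curve(self):
        """Ranking (TP, FP, TP) with 2 gts, checked against the
        exhaustive envelope oracle."""
        pairs = ((0.9, True), (0.8, False), (0.7, True))
        c = PRCurve(pairs, 2)
        assert average_precision(c) == pytest.approx(brute_force_ap(pairs, 2))

    def test_matches_brute_force_on_random_instances(self, rng):
        """Fast AP equals the exhaustive envelope computation on every
        random instance with up to 10 detections."""
        for _ in range(200):
            n = int(rng.integers(1, 11))
            pairs = tuple((float(c), bool(rng.uniform() < 0.6))
                          for c in np.sort(rng.uniform(0, 1, n))[::-1])
            n_gt = max(sum(tp for _, tp in pairs), 1) + int(rng.integers(0, 3))
            c = PRCurve(pairs, n_gt)
            assert average_precision(c) == pytest.approx(
                brute_force_ap(pairs, n_gt), abs=1e-12)

    def test_adding_best_tp_never_decreases_ap(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 9))
            pairs = tuple((float(c), bool(rng.uniform() < 0.5))
                          for c in np.sort(rng.uniform(0.1, 0.9, n))[::-1])
            n_gt = sum(tp for _, tp in pairs) + 2
            base = average_precision(PRCurve(pairs, n_gt))
            better = average_precision(PRCurve(((1.0, True),) + pairs, n_gt))
            worse = average_precision(PRCurve(pairs + ((0.01, False),), n_gt))
            assert better >= base - 1e-12
            assert worse <= base + 1e-12


class TestMeanAP:
    def _simple(self):
        gts = {0: [(np.array([0, 0, 10, 10.]), 0)],
               1: [(np.array([5, 5, 20, 20.]), 0)]}
        dets = [det(0, 0, 10, 10, 0.9, img=0), det(5, 5, 20, 20, 0.85, img=1)]
        return dets, gts

    def test_perfect_detector_scores_one_everywhere(self):
        dets, gts = self._simple()
        r = mean_ap(dets, gts)
        assert r["map50"] == pytest.approx(1.0)
        assert r["map5095"] == pytest.approx(1.0)
        assert r["precision"] == 1.0 and r["recall"] == 1.0

    def test_single_class_map_equals_ap(self):
        dets, gts = self._simple()
        r = mean_ap(dets, gts)
        labeled, n_gt = match_detections(dets, gts, 0.5)
        ap = average_precision(curve_from_matches(labeled, n_gt))
        assert r["map50"] == pytest.approx(ap)

    def test_map5095_not_above_map50(self, rng):
        gts = {i: [(np.sort(rng.uniform(0, 40, 2)).tolist()
                    + [50 + v for v in np.sort(rng.uniform(0, 40, 2))], 0)]
               for i in range(6)}
        gts = {i: [(np.array(b, np.float32), c) for b, c in v]
               for i, v in gts.items()}
        dets = [det(*(v[0][0] + rng.normal(0, 2, 4)), conf=float(rng.uniform(0.3, 1)),
                    img=i) for i, v in gts.items()]
        dets = [d for d in dets if d.box[0] < d.box[2] and d.box[1] < d.box[3]]
        r = mean_ap(dets, gts)
        assert r["map5095"] <= r["map50"] + 1e-12

    def test_empty_ground_truth_is_error(self):
        with pytest.raises(ValueError):
            mean_ap([], {0: []})
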