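"""Detection/tracking/counting metrics against formula and brute-force oracles."""

import numpy as np
import pytest

from fruitrack.errors import ValidationError
from fruitrack.metrics import (
    CountEvaluation,
    DetectionTally,
    TrackingTally,
    average_precision,
    label_detections,
    linear_fit_r2,
    mae,
    match_and_tally,
    mean_ap,
    mota,
    precision_recall,
)
from fruitrack.mot import BoundingBox, Detection, GroundTruthEntry


class TestPrecisionRecall:
    def test_perfect(self):
        assert precision_recall(DetectionTally(10, 0, 0)) == (1.0, 1.0)

    def test_direct_arithmetic(self):
        assert precision_recall(DetectionTally(5, 5, 15)) == (0.5, 0.25)

    def test_zero_over_zero_sentinel(self):
        p, r = precision_recall(DetectionTally(0, 0, 3))
        assert p is None and r == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            DetectionTally(-1, 0, 0)


def ap_oracle(labels, n_gt):
    """Hand enumeration of PR points with the running-max envelope."""
    pts = []
    tp = fp = 0
    for lab in labels:
        tp += lab
        fp += not lab
        pts.append((tp / n_gt, tp / (tp + fp)))
    area = 0.0
    prev_r = 0.0
    for idx, (r, _) in enumerate(pts):
        env = max(p for rr, p in pts[idx:])
        area += (r - prev_r) * env
        prev_r = r
    return area


class TestAveragePrecision:
    def test_single_correct(self):
        assert average_precision([True], 1) == 1.0

    def test_all_false(self):
        assert average_precision([False, False], 3) == 0.0

    def test_tp_fp_tp_against_enumerated_points(self):
        labels = [True, False, True]
        assert average_precision(labels, 2) == pytest.approx(ap_oracle(labels, 2))

    def test_random_against_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 12))
            labels = list(rng.random(n) < 0.5)
            n_gt = max(int(sum(labels)), 1) + int(rng.integers(0, 3))
            assert average_precision(labels, n_gt) == pytest.approx(
                ap_oracle(labels, n_gt), abs=1e-12
            )

    def test_flipping_tp_to_fp_never_increases(self, rng):
        labels = [True, True, False, True, False]
        base = average_precision(labels, 3)
        for i in (0, 1, 3):
            worse = list(labels)
            worse[i] = False
            assert average_precision(worse, 3) <= base + 1e-12

    def test_label_detections_greedy_by_score(self):
        gt = [GroundTruthEntry(frame=1, track_id=1, bbox=BoundingBox(0, 0, 10, 10))]
        dets = [
            Detection(bbox=BoundingBox(0, 0, 10, 10), score=0.5, frame=1),
            Detection(bbox=BoundingBox(1, 1, 10, 10), score=0.9, frame=1),
        ]
        labels, n_gt = label_detections(dets, gt)
        # higher-score detection claims the gt first
        assert labels == [True, False]
        assert n_gt == 1


class TestMeanAp:
    def test_values(self):
        assert mean_ap([1.0]) == 1.0
        assert mean_ap([0.8, 0.6]) == pytest.approx(0.7)

    def test_random_equals_mean(self, rng):
        v = rng.random(7)
        assert mean_ap(v) == pytest.approx(float(np.mean(v)))


class TestMota:
    def test_perfect(self):
        t = TrackingTally()
        t.append(0, 0, 0, 10)
        assert mota(t) == 1.0

    def test_direct_arithmetic(self):
        t = TrackingTally()
        t.append(1, 1, 0, 10)
        assert mota(t) == pytest.approx(0.8)

    def test_multiframe_matches_scalar_loop(self, rng):
        t = TrackingTally()
        rows = []
        for _ in range(25):
            g = int(rng.integers(1, 12))
            m = int(rng.integers(0, g + 1))
            fp = int(rng.integers(0, 5))
            mme = int(rng.integers(0, 3))
            t.append(m, fp, mme, g)
            rows.append((m, fp, mme, g))
        expect = 1.0 - sum(m + fp + mme for m, fp, mme, _ in rows) / sum(r[3] for r in rows)
        assert mota(t) == pytest.approx(expect, abs=1e-12)

    def test_no_gt_rejected(self):
        with pytest.raises(ValidationError):
            mota(TrackingTally())

    def test_can_be_negative(self):
        t = TrackingTally()
        t.append(2, 9, 1, 2)
        assert mota(t) < 0.0

    def test_miss_exceeding_gt_rejected(self):
        t = TrackingTally()
        with pytest.raises(ValidationError):
            t.append(5, 0, 0, 3)


def naive_tally(gt, results, thresh=0.5):
    """Quadratic per-frame reference: greedy-free optimal matching via
    exhaustive permutation (small frames only), persistence included."""
    import itertools

    from fruitrack.tracker import iou

    gtf, rf = {}, {}
    for g in gt:
        gtf.setdefault(g.frame, []).append(g)
    for r in results:
        rf.setdefault(r.frame, []).append(r)
    frames = sorted(set(gtf) | set(rf))
    prev = {}
    last = {}
    M = FP = MME = G = 0
    for f in frames:
        gs, rs = gtf.get(f, []), rf.get(f, [])
        match = {}
        used = set()
        rbyid = {r.track_id: r for r in rs}
        for g in gs:
            rid = prev.get(g.track_id)
            if rid in rbyid and rid not in used and iou(g.bbox, rbyid[rid].bbox) >= thresh:
                match[g.track_id] = rid
                used.add(rid)
        fg = [g for g in gs if g.track_id not in match]
        fr = [r for r in rs if r.track_id not in used]
        best, bestn = None, -1
        if fg and fr:
            k = min(len(fg), len(fr))
            for gsub in itertools.permutations(range(len(fg)), k):
                for rsub in itertools.permutations(range(len(fr)), k):
                    pairs = [
                        (fg[a], fr[b])
                        for a, b in zip(gsub, rsub)
                        if iou(fg[a].bbox, fr[b].bbox) >= thresh
                    ]
                    score = (len(pairs), sum(iou(a.bbox, b.bbox) for a, b in pairs))
                    if best is None or score > best:
                        best = score
                        keep = pairs
            if best and best[0] > 0:
                for a, b in keep:
                    match[a.track_id] = b.track_id
        for gid, rid in match.items():
            if gid in last and last[gid] != rid:
                MME += 1
            last[gid] = rid
        M += len(gs) - len(match)
        FP += len(rs) - len(match)
        G += len(gs)
        prev = dict(match)
    return M, FP, MME, G


class TestMatchAndTally:
    def make_gt(self):
        gt = []
        for f in range(1, 11):
            gt.append(GroundTruthEntry(frame=f, track_id=1, bbox=BoundingBox(10 + 2 * f, 10, 12, 12)))
            gt.append(GroundTruthEntry(frame=f, track_id=2, bbox=BoundingBox(60, 40 + f, 12, 12)))
        return gt

    def test_identity_results_perfect(self):
        gt = self.make_gt()
        tally, ids = match_and_tally(gt, gt)
        assert ids == 0
        assert sum(tally.misses) == 0 and sum(tally.false_positives) == 0
        assert mota(tally) == 1.0

    def test_single_mid_video_flip_counts_one_switch(self):
        gt = self.make_gt()
        results = [
            GroundTruthEntry(
                frame=g.frame,
                track_id=(g.track_id if g.frame <= 5 or g.track_id != 1 else 7),
                bbox=g.bbox,
            )
            for g in gt
        ]
        _, ids = match_and_tally(gt, results)
        assert ids == 1

    def test_matches_naive_reference_on_random_perturbations(self, rng):
        gt = self.make_gt()
        results = []
        for g in gt:
            if rng.random() < 0.15:
                continue  # dropped -> miss
            tid = g.track_id if rng.random() > 0.1 else int(rng.integers(5, 8))
            b = g.bbox
            results.append(
                GroundTruthEntry(
                    frame=g.frame,
                    track_id=tid,
                    bbox=BoundingBox(b.x + rng.normal(0, 1), b.y, b.w, b.h),
                )
            )
        tally, ids = match_and_tally(gt, results)
        M, FP, MME, G = naive_tally(gt, results)
        assert (sum(tally.misses), sum(tally.false_positives), ids, sum(tally.gt_counts)) == (
            M,
            FP,
            MME,
            G,
        )


class TestMae:
    def test_exact(self):
        assert mae(CountEvaluation([10, 20], [10, 20])) == 0.0

    def test_direct_arithmetic(self):
        assert mae(CountEvaluation([11, 9], [10, 10])) == pytest.approx(0.1)

    def test_random_fixture_scalar_loop(self, rng):
        y = rng.integers(1, 100, 7).astype(float)
        gt = rng.integers(1, 100, 7).astype(float)
        expect = sum(abs(a - b) / b for a, b in zip(y, gt)) / 7
        assert mae(CountEvaluation(y, gt)) == pytest.approx(expect, abs=1e-12)

    def test_scale_invariance(self, rng):
        y = rng.integers(1, 50, 5).astype(float)
        gt = rng.integers(1, 50, 5).astype(float)
        assert mae(CountEvaluation(3 * y, 3 * gt)) == pytest.approx(
            mae(CountEvaluation(y, gt)), abs=1e-12
        )

    def test_zero_gt_rejected(self):
        with pytest.raises(ValidationError):
            CountEvaluation([1.0], [0.0])


class TestLinearFit:
    def test_perfect_line(self):
        pairs = [(x, 2 * x + 1) for x in (1.0, 2.0, 5.0, 9.0)]
        slope, intercept, r2 = linear_fit_r2(pairs)
        assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_constant_y_r2_zero(self):
        _, _, r2 = linear_fit_r2([(1.0, 4.0), (2.0, 4.0), (3.0, 4.0)])
        assert r2 == 0.0

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(0, 100, 12)
        y = 1.5 * x + rng.normal(0, 5, 12)
        slope, intercept, r2 = linear_fit_r2(list(zip(x, y)))
        # closed-form normal equations
        A = np.vstack([x, np.ones_like(x)]).T
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        resid = y - A @ beta
        r2_expect = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert slope == pytest.approx(beta[0], abs=1e-10)
        assert intercept == pytest.approx(beta[1], abs=1e-10)
        assert r2 == pytest.approx(r2_expect, abs=1e-10)

    def test_identical_x_rejected(self):
        with pytest.raises(ValidationError):
            linear_fit_r2([(1.0, 2.0), (1.0, 3.0)])
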