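"""Geometry, assignment, Kalman prediction, camera motion, and track lifecycle."""

import itertools

import numpy as np
import pytest

from fruitrack.errors import SequencingError, ValidationError
from fruitrack.kalman import KalmanFilter, bbox_to_measurement
from fruitrack.mot import BoundingBox, Detection
from fruitrack.synthetic import SceneConfig, simulate_orchard
from fruitrack.tracker import (
    CameraMotion,
    MRSortTracker,
    Track,
    TrackerConfig,
    associate,
    count_tracks,
    estimate_camera_motion,
    iou,
    predict,
)


class TestIou:
    def test_identical(self):
        b = BoundingBox(3, 4, 10, 12)
        assert iou(b, b) == 1.0

    def test_disjoint(self):
        assert iou(BoundingBox(0, 0, 5, 5), BoundingBox(10, 10, 5, 5)) == 0.0

    def test_unit_grid_enumeration(self):
        """Overlap of (0,0,2,2) and (1,1,2,2) counted pixel by pixel: 1/7."""
        a, b = BoundingBox(0, 0, 2, 2), BoundingBox(1, 1, 2, 2)
        cells_a = {(x, y) for x in range(0, 2) for y in range(0, 2)}
        cells_b = {(x, y) for x in range(1, 3) for y in range(1, 3)}
        expect = len(cells_a & cells_b) / len(cells_a | cells_b)
        assert iou(a, b) == pytest.approx(expect)
        assert expect == pytest.approx(1 / 7)

    def test_symmetry_random(self, rng):
        for _ in range(50):
            a = BoundingBox(*rng.uniform(0, 50, 2), *rng.uniform(1, 30, 2))
            b = BoundingBox(*rng.uniform(0, 50, 2), *rng.uniform(1, 30, 2))
            assert iou(a, b) == pytest.approx(iou(b, a))
            assert 0.0 <= iou(a, b) <= 1.0


class TestAssociate:
    def test_single_accept(self):
        m, ut, ud = associate(np.array([[0.2]]), 0.5)
        assert m == [(0, 0)] and ut == [] and ud == []

    def test_single_gate_reject(self):
        m, ut, ud = associate(np.array([[0.9]]), 0.5)
        assert m == [] and ut == [0] and ud == [0]

    def test_empty(self):
        m, ut, ud = associate(np.zeros((0, 3)), 0.5)
        assert m == [] and ut == [] and ud == [0, 1, 2]

    def test_matches_permutation_oracle(self, rng):
        """Total assigned cost equals the exhaustive minimum over permutations."""
        for _ in range(30):
            n = int(rng.integers(2, 7))
            cost = rng.random((n, n))
            matches, _, _ = associate(cost, gate=np.inf)
            total = sum(cost[i, j] for i, j in matches)
            best = min(
                sum(cost[i, p[i]] for i in range(n)) for p in itertools.permutations(range(n))
            )
            assert total == pytest.approx(best, abs=1e-9)

    def test_deterministic_tie_break_row_major(self):
        cost = np.zeros((2, 2))  # every assignment optimal
        m, _, _ = associate(cost, 1.0)
        assert sorted(m) == [(0, 0), (1, 1)]

    def test_one_to_one_property(self, rng):
        cost = rng.random((6, 4))
        m, ut, ud = associate(cost, 0.8)
        rows = [i for i, _ in m]
        cols = [j for _, j in m]
        assert len(set(rows)) == len(rows) and len(set(cols)) == len(cols)
        assert set(rows) | set(ut) == set(range(6))
        assert set(cols) | set(ud) == set(range(4))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            associate(np.array([[np.inf]]), 1.0)


def make_track(bbox, vx=0.0, vy=0.0):
    kf = KalmanFilter()
    st = kf.initiate(bbox_to_measurement(bbox))
    st.mean[4] = vx
    st.mean[5] = vy
    return Track(state=st)


class TestPredict:
    def test_stationary_identity(self):
        t = make_track(BoundingBox(10, 10, 8, 8))
        predict([t], CameraMotion.identity())
        assert t.predicted_bbox.center == pytest.approx((14.0, 14.0))
        assert t.predicted_bbox.w == pytest.approx(8.0)

    def test_velocity_advances_center(self):
        t = make_track(BoundingBox(10, 10, 8, 8), vx=3.0)
        predict([t], CameraMotion.identity())
        assert t.predicted_bbox.center == pytest.approx((17.0, 14.0))

    def test_affine_translation_moves_center(self):
        t = make_track(BoundingBox(10, 10, 8, 8))
        motion = CameraMotion(affine=np.array([[1.0, 0.0, 5.0], [0.0, 1.0, -2.0]]))
        predict([t], motion)
        assert t.predicted_bbox.center == pytest.approx((19.0, 12.0))


class TestCameraMotion:
    def test_identical_frames_identity(self):
        cfg = SceneConfig(n_apples=10, n_frames=1, texture_seed=5)
        frames, _ = simulate_orchard(cfg)
        assert estimate_camera_motion(frames[0], frames[0]).is_identity

    def test_known_pan_recovered(self):
        cfg = SceneConfig(n_apples=12, n_frames=2, camera_velocity=(12.0, 0.0), texture_seed=5)
        frames, _ = simulate_orchard(cfg)
        m = estimate_camera_motion(frames[0], frames[1])
        assert m.affine[0, 2] == pytest.approx(-12.0, abs=1.0)
        assert m.affine[1, 2] == pytest.approx(0.0, abs=1.0)

    def test_textureless_identity_fallback(self, caplog):
        black = np.zeros((60, 80, 3), np.uint8)
        with caplog.at_level("WARNING"):
            m = estimate_camera_motion(black, black)
        assert m.is_identity
        assert any("identity" in r.message for r in caplog.records)

    def test_size_mismatch(self):
        with pytest.raises(ValidationError):
            estimate_camera_motion(np.zeros((10, 10, 3)), np.zeros((12, 10, 3)))

    def test_sanity_bound_on_transform(self):
        m = CameraMotion(affine=np.array([[1.0, 0.0, 3.0], [0.0, 1.0, 0.0]]))
        assert not m.is_identity


class TestLifecycle:
    def test_empty_step_noop(self):
        trk = MRSortTracker(TrackerConfig())
        rep = trk.step([])
        assert rep["new_tracks"] == 0
        assert trk.count() == 0

    def test_confirmation_after_two_matches(self):
        trk = MRSortTracker(TrackerConfig())
        b = BoundingBox(50, 50, 20, 20)
        trk.step([Detection(bbox=b, score=0.9, frame=1)])
        assert trk.count() == 0  # still tentative
        trk.step([Detection(bbox=b, score=0.9, frame=2)])
        assert trk.count() == 1
        ids = {t.track_id for t in trk.all_tracks() if t.track_id}
        assert ids == {1}

    def test_results_backfill_tentative_history(self):
        trk = MRSortTracker(TrackerConfig())
        b = BoundingBox(50, 50, 20, 20)
        for f in (1, 2, 3):
            trk.step([Detection(bbox=b, score=0.9, frame=f)])
        frames_out = sorted(r.frame for r in trk.results())
        assert frames_out == [1, 2, 3]

    def test_low_score_never_seeds(self):
        trk = MRSortTracker(TrackerConfig())
        b = BoundingBox(50, 50, 20, 20)
        for f in (1, 2, 3):
            trk.step([Detection(bbox=b, score=0.6, frame=f)])
        assert trk.count() == 0

    def test_track_buffer_expiry(self):
        trk = MRSortTracker(TrackerConfig(track_buffer=3))
        b = BoundingBox(50, 50, 20, 20)
        trk.step([Detection(bbox=b, score=0.9, frame=1)])
        trk.step([Detection(bbox=b, score=0.9, frame=2)])
        for f in range(3, 8):
            trk.step([], frame_index=f)
        statuses = [t.status for t in trk.all_tracks()]
        assert statuses == ["removed"]

    def test_out_of_order_frame_rejected(self):
        trk = MRSortTracker(TrackerConfig())
        trk.step([], frame_index=1)
        with pytest.raises(SequencingError):
            trk.step([], frame_index=1)

    def test_detection_frame_mismatch_rejected(self):
        trk = MRSortTracker(TrackerConfig())
        with pytest.raises(SequencingError):
            trk.step([Detection(bbox=BoundingBox(0, 0, 5, 5), score=0.9, frame=4)], frame_index=1)

    def test_ids_sequential_no_gaps(self):
        trk = MRSortTracker(TrackerConfig())
        boxes = [BoundingBox(20 + 60 * i, 40, 18, 18) for i in range(4)]
        for f in (1, 2):
            trk.step([Detection(bbox=b, score=0.9, frame=f) for b in boxes])
        ids = sorted(t.track_id for t in trk.all_tracks() if t.track_id)
        assert ids == [1, 2, 3, 4]
        assert trk.count() == 4

    def test_one_to_one_assignment_per_frame(self):
        trk = MRSortTracker(TrackerConfig())
        boxes = [BoundingBox(20 + 40 * i, 40, 18, 18) for i in range(5)]
        for f in (1, 2, 3):
            trk.step([Detection(bbox=b, score=0.9, frame=f) for b in boxes])
        per_frame = {}
        for r in trk.results():
            per_frame.setdefault(r.frame, []).append(r.track_id)
        for ids in per_frame.values():
            assert len(ids) == len(set(ids))

    def test_count_tracks_empty_and_sequential(self):
        assert count_tracks([]) == 0


class TestConfig:
    def test_invalid_thresholds(self):
        with pytest.raises(ValidationError):
            TrackerConfig(track_low_thresh=0.6, track_high_thresh=0.5)
        with pytest.raises(ValidationError):
            TrackerConfig(new_track_thresh=0.3)

    def test_config_hash_stable(self):
        assert TrackerConfig().config_hash() == TrackerConfig().config_hash()
        assert TrackerConfig().config_hash() != TrackerConfig(match_thresh=0.4).config_hash()
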