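"""MR-SORT: multi-rematching tracking-by-detection for fruit counting.

The tracker follows the BoT-SORT recipe — constant-velocity Kalman
prediction, camera-motion compensation, and a two-stage association that
splits detections into high- and low-confidence groups and assigns them to
tracks by Hungarian matching on IoU cost — and adds an appearance
*rematch* after each IoU stage: leftover detections are compared to
leftover tracks by cosine similarity of VLAD signatures, and a candidate
appearance match must also pass a displacement-consistency validation
against an independently matched anchor region before it is accepted.
Re-identifying a fruit that re-emerges from occlusion under the same id is
what keeps the final count (the largest id issued) honest.

Track lifecycle: a new high-confidence detection seeds a *tentative*
track; a second consecutive match confirms it and assigns the next
sequential id; a track unseen for more than ``track_buffer`` frames is
removed.  Only confirmed tracks are counted or reported, and the rows a
track accumulated while still tentative are emitted retroactively on
confirmation so that a perfect detector yields a perfect track ledger.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from skimage.feature import ORB, match_descriptors
from skimage.measure import ransac
from skimage.transform import AffineTransform
from skimage.transform import resize as sk_resize

from .appearance import (
    Codebook,
    DescriptorSet,
    VladVector,
    appearance_similarity,
    extract_descriptors,
    fit_codebook,
    validate_match,
    vlad_encode,
)
from .errors import SequencingError, ValidationError
from .kalman import KalmanFilter, KalmanState, bbox_to_measurement
from .mot import BoundingBox, Detection, GroundTruthEntry

logger = logging.getLogger(__name__)

__all__ = [
    "TrackerConfig",
    "CameraMotion",
    "Track",
    "MRSortTracker",
    "iou",
    "iou_matrix",
    "estimate_camera_motion",
    "associate",
    "count_tracks",
]

_INF_COST = 1e6


@dataclass
class TrackerConfig:
    """Association thresholds (shipped defaults are the method's published values).

    track_high_thresh / track_low_thresh split detections into the
    confident group (stage A) and the low-confidence group (stage B);
    new_track_thresh is the minimum score to seed a new track; match_thresh
    gates the IoU cost (1 - IoU); track_buffer is how many frames a lost
    track stays eligible; appearance_thresh gates the VLAD cosine distance.
    """

    track_high_thresh: float = 0.5
    track_low_thresh: float = 0.1
    new_track_thresh: float = 0.7
    match_thresh: float = 0.5
    track_buffer: int = 30
    appearance_thresh: float = 0.5
    # implementation knobs beyond the published table
    with_rematch: bool = True
    with_gmc: bool = True
    codebook_k: int = 8
    descriptor: str = "sift"
    crop_pad: float = 0.1
    crop_min_side: int = 48  # crops below this are upscaled 3x so the scale pyramid fires
    appearance_refresh_interval: int = 5  # frames between stored-signature refreshes
    validation_tolerance: float = 10.0  # px at 1920-wide frames, scaled by width
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.track_low_thresh < self.track_high_thresh <= 1.0:
            raise ValidationError("need 0 <= track_low_thresh < track_high_thresh <= 1")
        if self.new_track_thresh < self.track_high_thresh:
            raise ValidationError("new_track_thresh must be >= track_high_thresh")
        if self.track_buffer < 1:
            raise ValidationError("track_buffer must be >= 1")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class CameraMotion:
    """2x3 affine mapping previous-frame pixel coordinates to current-frame ones."""

    affine: np.ndarray

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float).reshape(2, 3)
        if not np.all(np.isfinite(self.affine)):
            raise ValidationError("camera motion transform must be finite")

    @classmethod
    def identity(cls) -> "CameraMotion":
        return cls(affine=np.hstack([np.eye(2), np.zeros((2, 1))]))

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.affine, CameraMotion.identity().affine)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two half-open pixel boxes."""
    ix = max(0.0, min(a.right, b.right) - max(a.x, b.x))
    iy = max(0.0, min(a.bottom, b.bottom) - max(a.y, b.y))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def iou_matrix(boxes_a: Sequence[BoundingBox], boxes_b: Sequence[BoundingBox]) -> np.ndarray:
    out = np.zeros((len(boxes_a), len(boxes_b)))
    for i, a in enumerate(boxes_a):
        for j, b in enumerate(boxes_b):
            out[i, j] = iou(a, b)
    return out


def _to_gray_u8(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 3:
        frame = frame.mean(axis=2)
    return frame.astype(float) / (255.0 if frame.max() > 1.5 else 1.0)


def _frame_features(img: np.ndarray, n_keypoints: int = 200) -> Optional[tuple[np.ndarray, np.ndarray]]:
    """ORB keypoints + descriptors of a whole frame, or None if textureless."""
    orb = ORB(n_keypoints=n_keypoints, fast_threshold=0.05)
    try:
        orb.detect_and_extract(_to_gray_u8(np.asarray(img)))
    except RuntimeError:
        return None
    if len(orb.keypoints) < 6:
        return None
    return orb.keypoints, orb.descriptors


def _motion_from_features(
    feats_prev: Optional[tuple[np.ndarray, np.ndarray]],
    feats_curr: Optional[tuple[np.ndarray, np.ndarray]],
    seed: int = 0,
) -> CameraMotion:
    if feats_prev is None or feats_curr is None:
        logger.warning("camera motion: too few keypoints, identity fallback")
        return CameraMotion.identity()
    kps = (feats_prev[0], feats_curr[0])
    matches = match_descriptors(feats_prev[1], feats_curr[1], cross_check=True)
    if len(matches) < 6:
        logger.warning("camera motion: too few matches, identity fallback")
        return CameraMotion.identity()
    src = kps[0][matches[:, 0]][:, ::-1]  # (row, col) -> (x, y)
    dst = kps[1][matches[:, 1]][:, ::-1]
    try:
        model, inliers = ransac(
            (src, dst),
            AffineTransform,
            min_samples=3,
            residual_threshold=2.0,
            max_trials=100,
            rng=seed,
        )
    except Exception:
        logger.warning("camera motion: RANSAC failed, identity fallback")
        return CameraMotion.identity()
    if model is None or inliers is None or inliers.sum() < 6:
        logger.warning("camera motion: too few inliers, identity fallback")
        return CameraMotion.identity()
    A = model.params[:2, :]
    det = np.linalg.det(A[:, :2])
    if not np.isfinite(det) or not 0.5 <= det <= 2.0:
        logger.warning("camera motion: transform outside sanity bounds, identity fallback")
        return CameraMotion.identity()
    return CameraMotion(affine=A)


def estimate_camera_motion(
    prev_frame: np.ndarray,
    curr_frame: np.ndarray,
    n_keypoints: int = 200,
    seed: int = 0,
) -> CameraMotion:
    """Estimate global inter-frame motion from sparse keypoint matches.

    ORB keypoints are matched between the frames (cross-checked) and a
    robust affine transform is fitted with RANSAC.  On failure — too few
    matches, too few inliers, or a transform whose 2x2 determinant leaves
    the sanity band [0.5, 2] — the identity is returned.
    """
    prev_frame = np.asarray(prev_frame)
    curr_frame = np.asarray(curr_frame)
    if prev_frame.shape[:2] != curr_frame.shape[:2]:
        raise ValidationError(
            f"frame sizes differ: {prev_frame.shape[:2]} vs {curr_frame.shape[:2]}"
        )
    return _motion_from_features(
        _frame_features(prev_frame, n_keypoints),
        _frame_features(curr_frame, n_keypoints),
        seed=seed,
    )


def predict(tracks: Sequence[Track], motion: Optional[CameraMotion] = None) -> Sequence[Track]:
    """Constant-velocity time update for each track, then camera-motion warp.

    Mutates and returns the given tracks; the warp propagates covariance
    through the linear part of the affine transform.
    """
    kf = KalmanFilter()
    motion = motion or CameraMotion.identity()
    for t in tracks:
        t.state = kf.predict(t.state)
        if not motion.is_identity:
            t.state = kf.apply_affine(t.state, motion.affine)
    return tracks


def associate(
    cost: np.ndarray, gate: float
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Gated minimum-cost one-to-one assignment.

    Returns (matches, unmatched rows, unmatched columns).  Pairs whose cost
    exceeds ``gate`` are removed after the assignment.  Ties between
    equal-cost optima are broken deterministically toward the lowest row
    index, then the lowest column index.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.size == 0:
        return [], list(range(cost.shape[0])), list(range(cost.shape[1]))
    if not np.all(np.isfinite(cost)):
        raise ValidationError("association costs must be finite (use a large sentinel)")
    n, m = cost.shape
    idx = np.arange(n)[:, None] * m + np.arange(m)[None, :]
    rows, cols = linear_sum_assignment(cost + 1e-12 * idx)
    matches = [(int(r), int(c)) for r, c in zip(rows, cols) if cost[r, c] <= gate]
    matched_r = {r for r, _ in matches}
    matched_c = {c for _, c in matches}
    return (
        matches,
        [i for i in range(n) if i not in matched_r],
        [j for j in range(m) if j not in matched_c],
    )


@dataclass
class Track:
    """One tracked fruit: Kalman state, lifecycle, appearance memory."""

    state: KalmanState
    status: str = "tentative"  # tentative | active | lost | removed
    track_id: Optional[int] = None  # assigned at confirmation
    hits: int = 1
    frames_since_seen: int = 0
    appearance: Optional[VladVector] = None
    appearance_center: Optional[tuple[float, float]] = None
    appearance_frame: Optional[int] = None
    last_center: Optional[tuple[float, float]] = None
    history: list[tuple[int, BoundingBox, float]] = field(default_factory=list)

    @property
    def predicted_bbox(self) -> BoundingBox:
        return self.state.bbox


def count_tracks(tracks: Sequence[Track]) -> int:
    """Number of fruit counted: the largest confirmed id ever issued."""
    ids = [t.track_id for t in tracks if t.track_id is not None]
    return max(ids) if ids else 0


class MRSortTracker:
    """Online multi-object tracker with IoU stages plus appearance rematching.

    Feed detections frame by frame through :meth:`step`; read the ledger
    with :meth:`results` and the fruit count with :meth:`count`.
    """

    def __init__(self, config: Optional[TrackerConfig] = None) -> None:
        self.config = config or TrackerConfig()
        self.kf = KalmanFilter()
        self.tracks: list[Track] = []  # live (non-removed) tracks
        self.finished: list[Track] = []  # removed tracks kept for the ledger
        self.frame_idx = 0
        self.prev_frame: Optional[np.ndarray] = None
        self.codebook: Optional[Codebook] = None
        self._codebook_pool: list[np.ndarray] = []
        self._gmc_feats: Optional[tuple[np.ndarray, np.ndarray]] = None
        self.last_motion = CameraMotion.identity()

    # -- appearance helpers -------------------------------------------------

    def _crop(self, frame: np.ndarray, bbox: BoundingBox) -> Optional[np.ndarray]:
        h, w = frame.shape[:2]
        pad_x = bbox.w * self.config.crop_pad
        pad_y = bbox.h * self.config.crop_pad
        x0 = int(np.floor(bbox.x - pad_x))
        y0 = int(np.floor(bbox.y - pad_y))
        x1 = int(np.ceil(bbox.right + pad_x))
        y1 = int(np.ceil(bbox.bottom + pad_y))
        # grow to the extractor's minimum region inside the frame
        while x1 - x0 < 16 and (x0 > 0 or x1 < w):
            x0, x1 = max(0, x0 - 1), min(w, x1 + 1)
        while y1 - y0 < 16 and (y0 > 0 or y1 < h):
            y0, y1 = max(0, y0 - 1), min(h, y1 + 1)
        x0, y0 = max(0, x0), max(0, y0)
        x1, y1 = min(w, x1), min(h, y1)
        if x1 - x0 < 16 or y1 - y0 < 16:
            return None
        return frame[y0:y1, x0:x1]

    def _descriptors_for(self, frame: np.ndarray, bbox: BoundingBox) -> DescriptorSet:
        crop = self._crop(frame, bbox)
        if crop is None:
            return DescriptorSet.empty()
        # small fruit crops sit below the keypoint pyramid's working scale; a
        # FIXED 3x upscale restores detector yield.  The factor must not vary
        # with the jittering box size or descriptors of the same fruit would
        # be computed at different physical scales and stop matching.
        if min(crop.shape[:2]) < self.config.crop_min_side:
            crop = sk_resize(
                crop,
                (crop.shape[0] * 3, crop.shape[1] * 3),
                preserve_range=True,
                anti_aliasing=False,
            ).astype(np.uint8)
        return extract_descriptors(crop, self.config.descriptor)

    def _maybe_fit_codebook(self) -> None:
        if self.codebook is not None or not self._codebook_pool:
            return
        pooled = np.vstack(self._codebook_pool)
        need = max(4 * self.config.codebook_k, 40)
        if len(pooled) >= need:
            self.codebook = fit_codebook(pooled, self.config.codebook_k, seed=self.config.seed)
            self._codebook_pool = []

    def _encode(self, ds: DescriptorSet) -> Optional[VladVector]:
        if self.codebook is None:
            return None
        return vlad_encode(ds, self.codebook)

    # -- core step ----------------------------------------------------------

    def step(
        self,
        detections: Sequence[Detection],
        frame: Optional[np.ndarray] = None,
        frame_index: Optional[int] = None,
    ) -> dict:
        """Advance the tracker by one frame.

        ``frame`` (the RGB image) enables camera-motion compensation and
        appearance rematching; without it the tracker runs on geometry
        alone.  Returns a per-frame report of the assignments made.
        """
        expected = self.frame_idx + 1
        if frame_index is None:
            frame_index = expected
        if frame_index != expected:
            raise SequencingError(
                f"frames must be consecutive: expected {expected}, got {frame_index}"
            )
        for det in detections:
            if det.frame != frame_index:
                raise SequencingError(
                    f"detection carries frame {det.frame}, stepping frame {frame_index}"
                )
        self.frame_idx = frame_index
        cfg = self.config
        report: dict = {"frame": frame_index, "matches": [], "rematches": [], "new_tracks": 0}

        # (1) camera motion + Kalman prediction (frame features cached across steps)
        motion = CameraMotion.identity()
        if cfg.with_gmc and frame is not None:
            feats_curr = _frame_features(frame)
            if self.prev_frame is not None:
                motion = _motion_from_features(self._gmc_feats, feats_curr, seed=cfg.seed)
            self._gmc_feats = feats_curr
        self.last_motion = motion
        for t in self.tracks:
            t.state = self.kf.predict(t.state)
            if not motion.is_identity:
                t.state = self.kf.apply_affine(t.state, motion.affine)

        # (2) confidence split
        dets = list(detections)
        high = [d for d in dets if d.score >= cfg.track_high_thresh]
        low = [d for d in dets if cfg.track_low_thresh <= d.score < cfg.track_high_thresh]

        # appearance features are extracted lazily: only leftover detections
        # at the rematch stages and periodic signature refreshes need them
        use_appearance = cfg.with_rematch and frame is not None
        det_features: dict[int, DescriptorSet] = {}

        def get_features(d: Detection) -> DescriptorSet:
            if id(d) not in det_features:
                det_features[id(d)] = self._descriptors_for(frame, d.bbox)
            return det_features[id(d)]

        if use_appearance and self.codebook is None:
            for d in high + low:
                ds = get_features(d)
                if len(ds):
                    self._codebook_pool.append(ds.descriptors)
            self._maybe_fit_codebook()

        pool = [t for t in self.tracks]
        matched_pairs: list[tuple[Track, Detection]] = []

        def run_iou_stage(tracks: list[Track], stage_dets: list[Detection]):
            boxes_t = [t.predicted_bbox for t in tracks]
            boxes_d = [d.bbox for d in stage_dets]
            cost = 1.0 - iou_matrix(boxes_t, boxes_d)
            matches, ut, ud = associate(cost, cfg.match_thresh)
            return matches, ut, ud

        def run_rematch(tracks: list[Track], stage_dets: list[Detection]):
            """Appearance-only rematch with displacement validation."""
            if not use_appearance or self.codebook is None or not tracks or not stage_dets:
                return [], list(range(len(tracks))), list(range(len(stage_dets)))
            vlads = [self._encode(get_features(d)) for d in stage_dets]
            cost = np.full((len(tracks), len(stage_dets)), _INF_COST)
            for i, t in enumerate(tracks):
                if t.appearance is None:
                    continue
                for j, v in enumerate(vlads):
                    if v is None:
                        continue
                    sim = appearance_similarity(t.appearance, v)
                    if sim is not None:
                        cost[i, j] = 1.0 - sim
            matches, ut, ud = associate(cost, cfg.appearance_thresh)
            # displacement-consistency validation against the best already-matched
            # pair.  Displacements are normalized by each pair's frame gap so a
            # track re-emerging after k occluded frames is compared per frame,
            # not against a k-times-shorter anchor displacement.
            anchor = None
            if matched_pairs:
                best = max(matched_pairs, key=lambda p: iou(p[0].predicted_bbox, p[1].bbox))
                if best[0].last_center is not None:
                    gap_a = max(best[0].frames_since_seen + 1, 1)
                    disp_a = (
                        np.subtract(best[1].bbox.center, best[0].last_center) / gap_a
                    )
                    anchor = ((0.0, 0.0), tuple(disp_a))
            base_tol = cfg.validation_tolerance
            if frame is not None:
                base_tol = cfg.validation_tolerance * frame.shape[1] / 1920.0
            accepted = []
            for i, j in matches:
                t = tracks[i]
                cand_origin = t.last_center if t.last_center is not None else t.predicted_bbox.center
                gap_c = max(t.frames_since_seen + 1, 1)
                disp_c = np.subtract(stage_dets[j].bbox.center, cand_origin) / gap_c
                # box-localization noise puts a floor under the tolerance: a
                # wrong match is tens of pixels inconsistent, box jitter only
                # a fraction of the box side
                box = stage_dets[j].bbox
                tol = max(base_tol, 0.3 * float(np.sqrt(box.w * box.h)))
                if validate_match(((0.0, 0.0), tuple(disp_c)), anchor, tol):
                    accepted.append((i, j))
                else:
                    ut.append(i)
                    ud.append(j)
            return accepted, sorted(ut), sorted(ud)

        # (3) stage A: high-confidence detections on IoU
        m_a, ut_a, ud_a = run_iou_stage(pool, high)
        for i, j in m_a:
            matched_pairs.append((pool[i], high[j]))
            report["matches"].append(("iou_high", i, j))
        left_tracks = [pool[i] for i in ut_a]
        left_high = [high[j] for j in ud_a]

        # (3b) rematch A: appearance on stage-A leftovers
        m_ra, ut_ra, ud_ra = run_rematch(left_tracks, left_high)
        for i, j in m_ra:
            matched_pairs.append((left_tracks[i], left_high[j]))
            report["rematches"].append(("vlad_high", i, j))
        left_tracks = [left_tracks[i] for i in ut_ra]
        unmatched_high = [left_high[j] for j in ud_ra]

        # (4) stage B: low-confidence detections on IoU
        m_b, ut_b, ud_b = run_iou_stage(left_tracks, low)
        for i, j in m_b:
            matched_pairs.append((left_tracks[i], low[j]))
            report["matches"].append(("iou_low", i, j))
        left_tracks_b = [left_tracks[i] for i in ut_b]
        left_low = [low[j] for j in ud_b]

        # (4b) rematch B: appearance on stage-B leftovers
        m_rb, ut_rb, ud_rb = run_rematch(left_tracks_b, left_low)
        for i, j in m_rb:
            matched_pairs.append((left_tracks_b[i], left_low[j]))
            report["rematches"].append(("vlad_low", i, j))
        final_unmatched_tracks = [left_tracks_b[i] for i in ut_rb]

        # (5) measurement updates and lifecycle
        for t, d in matched_pairs:
            t.state = self.kf.update(t.state, bbox_to_measurement(d.bbox))
            t.frames_since_seen = 0
            t.hits += 1
            if t.status == "tentative":
                if t.hits >= 2:
                    t.status = "active"
                    t.track_id = self._next_id()
            else:
                t.status = "active"
            t.history.append((frame_index, d.bbox, d.score))
            t.last_center = d.bbox.center
            stale = (
                t.appearance_frame is None
                or frame_index - t.appearance_frame >= cfg.appearance_refresh_interval
            )
            if use_appearance and self.codebook is not None and stale:
                v = self._encode(get_features(d))
                if v is not None and not v.degenerate:
                    t.appearance = v
                    t.appearance_center = d.bbox.center
                    t.appearance_frame = frame_index

        for t in final_unmatched_tracks:
            if t.status == "tentative":
                t.status = "removed"
            else:
                t.status = "lost"
                t.frames_since_seen += 1
                if t.frames_since_seen > cfg.track_buffer:
                    t.status = "removed"

        for d in unmatched_high:
            if d.score >= cfg.new_track_thresh:
                t = Track(state=self.kf.initiate(bbox_to_measurement(d.bbox)))
                t.history.append((frame_index, d.bbox, d.score))
                t.last_center = d.bbox.center
                if use_appearance and self.codebook is not None:
                    v = self._encode(get_features(d))
                    if v is not None and not v.degenerate:
                        t.appearance = v
                        t.appearance_center = d.bbox.center
                        t.appearance_frame = frame_index
                self.tracks.append(t)
                report["new_tracks"] += 1

        removed = [t for t in self.tracks if t.status == "removed"]
        self.finished.extend(removed)
        self.tracks = [t for t in self.tracks if t.status != "removed"]

        if frame is not None:
            self.prev_frame = frame
        return report

    def _next_id(self) -> int:
        issued = [t.track_id for t in self.tracks + self.finished if t.track_id is not None]
        return max(issued, default=0) + 1

    # -- outputs ------------------------------------------------------------

    def all_tracks(self) -> list[Track]:
        return self.tracks + self.finished

    def count(self) -> int:
        """Fruit count: the maximum confirmed track id issued so far."""
        return count_tracks(self.all_tracks())

    def results(self) -> list[GroundTruthEntry]:
        """Per-frame ledger of confirmed tracks (tentative rows backfilled)."""
        out: list[GroundTruthEntry] = []
        for t in self.all_tracks():
            if t.track_id is None:
                continue
            for frame, bbox, _score in t.history:
                out.append(GroundTruthEntry(frame=frame, track_id=t.track_id, bbox=bbox))
        out.sort(key=lambda r: (r.frame, r.track_id))
        return out
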