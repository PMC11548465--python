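"""Synthetic orchard videos with exact ground truth.

The simulator emulates the phenomenology of hand-held orchard footage at a
desk-test scale: round, textured fruit fixed in world coordinates; a
panning camera that shifts the whole scene; and opaque vertical strips
that occlude fruit for a stretch of frames, forcing the
disappear-and-reappear events that make re-identification testable.  Fruit
get per-object speckle textures drawn from two density families so that
appearance signatures can discriminate individuals, and a Lambertian-style
shading gradient so keypoint detectors find structure.

Ground truth follows the annotation policy of tracking benchmarks: the box
of the *visible* region, with the row omitted once more than 80% of the
fruit is covered or it leaves the frame.  Identities are stable across
occlusion.  Everything is deterministic given the seed.

A corruption operator turns ground truth into detector-like output
(misses, corner jitter, false positives, confidence scores), and the
augmentation transforms used to expand detector training sets are provided
as pure functions on (image, normalized boxes) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize as _sk_resize

from .errors import ConfigurationError, ValidationError
from .mot import BoundingBox, Detection, GroundTruthEntry, NormalizedAnnotation

__all__ = [
    "Occluder",
    "SceneConfig",
    "CorruptionConfig",
    "simulate_orchard",
    "corrupt_detections",
    "augment",
    "AUGMENT_OPS",
]


@dataclass(frozen=True)
class Occluder:
    """Opaque vertical strip in image coordinates, active over a frame interval."""

    x0: int
    x1: int
    frame_start: int
    frame_end: int  # inclusive

    def active(self, frame: int) -> bool:
        return self.frame_start <= frame <= self.frame_end


@dataclass
class SceneConfig:
    """Scene parameters for one synthetic orchard video.

    Defaults model a desk-scale clip: 320x240 at 30 fps metadata, 120
    frames (4 s), 25 fruit of 8-16 px radius.  ``camera_velocity`` is the
    camera pan in px/frame; world content moves by its negative.
    """

    n_apples: int = 25
    frame_size: tuple[int, int] = (320, 240)  # (w, h)
    n_frames: int = 120
    fps: int = 30
    camera_velocity: tuple[float, float] = (0.0, 0.0)
    camera_turns: list[tuple[int, tuple[float, float]]] = field(default_factory=list)
    apple_radius_range: tuple[int, int] = (8, 16)
    occluders: list[Occluder] = field(default_factory=list)
    texture_seed: int = 0
    occlusion_visibility_min: float = 0.2  # gt row kept while visible fraction >= this

    def __post_init__(self) -> None:
        if self.n_apples < 0 or self.n_frames < 1:
            raise ValidationError("need n_apples >= 0 and n_frames >= 1")
        if min(self.apple_radius_range) <= 2:
            raise ValidationError("apple radii must exceed 2 px")
        w, h = self.frame_size
        for occ in self.occluders:
            if not (0 <= occ.x0 < occ.x1 <= w):
                raise ValidationError(f"occluder x-extent ({occ.x0}, {occ.x1}) outside frame width {w}")


@dataclass
class CorruptionConfig:
    """Detector-imperfection model applied to ground truth.

    ``score_model`` maps per-box visibility to a confidence sample:
    ``score_model(rng, visibility_array) -> scores``.
    """

    miss_prob: float = 0.0
    jitter_sigma: float = 0.0
    fp_rate: float = 0.0
    score_model: Optional[Callable[[np.random.Generator, np.ndarray], np.ndarray]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.miss_prob <= 1.0:
            raise ValidationError("miss_prob must lie in [0, 1]")
        if self.jitter_sigma < 0 or self.fp_rate < 0:
            raise ValidationError("jitter_sigma and fp_rate must be >= 0")


def _default_scores(rng: np.random.Generator, visibility: np.ndarray) -> np.ndarray:
    # confidence tracks visibility: fully visible fruit score high enough to
    # seed tracks, heavily clipped slivers drop into the low-confidence band
    raw = 0.55 + 0.45 * visibility + rng.normal(0.0, 0.05, size=len(visibility))
    return np.clip(raw, 0.05, 0.98)


@dataclass
class _Apple:
    cx: float  # world coords
    cy: float
    r: int
    texture: np.ndarray  # (2r+1, 2r+1) brightness multiplier, 0 outside disk
    color: np.ndarray  # base RGB


def _make_apples(cfg: SceneConfig, rng: np.random.Generator, world_w: float, world_h: float) -> list[_Apple]:
    apples: list[_Apple] = []
    r_lo, r_hi = cfg.apple_radius_range
    margin = r_hi + 2
    attempts = 0
    while len(apples) < cfg.n_apples and attempts < 20000:
        attempts += 1
        r = int(rng.integers(r_lo, r_hi + 1))
        cx = rng.uniform(margin, world_w - margin)
        cy = rng.uniform(margin, world_h - margin)
        if any((a.cx - cx) ** 2 + (a.cy - cy) ** 2 < (a.r + r + 3) ** 2 for a in apples):
            continue
        side = 2 * r + 1
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        d = np.sqrt(xx**2 + yy**2) / r
        disk = d <= 1.0
        shading = np.where(disk, 0.45 + 0.55 * np.sqrt(np.clip(1 - d**2, 0, 1)), 0.0)
        # two speckle-density families make individuals distinguishable
        density = 0.12 if len(apples) % 2 == 0 else 0.4
        speckle = rng.random((side, side)) < density
        speckle = ndi.binary_dilation(speckle & disk)
        tex = shading * np.where(speckle, 0.45, 1.0)
        hue = rng.uniform(0.75, 1.0)
        color = np.array([230 * hue, 60 + 70 * rng.random(), 45 + 40 * rng.random()])
        apples.append(_Apple(cx=cx, cy=cy, r=r, texture=tex, color=color))
    if len(apples) < cfg.n_apples:
        raise ValidationError(
            f"could not place {cfg.n_apples} non-overlapping apples in the scene"
        )
    return apples


def _make_background(rng: np.random.Generator, world_h: int, world_w: int) -> np.ndarray:
    base = rng.normal(0.0, 1.0, (world_h, world_w))
    smooth = ndi.gaussian_filter(base, 3.0)
    smooth = (smooth - smooth.min()) / np.ptp(smooth)
    fine = ndi.gaussian_filter(rng.normal(0.0, 1.0, (world_h, world_w)), 0.8)
    fine = (fine - fine.min()) / np.ptp(fine)
    lum = 40 + 70 * smooth + 35 * fine
    bg = np.stack([0.35 * lum, 0.9 * lum, 0.35 * lum], axis=2)
    return np.clip(bg, 0, 255)


def simulate_orchard(cfg: SceneConfig) -> tuple[list[np.ndarray], list[GroundTruthEntry]]:
    """Render a synthetic orchard clip and its exact ground truth.

    Returns ``(frames, ground_truth)`` where frames are uint8 RGB arrays of
    ``cfg.frame_size`` and ground truth is in MOT form (1-based frames and
    ids, visible-region boxes).
    """
    rng = np.random.default_rng(cfg.texture_seed)
    w, h = cfg.frame_size
    # piecewise-constant camera velocity (hand-held pans change direction)
    vel = np.tile(np.asarray(cfg.camera_velocity, dtype=float), (cfg.n_frames, 1))
    for turn_frame, v in sorted(cfg.camera_turns):
        vel[turn_frame - 1 :] = v
    path = np.vstack([[0.0, 0.0], np.cumsum(vel[:-1], axis=0)])
    world_w = int(np.ceil(w + np.ptp(path[:, 0]))) + 2
    world_h = int(np.ceil(h + np.ptp(path[:, 1]))) + 2
    # camera starts wherever keeps the whole path inside the world
    cam0_x = 1.0 - path[:, 0].min()
    cam0_y = 1.0 - path[:, 1].min()

    apples = _make_apples(cfg, rng, world_w, world_h)
    background = _make_background(rng, world_h, world_w)

    frames: list[np.ndarray] = []
    gt: list[GroundTruthEntry] = []
    for t in range(1, cfg.n_frames + 1):
        cam_x = cam0_x + path[t - 1, 0]
        cam_y = cam0_y + path[t - 1, 1]
        ix0, iy0 = int(round(cam_x)), int(round(cam_y))
        frame = background[iy0 : iy0 + h, ix0 : ix0 + w].copy()

        occ_mask = np.zeros((h, w), dtype=bool)
        for occ in cfg.occluders:
            if occ.active(t):
                occ_mask[:, occ.x0 : occ.x1] = True

        for apple_id, a in enumerate(apples, start=1):
            # apple position in image coordinates
            acx, acy = a.cx - ix0, a.cy - iy0
            r = a.r
            x0 = int(np.floor(acx)) - r
            y0 = int(np.floor(acy)) - r
            side = 2 * r + 1
            # clip patch to frame
            fx0, fy0 = max(x0, 0), max(y0, 0)
            fx1, fy1 = min(x0 + side, w), min(y0 + side, h)
            if fx0 >= fx1 or fy0 >= fy1:
                continue
            tex = a.texture[fy0 - y0 : fy1 - y0, fx0 - x0 : fx1 - x0]
            disk = tex > 0
            region = frame[fy0:fy1, fx0:fx1]
            region[disk] = a.color[None, :] * tex[disk, None]

            visible = disk & ~occ_mask[fy0:fy1, fx0:fx1]
            total = int(np.count_nonzero(a.texture > 0))
            n_vis = int(np.count_nonzero(visible))
            if total == 0 or n_vis / total < cfg.occlusion_visibility_min:
                continue
            rows, cols = np.nonzero(visible)
            bx0, bx1 = fx0 + cols.min(), fx0 + cols.max() + 1
            by0, by1 = fy0 + rows.min(), fy0 + rows.max() + 1
            gt.append(
                GroundTruthEntry(
                    frame=t,
                    track_id=apple_id,
                    bbox=BoundingBox(x=float(bx0), y=float(by0), w=float(bx1 - bx0), h=float(by1 - by0)),
                    visibility=n_vis / total,
                )
            )

        if np.any(occ_mask):
            # dark, lightly textured strip so it reads as a branch/trunk
            strip_tex = 25 + 20 * rng.random((int(occ_mask.sum()),))
            frame[occ_mask] = strip_tex[:, None] * np.array([0.9, 0.7, 0.5])
        frames.append(np.clip(frame, 0, 255).astype(np.uint8))
    return frames, gt


def corrupt_detections(
    gt: Sequence[GroundTruthEntry],
    cfg: CorruptionConfig,
    frame_size: tuple[int, int] = (320, 240),
    n_frames: Optional[int] = None,
) -> list[Detection]:
    """Turn ground truth into detector-like output.

    Each box is dropped with probability ``miss_prob``; survivors get
    Gaussian corner jitter; Poisson(``fp_rate``) low-score false boxes are
    added per frame.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    score_model = cfg.score_model or _default_scores
    w, h = frame_size
    out: list[Detection] = []
    keep = rng.random(len(gt)) >= cfg.miss_prob
    vis = np.array([g.visibility for g in gt], dtype=float)
    scores = score_model(rng, vis)
    for g, k, s in zip(gt, keep, scores):
        if not k:
            continue
        b = g.bbox
        if cfg.jitter_sigma > 0:
            dx0, dy0, dx1, dy1 = rng.normal(0.0, cfg.jitter_sigma, 4)
            x0, y0 = b.x + dx0, b.y + dy0
            x1, y1 = b.right + dx1, b.bottom + dy1
            if x1 - x0 < 2:
                x1 = x0 + 2
            if y1 - y0 < 2:
                y1 = y0 + 2
            b = BoundingBox(x=x0, y=y0, w=x1 - x0, h=y1 - y0)
        out.append(Detection(bbox=b, score=float(np.clip(s, 0.0, 1.0)), frame=g.frame))
    if cfg.fp_rate > 0:
        last = n_frames or max((g.frame for g in gt), default=0)
        for t in range(1, last + 1):
            for _ in range(rng.poisson(cfg.fp_rate)):
                bw = rng.uniform(8, 30)
                bh = rng.uniform(8, 30)
                x = rng.uniform(0, max(w - bw, 1))
                y = rng.uniform(0, max(h - bh, 1))
                out.append(
                    Detection(
                        bbox=BoundingBox(x=x, y=y, w=bw, h=bh),
                        score=float(rng.uniform(0.1, 0.45)),
                        frame=t,
                    )
                )
    out.sort(key=lambda d: d.frame)
    return out


# -- augmentation transforms -------------------------------------------------


def _hflip(img, boxes, params, rng):
    return img[:, ::-1].copy(), [
        NormalizedAnnotation(b.class_id, 1.0 - b.cx, b.cy, b.nw, b.nh) for b in boxes
    ]


def _vflip(img, boxes, params, rng):
    return img[::-1].copy(), [
        NormalizedAnnotation(b.class_id, b.cx, 1.0 - b.cy, b.nw, b.nh) for b in boxes
    ]


def _brightness(img, boxes, params, rng):
    f = params.get("factor", 1.2)
    return np.clip(img.astype(float) * f, 0, 255).astype(np.uint8), list(boxes)


def _contrast(img, boxes, params, rng):
    f = params.get("factor", 1.2)
    return np.clip((img.astype(float) - 127.5) * f + 127.5, 0, 255).astype(np.uint8), list(boxes)


def _saturation(img, boxes, params, rng):
    f = params.get("factor", 1.2)
    gray = img.astype(float).mean(axis=2, keepdims=True)
    return np.clip(gray + (img.astype(float) - gray) * f, 0, 255).astype(np.uint8), list(boxes)


def _gauss_noise(img, boxes, params, rng):
    sigma = params.get("sigma", 10.0)
    noisy = img.astype(float) + rng.normal(0.0, sigma, img.shape)
    return np.clip(noisy, 0, 255).astype(np.uint8), list(boxes)


def _salt_pepper(img, boxes, params, rng):
    p = params.get("p", 0.05)
    out = img.copy()
    mask = rng.random(img.shape[:2]) < p
    salt = rng.random(img.shape[:2]) < 0.5
    out[mask & salt] = 255
    out[mask & ~salt] = 0
    return out, list(boxes)


def _resize(img, boxes, params, rng):
    scale = params.get("scale", 0.5)
    new_h = max(1, int(round(img.shape[0] * scale)))
    new_w = max(1, int(round(img.shape[1] * scale)))
    out = _sk_resize(img, (new_h, new_w), preserve_range=True, anti_aliasing=True)
    return out.astype(np.uint8), list(boxes)  # normalized boxes are scale-free


def _motion_blur(img, boxes, params, rng):
    length = int(params.get("length", 7))
    horizontal = params.get("horizontal", True)
    kernel = np.zeros((length, length))
    if horizontal:
        kernel[length // 2, :] = 1.0
    else:
        kernel[:, length // 2] = 1.0
    kernel /= kernel.sum()
    out = np.stack(
        [ndi.convolve(img[..., c].astype(float), kernel, mode="reflect") for c in range(img.shape[2])],
        axis=2,
    )
    return np.clip(out, 0, 255).astype(np.uint8), list(boxes)


AUGMENT_OPS = {
    "hflip": _hflip,
    "vflip": _vflip,
    "brightness": _brightness,
    "contrast": _contrast,
    "saturation": _saturation,
    "gauss_noise": _gauss_noise,
    "salt_pepper": _salt_pepper,
    "resize": _resize,
    "motion_blur": _motion_blur,
}


def augment(
    image: np.ndarray,
    boxes: Sequence[NormalizedAnnotation],
    op_name: str,
    params: Optional[dict] = None,
    seed: int = 0,
) -> tuple[np.ndarray, list[NormalizedAnnotation]]:
    """Apply one training-set augmentation to an image and its boxes.

    Geometric ops (flips) transform the normalized boxes consistently;
    photometric ops and resize leave them unchanged.  Stochastic ops
    (noise) are deterministic given ``seed``.
    """
    if op_name not in AUGMENT_OPS:
        raise ConfigurationError(
            f"unknown augmentation {op_name!r}; available: {sorted(AUGMENT_OPS)}"
        )
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValidationError("augment expects an RGB (h, w, 3) image")
    rng = np.random.default_rng(seed)
    return AUGMENT_OPS[op_name](image, list(boxes), params or {}, rng)
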