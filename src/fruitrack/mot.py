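"""MOTChallenge-style file I/O and annotation geometry.

Boxes use a 0-based, half-open pixel convention: a mask occupying columns
3..6 inclusive yields ``x=3, w=4``.  MOT CSV files keep their native 1-based
frame and id columns; pixel coordinates are read and written verbatim.

The MOT CSV layout is ``frame,id,bb_left,bb_top,bb_width,bb_height,conf,x,y,z``
with no header.  Detection rows carry ``id=-1`` and a confidence in the
``conf`` column; ground-truth rows carry a track id and their ``conf`` column
is treated as a visibility flag and ignored.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ParseError, ValidationError

__all__ = [
    "BoundingBox",
    "Detection",
    "GroundTruthEntry",
    "NormalizedAnnotation",
    "read_mot_file",
    "write_mot_file",
    "sort_by_frame",
    "mask_to_bbox",
    "polygon_to_bbox",
    "normalize_bbox",
    "denormalize_bbox",
    "read_normalized_annotations",
    "write_normalized_annotations",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box: left edge, top edge, width, height."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "w", "h"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"bounding box field {name!r} is not finite: {v}")
        if self.w <= 0 or self.h <= 0:
            raise ValidationError(
                f"bounding box must have positive extent, got w={self.w}, h={self.h}"
            )

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def right(self) -> float:
        return self.x + self.w

    @property
    def bottom(self) -> float:
        return self.y + self.h

    def as_xywh(self) -> tuple[float, float, float, float]:
        return (self.x, self.y, self.w, self.h)


@dataclass(frozen=True)
class Detection:
    """A detector output box with confidence, attached to a 1-based frame."""

    bbox: BoundingBox
    score: float
    frame: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError(f"detection score must lie in [0, 1], got {self.score}")
        if self.frame < 1:
            raise ValidationError(f"frame index must be >= 1, got {self.frame}")


@dataclass(frozen=True)
class GroundTruthEntry:
    """One annotated identity-box on one frame.

    ``visibility`` is the fraction of the object left uncovered by
    occluders and frame borders; annotation sources that do not provide it
    default to fully visible.
    """

    frame: int
    track_id: int
    bbox: BoundingBox
    visibility: float = 1.0

    def __post_init__(self) -> None:
        if self.frame < 1:
            raise ValidationError(f"frame index must be >= 1, got {self.frame}")
        if self.track_id < 1:
            raise ValidationError(f"track id must be >= 1, got {self.track_id}")
        if not 0.0 <= self.visibility <= 1.0:
            raise ValidationError(f"visibility must lie in [0, 1], got {self.visibility}")


@dataclass(frozen=True)
class NormalizedAnnotation:
    """YOLO-style annotation: class id plus center/size in image fractions."""

    class_id: int
    cx: float
    cy: float
    nw: float
    nh: float

    def __post_init__(self) -> None:
        for name in ("cx", "cy", "nw", "nh"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"normalized field {name!r} out of [0, 1]: {v}")


def _parse_row(fields: Sequence[str], lineno: int) -> tuple[int, int, float, float, float, float, float]:
    if len(fields) < 6:
        raise ParseError(f"line {lineno}: expected >= 6 comma-separated fields, got {len(fields)}")
    try:
        frame = int(float(fields[0]))
        obj_id = int(float(fields[1]))
        left, top, width, height = (float(f) for f in fields[2:6])
        conf = float(fields[6]) if len(fields) > 6 else 1.0
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-numeric field ({exc})") from None
    if width <= 0 or height <= 0:
        raise ValidationError(
            f"line {lineno}: non-positive box extent w={width}, h={height}"
        )
    return frame, obj_id, left, top, width, height, conf


def read_mot_file(path: str | os.PathLike, kind: str) -> list[Detection] | list[GroundTruthEntry]:
    """Read a MOTChallenge CSV as detections or ground-truth entries.

    Rows are returned in file order.  ``kind`` is ``"detections"`` (the id
    column is ignored, ``conf`` becomes the score) or ``"ground_truth"``
    (the ``conf`` column is ignored).
    """
    if kind not in ("detections", "ground_truth"):
        raise ValidationError(f"kind must be 'detections' or 'ground_truth', got {kind!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(f"MOT file not found: {path}")
    out: list = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            frame, obj_id, left, top, w, h, conf = _parse_row(line.split(","), lineno)
            bbox = BoundingBox(left, top, w, h)
            if kind == "detections":
                score = min(max(conf, 0.0), 1.0)
                out.append(Detection(bbox=bbox, score=score, frame=frame))
            else:
                out.append(GroundTruthEntry(frame=frame, track_id=obj_id, bbox=bbox))
    return out


def write_mot_file(path: str | os.PathLike, records: Iterable[Detection | GroundTruthEntry]) -> None:
    """Write detections or ground-truth entries in MOT CSV layout."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            # repr keeps full float precision so round-trips are exact
            b = rec.bbox
            coords = f"{b.x!r},{b.y!r},{b.w!r},{b.h!r}"
            if isinstance(rec, Detection):
                fh.write(f"{rec.frame},-1,{coords},{rec.score!r},-1,-1,-1\n")
            else:
                fh.write(f"{rec.frame},{rec.track_id},{coords},1,-1,-1,-1\n")


def sort_by_frame(records: Sequence) -> list:
    """Stable sort of MOT records by frame index (file order kept within a frame)."""
    return sorted(records, key=lambda r: r.frame)


def mask_to_bbox(mask: np.ndarray) -> BoundingBox:
    """Tightest half-open box containing all foreground pixels of a binary mask."""
    mask = np.asarray(mask)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValidationError("mask has no foreground pixels")
    y0, y1 = int(rows.min()), int(rows.max())
    x0, x1 = int(cols.min()), int(cols.max())
    return BoundingBox(x=x0, y=y0, w=x1 - x0 + 1, h=y1 - y0 + 1)


def polygon_to_bbox(vertices: Sequence[tuple[float, float]]) -> BoundingBox:
    """Axis-aligned box of the min/max vertex coordinates of a polygon."""
    pts = np.asarray(vertices, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValidationError("polygon needs at least 3 (x, y) vertices")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("polygon vertices must be finite")
    x0, y0 = pts.min(axis=0)
    x1, y1 = pts.max(axis=0)
    if x1 <= x0 or y1 <= y0:
        raise ValidationError("polygon is degenerate (zero area)")
    return BoundingBox(x=float(x0), y=float(y0), w=float(x1 - x0), h=float(y1 - y0))


def normalize_bbox(bbox: BoundingBox, image_w: float, image_h: float, class_id: int = 0) -> NormalizedAnnotation:
    """Convert a pixel box to class/center/size fractions of the image.

    The box must lie inside ``[0, image_w] x [0, image_h]``; partially
    visible objects are the caller's responsibility to clip first.
    """
    if bbox.x < 0 or bbox.y < 0 or bbox.right > image_w or bbox.bottom > image_h:
        raise ValidationError(
            f"box {bbox.as_xywh()} exceeds image bounds {image_w}x{image_h}"
        )
    return NormalizedAnnotation(
        class_id=class_id,
        cx=(bbox.x + bbox.w / 2.0) / image_w,
        cy=(bbox.y + bbox.h / 2.0) / image_h,
        nw=bbox.w / image_w,
        nh=bbox.h / image_h,
    )


def denormalize_bbox(ann: NormalizedAnnotation, image_w: float, image_h: float) -> BoundingBox:
    """Inverse of :func:`normalize_bbox`."""
    w = ann.nw * image_w
    h = ann.nh * image_h
    return BoundingBox(x=ann.cx * image_w - w / 2.0, y=ann.cy * image_h - h / 2.0, w=w, h=h)


def write_normalized_annotations(path: str | os.PathLike, anns: Iterable[NormalizedAnnotation]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a in anns:
            fh.write(f"{a.class_id} {a.cx:.9f} {a.cy:.9f} {a.nw:.9f} {a.nh:.9f}\n")


def read_normalized_annotations(path: str | os.PathLike) -> list[NormalizedAnnotation]:
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 5:
                raise ParseError(f"line {lineno}: expected 5 fields, got {len(fields)}")
            try:
                out.append(
                    NormalizedAnnotation(
                        class_id=int(fields[0]),
                        cx=float(fields[1]),
                        cy=float(fields[2]),
                        nw=float(fields[3]),
                        nh=float(fields[4]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-numeric field ({exc})") from None
    return out
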