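"""Appearance signatures for fruit re-identification.

A fruit crop is summarized by a VLAD vector: local keypoint descriptors are
extracted from the crop, each descriptor is assigned to its nearest
codebook centroid, the descriptor-minus-centroid residuals are accumulated
per centroid, and the concatenated residual vector is power-normalized
(signed square root) and L2-normalized.  Two crops are compared by cosine
similarity of their VLAD vectors.

Descriptor backends are pluggable (ORB by default, SIFT optional, both via
scikit-image).  Crops with no detectable keypoints yield a *degenerate*
all-zero VLAD vector; similarity against a degenerate vector is reported as
"no evidence" (``None``) rather than a number, so a textureless crop can
never win an appearance-only rematch.

Because aggregated-residual matching is unstable on near-uniform fruit, a
candidate appearance match is additionally validated against an anchor: two
regions of the same scene must show the same inter-frame displacement
(:func:`validate_match`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist
from skimage.color import rgb2gray
from skimage.feature import ORB, SIFT
from sklearn.cluster import KMeans

from .errors import ConfigurationError, ValidationError

__all__ = [
    "DescriptorSet",
    "Codebook",
    "VladVector",
    "extract_descriptors",
    "fit_codebook",
    "vlad_encode",
    "appearance_similarity",
    "validate_match",
]

_MIN_REGION = 16


@dataclass
class DescriptorSet:
    """Local descriptors plus their keypoint positions within the crop."""

    descriptors: np.ndarray  # (m, d) float
    keypoints: np.ndarray  # (m, 2) float, (x, y) pixel positions

    def __post_init__(self) -> None:
        desc = np.asarray(self.descriptors, dtype=float)
        self.descriptors = desc if desc.ndim == 2 else desc.reshape(0, 0)
        kps = np.asarray(self.keypoints, dtype=float)
        self.keypoints = kps.reshape(-1, 2) if kps.size else np.empty((0, 2))
        if len(self.descriptors) != len(self.keypoints):
            raise ValidationError("descriptor and keypoint counts differ")

    def __len__(self) -> int:
        return len(self.descriptors)

    @classmethod
    def empty(cls, d: int = 0) -> "DescriptorSet":
        return cls(descriptors=np.empty((0, d)), keypoints=np.empty((0, 2)))


@dataclass
class Codebook:
    """K-means centroids that VLAD residuals are computed against."""

    centroids: np.ndarray  # (K, d)

    def __post_init__(self) -> None:
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        if not np.all(np.isfinite(self.centroids)):
            raise ValidationError("codebook centroids must be finite")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def d(self) -> int:
        return self.centroids.shape[1]


@dataclass
class VladVector:
    """Aggregated-residual signature; ``degenerate`` marks the no-keypoint case."""

    values: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("VLAD vector must be finite")


def _to_gray(region: np.ndarray) -> np.ndarray:
    region = np.asarray(region)
    if region.ndim == 3:
        region = rgb2gray(region)
    elif region.ndim != 2:
        raise ValidationError(f"region must be 2-D or 3-D, got shape {region.shape}")
    region = region.astype(float)
    if region.max() > 1.5:  # uint8-scaled input
        region = region / 255.0
    return region


def extract_descriptors(
    region: np.ndarray,
    detector_name: str = "orb",
    n_keypoints: int = 50,
) -> DescriptorSet:
    """Detect keypoints in a crop and return their local descriptors.

    ``detector_name`` selects the backend: ``"orb"`` (default, binary
    descriptors as 0/1 floats) or ``"sift"``.  Extraction is deterministic
    for fixed parameters and may legitimately return an empty set on
    textureless crops.
    """
    gray = _to_gray(region)
    if gray.shape[0] < _MIN_REGION or gray.shape[1] < _MIN_REGION:
        raise ValidationError(
            f"region {gray.shape} smaller than minimum {_MIN_REGION}x{_MIN_REGION}"
        )
    if detector_name == "orb":
        extractor = ORB(n_keypoints=n_keypoints, fast_threshold=0.05)
    elif detector_name == "sift":
        # internal 2x pre-upsampling off: callers feed already-upscaled crops
        extractor = SIFT(upsampling=1)
    else:
        raise ConfigurationError(
            f"unknown descriptor backend {detector_name!r}; this build provides 'orb' and 'sift'"
            + (" (SURF is not available in any installed library)" if detector_name == "surf" else "")
        )
    try:
        extractor.detect_and_extract(gray)
    except RuntimeError:
        # scikit-image raises when no keypoints survive; treat as textureless
        return DescriptorSet.empty()
    desc = np.asarray(extractor.descriptors, dtype=float)
    # keypoints come back (row, col); store (x, y)
    kps = np.asarray(extractor.keypoints, dtype=float)[:, ::-1]
    if desc.size == 0:
        return DescriptorSet.empty()
    return DescriptorSet(descriptors=desc, keypoints=kps)


def fit_codebook(descriptors: DescriptorSet | np.ndarray, k: int, seed: int = 0) -> Codebook:
    """Cluster pooled descriptors into a K-centroid codebook (k-means)."""
    if isinstance(descriptors, DescriptorSet):
        data = descriptors.descriptors
    else:
        data = np.asarray(descriptors, dtype=float)
    if len(data) < k:
        raise ValidationError(f"need at least k={k} descriptors, got {len(data)}")
    if k < 1:
        raise ValidationError("k must be >= 1")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    km.fit(data)
    return Codebook(centroids=km.cluster_centers_)


def vlad_encode(ds: DescriptorSet, cb: Codebook) -> VladVector:
    """Aggregate descriptor residuals against the codebook into one vector.

    Residuals to the nearest centroid are accumulated per centroid,
    concatenated (K*d), power-normalized elementwise with the signed square
    root, then L2-normalized.  An empty descriptor set (or all-zero
    aggregate) yields a degenerate all-zero vector.
    """
    if len(ds) == 0:
        return VladVector(values=np.zeros(cb.k * cb.d), degenerate=True)
    if ds.descriptors.shape[1] != cb.d:
        raise ValidationError(
            f"descriptor dimension {ds.descriptors.shape[1]} != codebook dimension {cb.d}"
        )
    assign = np.argmin(cdist(ds.descriptors, cb.centroids), axis=1)
    agg = np.zeros((cb.k, cb.d))
    np.add.at(agg, assign, ds.descriptors - cb.centroids[assign])
    v = agg.ravel()
    norm = np.linalg.norm(v)
    if norm == 0.0:
        return VladVector(values=np.zeros(cb.k * cb.d), degenerate=True)
    v = np.sign(v) * np.sqrt(np.abs(v))
    return VladVector(values=v / np.linalg.norm(v))


def appearance_similarity(a: VladVector, b: VladVector) -> Optional[float]:
    """Cosine similarity of two VLAD vectors, or ``None`` if either is degenerate."""
    if a.values.shape != b.values.shape:
        raise ValidationError(
            f"VLAD dimensions differ: {a.values.shape} vs {b.values.shape}"
        )
    if a.degenerate or b.degenerate:
        return None
    na = np.linalg.norm(a.values)
    nb = np.linalg.norm(b.values)
    if na == 0.0 or nb == 0.0:
        return None
    return float(np.clip(np.dot(a.values, b.values) / (na * nb), -1.0, 1.0))


def validate_match(
    candidate: tuple[tuple[float, float], tuple[float, float]],
    anchor: Optional[tuple[tuple[float, float], tuple[float, float]]],
    tolerance: float = 10.0,
) -> bool:
    """Displacement-consistency check for a candidate appearance match.

    Each argument is ``(track_center, detection_center)``.  Two regions of
    the same scene must move together between neighboring frames, so the
    candidate is accepted iff the Euclidean difference between its
    track-to-detection displacement and the anchor's is at most
    ``tolerance`` (closed boundary).  With no anchor available the check is
    vacuously passed.
    """
    if anchor is None:
        return True
    (tc, dc) = candidate
    (ta, da) = anchor
    disp_c = np.subtract(dc, tc)
    disp_a = np.subtract(da, ta)
    return bool(np.linalg.norm(disp_c - disp_a) <= tolerance)
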