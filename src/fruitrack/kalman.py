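"""Constant-velocity Kalman filter over (cx, cy, w, h) box states.

The 8-dimensional state holds box center, width and height plus their
per-frame velocities, with width/height modeled directly rather than as an
aspect ratio.  Process and measurement noise scale with box size: standard
deviations are ``size / 20`` for positions and ``size / 160`` for
velocities, the usual choice for box tracking at video frame rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .mot import BoundingBox

__all__ = ["KalmanState", "KalmanFilter", "bbox_to_measurement", "measurement_to_bbox"]

_STD_POS = 1.0 / 20.0
_STD_VEL = 1.0 / 160.0


def bbox_to_measurement(bbox: BoundingBox) -> np.ndarray:
    cx, cy = bbox.center
    return np.array([cx, cy, bbox.w, bbox.h], dtype=float)


def measurement_to_bbox(z: np.ndarray) -> BoundingBox:
    cx, cy, w, h = (float(v) for v in z[:4])
    w = max(w, 1e-3)
    h = max(h, 1e-3)
    return BoundingBox(x=cx - w / 2.0, y=cy - h / 2.0, w=w, h=h)


@dataclass
class KalmanState:
    """Gaussian belief over the 8-d box state."""

    mean: np.ndarray  # (8,)
    covariance: np.ndarray  # (8, 8)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.mean.shape != (8,) or self.covariance.shape != (8, 8):
            raise ValidationError("Kalman state must be an 8-vector with 8x8 covariance")

    @property
    def bbox(self) -> BoundingBox:
        return measurement_to_bbox(self.mean)


class KalmanFilter:
    """Linear-Gaussian filter with size-scaled noise for box tracking."""

    def __init__(self) -> None:
        self.F = np.eye(8)
        self.F[:4, 4:] = np.eye(4)  # x' = x + v per frame
        self.H = np.zeros((4, 8))
        self.H[:4, :4] = np.eye(4)

    def initiate(self, measurement: np.ndarray) -> KalmanState:
        z = np.asarray(measurement, dtype=float)
        mean = np.zeros(8)
        mean[:4] = z
        size = np.array([z[2], z[3], z[2], z[3]])
        std = np.concatenate([2 * _STD_POS * size, 10 * _STD_VEL * size])
        return KalmanState(mean=mean, covariance=np.diag(std**2))

    def _process_noise(self, mean: np.ndarray) -> np.ndarray:
        size = np.array([mean[2], mean[3], mean[2], mean[3]])
        std = np.concatenate([_STD_POS * size, _STD_VEL * size])
        return np.diag(std**2)

    def predict(self, state: KalmanState) -> KalmanState:
        mean = self.F @ state.mean
        cov = self.F @ state.covariance @ self.F.T + self._process_noise(state.mean)
        return KalmanState(mean=mean, covariance=cov)

    def update(self, state: KalmanState, measurement: np.ndarray) -> KalmanState:
        z = np.asarray(measurement, dtype=float)
        size = np.array([state.mean[2], state.mean[3], state.mean[2], state.mean[3]])
        R = np.diag((_STD_POS * size) ** 2)
        S = self.H @ state.covariance @ self.H.T + R
        K = state.covariance @ self.H.T @ np.linalg.solve(S, np.eye(4)).T
        innov = z - self.H @ state.mean
        mean = state.mean + K @ innov
        cov = (np.eye(8) - K @ self.H) @ state.covariance
        cov = (cov + cov.T) / 2.0
        return KalmanState(mean=mean, covariance=cov)

    def apply_affine(self, state: KalmanState, affine: np.ndarray) -> KalmanState:
        """Warp the state by a 2x3 camera-motion transform.

        The linear 2x2 part rotates/scales center position and velocity; the
        translation applies to position only.  Width/height are left
        untouched (pan-dominant motion), matching common camera-motion
        compensation practice for box trackers.
        """
        A = np.asarray(affine, dtype=float)
        M, t = A[:, :2], A[:, 2]
        T = np.eye(8)
        T[0:2, 0:2] = M
        T[4:6, 4:6] = M
        mean = T @ state.mean
        mean[0:2] += t
        cov = T @ state.covariance @ T.T
        return KalmanState(mean=mean, covariance=cov)
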