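"""Forward-only reference operators for the detector's building blocks.

These are the array-level forwards of the attention/pooling modules that an
occlusion-robust fruit detector inserts into a YOLO-style backbone:

* omni-dimensional dynamic convolution — a bank of kernels, each modulated
  elementwise by four attention factors (spatial position, input channel,
  output filter, whole kernel) before being summed and applied as one
  cross-correlation;
* a global attention gate — a channel stage (permute, two-layer MLP,
  sigmoid) followed by a spatial stage (two convolutions, sigmoid), each
  gating the feature map multiplicatively;
* soft pooling — a softmax-of-activations weighted mean per window, which
  keeps more signal than max pooling and sharpens more than average pooling;
* a CSP-style soft spatial pyramid pooling layer stacking parallel
  soft-pools at kernel sizes {3, 5, 9, 13}.

Everything here is inference-level numpy: no training, no gradients, and
batch normalization folded to identity.  Attention factors for the dynamic
convolution are operator *inputs* — the squeeze/excite sub-network that
would produce them is training-dependent and out of scope.

Feature maps are ``(h, w, c)`` float arrays.  Convolution kernels are
``(k, k, c_in, c_out)`` and applied as cross-correlation (no kernel flip),
matching deep-learning convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ValidationError

__all__ = [
    "ConvKernelBank",
    "GamParams",
    "SspplWeights",
    "conv2d",
    "odconv_forward",
    "gam_forward",
    "softpool2d",
    "maxpool2d",
    "ssppl_forward",
]


def _check_feature_map(x: np.ndarray, name: str = "x") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValidationError(f"{name} must be (h, w, c), got shape {x.shape}")
    if min(x.shape) < 1:
        raise ValidationError(f"{name} has an empty dimension: {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValidationError(f"{name} contains non-finite entries")
    return x


@dataclass
class ConvKernelBank:
    """A bank of n kernels with per-kernel four-dimensional attention.

    kernels: ``(n, k, k, c_in, c_out)``; alpha_s: ``(n, k, k)`` spatial;
    alpha_c: ``(n, c_in)`` input-channel; alpha_f: ``(n, c_out)`` filter;
    alpha_w: ``(n,)`` whole-kernel scalars.
    """

    kernels: np.ndarray
    alpha_s: np.ndarray
    alpha_c: np.ndarray
    alpha_f: np.ndarray
    alpha_w: np.ndarray

    def __post_init__(self) -> None:
        self.kernels = np.asarray(self.kernels, dtype=float)
        if self.kernels.ndim != 5 or self.kernels.shape[1] != self.kernels.shape[2]:
            raise ValidationError(
                f"kernels must be (n, k, k, c_in, c_out), got {self.kernels.shape}"
            )
        n, k, _, c_in, c_out = self.kernels.shape
        expected = {"alpha_s": (n, k, k), "alpha_c": (n, c_in), "alpha_f": (n, c_out), "alpha_w": (n,)}
        for name, shape in expected.items():
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValidationError(f"{name} must have shape {shape}, got {arr.shape}")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValidationError(f"{name} must be finite and non-negative")
            setattr(self, name, arr)

    @classmethod
    def identity(cls, kernels: np.ndarray) -> "ConvKernelBank":
        """Bank with all attention factors equal to one."""
        kernels = np.asarray(kernels, dtype=float)
        n, k, _, c_in, c_out = kernels.shape
        return cls(
            kernels=kernels,
            alpha_s=np.ones((n, k, k)),
            alpha_c=np.ones((n, c_in)),
            alpha_f=np.ones((n, c_out)),
            alpha_w=np.ones(n),
        )


def conv2d(x: np.ndarray, kernel: np.ndarray, stride: int = 1, padding: int = 0) -> np.ndarray:
    """Plain 2-D cross-correlation of an (h, w, c_in) map with a (k, k, c_in, c_out) kernel."""
    x = _check_feature_map(x)
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 4 or kernel.shape[0] != kernel.shape[1]:
        raise ValidationError(f"kernel must be (k, k, c_in, c_out), got {kernel.shape}")
    if kernel.shape[2] != x.shape[2]:
        raise ValidationError(
            f"kernel expects {kernel.shape[2]} input channels, feature map has {x.shape[2]}"
        )
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    k = kernel.shape[0]
    if padding:
        x = np.pad(x, ((padding, padding), (padding, padding), (0, 0)))
    if x.shape[0] < k or x.shape[1] < k:
        raise ValidationError(f"padded input {x.shape[:2]} smaller than kernel {k}")
    # windows: (h', w', k, k, c_in) after stride slicing
    win = sliding_window_view(x, (k, k), axis=(0, 1))[::stride, ::stride]
    win = win.transpose(0, 1, 3, 4, 2)
    return np.tensordot(win, kernel, axes=([2, 3, 4], [0, 1, 2]))


def odconv_forward(x: np.ndarray, bank: ConvKernelBank, stride: int = 1, padding: int = 0) -> np.ndarray:
    """Dynamic convolution: sum of attention-modulated kernels, applied once.

    Each kernel is modulated elementwise in the order spatial position →
    input channel → output filter → whole-kernel scalar; the modulated
    kernels are summed and the result is applied as a single
    cross-correlation, which equals summing n separate convolutions by
    linearity.
    """
    x = _check_feature_map(x)
    if bank.kernels.shape[3] != x.shape[2]:
        raise ValidationError(
            f"bank expects {bank.kernels.shape[3]} input channels, feature map has {x.shape[2]}"
        )
    modulated = (
        bank.kernels
        * bank.alpha_s[:, :, :, None, None]
        * bank.alpha_c[:, None, None, :, None]
        * bank.alpha_f[:, None, None, None, :]
        * bank.alpha_w[:, None, None, None, None]
    )
    return conv2d(x, modulated.sum(axis=0), stride=stride, padding=padding)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class GamParams:
    """Weights of the global attention gate.

    Channel stage: two-layer MLP ``c -> c/reduction -> c`` applied at every
    spatial position (w1: ``(c, c/r)``, w2: ``(c/r, c)``).  Spatial stage:
    two channel-preserving same-padding convolutions (conv1: ``(k, k, c,
    c/r)``, conv2: ``(k, k, c/r, c)``), ReLU after the first.
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    conv1: np.ndarray
    conv2: np.ndarray
    reduction: int = 4

    @classmethod
    def random(cls, c: int, reduction: int = 4, kernel: int = 7, seed: int = 0, scale: float = 0.1) -> "GamParams":
        if c % reduction:
            raise ValidationError(f"channels {c} not divisible by reduction {reduction}")
        rng = np.random.default_rng(seed)
        cr = c // reduction
        return cls(
            w1=rng.normal(0, scale, (c, cr)),
            b1=rng.normal(0, scale, cr),
            w2=rng.normal(0, scale, (cr, c)),
            b2=rng.normal(0, scale, c),
            conv1=rng.normal(0, scale, (kernel, kernel, c, cr)),
            conv2=rng.normal(0, scale, (kernel, kernel, cr, c)),
            reduction=reduction,
        )


def gam_forward(f1: np.ndarray, params: GamParams) -> np.ndarray:
    """Channel gate then spatial gate, each multiplicative on the feature map."""
    f1 = _check_feature_map(f1, "f1")
    h, w, c = f1.shape
    if params.w1.shape[0] != c or params.w2.shape[1] != c:
        raise ValidationError(
            f"MLP weights map {params.w1.shape[0]} channels, feature map has {c}"
        )
    # channel stage: flatten spatial, MLP per position, sigmoid gate
    flat = f1.reshape(-1, c)
    hidden = np.maximum(flat @ params.w1 + params.b1, 0.0)
    mc = _sigmoid((hidden @ params.w2 + params.b2).reshape(h, w, c))
    f2 = mc * f1
    # spatial stage: conv -> ReLU -> conv -> sigmoid gate, same padding
    k = params.conv1.shape[0]
    pad = k // 2
    mid = np.maximum(conv2d(f2, params.conv1, padding=pad), 0.0)
    ms = _sigmoid(conv2d(mid, params.conv2, padding=pad))
    return ms * f2


def _pool2d(x: np.ndarray, kernel: int, stride: int, mode: Literal["soft", "max"], same: bool) -> np.ndarray:
    x = _check_feature_map(x)
    if kernel < 1:
        raise ValidationError("pooling kernel must be >= 1")
    if same:
        pad = kernel // 2
        # -inf padding contributes zero softmax weight and never wins a max
        x = np.pad(x, ((pad, pad), (pad, pad), (0, 0)), constant_values=-np.inf)
    if kernel > x.shape[0] or kernel > x.shape[1]:
        raise ValidationError(
            f"pooling kernel {kernel} exceeds spatial dims {x.shape[:2]}"
        )
    win = sliding_window_view(x, (kernel, kernel), axis=(0, 1))[::stride, ::stride]
    # win: (h', w', c, k, k)
    if mode == "max":
        return win.max(axis=(3, 4))
    m = win.max(axis=(3, 4), keepdims=True)
    ex = np.exp(win - m)  # -inf pads -> exp(-inf) = 0
    ex = np.where(np.isfinite(win), ex, 0.0)
    vals = np.where(np.isfinite(win), win, 0.0)
    return (ex * vals).sum(axis=(3, 4)) / ex.sum(axis=(3, 4))


def softpool2d(x: np.ndarray, kernel: int, stride: int = 1, same_padding: bool = False) -> np.ndarray:
    """Softmax-weighted mean per pooling window, per channel.

    Output per window is ``sum(exp(a_i) * a_i) / sum(exp(a_i))``, stabilized
    by subtracting the window max.  With ``same_padding`` the borders are
    padded with ``-inf`` so padded cells carry zero weight.
    """
    return _pool2d(x, kernel, stride, "soft", same_padding)


def maxpool2d(x: np.ndarray, kernel: int, stride: int = 1, same_padding: bool = False) -> np.ndarray:
    """Max pooling with the same windowing as :func:`softpool2d`."""
    return _pool2d(x, kernel, stride, "max", same_padding)


@dataclass
class SspplWeights:
    """1x1-convolution weights of the soft spatial pyramid pooling layer.

    branch_a / branch_b: ``(c_in, c_mid)``; after_pool: ``(5*c_mid, c_mid)``
    mixing the un-pooled tensor with the four pyramid levels; merge:
    ``(2*c_mid, c_out)``.
    """

    branch_a: np.ndarray
    branch_b: np.ndarray
    after_pool: np.ndarray
    merge: np.ndarray

    @classmethod
    def identity(cls, c: int) -> "SspplWeights":
        """Weights that pass features through unchanged for constant inputs.

        Branch convs are identity; the pyramid concat is averaged back to
        ``c`` channels; the final merge averages the two branches.
        """
        eye = np.eye(c)
        return cls(
            branch_a=eye,
            branch_b=eye,
            after_pool=np.vstack([eye] * 5) / 5.0,
            merge=np.vstack([eye, eye]) / 2.0,
        )

    @classmethod
    def random(cls, c_in: int, c_mid: int, c_out: int, seed: int = 0, scale: float = 0.1) -> "SspplWeights":
        rng = np.random.default_rng(seed)
        return cls(
            branch_a=rng.normal(0, scale, (c_in, c_mid)),
            branch_b=rng.normal(0, scale, (c_in, c_mid)),
            after_pool=rng.normal(0, scale, (5 * c_mid, c_mid)),
            merge=rng.normal(0, scale, (2 * c_mid, c_out)),
        )


_SSPPL_KERNELS = (3, 5, 9, 13)


def ssppl_forward(
    x: np.ndarray,
    weights: SspplWeights,
    pool: Literal["soft", "max"] = "soft",
) -> np.ndarray:
    """CSP-style pyramid pooling with soft pools at kernel sizes {3, 5, 9, 13}.

    Branch A is a 1x1 conv of the input.  Branch B is a 1x1 conv followed by
    four parallel stride-1 same-padding pools; the un-pooled tensor and the
    four pooled tensors are concatenated and mixed by a 1x1 conv.  The two
    branches are concatenated and mixed by a final 1x1 conv.  Spatial
    dimensions are preserved.  ``pool="max"`` substitutes max pooling, which
    is useful for oracle comparisons.
    """
    x = _check_feature_map(x)
    if min(x.shape[:2]) < max(_SSPPL_KERNELS):
        raise ValidationError(
            f"spatial dims {x.shape[:2]} smaller than largest pyramid kernel {max(_SSPPL_KERNELS)}"
        )
    a = x @ weights.branch_a
    b = x @ weights.branch_b
    pools = [_pool2d(b, k, stride=1, mode=pool, same=True) for k in _SSPPL_KERNELS]
    stacked = np.concatenate([b] + pools, axis=2)
    b_mixed = stacked @ weights.after_pool
    merged = np.concatenate([a, b_mixed], axis=2) @ weights.merge
    return merged
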