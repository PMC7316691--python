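"""Trainable Nadaraya-Watson (NW) regression as a convolutional layer.

Classical NW kernel regression reconstructs a value at (u, v) as a
kernel-weighted average of nearby samples. The NW layer generalises this to
a trainable operation on a sparse feature map S and a sparsity map M:

    R(u, v) = sum_{i,j} S(u+i, v+j) w_{i,j} / sum_{i,j} M(u+i, v+j) |w_{i,j}| + b
    M_up(u, v) = sum_{i,j} M(u+i, v+j) |w_{i,j}|

The weights w may be negative (unlike handcrafted kernels), so the mask
arithmetic uses |w| to capture the geometric influence of neighbouring
samples. For numerical stability every kernel is normalised to
sum |w| = 1. The input mask of the first layer is binary (1 at fibre
pixels); the updated map M_up is a non-negative, probabilistic sparsity
pattern that subsequent NW layers consume, so stacked layers propagate both
features and certainty. Layers are stackable into an NWNet head via
:func:`nwnet_forward` / :class:`NWLayer`.

For multi-channel input the numerator and denominator both sum over input
channels, pairing each channel's mask with the absolute weights of that
channel's kernel slice; the ratio stays a weighted average and the layer
keeps exactly the parameter count of the plain convolution it replaces
(t * C_in * (2k+1)^2 weights + t biases).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .fiber_model import SparseFrame

__all__ = ["NWKernelBank", "normalize_kernels", "init_kernels", "nw_forward",
           "nwnet_forward", "nw_core", "EPS"]

#: Denominator threshold below which a window is treated as empty.
EPS = 1e-8

#: Normalisation tolerance on sum |w| = 1.
NORM_TOL = 1e-6


@dataclass(frozen=True)
class NWKernelBank:
    """Kernels and biases of one NW layer.

    weights: (t, C_in, 2k+1, 2k+1), real-valued, negatives allowed.
    biases:  (t,)
    """

    weights: np.ndarray
    biases: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        b = np.asarray(self.biases, dtype=np.float64)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "biases", b)
        if w.ndim != 4:
            raise ValueError("weights must be (t, C_in, 2k+1, 2k+1)")
        t, _, kh, kw = w.shape
        if t < 1 or kh != kw or kh % 2 == 0 or kh < 3:
            raise ValueError("kernels must be odd, square, size >= 3")
        if b.shape != (t,):
            raise ValueError(f"biases must have shape ({t},)")

    @property
    def n_kernels(self) -> int:
        return self.weights.shape[0]

    @property
    def in_channels(self) -> int:
        return self.weights.shape[1]

    @property
    def half_width(self) -> int:
        return (self.weights.shape[2] - 1) // 2

    @property
    def n_parameters(self) -> int:
        return self.weights.size + self.biases.size

    def is_normalized(self, tol: float = NORM_TOL) -> bool:
        sums = np.abs(self.weights).sum(axis=(1, 2, 3))
        return bool(np.all(np.abs(sums - 1.0) <= tol))

    def save(self, path):
        np.savez(path, weights=self.weights, biases=self.biases)

    @classmethod
    def load(cls, path) -> "NWKernelBank":
        with np.load(path) as data:
            return cls(weights=data["weights"], biases=data["biases"])


def normalize_kernels(bank: NWKernelBank) -> NWKernelBank:
    """Divide each kernel by its sum of absolute weights (idempotent)."""
    sums = np.abs(bank.weights).sum(axis=(1, 2, 3), keepdims=True)
    if np.any(sums == 0):
        raise ValueError("cannot normalise an all-zero kernel")
    return NWKernelBank(weights=bank.weights / sums, biases=bank.biases)


def init_kernels(t: int, k: int, c_in: int = 1, seed: int = 0,
                 mean: float = 0.2, std: float = 0.05,
                 trunc_stds: float = 2.0) -> NWKernelBank:
    """Draw an NW kernel bank from a truncated normal and normalise it.

    Entries come from N(mean, std^2) truncated at mean +/- trunc_stds * std
    (rejection sampling), then each kernel is rescaled to sum |w| = 1.
    Biases start at 0. Deterministic given ``seed``.
    """
    if t < 1 or k < 1 or c_in < 1:
        raise ValueError("t, k and c_in must all be >= 1")
    rng = np.random.default_rng(seed)
    shape = (t, c_in, 2 * k + 1, 2 * k + 1)
    w = _truncated_normal(rng, shape, mean, std, trunc_stds)
    bank = NWKernelBank(weights=w, biases=np.zeros(t))
    return normalize_kernels(bank)


def _truncated_normal(rng, shape, mean, std, trunc_stds):
    lo, hi = mean - trunc_stds * std, mean + trunc_stds * std
    out = rng.normal(mean, std, size=shape)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, std, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------

def nw_core(features: Tensor, masks: Tensor, weights: Tensor, biases: Tensor,
            eps: float = EPS) -> tuple[Tensor, Tensor]:
    """Differentiable NW operation on batched (N, C, H, W) tensors.

    ``weights`` must already satisfy sum |w| = 1 per kernel (trainable
    callers re-project before calling; see :class:`NWLayer`). Where the
    mask-weighted denominator falls below ``eps`` the window holds no
    informative pixel: the output is the bias alone and the updated map is 0,
    which keeps the forward pass total and the gradient finite.
    """
    k = (weights.shape[2] - 1) // 2
    num = ad.conv2d(features, weights, padding=k)
    den = ad.conv2d(masks, ad.absolute(weights), padding=k)
    support = (den.data > eps).astype(np.float64)
    den_safe = den + Tensor(1.0 - support)  # 1 where unsupported; grad-free shift
    t = weights.shape[0]
    r = (num / den_safe) * Tensor(support) + biases.reshape(1, t, 1, 1)
    m_up = ad.relu(den) * Tensor(support)
    return r, m_up


def nw_forward(features: np.ndarray, masks: np.ndarray,
               bank: NWKernelBank) -> tuple[np.ndarray, np.ndarray]:
    """Apply one NW layer to (C, H, W) features and sparsity maps.

    Returns the t reconstructed feature maps R and the t updated sparsity
    maps M_up, both (t, H, W) with the spatial size preserved by zero
    padding. The bank must be normalised; features of a binary input mask
    must be 0 wherever that mask is 0.
    """
    features = np.asarray(features, dtype=np.float64)
    masks = np.asarray(masks, dtype=np.float64)
    if features.ndim == 2:
        features, masks = features[None], masks[None]
    if features.shape != masks.shape:
        raise ValueError(f"features {features.shape} and masks {masks.shape} differ")
    if features.ndim != 3:
        raise ValueError("expected (C, H, W) features")
    if features.shape[0] != bank.in_channels:
        raise ValueError(f"bank expects {bank.in_channels} channels, "
                         f"got {features.shape[0]}")
    if not bank.is_normalized():
        raise ValueError("kernel bank is not normalised (sum |w| != 1); "
                         "apply normalize_kernels first")
    if np.any(masks < 0):
        raise ValueError("sparsity maps must be non-negative")
    binary = np.isin(masks, (0.0, 1.0)).all()
    if binary and np.any(features[masks == 0] != 0):
        raise ValueError("features must be 0 at masked-out pixels of a binary mask")
    r, m_up = nw_core(Tensor(features[None]), Tensor(masks[None]),
                      Tensor(bank.weights), Tensor(bank.biases))
    return r.data[0], m_up.data[0]


def nwnet_forward(sparse: SparseFrame, banks) -> np.ndarray:
    """Chain NW layers over a sparse frame; the final masks are discarded.

    The first layer consumes the sparse image and its binary mask; each
    subsequent layer consumes the previous layer's t feature maps and t
    updated sparsity maps. Consecutive banks must be channel-compatible.
    """
    banks = list(banks)
    if not banks:
        raise ValueError("need at least one kernel bank")
    feats = sparse.values[None]
    masks = sparse.mask[None]
    for n, bank in enumerate(banks):
        if bank.in_channels != feats.shape[0]:
            raise ValueError(
                f"layer {n} expects {bank.in_channels} channels but receives "
                f"{feats.shape[0]} (t of layer {n - 1})")
        feats, masks = nw_forward(feats, masks, bank)
    return feats
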