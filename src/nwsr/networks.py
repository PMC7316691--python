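"""Single-image super-resolution architectures for endomicroscopy.

Two residual networks share one trunk, differing only in their head:

* :class:`CNNnetSR` — a compact EDSR-style network for dense input (either a
  Cartesian reconstruction or the raw sparse image fed as an ordinary
  image). Because synthetic LR and HR frames share a grid there is no
  upsampling stage; in its place sits a 32-filter convolution, and the final
  layer is a 1x1 linearly-activated convolution fusing the feature maps
  into the output image. All other convolutions are 3x3.
* :class:`NWnetSR` — the same trunk, but the head is a stack of NW layers
  consuming the sparse image and its binary fibre mask. The first NW layer
  uses a 9x9 kernel (wide enough to capture several informative pixels at
  realistic fibre densities), deeper NW layers 3x3; after the last NW layer
  the sparsity maps are discarded and the dense trunk proceeds unchanged.

Corresponding layers of the two networks have identical parameter counts:
the NW layer shares its kernels between the feature and mask convolutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nw_layer import _truncated_normal, nw_core

__all__ = ["NetworkConfig", "Module", "Conv2d", "NWLayer", "ResBlock",
           "CNNnetSR", "NWnetSR", "build_cnnnet_sr", "build_nwnet_sr"]


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters shared by both architectures.

    Defaults target desk-scale CPU training; all fields are free to grow.
    """

    n_res_blocks: int = 8
    n_features: int = 32
    head_features: int = 32       # width of the conv replacing upsampling
    nw_first_kernel: int = 4      # half-width k: first NW layer is 9x9
    nw_deep_kernel: int = 1       # deeper NW layers are 3x3
    n_nw_layers: int = 2
    in_channels: int = 1
    res_scale: float | None = None  # optional EDSR residual scaling

    def __post_init__(self):
        counts = (self.n_res_blocks, self.n_features, self.head_features,
                  self.nw_first_kernel, self.nw_deep_kernel, self.n_nw_layers,
                  self.in_channels)
        if any(int(v) < 1 for v in counts):
            raise ValueError("all NetworkConfig counts must be >= 1")


class Module:
    """Base class tracking trainable parameters recursively."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=np.float64).reshape(p.shape)

    def named_parameters(self):
        out = []
        for key, value in self.__dict__.items():
            if isinstance(value, Tensor) and value.requires_grad:
                out.append((key, value))
            elif isinstance(value, Module):
                out.extend((f"{key}.{n}", p) for n, p in value.named_parameters())
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend((f"{key}.{i}.{n}", p)
                                   for n, p in item.named_parameters())
        return out


class Conv2d(Module):
    """Same-padded 2-D convolution layer with bias (He-initialised).

    ``zero_init`` starts the weights at 0 — used for the final fusing layer
    so the network output begins at its bias regardless of the activation
    scale reaching it, which keeps early training well conditioned.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, zero_init: bool = False):
        fan_in = in_channels * kernel_size ** 2
        scale = 0.0 if zero_init else np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, 1.0,
                                        (out_channels, in_channels,
                                         kernel_size, kernel_size)) * scale,
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.padding = kernel_size // 2

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, bias=self.bias, padding=self.padding)


class NWLayer(Module):
    """Trainable NW layer; weights are re-projected to sum|w|=1 each forward.

    Re-projecting at every forward (rather than after optimiser steps) keeps
    the normalisation invariant exact mid-training, and the gradient flows
    through the projection. Raw weights are drawn from the truncated normal
    N(0.2, 0.05^2) clipped at two standard deviations; biases start at 0.
    """

    def __init__(self, in_channels: int, n_kernels: int, half_width: int,
                 rng: np.random.Generator):
        shape = (n_kernels, in_channels, 2 * half_width + 1, 2 * half_width + 1)
        self.weight = Tensor(_truncated_normal(rng, shape, 0.2, 0.05, 2.0),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_kernels), requires_grad=True)
        self.half_width = half_width

    def projected_weight(self) -> Tensor:
        sums = ad.absolute(self.weight).sum(axis=(1, 2, 3), keepdims=True)
        return self.weight / sums

    def __call__(self, x: Tensor, mask: Tensor) -> tuple[Tensor, Tensor]:
        return nw_core(x, mask, self.projected_weight(), self.bias)


class ResBlock(Module):
    """conv -> ReLU -> conv with an additive skip (EDSR residual block)."""

    def __init__(self, n_features: int, rng: np.random.Generator,
                 res_scale: float | None = None):
        self.conv1 = Conv2d(n_features, n_features, 3, rng)
        self.conv2 = Conv2d(n_features, n_features, 3, rng)
        self.res_scale = res_scale

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv2(ad.relu(self.conv1(x)))
        if self.res_scale is not None:
            h = h * self.res_scale
        return x + h


class _Trunk(Module):
    """Residual blocks + global skip + pre-fusion conv + 1x1 fusing conv."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.blocks = [ResBlock(config.n_features, rng, config.res_scale)
                       for _ in range(config.n_res_blocks)]
        self.pre_fuse = Conv2d(config.n_features, config.head_features, 3, rng)
        # linear activation; zero-initialised so the output starts at the bias
        self.fuse = Conv2d(config.head_features, 1, 1, rng, zero_init=True)

    def __call__(self, h: Tensor) -> Tensor:
        x = h
        for block in self.blocks:
            x = block(x)
        x = x + h  # global skip
        return self.fuse(self.pre_fuse(x))


class CNNnetSR(Module):
    """EDSR-style SR network for dense (Cartesian or sparse-as-image) input."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.head = Conv2d(config.in_channels, config.n_features, 3, rng)
        self.trunk = _Trunk(config, rng)

    def __call__(self, x) -> Tensor:
        x = _as_batch(x)
        return self.trunk(self.head(x))

    def predict(self, frame: np.ndarray) -> np.ndarray:
        return self(frame[None, None]).data[0, 0]


class NWnetSR(Module):
    """CNNnetSR with the head replaced by a stack of NW layers."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        layers = []
        c_in = config.in_channels
        for n in range(config.n_nw_layers):
            k = config.nw_first_kernel if n == 0 else config.nw_deep_kernel
            layers.append(NWLayer(c_in, config.n_features, k, rng))
            c_in = config.n_features
        self.nw_layers = layers
        self.trunk = _Trunk(config, rng)

    def __call__(self, x, mask) -> Tensor:
        x, mask = _as_batch(x), _as_batch(mask)
        for layer in self.nw_layers:
            x, mask = layer(x, mask)
        # masks of the last NW layer are discarded; dense trunk follows
        return self.trunk(x)

    def predict(self, sparse: np.ndarray, mask: np.ndarray) -> np.ndarray:
        return self(sparse[None, None], mask[None, None]).data[0, 0]


def _as_batch(x) -> Tensor:
    x = ad.as_tensor(x)
    if x.ndim == 2:
        return x.reshape(1, 1, *x.shape)
    if x.ndim == 3:
        return x.reshape(1, *x.shape)
    if x.ndim != 4:
        raise ValueError(f"expected 2-4 dims, got shape {x.shape}")
    return x


def build_cnnnet_sr(config: NetworkConfig, seed: int = 0) -> CNNnetSR:
    return CNNnetSR(config, seed=seed)


def build_nwnet_sr(config: NetworkConfig, seed: int = 0) -> NWnetSR:
    return NWnetSR(config, seed=seed)
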