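"""Dataset preparation, the SSIM+L1 objective, training, and IQA.

Frames are normalised per frame by the LR frame's statistics (computed over
informative pixels only for sparse frames) and affinely mapped so the LR
informative values span [0, 1]; the HR frame uses the *same* map, so the
pair stays comparable and the map is invertible. Training minimises a mix
of structural dissimilarity and mean absolute error,

    loss = alpha * (1 - SSIM(pred, target)) + (1 - alpha) * L1(pred, target)

with Adam (beta1=0.9, beta2=0.999, eps=1e-8). Model selection runs a
sequential learning-rate grid over {1e-2 ... 1e-7}, keeping the rate with
the best validation loss. Image quality is assessed per frame by PSNR and
SSIM against the HR reference and aggregated as mean +/- std over the test
set; both metrics can be restricted to the circular field of view.

SSIM follows the standard formulation: an 11-tap Gaussian window with
sigma = 1.5, constants K1 = 0.01 and K2 = 0.03, local statistics without
sample-covariance correction, and border windows discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import convolve

from . import autodiff as ad
from .autodiff import Tensor
from .networks import Module

__all__ = [
    "FrameStats", "IQARecord", "TrainConfig", "Adam",
    "normalize_pair", "apply_frame_stats", "denormalize", "extract_patches",
    "ssim", "psnr", "ssim_l1_loss", "train", "train_lr_grid", "evaluate",
    "LEARNING_RATE_GRID",
]

#: Learning-rate grid 10^i, i in {-2 ... -7}, searched sequentially.
LEARNING_RATE_GRID = tuple(10.0 ** -i for i in range(2, 8))

_SSIM_WIN = 11
_SSIM_SIGMA = 1.5
_K1, _K2 = 0.01, 0.03


# ---------------------------------------------------------------------------
# Normalisation and patching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameStats:
    """Per-frame normalisation parameters (LR statistics + [0,1] rescale)."""

    mean_lr: float
    std_lr: float
    scale_bounds: tuple[float, float]

    def __post_init__(self):
        lo, hi = self.scale_bounds
        if self.std_lr <= 0 or hi <= lo:
            raise ValueError("degenerate frame statistics")


def normalize_pair(lr: np.ndarray, hr: np.ndarray,
                   mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, FrameStats]:
    """Standardise an LR/HR pair by the LR frame's informative-pixel stats.

    Both frames are shifted/scaled by mean and std of the LR values where
    ``mask`` is set, then mapped affinely so the LR informative values span
    exactly [0, 1]. Sparse zeros outside the mask are re-imposed on the LR
    frame. The returned stats invert the whole map via :func:`denormalize`.
    """
    lr = np.asarray(lr, dtype=np.float64)
    hr = np.asarray(hr, dtype=np.float64)
    m = np.asarray(mask) > 0
    vals = lr[m]
    if vals.size == 0:
        raise ValueError("mask selects no informative pixels")
    mean, std = float(vals.mean()), float(vals.std())
    if std == 0:
        raise ValueError("LR frame is constant over informative pixels")
    z = (vals - mean) / std
    lo, hi = float(z.min()), float(z.max())
    stats = FrameStats(mean_lr=mean, std_lr=std, scale_bounds=(lo, hi))
    lr_out = apply_frame_stats(lr, stats)
    lr_out[~m] = 0.0
    return lr_out, apply_frame_stats(hr, stats), stats


def apply_frame_stats(frame: np.ndarray, stats: FrameStats) -> np.ndarray:
    """Apply an LR-derived normalisation map to any frame of the same video."""
    lo, hi = stats.scale_bounds
    z = (np.asarray(frame, dtype=np.float64) - stats.mean_lr) / stats.std_lr
    return (z - lo) / (hi - lo)


def denormalize(frame: np.ndarray, stats: FrameStats) -> np.ndarray:
    lo, hi = stats.scale_bounds
    return (np.asarray(frame, dtype=np.float64) * (hi - lo) + lo) * stats.std_lr \
        + stats.mean_lr


def extract_patches(frame: np.ndarray, mask: np.ndarray,
                    size: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Cut aligned non-overlapping square patches (row-major; remainder dropped)."""
    frame = np.asarray(frame)
    mask = np.asarray(mask)
    if frame.shape != mask.shape:
        raise ValueError("frame and mask shapes differ")
    h, w = frame.shape
    if h < size or w < size:
        raise ValueError(f"frame {frame.shape} smaller than patch size {size}")
    nr, nc = h // size, w // size
    f = frame[:nr * size, :nc * size].reshape(nr, size, nc, size)
    m = mask[:nr * size, :nc * size].reshape(nr, size, nc, size)
    return (f.transpose(0, 2, 1, 3).reshape(-1, size, size),
            m.transpose(0, 2, 1, 3).reshape(-1, size, size))


# ---------------------------------------------------------------------------
# Image quality metrics
# ---------------------------------------------------------------------------

def _gaussian_window(size: int = _SSIM_WIN, sigma: float = _SSIM_SIGMA) -> np.ndarray:
    half = (size - 1) // 2
    g = np.exp(-np.arange(-half, half + 1) ** 2 / (2.0 * sigma ** 2))
    g /= g.sum()
    return np.outer(g, g)


def psnr(a: np.ndarray, b: np.ndarray, data_range: float = 1.0,
         mask: np.ndarray | None = None) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical frames."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("frame shapes differ")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    err = (a - b) ** 2
    mse = float(err[np.asarray(mask) > 0].mean()) if mask is not None \
        else float(err.mean())
    if mse == 0:
        return float("inf")
    return 10.0 * np.log10(data_range ** 2 / mse)


def _ssim_map(a: np.ndarray, b: np.ndarray, data_range: float) -> np.ndarray:
    win = _gaussian_window()
    ua = convolve(a, win, mode="valid")
    ub = convolve(b, win, mode="valid")
    uaa = convolve(a * a, win, mode="valid")
    ubb = convolve(b * b, win, mode="valid")
    uab = convolve(a * b, win, mode="valid")
    va, vb = uaa - ua * ua, ubb - ub * ub
    vab = uab - ua * ub
    c1 = (_K1 * data_range) ** 2
    c2 = (_K2 * data_range) ** 2
    return ((2 * ua * ub + c1) * (2 * vab + c2)) / \
        ((ua * ua + ub * ub + c1) * (va + vb + c2))


def ssim(a: np.ndarray, b: np.ndarray, data_range: float = 1.0,
         mask: np.ndarray | None = None) -> float:
    """Mean structural similarity between two frames.

    With ``mask`` the local-SSIM map is averaged only over windows centred
    inside the mask (border windows are always discarded).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("frame shapes differ")
    smap = _ssim_map(a, b, data_range)
    if mask is None:
        return float(smap.mean())
    half = (_SSIM_WIN - 1) // 2
    inner = np.asarray(mask)[half:-half, half:-half] > 0
    if not inner.any():
        raise ValueError("mask selects no interior windows")
    return float(smap[inner].mean())


def ssim_l1_loss(pred, target, alpha: float = 0.84, data_range: float = 1.0):
    """Differentiable alpha*(1 - SSIM) + (1-alpha)*L1 objective.

    Accepts (H, W) or (N, 1, H, W) inputs; ``pred`` may be a Tensor, in which
    case the result is a Tensor suitable for ``backward()``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    p = ad.as_tensor(pred)
    t = ad.as_tensor(target)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if p.ndim == 2:
        p = p.reshape(1, 1, *p.shape)
        t = t.reshape(1, 1, *t.shape)
    win = Tensor(_gaussian_window()[None, None])
    c1 = (_K1 * data_range) ** 2
    c2 = (_K2 * data_range) ** 2
    up = ad.conv2d(p, win)
    ut = ad.conv2d(t, win)
    vp = ad.conv2d(p * p, win) - up * up
    vt = ad.conv2d(t * t, win) - ut * ut
    vpt = ad.conv2d(p * t, win) - up * ut
    smap = ((2.0 * up * ut + c1) * (2.0 * vpt + c2)) / \
        ((up * up + ut * ut + c1) * (vp + vt + c2))
    loss = alpha * (1.0 - smap.mean()) + (1.0 - alpha) * ad.absolute(p - t).mean()
    return loss if isinstance(pred, Tensor) or _requires_graph(pred) else loss.item()


def _requires_graph(x) -> bool:
    return isinstance(x, Tensor) and (x.requires_grad or x._parents != ())


# ---------------------------------------------------------------------------
# Optimisation
# ---------------------------------------------------------------------------

class Adam:
    """Adam optimiser (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    steps: int = 200
    batch_size: int = 8
    alpha: float = 0.84        # SSIM weight in the mixed loss
    data_range: float = 1.0
    seed: int = 0
    loss: str = "ssim_l1"      # or "l1", "mse"
    val_interval: int = 0      # 0 disables validation-based early stopping
    patience: int = 2          # stop after this many non-improving checks
    min_delta: float = 1e-3    # improvement threshold for the val loss


def _batch_loss(network: Module, inputs, targets, idx, config: TrainConfig) -> Tensor:
    tgt = Tensor(targets[idx][:, None])
    if isinstance(inputs, tuple):
        pred = network(Tensor(inputs[0][idx][:, None]), Tensor(inputs[1][idx][:, None]))
    else:
        pred = network(Tensor(inputs[idx][:, None]))
    if config.loss == "ssim_l1":
        return ssim_l1_loss(pred, tgt, alpha=config.alpha,
                            data_range=config.data_range)
    diff = pred - tgt
    if config.loss == "l1":
        return ad.absolute(diff).mean()
    if config.loss == "mse":
        return (diff * diff).mean()
    raise ValueError(f"unknown loss {config.loss!r}")


def train(network: Module, inputs, targets: np.ndarray, config: TrainConfig,
          val_inputs=None, val_targets=None) -> list[float]:
    """Minimise the configured loss over shuffled mini-batches.

    ``inputs`` is an (N, H, W) array for dense networks or a tuple
    ``(sparse, mask)`` of such arrays for NW networks; ``targets`` the
    aligned HR patches. With a validation set and ``config.val_interval``
    set, the validation loss is checked periodically: training stops once
    it has not improved by ``min_delta`` for ``patience`` checks and the
    best-scoring parameters are restored. Returns the per-step loss
    history. Deterministic given ``config.seed``. Raises on an empty
    dataset or a NaN loss.
    """
    n = targets.shape[0] if hasattr(targets, "shape") else len(targets)
    if n == 0:
        raise ValueError("empty training dataset")
    use_val = val_targets is not None and config.val_interval > 0
    rng = np.random.default_rng(config.seed)
    optimiser = Adam(network.parameters(), lr=config.lr)
    order = rng.permutation(n)
    cursor = 0
    history: list[float] = []
    best_val, best_state, stale = np.inf, None, 0
    for step in range(config.steps):
        if cursor + config.batch_size > n:
            order = rng.permutation(n)
            cursor = 0
        idx = order[cursor:cursor + config.batch_size]
        cursor += config.batch_size
        optimiser.zero_grad()
        loss = _batch_loss(network, inputs, targets, idx, config)
        value = loss.item()
        if not np.isfinite(value):
            raise RuntimeError(
                f"non-finite loss {value} at step {step} (lr={config.lr}); "
                "check input normalisation or lower the learning rate")
        loss.backward()
        optimiser.step()
        history.append(value)
        if use_val and (step + 1) % config.val_interval == 0:
            val = validation_loss(network, val_inputs, val_targets, config)
            if val < best_val - config.min_delta:
                best_val, best_state, stale = val, network.state_dict(), 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
    if use_val:
        final_val = validation_loss(network, val_inputs, val_targets, config)
        if best_state is not None and final_val > best_val:
            network.load_state_dict(best_state)
    return history


def validation_loss(network: Module, inputs, targets: np.ndarray,
                    config: TrainConfig, batch_size: int = 8) -> float:
    """Average loss over a held-out set, evaluated without training."""
    n = targets.shape[0]
    total = 0.0
    for start in range(0, n, batch_size):
        idx = np.arange(start, min(start + batch_size, n))
        total += _batch_loss(network, inputs, targets, idx, config).item() * len(idx)
    return total / n


def train_lr_grid(make_network, inputs, targets, val_inputs, val_targets,
                  config: TrainConfig, grid_steps: int,
                  learning_rates=LEARNING_RATE_GRID):
    """Sequential learning-rate search, then fine-tune the winner.

    For each candidate rate a fresh network (from ``make_network()``) trains
    for ``grid_steps`` steps; the rate with the lowest validation loss is
    then trained for the remaining ``config.steps - grid_steps`` steps.
    Returns ``(network, info)`` where info records per-rate validation
    losses, the selected rate and the loss history of the final model.
    """
    scores: dict[float, float] = {}
    best_net, best_lr, best_val = None, None, np.inf
    for lr in learning_rates:
        net = make_network()
        cfg = replace(config, lr=lr, steps=grid_steps)
        try:
            train(net, inputs, targets, cfg)
            val = validation_loss(net, val_inputs, val_targets, cfg)
        except RuntimeError:  # diverged at this rate
            val = np.inf
        scores[lr] = val
        if val < best_val:
            best_net, best_lr, best_val = net, lr, val
    if best_net is None:
        raise RuntimeError("all learning rates diverged")
    checkpoint = best_net.state_dict()
    try:
        history = train(best_net, inputs, targets,
                        replace(config, lr=best_lr,
                                steps=max(config.steps - grid_steps, 0)),
                        val_inputs=val_inputs, val_targets=val_targets)
    except RuntimeError:
        # fine-tuning diverged late; keep the grid-phase weights
        best_net.load_state_dict(checkpoint)
        history = [best_val]
    return best_net, {"lr_scores": scores, "selected_lr": best_lr,
                      "history": history}


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class IQARecord:
    """Per-frame PSNR/SSIM values with mean +/- std aggregation."""

    per_frame: list[tuple[float, float]] = field(default_factory=list)

    def add(self, psnr_db: float, ssim_score: float):
        self.per_frame.append((float(psnr_db), float(ssim_score)))

    @property
    def psnr_values(self) -> np.ndarray:
        return np.array([p for p, _ in self.per_frame])

    @property
    def ssim_values(self) -> np.ndarray:
        return np.array([s for _, s in self.per_frame])

    @property
    def mean_psnr(self) -> float:
        return float(self.psnr_values.mean())

    @property
    def std_psnr(self) -> float:
        return float(self.psnr_values.std())

    @property
    def mean_ssim(self) -> float:
        return float(self.ssim_values.mean())

    @property
    def std_ssim(self) -> float:
        return float(self.ssim_values.std())

    @property
    def has_infinite_psnr(self) -> bool:
        return bool(np.isinf(self.psnr_values).any())

    def summary(self) -> str:
        return (f"SSIM {self.mean_ssim:.3f} +/- {self.std_ssim:.3f}   "
                f"PSNR {self.mean_psnr:.2f} +/- {self.std_psnr:.2f} dB")


def evaluate(predict, testset, data_range: float = 1.0,
             fov: np.ndarray | None = None,
             reference=lambda item: item.hr) -> IQARecord:
    """Score a reconstruction method frame by frame against HR references.

    ``predict`` maps one test item to a reconstructed 2-D frame;
    ``reference`` extracts the HR frame from the item. Metrics are computed
    on full-size frames at the given intensity ``data_range``, optionally
    restricted to the circular FoV mask, and aggregated as mean +/- std.
    """
    record = IQARecord()
    for item in testset:
        pred = np.asarray(predict(item), dtype=np.float64)
        ref = np.asarray(reference(item), dtype=np.float64)
        record.add(psnr(pred, ref, data_range=data_range, mask=fov),
                   ssim(pred, ref, data_range=data_range, mask=fov))
    if not record.per_frame:
        raise ValueError("empty test set")
    return record


def iqa_table(records: dict[str, IQARecord]) -> str:
    """Render records as a comparison table (model, SSIM, PSNR columns)."""
    lines = [f"{'Model name':<18}{'SSIM':<18}PSNR"]
    for name, rec in records.items():
        lines.append(f"{name:<18}"
                     f"{rec.mean_ssim:.3f} ± {rec.std_ssim:.3f}     "
                     f"{rec.mean_psnr:.2f} ± {rec.std_psnr:.2f}")
    return "\n".join(lines)


def iqa_csv(records: dict[str, IQARecord], path):
    """Write per-frame scores plus summary rows as CSV."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["model", "frame_id", "psnr_db", "ssim"])
        for name, rec in records.items():
            for i, (p, s) in enumerate(rec.per_frame):
                writer.writerow([name, i, f"{p:.6f}", f"{s:.6f}"])
            writer.writerow([name, "mean±std",
                             f"{rec.mean_psnr:.6f}±{rec.std_psnr:.6f}",
                             f"{rec.mean_ssim:.6f}±{rec.std_ssim:.6f}"])
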