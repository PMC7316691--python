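"""End-to-end orchestration: simulation, training and the comparative study.

The comparative study mirrors the evaluation protocol of the package's
scientific question: given paired synthetic LR/HR endomicroscopy videos,
how do classical scattered-data reconstructions compare with
super-resolution networks fed (a) the Cartesian reconstruction, (b) the raw
sparse image, and (c) the sparse image plus mask through NW layers?

Five methods are scored with per-frame PSNR/SSIM on held-out videos:

* LINEAR BASELINE — Delaunay linear interpolation (clinical reference)
* GAUSS BASELINE  — handcrafted-Gaussian NW regression
* CARTESIAN       — CNNnetSR trained on Delaunay reconstructions
* SPARSE          — CNNnetSR trained on sparse images
* NWNET           — NWnetSR trained on sparse images + masks
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .baselines import delaunay_linear, nw_gaussian_reconstruct
from .fiber_model import (CellMap, FiberLayout, SparseFrame, add_noise,
                          build_cellmap, downsample_to_fibers, extract_hr_frames,
                          fov_mask, generate_fiber_layout, signals_to_sparse)
from .fixtures import generate_fixture_image
from .networks import NetworkConfig, build_cnnnet_sr, build_nwnet_sr
from .training_eval import (TrainConfig, apply_frame_stats,
                            denormalize, evaluate, extract_patches,
                            normalize_pair, train_lr_grid)

__all__ = ["VideoData", "StudyConfig", "simulate_video", "make_study_videos",
           "build_training_arrays", "run_comparative_study", "METHOD_NAMES"]

METHOD_NAMES = ("GAUSS BASELINE", "LINEAR BASELINE", "CARTESIAN", "SPARSE", "NWNET")


@dataclass
class VideoData:
    """One synthetic video: geometry, HR frames and their sparse LR frames."""

    layout: FiberLayout
    cellmap: CellMap
    hr: np.ndarray                      # (F, H, W) clean HR frames
    signals: np.ndarray                 # (F, n_fibers) noisy LR fibre signals
    sparse: list[SparseFrame] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.hr.shape[0]

    def linear_recon(self, frame: int) -> np.ndarray:
        return delaunay_linear(self.sparse[frame])

    def gauss_recon(self, frame: int) -> np.ndarray:
        return nw_gaussian_reconstruct(self.sparse[frame])


def simulate_video(source_image: np.ndarray, n_fibers: int,
                   grid_shape: tuple[int, int], jitter: float = 0.15,
                   sigma_mult: float = 0.05, sigma_add: float = 0.02,
                   seed: int = 0) -> VideoData:
    """Turn one source image into a paired LR/HR synthetic video.

    HR frames are cropped with the sliding FoV box; each frame is Voronoi
    downsampled to fibre signals, corrupted with multiplicative and additive
    noise, and scattered back onto the grid as a sparse frame.
    """
    seeds = np.random.SeedSequence(seed).generate_state(2)
    layout = generate_fiber_layout(n_fibers, grid_shape, jitter=jitter,
                                   seed=int(seeds[0] % (2 ** 31)))
    cellmap = build_cellmap(layout)
    hr = extract_hr_frames(source_image, layout)
    frame_seeds = np.random.SeedSequence(int(seeds[1] % (2 ** 31))).generate_state(
        hr.shape[0])
    signals = []
    sparse = []
    for f in range(hr.shape[0]):
        clean = downsample_to_fibers(hr[f], cellmap)
        noisy = add_noise(clean, sigma_mult=sigma_mult, sigma_add=sigma_add,
                          seed=int(frame_seeds[f] % (2 ** 31)))
        signals.append(noisy)
        sparse.append(signals_to_sparse(noisy, layout))
    return VideoData(layout=layout, cellmap=cellmap, hr=hr,
                     signals=np.stack(signals), sparse=sparse)


@dataclass(frozen=True)
class StudyConfig:
    """Scale and hyperparameters of the desk-scale comparative study."""

    n_videos: int = 10
    source_size: int = 384
    grid_size: int = 128
    n_fibers: int = 1500   # fill ~0.12: >10 informative pixels per 9x9 window
    jitter: float = 0.15
    sigma_mult: float = 0.05
    sigma_add: float = 0.02
    n_train_videos: int = 7
    n_val_videos: int = 1
    patch_size: int = 64
    network: NetworkConfig = NetworkConfig(n_res_blocks=2, n_features=16)
    steps: int = 550
    grid_steps: int = 25
    batch_size: int = 8
    alpha: float = 0.84
    val_interval: int = 75
    max_train_patches: int = 700


def make_study_videos(seed: int, config: StudyConfig) -> list[VideoData]:
    """Simulate the full set of synthetic videos for one study run."""
    video_seeds = np.random.SeedSequence([seed, 17]).generate_state(
        2 * config.n_videos)
    videos = []
    for v in range(config.n_videos):
        source = generate_fixture_image(config.source_size, config.source_size,
                                        seed=int(video_seeds[2 * v] % (2 ** 31)))
        videos.append(simulate_video(
            source, n_fibers=config.n_fibers,
            grid_shape=(config.grid_size, config.grid_size),
            jitter=config.jitter, sigma_mult=config.sigma_mult,
            sigma_add=config.sigma_add,
            seed=int(video_seeds[2 * v + 1] % (2 ** 31))))
    return videos


def _frame_tensors(video: VideoData, frame: int):
    """Normalised (sparse, cartesian, hr, mask, stats) for one frame."""
    sp = video.sparse[frame]
    lr_n, hr_n, stats = normalize_pair(sp.values, video.hr[frame], sp.mask)
    cart_n = apply_frame_stats(video.linear_recon(frame), stats)
    return lr_n, cart_n, hr_n, sp.mask, stats


def build_training_arrays(videos, config: StudyConfig, seed: int = 0):
    """Patch arrays for all three model inputs, aligned on the same targets.

    Returns a dict with keys 'cartesian', 'sparse', 'mask', 'target', each an
    (N, p, p) array of normalised 64x64 patches. Patches are subsampled to
    ``max_train_patches`` with a seeded permutation to bound training cost.
    """
    cart_p, sparse_p, mask_p, hr_p = [], [], [], []
    for video in videos:
        for f in range(video.n_frames):
            lr_n, cart_n, hr_n, mask, _ = _frame_tensors(video, f)
            sp, mp = extract_patches(lr_n, mask, config.patch_size)
            cp, _ = extract_patches(cart_n, mask, config.patch_size)
            hp, _ = extract_patches(hr_n, mask, config.patch_size)
            sparse_p.append(sp)
            mask_p.append(mp)
            cart_p.append(cp)
            hr_p.append(hp)
    arrays = {
        "cartesian": np.concatenate(cart_p),
        "sparse": np.concatenate(sparse_p),
        "mask": np.concatenate(mask_p),
        "target": np.concatenate(hr_p),
    }
    n = arrays["target"].shape[0]
    if n > config.max_train_patches:
        keep = np.random.default_rng(seed).permutation(n)[:config.max_train_patches]
        arrays = {k: v[keep] for k, v in arrays.items()}
    return arrays


def _eval_items(videos):
    items = []
    for video in videos:
        for f in range(video.n_frames):
            items.append((video, f))
    return items


def _model_predict(model, kind):
    def predict(item):
        video, f = item
        lr_n, cart_n, hr_n, mask, stats = _frame_tensors(video, f)
        if kind == "cartesian":
            out = model.predict(cart_n)
        elif kind == "sparse":
            out = model.predict(lr_n)
        else:
            out = model.predict(lr_n, mask)
        return denormalize(out, stats)

    return predict


def run_comparative_study(seed: int, config: StudyConfig | None = None,
                          verbose: bool = False):
    """Run the full scaled-down comparative study.

    Simulates the synthetic videos, trains CARTESIAN, SPARSE and NWNET with
    the learning-rate grid, and scores all five methods on the held-out
    videos. Returns ``(records, info)``: a name -> IQARecord mapping and a
    dict with the split sizes and selected learning rates.
    """
    config = config or StudyConfig()
    videos = make_study_videos(seed, config)
    n_tr, n_val = config.n_train_videos, config.n_val_videos
    train_videos = videos[:n_tr]
    val_videos = videos[n_tr:n_tr + n_val]
    test_videos = videos[n_tr + n_val:]
    if not test_videos:
        raise ValueError("study config leaves no held-out test videos")

    arrays = build_training_arrays(train_videos, config, seed=seed + 1)
    val_arrays = build_training_arrays(
        val_videos, dataclasses.replace(config, max_train_patches=96),
        seed=seed + 2)

    tcfg = TrainConfig(steps=config.steps, batch_size=config.batch_size,
                       alpha=config.alpha, seed=seed + 3,
                       val_interval=config.val_interval)
    model_inputs = {
        "cartesian": (arrays["cartesian"], val_arrays["cartesian"]),
        "sparse": (arrays["sparse"], val_arrays["sparse"]),
        "nwnet": ((arrays["sparse"], arrays["mask"]),
                  (val_arrays["sparse"], val_arrays["mask"])),
    }
    builders = {
        "cartesian": lambda: build_cnnnet_sr(config.network, seed=seed + 10),
        "sparse": lambda: build_cnnnet_sr(config.network, seed=seed + 11),
        "nwnet": lambda: build_nwnet_sr(config.network, seed=seed + 12),
    }
    models, info = {}, {"split": {"train": n_tr, "val": n_val,
                                  "test": len(test_videos)}}
    for kind in ("cartesian", "sparse", "nwnet"):
        tr_in, val_in = model_inputs[kind]
        model, fit_info = train_lr_grid(
            builders[kind], tr_in, arrays["target"], val_in,
            val_arrays["target"], tcfg, grid_steps=config.grid_steps)
        models[kind] = model
        info[kind] = {"selected_lr": fit_info["selected_lr"],
                      "final_loss": fit_info["history"][-1]}
        if verbose:
            print(f"{kind}: lr={fit_info['selected_lr']:g} "
                  f"final loss={fit_info['history'][-1]:.4f}")

    items = _eval_items(test_videos)
    fov = fov_mask(test_videos[0].layout)
    records = {
        "GAUSS BASELINE": evaluate(lambda it: it[0].gauss_recon(it[1]), items,
                                   fov=fov, reference=lambda it: it[0].hr[it[1]]),
        "LINEAR BASELINE": evaluate(lambda it: it[0].linear_recon(it[1]), items,
                                    fov=fov, reference=lambda it: it[0].hr[it[1]]),
        "CARTESIAN": evaluate(_model_predict(models["cartesian"], "cartesian"),
                              items, fov=fov, reference=lambda it: it[0].hr[it[1]]),
        "SPARSE": evaluate(_model_predict(models["sparse"], "sparse"), items,
                           fov=fov, reference=lambda it: it[0].hr[it[1]]),
        "NWNET": evaluate(_model_predict(models["nwnet"], "nwnet"), items,
                          fov=fov, reference=lambda it: it[0].hr[it[1]]),
    }
    info["models"] = models
    return records, info
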