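"""File formats: layout sidecars, 16-bit frames, dataset bundles, configs.

Datasets live one directory per synthetic video:

    video_000/
        layout.json       fibre positions, FoV bbox, grid shape
        hr/000.png ...    16-bit greyscale HR frames
        lr_sparse.npz     arrays lr_sparse (F,H,W), mask (H,W), hr (F,H,W)

16-bit PNG avoids visible quantisation of the [0, 1] intensity range.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .fiber_model import FiberLayout

__all__ = ["save_layout", "load_layout", "save_frame_png", "load_frame_png",
           "save_video_bundle", "load_video_bundle", "load_config", "save_config"]

_PNG_SCALE = 65535.0


def save_layout(layout: FiberLayout, path):
    payload = {
        "positions": np.asarray(layout.positions).tolist(),
        "fov_bbox": list(layout.fov_bbox),
        "grid_shape": list(layout.grid_shape),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_layout(path) -> FiberLayout:
    payload = json.loads(Path(path).read_text())
    return FiberLayout(positions=np.array(payload["positions"]),
                       fov_bbox=tuple(payload["fov_bbox"]),
                       grid_shape=tuple(payload["grid_shape"]))


def save_frame_png(frame: np.ndarray, path):
    """Write a [0, 1] frame as 16-bit greyscale PNG (values clipped)."""
    data = np.clip(np.asarray(frame, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(data * _PNG_SCALE).astype(np.uint16),
                extension=".png")


def load_frame_png(path) -> np.ndarray:
    return iio.imread(Path(path)).astype(np.float64) / _PNG_SCALE


def save_video_bundle(directory, layout: FiberLayout, hr: np.ndarray,
                      lr_sparse: np.ndarray, mask: np.ndarray):
    """Write one synthetic video: layout sidecar, HR PNGs, NPZ arrays."""
    directory = Path(directory)
    (directory / "hr").mkdir(parents=True, exist_ok=True)
    save_layout(layout, directory / "layout.json")
    for i, frame in enumerate(hr):
        save_frame_png(frame, directory / "hr" / f"{i:03d}.png")
    np.savez(directory / "lr_sparse.npz", lr_sparse=lr_sparse, mask=mask, hr=hr)


def load_video_bundle(directory):
    """Read a video directory back as (layout, hr, lr_sparse, mask)."""
    directory = Path(directory)
    layout = load_layout(directory / "layout.json")
    with np.load(directory / "lr_sparse.npz") as data:
        return layout, data["hr"], data["lr_sparse"], data["mask"]


def save_config(config: dict, path):
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def load_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
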