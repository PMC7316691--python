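"""Simulation of fibre-bundle endomicroscopy acquisition.

A probe-based confocal laser endomicroscope (pCLE) images tissue through a
coherent bundle of optical fibres whose cores are distributed across the
field of view (FoV) in a quasi-hexagonal, irregular pattern. Each fibre
yields one scalar signal per frame, so the native sampling is irregular and
much sparser than the Cartesian grid the clinical display uses.

This module emulates that acquisition on synthetic data:

* :func:`generate_fiber_layout` draws a jittered hexagonal fibre layout
  inside a circular FoV (a stand-in for real bundle metadata);
* :func:`extract_hr_frames` cuts overlapping high-resolution (HR) frames out
  of a large source image by sliding the FoV bounding box in half-box steps;
* :func:`build_cellmap` assigns every grid pixel to its nearest fibre (the
  Voronoi tessellation of the layout);
* :func:`downsample_to_fibers` simulates signal loss by averaging each
  Voronoi cell into a single fibre signal;
* :func:`add_noise` applies multiplicative (calibration) and additive
  (acquisition) Gaussian noise to the fibre signals;
* :func:`signals_to_sparse` scatters the signals back onto the Cartesian
  grid as a sparse image plus binary mask — the native input representation
  of the sparse reconstruction networks.

Coordinates are 0-based (row, col) with pixel centres at integer positions;
continuous fibre positions are discretised by rounding half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "FiberLayout", "SparseFrame", "CellMap",
    "generate_fiber_layout", "extract_hr_frames", "build_cellmap",
    "downsample_to_fibers", "add_noise", "signals_to_sparse",
    "fov_mask", "rgb_to_gray",
]

#: Rec. 601 luma weights used for RGB -> greyscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])

# Default noise levels for signals scaled to [0, 1].
DEFAULT_SIGMA_MULT = 0.05
DEFAULT_SIGMA_ADD = 0.02


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (numpy's default rounds half to even)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def rgb_to_gray(image: np.ndarray) -> np.ndarray:
    """Convert an (H, W, 3) RGB image to greyscale; pass greyscale through."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[-1] == 3:
        return image @ _LUMA
    raise ValueError(f"expected (H, W) or (H, W, 3) image, got {image.shape}")


@dataclass(frozen=True)
class FiberLayout:
    """Fibre centre coordinates and FoV geometry of one synthetic bundle.

    positions : (n, 2) float array of continuous (row, col) coordinates.
    fov_bbox  : (height, width) of the FoV bounding box; frames cut from
                source images have this size.
    grid_shape: (H, W) of the discretised Cartesian grid the sparse images
                live on.
    """

    positions: np.ndarray
    fov_bbox: tuple[int, int]
    grid_shape: tuple[int, int]

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=np.float64))
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array of (row, col)")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "fov_bbox", tuple(int(v) for v in self.fov_bbox))
        object.__setattr__(self, "grid_shape", tuple(int(v) for v in self.grid_shape))
        h, w = self.fov_bbox
        gh, gw = self.grid_shape
        if h > gh or w > gw:
            raise ValueError("fov_bbox does not fit inside grid_shape")
        if np.any(pos < -0.5) or np.any(pos[:, 0] > h - 0.5) or np.any(pos[:, 1] > w - 0.5):
            raise ValueError("fibre positions must lie inside fov_bbox")
        pix = self.pixel_positions
        keys = pix[:, 0] * gw + pix[:, 1]
        if len(np.unique(keys)) != len(keys):
            raise ValueError("two fibres discretise to the same grid pixel")

    @property
    def n_fibers(self) -> int:
        return self.positions.shape[0]

    @property
    def pixel_positions(self) -> np.ndarray:
        """Discretised (row, col) integer pixel of each fibre."""
        return _round_half_away(self.positions).astype(np.int64)

    @property
    def fov_center(self) -> tuple[float, float]:
        return ((self.grid_shape[0] - 1) / 2.0, (self.grid_shape[1] - 1) / 2.0)

    @property
    def fov_radius(self) -> float:
        return min(self.fov_bbox) / 2.0

    def mean_spacing(self) -> float:
        """Mean nearest-neighbour distance between fibre centres."""
        if self.n_fibers < 2:
            raise ValueError("spacing needs at least two fibres")
        d, _ = cKDTree(self.positions).query(self.positions, k=2)
        return float(d[:, 1].mean())


@dataclass(frozen=True)
class SparseFrame:
    """Sparse Cartesian image S plus binary mask M of informative pixels."""

    values: np.ndarray
    mask: np.ndarray
    layout_ref: FiberLayout

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        mask = np.asarray(self.mask)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask.astype(np.float64))
        if values.shape != mask.shape:
            raise ValueError("values and mask shapes differ")
        if values.shape != self.layout_ref.grid_shape:
            raise ValueError("frame shape differs from layout grid_shape")
        if not np.isin(mask, (0, 1)).all():
            raise ValueError("mask must be binary")
        if np.any(values[mask == 0] != 0):
            raise ValueError("values must be 0 at non-informative pixels")

    def fiber_signals(self) -> np.ndarray:
        """Read the signal vector back out of the grid, in fibre order."""
        pix = self.layout_ref.pixel_positions
        return self.values[pix[:, 0], pix[:, 1]]


@dataclass(frozen=True)
class CellMap:
    """Per-pixel nearest-fibre labels (the discretised Voronoi diagram)."""

    labels: np.ndarray
    layout_ref: FiberLayout = field(repr=False)

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        if labels.shape != self.layout_ref.grid_shape:
            raise ValueError("labels shape differs from layout grid_shape")

    def cell_sizes(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=self.layout_ref.n_fibers)


# ---------------------------------------------------------------------------
# Layout generation
# ---------------------------------------------------------------------------

def _hex_lattice(center: tuple[float, float], spacing: float, radius: float) -> np.ndarray:
    """Points of a hexagonal lattice with one node at `center`, within `radius`."""
    row_step = spacing * np.sqrt(3.0) / 2.0
    n_rows = int(np.ceil(radius / row_step)) + 1
    pts = []
    for i in range(-n_rows, n_rows + 1):
        r = center[0] + i * row_step
        offset = 0.0 if i % 2 == 0 else spacing / 2.0
        n_cols = int(np.ceil(radius / spacing)) + 1
        for j in range(-n_cols, n_cols + 1):
            c = center[1] + offset + j * spacing
            pts.append((r, c))
    pts = np.array(pts)
    keep = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1]) <= radius
    return pts[keep]


def generate_fiber_layout(n_fibers: int, grid_shape: tuple[int, int],
                          jitter: float = 0.15, seed: int = 0) -> FiberLayout:
    """Generate a pseudo-hexagonal fibre layout inside a circular FoV.

    Real bundles pack their cores quasi-hexagonally; this emulates that with
    a hexagonal lattice inscribed in the FoV circle, each node perturbed by
    uniform jitter of ±``jitter`` lattice spacings per axis. The ``n_fibers``
    lattice nodes closest to the FoV centre are kept, so ``jitter=0`` with
    ``n_fibers=7`` yields a perfect central hexagon. Fibres whose jittered
    positions would round to an already occupied pixel are re-jittered.

    Deterministic given ``seed``.
    """
    if n_fibers < 3:
        raise ValueError("need at least 3 fibres for triangulation")
    if not 0.0 <= jitter < 0.5:
        raise ValueError("jitter must lie in [0, 0.5)")
    gh, gw = (int(v) for v in grid_shape)
    center = ((gh - 1) / 2.0, (gw - 1) / 2.0)
    radius = min(gh, gw) / 2.0 - 1.0
    if radius <= 1.0:
        raise ValueError("grid too small for a fibre field of view")

    # Spacing so the FoV circle holds ~30% more lattice nodes than requested,
    # leaving a margin to keep the n nearest nodes well inside the circle.
    density = 1.3 * n_fibers / (np.pi * radius ** 2)
    spacing = np.sqrt(2.0 / (np.sqrt(3.0) * density))
    lattice = _hex_lattice(center, spacing, radius)
    while len(lattice) < n_fibers:
        spacing *= 0.95
        lattice = _hex_lattice(center, spacing, radius)
        if spacing < 1.5:
            raise ValueError(
                f"grid {grid_shape} too small to place {n_fibers} collision-free fibres")
    dist = np.hypot(lattice[:, 0] - center[0], lattice[:, 1] - center[1])
    order = np.lexsort((lattice[:, 1], lattice[:, 0], dist))
    base = lattice[order[:n_fibers]]

    rng = np.random.default_rng(seed)
    lim = np.array([gh - 1.0, gw - 1.0])
    positions = np.clip(
        base + rng.uniform(-jitter, jitter, size=base.shape) * spacing, 0.0, lim)

    # Resolve discretisation collisions by re-jittering the later fibre.
    occupied: dict[tuple[int, int], int] = {}
    for i in range(n_fibers):
        for attempt in range(200):
            pix = tuple(_round_half_away(positions[i]).astype(int))
            if pix not in occupied:
                occupied[pix] = i
                break
            positions[i] = np.clip(
                base[i] + rng.uniform(-max(jitter, 0.25), max(jitter, 0.25),
                                      size=2) * spacing, 0.0, lim)
        else:
            raise ValueError(
                f"grid {grid_shape} too small to place {n_fibers} collision-free fibres")

    return FiberLayout(positions=positions, fov_bbox=(gh, gw), grid_shape=(gh, gw))


# ---------------------------------------------------------------------------
# HR frame extraction
# ---------------------------------------------------------------------------

def extract_hr_frames(source_image: np.ndarray, layout: FiberLayout) -> np.ndarray:
    """Cut HR frames from a source image by sliding the FoV bounding box.

    The box moves left to right and top to bottom in steps of half the box
    size; only fully contained crops are kept. RGB sources are converted to
    greyscale first. Returns an (n_frames, bh, bw) stack in row-major scan
    order.
    """
    img = rgb_to_gray(source_image)
    bh, bw = layout.fov_bbox
    h, w = img.shape
    if h < bh or w < bw:
        raise ValueError(f"source {img.shape} smaller than fov_bbox {layout.fov_bbox}")
    row_offsets = range(0, h - bh + 1, max(bh // 2, 1))
    col_offsets = range(0, w - bw + 1, max(bw // 2, 1))
    frames = [img[r:r + bh, c:c + bw] for r in row_offsets for c in col_offsets]
    return np.stack(frames)


# ---------------------------------------------------------------------------
# Voronoi downsampling
# ---------------------------------------------------------------------------

def build_cellmap(layout: FiberLayout) -> CellMap:
    """Assign every grid pixel to its Euclidean-nearest fibre.

    Ties (equidistant pixels) break to the lowest fibre index so the result
    is deterministic and matches an exhaustive nearest-neighbour search.
    """
    gh, gw = layout.grid_shape
    rr, cc = np.meshgrid(np.arange(gh), np.arange(gw), indexing="ij")
    pixels = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
    tree = cKDTree(layout.positions)
    k = min(2, layout.n_fibers)
    dist, idx = tree.query(pixels, k=k)
    if k == 1:
        labels = np.asarray(idx).reshape(gh, gw)
        return CellMap(labels=labels, layout_ref=layout)
    labels = idx[:, 0].copy()
    # kd-tree tie order is arbitrary; redo near-ties exhaustively.
    ties = dist[:, 1] - dist[:, 0] <= 1e-9 * (1.0 + dist[:, 0])
    if np.any(ties):
        diff = pixels[ties, None, :] - layout.positions[None, :, :]
        labels[ties] = np.argmin((diff ** 2).sum(-1), axis=1)
    return CellMap(labels=labels.reshape(gh, gw), layout_ref=layout)


def downsample_to_fibers(hr_frame: np.ndarray, cellmap: CellMap) -> np.ndarray:
    """Average each Voronoi cell of the HR frame into one LR fibre signal."""
    hr_frame = np.asarray(hr_frame, dtype=np.float64)
    if hr_frame.shape != cellmap.labels.shape:
        raise ValueError(
            f"frame shape {hr_frame.shape} != cellmap shape {cellmap.labels.shape}")
    n = cellmap.layout_ref.n_fibers
    sums = np.bincount(cellmap.labels.ravel(), weights=hr_frame.ravel(), minlength=n)
    counts = cellmap.cell_sizes()
    return sums / counts


def add_noise(signals: np.ndarray, sigma_mult: float = DEFAULT_SIGMA_MULT,
              sigma_add: float = DEFAULT_SIGMA_ADD, seed: int = 0) -> np.ndarray:
    """Corrupt fibre signals as ``s' = s * (1 + e_m) + e_a``.

    ``e_m ~ N(0, sigma_mult^2)`` mimics per-fibre calibration imperfection,
    ``e_a ~ N(0, sigma_add^2)`` acquisition noise; both are drawn
    independently per fibre. Deterministic given ``seed``.
    """
    if sigma_mult < 0 or sigma_add < 0:
        raise ValueError("noise standard deviations must be non-negative")
    signals = np.asarray(signals, dtype=np.float64)
    rng = np.random.default_rng(seed)
    e_mult = rng.normal(0.0, sigma_mult, size=signals.shape) if sigma_mult > 0 else 0.0
    e_add = rng.normal(0.0, sigma_add, size=signals.shape) if sigma_add > 0 else 0.0
    return signals * (1.0 + e_mult) + e_add


def signals_to_sparse(signals: np.ndarray, layout: FiberLayout) -> SparseFrame:
    """Scatter fibre signals onto the grid as a sparse image + binary mask."""
    signals = np.asarray(signals, dtype=np.float64)
    if signals.shape != (layout.n_fibers,):
        raise ValueError(
            f"expected {layout.n_fibers} signals, got shape {signals.shape}")
    values = np.zeros(layout.grid_shape)
    mask = np.zeros(layout.grid_shape)
    pix = layout.pixel_positions
    values[pix[:, 0], pix[:, 1]] = signals
    mask[pix[:, 0], pix[:, 1]] = 1.0
    return SparseFrame(values=values, mask=mask, layout_ref=layout)


def fov_mask(layout: FiberLayout) -> np.ndarray:
    """Binary mask of the circular field of view inscribed in the grid."""
    gh, gw = layout.grid_shape
    cr, cc = layout.fov_center
    rr, cc_ = np.meshgrid(np.arange(gh), np.arange(gw), indexing="ij")
    return (np.hypot(rr - cr, cc_ - cc) <= layout.fov_radius).astype(np.float64)
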