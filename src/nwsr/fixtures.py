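"""Procedural source images standing in for histopathology slides.

The simulator needs large greyscale source images rich in high frequencies
and pixel-level detail, from which HR endomicroscopy frames are cropped.
Real slides are out of scope for this package, so
:func:`generate_fixture_image` synthesises stand-ins with comparable
statistics: band-passed correlated noise for tissue texture, randomly
oriented elliptical blobs for nuclei/gland-like structures, filament
strokes for fibrous structure, and a touch of white noise so the spectrum
stays populated up to Nyquist.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["generate_fixture_image", "highfreq_power_fraction"]

_MIN_DIM = 32


def generate_fixture_image(height: int, width: int, seed: int = 0,
                           texture_strength: float = 1.0,
                           n_blobs: int = 60,
                           n_filaments: int = 10) -> np.ndarray:
    """Deterministic procedural greyscale image in [0, 1].

    ``texture_strength`` scales the noise textures; with all complexity
    knobs at zero the image is flat mid-grey. Deterministic given ``seed``.
    """
    if height < _MIN_DIM or width < _MIN_DIM:
        raise ValueError(f"fixture dimensions must be >= {_MIN_DIM}")
    if texture_strength < 0 or n_blobs < 0 or n_filaments < 0:
        raise ValueError("complexity knobs must be non-negative")
    rng = np.random.default_rng(seed)
    img = np.full((height, width), 0.5)

    if texture_strength > 0:
        coarse = rng.standard_normal((height, width))
        band = ndimage.gaussian_filter(coarse, 2.5) - ndimage.gaussian_filter(coarse, 8.0)
        band /= band.std() + 1e-12
        img += 0.08 * texture_strength * band
        # unfiltered grain keeps power up to Nyquist (pixel-level detail)
        img += 0.012 * texture_strength * rng.standard_normal((height, width))

    rr, cc = np.meshgrid(np.arange(height), np.arange(width), indexing="ij")
    for _ in range(int(n_blobs)):
        r0 = rng.uniform(0, height)
        c0 = rng.uniform(0, width)
        a = rng.uniform(6.0, 20.0)
        b = rng.uniform(6.0, 20.0)
        theta = rng.uniform(0, np.pi)
        amp = rng.uniform(0.1, 0.35) * rng.choice([-1.0, 1.0])
        dr, dc = rr - r0, cc - c0
        u = dr * np.cos(theta) + dc * np.sin(theta)
        v = -dr * np.sin(theta) + dc * np.cos(theta)
        q = (u / a) ** 2 + (v / b) ** 2
        img += amp * np.exp(-2.0 * q)

    if n_filaments > 0:
        canvas = np.zeros((height, width))
        for _ in range(int(n_filaments)):
            r = rng.uniform(0, height)
            c = rng.uniform(0, width)
            angle = rng.uniform(0, 2 * np.pi)
            amp = rng.uniform(0.15, 0.4) * rng.choice([-1.0, 1.0])
            for _ in range(int(0.6 * max(height, width))):
                angle += rng.normal(0.0, 0.15)
                r += np.sin(angle)
                c += np.cos(angle)
                ri, ci = int(round(r)), int(round(c))
                if not (0 <= ri < height and 0 <= ci < width):
                    break
                canvas[ri, ci] += amp
        img += ndimage.gaussian_filter(canvas, 1.2)

    lo, hi = np.percentile(img, [1.0, 99.0])
    if hi - lo < 1e-12:
        return np.full((height, width), 0.5)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def highfreq_power_fraction(image: np.ndarray, cutoff: float = 0.25) -> float:
    """Fraction of non-DC spectral power at radial frequency > ``cutoff``.

    Frequencies are in cycles/pixel (Nyquist = 0.5), so the default cutoff
    is half-Nyquist.
    """
    image = np.asarray(image, dtype=np.float64)
    spec = np.abs(np.fft.fft2(image - image.mean())) ** 2
    fr = np.fft.fftfreq(image.shape[0])
    fc = np.fft.fftfreq(image.shape[1])
    rad = np.hypot(*np.meshgrid(fr, fc, indexing="ij"))
    total = spec.sum()
    if total == 0:
        return 0.0
    return float(spec[rad > cutoff].sum() / total)
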