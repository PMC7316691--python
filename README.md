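# nwsr — super-resolution of irregularly sampled fibre-bundle endomicroscopy

Probe-based confocal laser endomicroscopy (pCLE) images tissue through a
coherent bundle of optical fibres. Each fibre contributes one signal per
frame, and the fibre cores are packed in a quasi-hexagonal, *irregular*
pattern across the field of view (FoV). Clinical devices therefore display
not the native measurements but an interpolation of them onto a Cartesian
grid — typically piecewise-linear interpolation over a Delaunay
triangulation, which introduces triangle-edge artefacts and interpolated
noise.

`nwsr` is a research tool for studying how learned reconstructions compare
with the classical ones, and in particular whether a network should consume
the *sparse* native samples or an already-interpolated image. It provides:

* a **simulator** that turns high-resolution (HR) greyscale sources into
  paired HR / low-resolution (LR) pseudo-pCLE videos: pseudo-hexagonal fibre
  layouts, Voronoi-cell signal averaging (each fibre reports the mean of
  the HR pixels nearest to it), multiplicative + additive Gaussian signal
  noise, and sparse Cartesian images `S` with binary fibre masks `M`;
* two **classical baselines**: Delaunay linear interpolation (the clinical
  reference) and Nadaraya–Watson (NW) kernel regression with a handcrafted
  Gaussian kernel;
* a trainable **NW layer** — the core method — which generalises NW kernel
  regression to a convolutional layer on a sparse input and its sparsity
  map:

      R(u,v) = Σᵢⱼ S(u+i, v+j) · wᵢⱼ / Σᵢⱼ M(u+i, v+j) · |wᵢⱼ| + b
      Mᵘᵖ(u,v) = Σᵢⱼ M(u+i, v+j) · |wᵢⱼ|

  with kernels normalised to Σ|w| = 1, negative weights allowed, and the
  updated (now probabilistic) sparsity map `Mᵘᵖ` propagated to the next NW
  layer. The layer has exactly the parameter count of the convolution it
  replaces;
* two compact EDSR-style **architectures**: `CNNnetSR` (dense input) and
  `NWnetSR` (NW-layer head on the sparse input + mask, then the same dense
  trunk), with no upsampling stage (LR and HR share a grid), a 32-filter
  convolution in its place, and a linear 1×1 fusing layer;
* a **training/evaluation harness**: per-frame LR-statistics normalisation,
  64×64 patch extraction, the SSIM+L1 objective, Adam with a learning-rate
  grid over {1e-2 … 1e-7}, and per-frame PSNR/SSIM aggregation over
  held-out videos.

The trainable components run on a small numpy reverse-mode autodiff engine
included in the package (`nwsr.autodiff`), so everything works on a plain
CPU with no deep-learning framework.

## Worked example

Simulate one synthetic video, reconstruct it both classically and with a
Gaussian-kernel NW layer, and compare image quality:

```python
import numpy as np
from nwsr import (generate_fiber_layout, build_cellmap, downsample_to_fibers,
                  add_noise, signals_to_sparse, delaunay_linear,
                  nw_gaussian_reconstruct, ssim, psnr)
from nwsr.fixtures import generate_fixture_image
from nwsr.fiber_model import extract_hr_frames, fov_mask

source = generate_fixture_image(384, 384, seed=7)
layout = generate_fiber_layout(1500, (128, 128), jitter=0.15, seed=7)
hr = extract_hr_frames(source, layout)[0]           # one 128x128 HR frame
cells = build_cellmap(layout)
signals = add_noise(downsample_to_fibers(hr, cells), 0.05, 0.02, seed=7)
sparse = signals_to_sparse(signals, layout)          # S and its mask M

fov = fov_mask(layout)
for name, recon in [("linear", delaunay_linear(sparse)),
                    ("gauss", nw_gaussian_reconstruct(sparse))]:
    print(f"{name}: SSIM={ssim(recon, hr, mask=fov):.3f}  "
          f"PSNR={psnr(recon, hr, mask=fov):.2f} dB")
```

```
linear: SSIM=0.704  PSNR=21.07 dB
gauss: SSIM=0.663  PSNR=13.51 dB
```

The Delaunay reconstruction is sharper and scores higher on both metrics
at this sampling density; the narrow Gaussian NW regression blurs structure
between fibres. The learned models are trained to beat both — run the
comparative study below or `nwsr evaluate --seed 1 --out report.csv` to
reproduce the full five-method table.

A command-line interface covers the same pipeline end to end:

```bash
nwsr simulate  --seed 1 --out data/            # paired LR/HR videos
nwsr reconstruct --dataset data/ --method gauss --out recon/
nwsr evaluate  --seed 1 --out report.csv       # full 5-method study + CSV
nwsr selftest  --seed 1                        # quick oracle checks
```

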