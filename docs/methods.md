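# Methods

## The reconstruction problem

A fibre-bundle endomicroscope measures tissue fluorescence through several
thousand optical fibre cores packed quasi-hexagonally across a circular
field of view (FoV). Each core yields one scalar per frame, so the native
data are irregular samples of the tissue signal; the clinical display is an
interpolation of those samples onto an over-sampled Cartesian grid. The
question this package studies is whether a learned reconstruction should
start from an already-interpolated Cartesian image ("dense" approach) or
from the native sparse samples themselves ("sparse" approach), and whether
an interpolation-aware layer helps the sparse route.

## Acquisition simulation

Real paired LR/HR endomicroscopy does not exist (there is no ground-truth
high-resolution modality), so the pipeline manufactures it:

1. **Sources.** Procedural greyscale images stand in for the
   histology-like HR signal source: band-passed correlated noise (texture),
   randomly oriented elliptical blobs (nuclei/gland-like), filament strokes
   (fibrous structure) and a small unfiltered grain term that keeps the
   power spectrum populated up to Nyquist (>1% of non-DC power above half
   Nyquist at default settings). Texture correlation lengths are a few
   pixels to a few tens of pixels, i.e. mostly — but not entirely —
   resolvable at the simulated fibre spacing, which is the regime a real
   microscope operates in.
2. **Fibre layout.** A hexagonal lattice inscribed in the FoV circle,
   jittered by a uniform fraction (default 0.15) of the lattice spacing per
   axis, discretised to grid pixels by rounding half away from zero;
   collisions are re-jittered. This emulates the quasi-hexagonal,
   collision-free packing of real bundles.
3. **Frame extraction.** The FoV bounding box slides across the source in
   half-box steps, row-major; each fully contained crop is one HR frame, so
   one source yields a short "video".
4. **Signal loss.** Every HR pixel is assigned to its nearest fibre
   (Voronoi tessellation; ties break to the lowest fibre index) and each
   cell is averaged into a single LR fibre signal. The construction
   partitions the grid, so total intensity is conserved exactly.
5. **Noise.** `s' = s (1 + e_m) + e_a`, with `e_m ~ N(0, 0.05^2)`
   (calibration imperfection, multiplicative) and `e_a ~ N(0, 0.02^2)`
   (acquisition noise, additive), drawn independently per fibre per frame,
   applied before any reconstruction so interpolated images contain
   interpolated noise. The magnitudes are package defaults on [0,1]-scaled
   signals, chosen to be clearly visible yet leave the signal dominant
   (SNR ≈ 20 at mid-grey).
6. **Sparse representation.** Signals are scattered back onto the grid as
   the sparse image `S` (zeros at non-informative pixels) plus the binary
   mask `M` of fibre pixels.

## Classical baselines

*Delaunay linear*: piecewise-linear barycentric interpolation over the
Delaunay triangulation of the fibre pixels (`scipy` qhull). Exact at fibre
pixels and for planar fields (verified to 1e-6). Outside the convex hull
but inside the FoV, nearest-fibre fill; outside the FoV, zero — the border
policy mirrors the circular masking of clinical displays.

*Gaussian NW*: Nadaraya–Watson regression with one handcrafted Gaussian
kernel, σ defaulting to half the mean nearest-neighbour fibre spacing,
circularly truncated at radius ≥ 3σ. Pixels with an empty neighbourhood
are zero and flagged in a coverage map. Both baselines consume only the
sparse frame (discretised positions); both produce values inside the hull
bounded by the sampled signals.

## The trainable NW layer

The core operation on a feature map `S` and sparsity map `M` is

    R(u,v)   = Σ_{i,j} S(u+i,v+j) w_{i,j} / Σ_{i,j} M(u+i,v+j) |w_{i,j}| + b
    M_up(u,v) = Σ_{i,j} M(u+i,v+j) |w_{i,j}|

computed with zero padding (borders therefore read as lower certainty
through the mask arithmetic). Weights may be negative; the mask path uses
|w| so it captures geometric influence regardless of sign. Kernels are
normalised to Σ|w| = 1 for numerical stability; with an all-ones mask the
interior denominator is then exactly 1 and the layer reduces to a plain
correlation. With a fixed discretised Gaussian kernel the layer reproduces
the classical Gaussian-NW baseline to machine precision — the oracle used
in the tests.

Numerical choices:

* **ε-branch.** Where the denominator ≤ 1e-8 the window holds no
  informative pixel: the output is the bias alone and `M_up` is 0. This
  keeps the forward pass total and gradients finite; it is the only
  non-differentiable set, and it has measure zero in training practice.
* **Normalisation as re-projection.** Raw weights are divided by their
  Σ|w| inside every forward pass rather than re-normalised after optimiser
  steps, so the invariant holds exactly mid-training and gradients flow
  through the projection.
* **Multi-channel form.** Numerator and denominator both sum over input
  channels, pairing each channel's sparsity map with the absolute weights
  of that channel's kernel slice. This keeps the ratio a weighted average
  and gives the layer exactly the parameter count of the convolution it
  replaces: t·C_in·(2k+1)² weights + t biases.
* **Initialisation.** Truncated normal, mean 0.2, std 0.05, clipped at two
  standard deviations, then normalised; biases start at zero. At this
  initialisation all kernels are positive, so the first layer starts as a
  (trainable) interpolator.
* **Mask/feature scale mismatch in deep stacks.** After the first layer the
  propagated maps are O(window fill) while the features are O(signal), so
  the second layer's ratio amplifies activations by roughly the reciprocal
  fill factor at initialisation. This is a property of the stacked
  equations themselves. It is handled downstream: the networks' final
  fusing convolution is zero-initialised, so the output starts at its bias
  and Adam (which is scale-free per parameter) conditions the trunk in a
  few steps.

## Architectures

`CNNnetSR`: 3×3 conv head → `n_res_blocks` residual blocks
(conv–ReLU–conv with additive skip, optional residual scaling, off by
default) → global skip → 3×3 conv with `head_features`=32 filters (in
place of the upsampling stage an SR network would normally carry — LR and
HR share a grid here) → 1×1 conv, linear activation, fusing the maps into
the output image. `NWnetSR` replaces the head with `n_nw_layers`=2 NW
layers (first 9×9, deeper 3×3 — sizes chosen so the first window captures
more than ten informative pixels at the simulated fibre density); after
the last NW layer the sparsity maps are discarded and the identical dense
trunk follows. Defaults for desk-scale work: 8 blocks × 32 features
(fully configurable; the comparative study uses 2 × 16).

## Training and evaluation protocol

Frames are normalised per frame: LR mean/std computed over informative
pixels only (including the structural zeros would tie the statistics to
fibre density), both frames standardised by those statistics, then mapped
affinely so the LR informative values span [0, 1]; HR shares the map, may
exceed [0, 1], and is not clipped. Sparse zeros are re-imposed after
normalisation. Non-overlapping 64×64 patches feed batch training; the
objective is `0.84·(1 − SSIM) + 0.16·L1` (the conventional mixing weight
for this loss family), with SSIM computed under an 11-tap Gaussian window,
σ = 1.5, K1 = 0.01, K2 = 0.03, border windows discarded. Optimisation is
Adam (β1 = 0.9, β2 = 0.999, ε = 1e-8). Hyperparameter search is a
sequential learning-rate grid over 10^{-2} … 10^{-7}: each rate trains a
fresh model briefly, the rate with the best validation loss is fine-tuned
for the remaining budget with periodic validation checks — training stops
early once the validation loss plateaus and the best-scoring parameters
are restored. (A population-based scheduler would need a worker
population; the grid covers the same initial rates sequentially.)

Evaluation runs on full-size held-out frames, never patches: predictions
are de-normalised back to source intensities and scored against the clean
HR frame by PSNR and SSIM (data range 1.0) inside the circular FoV, then
aggregated as mean ± std over frames. Identical frames flag an infinite
PSNR rather than failing.

## Comparative study scale

The bundled study (`nwsr.pipeline.run_comparative_study`, also behind
`scripts/acceptance.py` and `nwsr evaluate`) uses 10 synthetic videos of
25 frames each — 384×384 sources, 128×128 FoV, 1500 fibres (fill ≈ 0.12,
≈ 10 informative pixels per 9×9 window, the density regime fibre bundles
operate in), noise as above; videos 0–6 train (700 64×64 patches),
video 7 validates (96 patches, used for rate selection and early
stopping), videos 8–9 are the held-out test set (50 full frames). Models
are the 2-block/16-feature variants; each learning rate gets a 25-step
probe, the winner up to 550 steps total with validation checks every 75.
This scale keeps the whole study within roughly a quarter hour on one CPU
core while preserving the qualitative findings: every learned model
outperforms both classical baselines in mean SSIM, and the three learned
variants score close to one another.

At markedly sparser sampling (e.g. 300 fibres on the same grid, ≈ 2
informative pixels per 9×9 window) the picture changes: the dense-input
model keeps an SSIM advantage that the sparse-input models cannot close at
this model size, consistent with the observation that pseudo-regular,
sufficiently dense sampling is what lets dense and sparse approaches
converge to similar quality.

## What the synthetic data does and does not show

The simulator reproduces the geometry (quasi-hexagonal irregular sampling,
circular FoV), the physics of signal loss (cell averaging) and a
first-order noise model. It does not model honeycomb artefacts of raw
bundle images, the calibration step that produces fibre signals, vendor
bundle geometries, motion, or the staining statistics of real histology.
Passing results therefore demonstrate correctness of the methods and the
relative behaviour of reconstruction approaches under controlled
conditions — not clinical image quality, and not the absolute scores
reported on any real dataset.

## Known limitations

* The autodiff engine is float64 and CPU-only; at larger scales a GPU
  framework would be the natural substrate.
* Stacked NW layers inherit the scale-amplification noted above; very deep
  NW stacks would need explicit renormalisation between layers.
* The Gaussian baseline's kernel width is a heuristic (half the mean
  nearest-neighbour spacing); its scores move with that choice.
* Training budgets are short by deep-learning standards; scores quoted
  anywhere in this repository are those of the bundled desk-scale runs,
  not converged large-scale results.
* The advantage of every learned model over both baselines is stable
  across study seeds; the *mutual* spread of the three learned models is
  not fully converged at this budget and varies by a few hundredths of
  SSIM from seed to seed.
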