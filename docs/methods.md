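# Methods

This note documents the models, numerical choices, and limitations of
`scnct`: a toolkit that trains stacked competitive networks (SCNs) to
map low-dose CT (LDCT) images to their normal-dose (NDCT) counterparts,
together with the full fan-beam simulation chain used to fabricate
paired training data from synthetic phantoms.

## The simulation chain

### Phantoms

Phantoms are sums of constant-attenuation ellipses on a square raster
(default 256×256 px over a 200×200 mm field of view). Continuous
coordinates are in mm with the origin at the rotation centre, x right,
y up; array element (0, 0) is the top-left pixel. A pixel belongs to an
ellipse iff its centre does — no anti-aliasing — so line-integral and
area oracles can be computed exactly against the same raster.
Overlapping deltas accumulate and the result is clipped at zero.

The random phantom population (`random_phantom_spec`) is abdomen-like:
an elliptical soft-tissue body (μ = 0.022 mm⁻¹, roughly water at
~60 keV) nearly filling the field of view, two to five low-contrast
internal structures (|Δμ| = 0.002–0.008 mm⁻¹), a vertebra-like dense
insert (Δμ = 0.05 mm⁻¹) in the posterior half, and up to two further
bone-like disks (Δμ = 0.04 mm⁻¹). The long paths through body and bone
produce photon-starved rays at low doses, which is what makes real
low-dose abdominal CT noisy and streaky.

When the dataset pipeline rasterizes a phantom it applies a small
Gaussian blur (`partial_volume_px`, default 0.7 px) before projection.
Real CT slices are partial-volume smooth at coarse pixel sizes;
pixel-sharp raster steps would otherwise fill both members of every
image pair with Gibbs ringing at the detector band limit — texture no
scanner produces and against which no denoiser (learned or classical)
can operate. `generate_phantom` itself stays pixel-sharp so that the
projector and area oracles remain exact.

### Fan-beam projection

The scanner model is a rotating fan-beam system with a flat detector:
source–centre distance 400 mm, centre–detector distance 400 mm,
detector length 413 mm with 512 equally spaced bins, 1024 views
uniformly covering 360° (view v at angle 360°·v/n_views, no endpoint
duplication). The 413 mm detector subtends a half-fan that covers a
centred disk of radius 99.97 mm — i.e. the inscribed circle of the
200 mm field of view, to within 0.03%; the geometry constructor warns
when a requested FOV exceeds coverage by more than 0.5%.

Line integrals are exact radiological paths through the pixel raster,
computed by the parametric pixel-crossing walk (Siddon): the ray's
parameter interval is clipped to the grid, and the walk advances to the
next x- or y-plane crossing, accumulating (segment length × pixel
value). No interpolation is involved; the projector is linear and
matches an independent dense line-sampling oracle to better than 10⁻³
relative on every ray (and a Liang–Barsky chord oracle exactly).

### Photon statistics

Low-dose measurements follow the monoenergetic transmission model:
counts per ray are Poisson with mean b₀·exp(−l) + r, where b₀ is the
blank-scan photon count (uniform across rays), l the line integral, and
r the electronic-noise mean. r defaults to 0 — no value is established
for it — and is exposed as a configuration knob. Noisy line integrals
are recovered as l̂ = ln(b₀ / max(z − r, ε)) with an ε-floor of one
count so photon-starved rays stay finite, clipped below at zero. The
three study dose levels are b₀ ∈ {5×10⁴, 10⁵, 5×10⁵}; the variance of
(l̂ − l) decreases strictly across them.

### Filtered back-projection

Reconstruction is standard flat-detector fan-beam FBP (Kak–Slaney
formulation with the detector rebinned to the virtual line through the
rotation centre):

1. cosine pre-weighting of each bin by D/√(D² + s²);
2. ramp filtering along the bin axis in the frequency domain,
   zero-padded to the next power of two ≥ 2× bins. The filter is the
   FFT of the exact band-limited spatial ramp kernel
   (h(0) = 1/(4Δs²), h(odd n) = −1/(πnΔs)², h(even) = 0), which avoids
   the DC bias of sampling |f| directly; a Hann window apodizes it by
   default (`ram-lak` available) to tame noise blow-up at 5×10⁴
   photons;
3. distance-weighted back-projection with linear interpolation between
   bins and the 1/U² fan weight, scaled by Δβ/2 for the full turn
   (every line measured twice).

Negative output pixels are clipped at zero in `fbp_reconstruct`; the
unclipped linear operator is exposed separately
(`fbp_filtered_backprojection`) and is linear to 10⁻⁶ relative. The
noiseless project→reconstruct round trip on the uniform-disk phantom
recovers the interior to ≤ 5% relative RMS (measured ≈ 0.1% with the
Hann window at the default geometry).

The NDCT member of each training pair is the FBP of the *noiseless*
sinogram, not the phantom raster: both doses pass through the same
reconstruction operator, so the network learns reconstruction-domain
noise rather than raster-versus-reconstruction bias. All images of a
dataset are mapped to [0, 1] by one fixed affine map (min/max of the
NDCT set), and all metrics use peak = 1 on that scale.

## The network

A competitive block convolves its input with filters at several kernel
scales (default K = {1, 3, 5}), applies ReLU per scale, and combines the
scale responses by element-wise maximum, per pixel and per filter index.
All scales use zero same-padding of (k−1)/2 so their maps align
spatially and the block preserves the input size; there is no pooling.
The network stacks `depth` blocks (reference default: depth 5, 96
filters; toy profile: depth 3, 16 filters); the final block keeps the
multi-scale competitive structure with a single output filter and emits
the denoised image directly (no residual skip by default; a residual
variant sits behind a config flag). ReLU after the final block is
disabled so the output layer keeps a signed gradient; per-scale,
per-filter biases are used throughout.

The training objective is the squared error summed over pixels and
averaged over the batch, plus α·Σ‖W‖²_F over all convolution weights
(biases excluded), α default 10⁻⁶ at toy scale.

Everything is plain NumPy. Convolutions are im2col GEMMs in a
channels-first layout with the batch folded into the GEMM column axis,
so a single BLAS call evaluates each block for the whole batch; all
scales of a block are evaluated in one GEMM by centre-embedding each
k×k kernel in a k_max×k_max kernel (identical result under
same-padding). The backward passes are hand-written and verified
against central-difference numerical gradients to ~10⁻⁷ relative.

## Training regimen

Weights initialize from zero-mean Gaussians with std 0.01, biases at
zero. Optional greedy pretraining trains each of the first depth−1
blocks as a per-block autoencoder on the LDCT patches: a throwaway
linear 3×3 head regresses the block's own input; the head is then
discarded and the block's output feeds the next block; the final block
keeps its random initialization. Fine-tuning minimizes the full
objective end to end: an Adam phase for the first half of the epoch
budget, then plain SGD, under multiplicative ×0.1 learning-rate decay
at evenly spaced milestones from `lr_init` to `lr_final`. Per-epoch
training loss and validation PSNR are logged and the best-validation
checkpoint is retained. Training is bit-for-bit reproducible under a
fixed seed (single-threaded deterministic BLAS kernels; all randomness
flows from `numpy.random.SeedSequence`).

Patches are extracted on a regular stride grid (all windows fully
inside the image; count per axis = floor((N − patch)/stride) + 1), and
every patch records its source image and offset. The splitter holds out
validation images at the *image* level, and held-out test phantoms come
from an independent seed stream, so train/validation/test source images
are provably disjoint — asserted from the provenance ids.

The reference full-scale regimen (patch 100, stride 4, lr 10⁻² → 10⁻⁵,
96 filters) is preserved as the `TrainConfig` defaults; it is not
executed by the test suite.

## The toy study profile

`toy_experiment_config` fixes the scaled-down end-to-end study the test
suite and the acceptance script run: 64×64 phantoms over the 200 mm
FOV, depth-3 networks with 16 hidden filters, b₀ = 10⁵, 41 training
phantoms → 1813/196 train/validation patches of 16×16 at stride 8,
30 epochs of batch 16, lr 3×10⁻³ → 3×10⁻⁵, no pretraining (pretraining
is exercised by its own unit tests). Geometry: the full 512-bin
detector with views scaled 1024 → 128 in proportion to the grid
(4096 ÷ 32 rays per view·pixel as in the reference geometry).

Two choices deserve emphasis:

* **Detector sampling sets the noise level.** FBP noise grows with the
  detector band; keeping the reference 512-bin detector at the coarse
  grid, together with the abdomen-like population, places the toy LDCT
  at ≈ 36–39 dB PSNR against its NDCT — the mid-to-high-30s dB regime
  typical of clinical low-dose simulations at this blank-scan level.
  Halving the bins instead would have produced a ~50 dB "low-dose"
  image with nothing to denoise.
* **Partial-volume smoothing makes the task well-posed.** Without it,
  the coarse-pixel reconstructions are dominated by raster-edge Gibbs
  texture; with it, the LDCT error is predominantly white measurement
  noise over sub-Nyquist-smooth anatomy, and an oracle-tuned non-local
  means gains ≈ +3.3 dB — headroom a trained network can realize.

Under this profile the trained SCN-3 gains ≈ +2.7 dB PSNR over the
LDCT input on held-out phantoms from unseen specs, consistently across
seeds, and SCN-3 ≥ CNN-3 (single-scale 3×3, widened to the same
parameter budget) on the mean.

## What the synthetic data does and does not show

The generator emulates: paired LDCT/NDCT slices at controllable dose,
photon-starvation streaks near dense structures, dose-ordering of noise
levels, and subject-disjoint train/test splits. It does not emulate:
real anatomy and its texture statistics, polyenergetic spectra, scatter,
detector cross-talk, helical/cone-beam geometry, HU calibration, or the
full-scale 10⁶-patch training regimen. Passing the toy study shows the
architecture, simulation chain, and training loop are correct and that
the multi-scale blocks help at matched capacity; it does not certify
clinical denoising performance.

## Numerical choices and degenerate inputs

* Siddon walk tolerances: the entry cell is found by nudging 10⁻¹²
  of the parameter range inside the grid; plane-crossing ties advance
  both indices (exactly diagonal crossings contribute zero-length
  segments).
* Rays missing the image support integrate to 0 (not an error).
* ε-floor of 1 count before the log transform; counts above the blank
  scan clip l̂ at 0.
* Maxout argmax ties route gradients to the lowest scale index.
* A depth-1 model has no pretraining phase; `pretrain="none"` skips it
  entirely.
* Identical images give PSNR = +inf (serialized as "inf"); SSIM uses
  the canonical 11×11 Gaussian window (σ 1.5), C₁ = (0.01·peak)²,
  C₂ = (0.03·peak)², and refuses images smaller than the window.
* Training aborts with block/step context on non-finite losses.
* Float32 is used for training compute (the data's dynamic range is
  [0, 1]); float64 everywhere correctness oracles are asserted.

## Known limitations

* The greedy pretraining objective is one canonical reading of
  "unsupervised stacked initialization"; other readings (RBM-style,
  denoising autoencoders) exist.
* The network depth of the reference profile (5) is a documented
  default, not an established value.
* At 64² the PSNR ceiling of *any* denoiser on this data is a few dB;
  ablation differences between variants are correspondingly small and
  are assessed only directionally, within one standard deviation.
* The projector and FBP are single-threaded (numba) and sized for
  desk-scale experiments, not clinical throughput.
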