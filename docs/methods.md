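# Methods

## Problem and approach

Counting retinal ganglion cell axons in light micrographs of optic nerve
cross sections is the standard outcome measure in rodent and primate
glaucoma models, and manual counting is the gold standard but
prohibitively slow (tens of thousands of axons per rat nerve). Direct
segmentation of individual axons is unreliable at light-microscope
resolution, especially in damaged tissue. `axodense` therefore counts by
**density regression**: a convolutional network maps an image to a
per-pixel count-density field whose integral over any region is the
expected number of axons in that region. Counting becomes a pixelwise
regression problem, sidestepping instance segmentation entirely.

## Ground-truth density targets

Each of K manual counters marks one point per "normal"-appearing axon
(intact continuous myelin sheath, homogeneous light interior). The marks
are averaged into a per-pixel indicator matrix

    D(i,j) = (1/K) * sum_k c_k(i,j),

where `c_k(i,j)` is 1 iff counter k marked pixel (i,j). The sum of D is
the mean manual count (MC). D is then convolved with an isotropic
Gaussian (sigma = 8 px, 33 x 33 support) so the point mass is spread
over roughly one axon's extent:

    D_dist = G(D).

Two numerical choices matter here.

1. **Kernel renormalization.** A sigma = 8 Gaussian truncated at
   +/-16 px retains only ~91% of its 2-D mass. The truncated kernel is
   renormalized to unit sum so that an interior annotation integrates to
   exactly one count; otherwise every count would be biased low by ~9%.
2. **Boundary handling.** Convolution uses implicit zero padding and the
   result is cropped to the image extent, so mass blurred beyond the
   border is discarded. This is deliberate: an object lying partly
   outside the frame should count fractionally.

Images are resized bilinearly so each side is the nearest multiple of 16
(ties round up; 187 -> 192), because four max-pooling levels halve the
side length four times. Point annotations are rescaled with the
pixel-center convention and density maps are built **after** rescaling —
bilinear interpolation of a density map would not conserve its integral.

## Network

A U-Net encoder/decoder with every filter count halved relative to the
original architecture (`base_filters` = 32, doubling at each of 4
pooling levels), padded 3 x 3 convolutions so feature maps never shrink,
2 x 2 stride-2 transposed convolutions on the decoding path with skip
concatenations, and a final 1 x 1 convolution with a ReLU head so
predicted densities are nonnegative and unbounded above (a sigmoid would
bias outputs toward 0/1; the task is regression, not segmentation).
No batch normalization or dropout. He-normal initialization, seeded.

Because no deep-learning framework is a dependency of this package, the
network, its backpropagation and the Adam optimizer are implemented
directly in NumPy (im2col + BLAS matrix multiplication, float32
parameters). The implementation is validated against central finite
differences in float64 in the test suite.

Inputs are normalized per image: subtract the mean, divide by twice the
standard deviation, clip to [-1, 1] (so +/-2 SD spans the unit range;
constant images map to zeros).

## Training

- Loss: mean over **non-mirrored** pixels of `(Dhat - m * D_dist)^2`,
  with density scaling factor m = 1000. Scaling the target up improves
  convergence of the regression; predictions are divided by m at
  inference.
- Mirror padding: images and targets are reflection-padded by 16 px
  (192 -> 224) without repeating the edge pixel, so border axons see
  plausible context; the padded region is excluded from the loss.
- Optimizer: Adam, learning rate 1e-4, batch size 1, 25 epochs (the
  full-scale recipe; see "Desk-scale runs" below).
- Augmentation: one of the 8 dihedral transforms applied jointly to
  image and target (the target integral is exactly preserved), plus
  per-pixel multiplicative intensity noise uniform in [0.85, 1.15]
  applied to the image only. Noise is applied after normalization;
  normalization is affine-invariant, so pre-normalization scaling would
  be a no-op, which indicates post-normalization application is the
  meaningful variant.
- Uniform-count resampling: a 10-bin histogram of MC over the training
  set is built and all images in each under-filled bin are replicated
  `round(max_bin_size / bin_size)` times (whole-image replication only),
  flattening the count distribution to reduce regression-to-the-mean
  bias on images with unusually few or many axons. Originals are always
  retained; empty bins are skipped. One epoch is one shuffled pass over
  the expanded multiset.
- Seeded runs reproduce loss histories on one platform; bitwise
  reproducibility across platforms/BLAS builds is not promised.

## Inference and whole-nerve tiling

Prediction mirrors training: normalize, reflection-pad by 16 px,
forward pass, crop to the original extent, divide by m. The count is
the integral (sum) of the predicted density map.

Whole-nerve mosaics are processed in tiles (default 192 px core) padded
with 16 px of *true* neighbouring pixels where available; mirror padding
is used only at the mosaic boundary. Each tile's prediction is cropped
back to its core and the cores partition the mosaic exactly, so every
pixel's density is predicted once. Mosaic sides that are not multiples
of the tile size are handled with end-aligned final tiles whose cores
are clipped to the uncovered remainder. Tile and context sizes are
restricted to multiples of 16 so every padded window remains a valid
network input. With >= 16 px of true context, a fully convolutional
network produces near-identical interior predictions tiled or whole, so
tiled and whole-image counts agree to within a few percent.

## Bias correction and agreement statistics

Automated counts (AC) show a systematic linear bias against manual
counts. On a validation subset, `AC = a * MC + b` is fitted by ordinary
least squares, and new counts are corrected as
`AC_corrected = (AC - b) / a`. Agreement on a test subset is summarized
by:

- mean absolute error of corrected AC vs mean MC;
- R^2 of the corrected-vs-manual linear regression;
- Bland-Altman bias and limits of agreement, mean error +/- 1.96 * SD
  of error (sample SD, ddof = 1 throughout);
- success rate: the fraction of images (with exactly four counters)
  whose corrected AC falls inside the t-based 95% confidence interval
  of the mean manual count (df = 3). The reference analysis does not
  specify the interval construction; the t-interval of the mean is used
  here, and a coverage simulation in the tests documents its actual
  coverage for a fifth-counter-like observation (~75%, well below 95%,
  as expected for a mean CI);
- median per-image coefficient of variation of the manual counts
  (SD / mean, images with zero mean excluded).

Normality screening and omnibus tests (Shapiro-Wilk, Kruskal-Wallis,
Dunn) are deliberately delegated to scipy/statsmodels rather than
reimplemented.

## Synthetic study conditions

The synthetic generator emulates the statistical structure of
toluidine-blue-stained nerve images, not their photorealistic texture:

- "Normal" axons are annuli: a light axoplasmic core (about +65 grey
  levels above background) inside a dark myelin ring (about -70),
  inner radius uniform in 4-9 px at ~15.7 px/um, myelin width 2.5 px,
  ~1 px antialiased edges, per-axon contrast jitter, and angular radius
  wobble proportional to `damage_level`.
- "Abnormal" features (collapsed dark cores or broken rings with an
  angular gap) are rendered at `0.5 * damage_level` of the normal
  density and are never listed in the ground truth — they are the
  distractors a counter is instructed to skip.
- Placement is a Poisson process over the frame extended by the maximum
  outer radius, thinned by dart-throwing spacing (placed regardless
  after 60 failed attempts, preserving the expected count).
- The counting **border rule** matches annotation practice: an axon is
  listed iff its disk lies fully inside the frame, or crosses only the
  left/top border with more than half its area inside (computed
  geometrically via polygonal circle-rectangle intersection). Disks
  crossing the right or bottom border belong to the neighbouring tile.
- Background: mean grey 150 with a low-frequency staining field and
  pixelwise Gaussian noise (SD 8), clipped to [0, 255].

Simulated counters drop true points, add spurious ones and jitter
retained marks (SD 1.5 px). Independent thinning alone cannot reproduce
the observed inter-counter disagreement (median per-image CoV ~0.12 at
~40 axons/image implies systematic observer differences, since binomial
noise alone gives ~0.06), so each counter draws a latent *strictness*:
strict counters miss more true axons, liberal counters add more spurious
marks, with the mean miss (0.08) and spurious (0.05) rates preserved.
The strictness scale (`counter_spread` = 1.25) was calibrated once, by
simulation, to the published median CoV of 0.12.

Datasets are split 60-20-20 at the **nerve** level (no nerve contributes
images to two subsets), with per-nerve axon density varied +/-50-70%
and per-nerve damage +/-50% around the template, emulating the health
range across animals.

What passing tests on this generator do **not** show: robustness to real
staining chemistry, glia, vasculature, focus variation, or species
differences. The generator exists to verify the pipeline's mechanics
(conservation, geometry, training dynamics, calibration algebra), not to
certify accuracy on real tissue.

## Desk-scale run sizes

The full-scale recipe (25 epochs over ~900 images at 192 px with a
base-32 network) is far larger than needed to exercise the pipeline, so
the test suite and the acceptance script use reduced problem sizes,
chosen once as the package's own desk-scale conditions:

- **Recovery study**: 10 nerves x 10 images at 128 px (axon density 19,
  the 187-px standard density scaled by image area), 60-20-20 split,
  base-16 network, 10 epochs. With only ~600 optimizer steps (vs ~22k
  full-scale), the Adam step size is raised to 1e-3 and augmentation is
  disabled — augmentation costs convergence speed and mainly buys
  robustness that a 10-epoch synthetic run cannot cash in; the
  reference workflow itself probes overfitting behaviour with
  augmentation disabled. Recovery is judged against the generator's
  known true counts: corrected validation MAE vs the constant-mean-count
  predictor, and corrected-count R^2.
- **Overfit probe**: a single repeated 192-px image, base-16 network,
  learning rate 1e-3, early-stopped once the memorized count is within
  0.5 axons (cap 40 epochs x 10 repeats). Reproduces the zero-bias
  overfit check (< 1 axon error on the training image).
- **Tiling consistency**: a 576-px synthetic mosaic counted tiled
  (192 px tiles, 16 px context) vs in one pass with the recovery-study
  model.

## Known limitations

- The NumPy training engine is single-threaded GEMM-bound; it is sized
  for desk-scale experiments, not full-scale training.
- Only batch size 1 is implemented (the published recipe uses exactly
  that).
- The success-rate CI and the reflection convention ("reflect without
  edge repetition") are documented reconstructions of under-specified
  details; both are pinned by tests and configurable where reasonable.
- Whole-nerve counts cover the full frame; no nerve/background mask is
  applied.
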