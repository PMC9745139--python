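# Methods

This note documents the models, parameters and numerical choices behind
`hsiseg`, and what the synthetic experiments do and do not establish.

## Synthetic scenes

The generator (`hsiseg.synthetic`) emulates the statistical structure of
airborne vegetation imagery that the method actually relies on; it makes
no attempt at radiative-transfer realism.

**Endmembers.** Each class gets a smooth archetype spectrum by kind —
vegetation: low visible reflectance with a green bump at 550 nm and a
chlorophyll well at 670 nm, a logistic red edge near 705–730 nm rising
to a NIR plateau (0.25–0.7); water: exponential decay toward the NIR;
bare soil: a gentle brightening ramp; built: near-flat — plus one to
three low-amplitude Gaussian bumps for within-kind diversity. Candidate
spectra are rejected until every pair is separated by a spectral angle
of at least 0.05 rad and the red-edge sign contract holds (NIR mean >
red mean for vegetation, the reverse for water), so NDVI is guaranteed
informative. Spectral feature widths scale with the band spacing: a red
edge steeper than the grid would decorrelate adjacent bands, which
contiguous-band sensors do not show.

**Layout and rendering.** Class regions are the argmax over per-class
Gaussian random fields smoothed at length scale `blob_smoothness`
(default 24 px), giving irregular interlocking blobs rather than convex
cells — deliberately, so edge features carry signal. Every pixel is its
class endmember times `(1 + texture)` times `(1 + illumination)` plus
iid Gaussian noise, clipped to [0, 1]:

* *texture* — per-class smoothed noise with a class-dependent
  correlation length (0.8–4.1 px), amplitude 0.05. Multiplicative and
  spectrally flat, so it survives PCA and is visible to the GLCM.
* *illumination* — one scene-wide smooth brightness field (σ = 16 px),
  amplitude 0.10, shared by all bands: the sun-angle/topography
  common mode that gives real cubes their strong inter-band redundancy.
* *noise* — iid per band, σ = 0.005 reflectance. Calibrated together
  with the spectral smoothness so adjacent-band correlation stays above
  0.9 under the default scene, the redundancy the PCA step presumes.

One global seed fans out to fixed per-stage child seeds (endmembers,
class map, texture, noise, illumination), so stages can be regenerated
independently and whole scenes are bit-reproducible.

**What this does not model:** mixed pixels and sub-pixel abundances,
atmospheric effects, sensor striping, spatially varying class spectra.
Passing the end-to-end test therefore shows the pipeline is correct and
trainable, not that the accuracy figures transfer to real imagery.

## Preprocessing

PCA is the standardized (correlation-matrix) variant: per-band z-score,
then an eigendecomposition of the covariance of the standardized pixels;
the top k = 6 eigenvectors are kept. Component signs are fixed by making
each column's largest-magnitude loading positive, so fits are
deterministic across eigensolvers. Constant bands get unit scale with a
warning. Scenes are tiled into non-overlapping squares (edge divisible
by 16 so four 2× poolings stay integral; 64 px default against 512 px at
full scale), remainders reflect-padded with the padding recorded, and
split 8:2 at the tile level by a seeded shuffle — splitting pixels
instead would leak spatial context across the split.

## Feature branch

* **NDVI** from the raw cube at the nearest bands to 800/670 nm
  (configurable). Where NIR + R = 0 the output is defined as 0, matching
  the bare-substrate reading of a vanishing index. Band lookup widens
  its 50 nm tolerance to half the local band spacing on coarse grids, so
  nearest-band selection inside the covered range never fails.
* **GLCM** on PC1 (most variance; configurable), min-max scaled and
  quantized to 16 gray levels. For each pixel, all pixel pairs inside
  its 3×3 window at four symmetric offsets (0°, 90°, 45°, 135°) are
  accumulated into one normalized co-occurrence distribution, summarized
  as homogeneity, mean, dissimilarity and entropy. The window size is
  the method's fixed choice; levels and offsets are common texture
  -analysis defaults, kept configurable. The sliding implementation is
  vectorized over pair "slots" and verified pixel-for-pixel against
  brute-force pair enumeration.
* **Sobel magnitude** on the same PC1 image with the two classic 3×3
  directional masks applied as cross-correlation; one channel, so the
  branch totals 6 (1 + 4 + 1).

Every sliding operation uses edge-excluding reflect padding, keeping all
rasters pixel-aligned. Each channel is min-max normalized to [0, 1] with
the affine map recorded (`FeatureStack.raw_channel` undoes it).

## Networks

Feature maps are N×C×H×W float32 on a purpose-built numpy autograd
engine (`hsiseg.nn`) with finite-difference-tested backward rules for
every op. Initialization is He-normal from a per-model seed (transfer
from RGB-pretrained weights is not meaningful for 6-channel dual
inputs, so training always starts from random weights).

Block ordering is DW → PW → BN → (+input) → h-swish; one batch norm
after the pointwise convolution, activation after the residual add. The
shortcut is identity-only: blocks that change width simply omit it
(logged once), because a projection shortcut would contradict the
block's zero-parameter-shortcut design. Within each level the first
block changes width and the second preserves it, so every level carries
one shortcut.

Both builders use five levels at widths (32, 64, 128, 256, 512) by
default — widths are a free choice here, so absolute parameter totals
are configuration-dependent; the invariants (residual toggle changes
nothing; separable ≪ plain at equal widths) are what the tests pin.
Down-sampling is 2×2 max pooling; up-sampling is 2× bilinear
interpolation (align-corners-false weights; nearest available) followed
by a 1×1 width reduction, then skip concatenation and two blocks. Dual
-branch fusion is per-level concat + 1×1 reduction of the two encoders'
pre-pool maps; the two encoders never share weights.

## Training

Per-pixel classification is treated as C independent binary problems:
sigmoid per class, masked mean binary cross-entropy in the numerically
stable fused form, argmax fusion at prediction. Unlabeled pixels
(label 0) and tile padding are masked out of loss and metrics; a softmax
cross-entropy alternative sits behind a config flag. The optimizer is
Adam (β = 0.9/0.999, float64 moments — squared gradients overflow
float32). The full-scale protocol is batch 4, up to 600 epochs, lr 1e-4
with an optional ×0.1 step at epoch 100 (kept optional because a
constant schedule is the conservative reading of an ambiguous
protocol); desk-scale runs use 30 epochs at lr 1e-3, scaling the rate
up as the step budget shrinks ~20×. This calibration was fixed before
any experiment was run. Batch norm uses batch statistics in training
and running estimates (momentum 0.1) at inference; the best
validation-loss state is restored after training. A non-finite loss
aborts with the offending epoch.

## Metrics

Confusion matrices count labeled pixels only (rows = truth). Precision,
recall and F1 are per class with zero denominators flagged and scored 0;
macro averages cover classes present in the truth. Grouped F1 collapses
the matrix by first-level cover groups before recomputing, so
within-group confusion vanishes — collapsing can only raise overall
accuracy. Tables render percentages at two decimals; internal values
stay fractions.

## Experiment ladders

`run_experiment` trains every variant of a ladder (e1 architecture, e2
single-input stacking, e3 dual-branch fusion) from one shared,
byte-identical 12-channel tile set — variants slice their channels out
of it — with the same seed and split, and writes a comparison table,
per-epoch histories, checkpoints and a regenerable report. Whether the
qualitative orderings seen at full scale (stacking hand-crafted features
onto spectra in a single input hurting; dual-branch fusion helping)
reappear on synthetic scenes is an empirical question the runner
surfaces but the tests deliberately do not assert. Desk-scale problem
sizes throughout: 256×256×32 scenes, 5 classes, 64 px tiles, 30 epochs
— small enough for minutes-scale CPU runs while leaving every pipeline
stage non-trivial.

## Known limitations

* The autograd engine is minimal by design: no broadcasting, no GPU, no
  mixed precision; wall-clock performance is adequate for desk-scale
  experiments only.
* Batch norm with very small batches can leave running statistics that
  lag batch statistics on hard, noise-free scenes; validation-based
  checkpointing mitigates this.
* GeoTIFF support carries wavelengths in a JSON image description, not
  in per-band GDAL metadata; map projections are out of scope.
* The ENVI codec covers the common header keys (samples, lines, bands,
  interleave, data type, byte order, wavelength) and all three
  interleaves, not the full header zoo.
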