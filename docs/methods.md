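# Methods

## Problem setting and model

`tomopick` localizes macromolecular particles in reconstructed cryo-electron
tomograms given only center annotations. The picking model is a voxel-wise
classifier: a 3D residual U-Net maps a cubic subtomogram to per-voxel class
probabilities (background plus one channel per particle species), trained
against *weak labels* — simple geometric masks stamped around the annotated
centers. The working assumption is that a blob-shaped over- or
under-segmentation of each particle is sufficient supervision for center
*localization*, because the postprocessing (MP-NMS) only needs each
particle's predicted foreground to form a connected blob whose centroid is
near the true center; the mask need not trace the molecular envelope.

### Weak labels

Masks live on the lattice cube [-r, r]³: `cubic` keeps every point, `ball`
keeps ‖x‖ < r, and the default `tball` (truncated ball) keeps ‖x‖ < √2·r.
Set membership is evaluated integer-exactly (‖x‖² < r², ‖x‖² < 2r²);
lattice points exactly on the √2·r sphere are excluded by the strict
inequality, giving 7 voxels at r=1 and 275 at r=3. The mask diameter
d = 2r+1 must not exceed the particle diameter; particle diameters outside
7–25 voxels trigger a warning and are best handled by re-binning the
tomogram. The default is a constant d = 7 regardless of particle size: a
constant-size label avoids class imbalance between species and, in
practice, slightly noisy labels of this kind regularize rather than hurt.

When stamps of two particles overlap, each voxel is assigned to the nearer
center (ties to the earlier record). This keeps adjacent particles
separable downstream, which is exactly what MP-NMS needs.

### Network

Input channels: the intensity volume, plus (optionally) three coordinate
channels normalized to [-1, 1] ("coordinate convolution") and, at each
encoder stage, a 2×/4×/8× average-pooled copy of the raw input ("image
pyramid"). The encoder is a stem (one 3³ conv → b channels at full
resolution) followed by three stages; each stage max-pools by 2³ and
applies a residual block (two 3³ convolutions with a 1³ projection on the
skip when widths change) doubling the width: b, 2b, 4b, 8b. The decoder
mirrors the encoder with 2³ transpose convolutions (stride 2) and skip
concatenations; the full-resolution decoder unit mirrors the stem as a
single conv block; a 1³ convolution and per-voxel softmax produce the
score map. Activations are ELU. The residual connections, coordinate
channels, pyramid inputs, normalization, and augmentation can each be
switched off independently for ablation.

Design choices where the architecture was genuinely open:

* **Downsampling** is 2³ max pooling; upsampling is transpose convolution
  with kernel 2, stride 2.
* **Normalization**: each convolution is followed by channel-wise
  normalization over the spatial dimensions of the sample (batch-norm
  semantics at batch size one), with running statistics used at
  evaluation. Evaluation-mode normalization is therefore an affine map
  independent of the input, so inference is a fixed function of the tile —
  a property the overlap-tile stitching relies on. Configurable off.
* **Stem and its mirror are single conv units** while the three halving
  stages are double-conv residual blocks; this concentrates capacity at
  the coarser scales where context lives and halves the full-resolution
  compute, which dominates the cost of a pure-numpy implementation.
* **Width**: base_channels = 32 by default (≈5.6 M parameters — small by
  volumetric-segmentation standards); the test and reproduction
  experiments use 16 and 8 to stay fast on a single CPU core.

All layers carry hand-written forward and backward passes in numpy
(convolutions are evaluated as a single flat-shift im2col GEMM; the input
gradient is the same operation with the flipped kernel). Gradients of every
layer and of the assembled network are verified against central finite
differences in the test suite.

### Training

One training window per annotated particle per epoch, centered on the
particle and shifted inward (never padded) at volume boundaries — so every
window contains at least one particle and all annotations are used each
epoch. Augmentation (each transform with independent probability 0.5):
axis mirrors; scaling in [0.95, 1.05] and rotation about the beam axis
within ±15°, applied as one trilinear/nearest affine; elastic deformation
with a smooth displacement field capped at 5% of the window side. The loss
is the multi-class Dice loss over foreground classes (ε = 10⁻⁸); the
background channel is supervised implicitly through the softmax
competition. Optimization is AdamW with learning rate 10⁻³ and weight
decay 0.01, batch size 4 realized by gradient accumulation, no schedule.
After each epoch the model runs the *full inference chain* on a held-out
validation scene; the checkpoint maximizing F1_α (α = 3, favoring recall —
false positives can be discarded during later subtomogram classification,
missed particles cannot be recovered) is returned. Training is
deterministic for a fixed seed up to floating-point reassociation in BLAS.

### Inference and postprocessing

The tomogram is reflect-padded by `pad_size` on every face and scanned with
N³ tiles at stride s = N − 2·pad_size; only each tile's central s³ region
is written to the stitched score map (trailing tiles are clamped flush), so
every voxel is predicted exactly once and never from a tile border region.
Per foreground class the map is binarized at t_seg, mean-filtered
(`k = 3`, zero padding) for n_iter = ⌈2r/(k−1)⌉ iterations, and strict
26-neighborhood local maxima are extracted; maxima with soft value below
t_lm are dropped and, processing in decreasing value, any maximum closer
than t_dist to an already-kept one is discarded. Pick scores are soft
values normalized by the class-wise maximum.

Numerical details: because the MP input is binary, the iterated mean
filter is computed as iterated integer box sums divided by k^(3·n_iter),
making local-maximum comparisons and tie-breaks exact (no float ties). On
plateaus a voxel also qualifies as a maximum when it equals a neighbor it
precedes in lexicographic (z, y, x) order and strictly exceeds the rest —
so a plateau yields exactly one candidate. Defaults: t_seg = 0.5,
t_lm = 0.1, t_dist = r.

Overlap-tile equivalence — tiled picks equal whole-volume picks — is exact
precisely when the model's receptive field fits inside the pad margin
(pad_size ≥ model RF, and ≥ r + n_iter for the pooling stage); the test
suite verifies it bit-exactly with a bounded-receptive-field model. For
the full encoder-decoder, whose receptive field spans the tile, the
equivalence is approximate and improves as training focuses the network on
local structure; this is the practical regime the overlap-tile strategy is
designed for.

### Evaluation

Matching between picks and reference centers is greedy one-to-one in
increasing distance with acceptance radius r (the particle radius);
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R), 0/0 → 0, and
AD is the mean matched distance in voxels. Greedy matching can in
principle return fewer pairs than optimal assignment on adversarial
conflict chains; on the non-degenerate instances that occur here it equals
the optimum (tested against a Hungarian oracle). The same greedy machinery
computes intersection/difference sets between two pickers (threshold
t_dist, normally half the particle diameter), which keeps the two analyses
mutually consistent. FSC uses shells one frequency voxel wide (DC shell
included, rounded-radius binning); the resolution is the linearly
interpolated FSC = 0.143 crossing, or the Nyquist bound 2·voxel size,
flagged as a bound, when the curve never crosses.

## The simulator: what it emulates and what it does not

Scenes are cubic volumes with non-overlapping solid particles (balls,
cubes, or z-axis cylinders) of stated diameter and contrast, placed by
rejection sampling under a minimum center separation; the clean density is
optionally Gaussian-smoothed (σ = 1 voxel by default, mimicking the
band-limiting of reconstruction) and corrupted with i.i.d. Gaussian noise.
The reported SNR is std(clean density)/noise σ — a *global* measure:
because foreground fills only a few percent of a scene, SNR 2 corresponds
to an easy task (per-voxel contrast ≈ 20× the noise), and degradation sets
in around SNR 0.1–0.3. The simulator does **not** model the missing wedge,
CTF, crowding, or structured background; consequently, passing the
recovery tests demonstrates that the pipeline is implemented correctly and
recovers well-separated blob-like particles under additive noise — not
that it matches any particular performance level on real tomograms.

## Reference experiment and problem sizes

The reproduction script runs one reference condition: 96³ scene, 20 balls
of diameter 9 voxels, minimum separation 12, global SNR 2, truncated-ball
labels d = 7, base width 16, 30 epochs, training windows N = 48,
validation on a separate 48³ scene with 4 particles, picking with default
thresholds and pad_size = 8. The robustness checks rerun a scaled replica
(64³, 10 particles, base width 8, 20 epochs, N = 32, validation on a 32³
scene) across SNR ∈ {2.0, 0.2, 0.03} and three seeds, and with training
annotations jittered by 0.5–0.7·r (labels themselves shifted; the
evaluation truth is not). The replica's epoch count was set so that
optimization reliably converges at the reference SNR for every seed —
otherwise the noise sweep measures convergence failures rather than the
noise response — and the three noise levels were spread to separate the
saturated, degraded, and floor regimes. These sizes keep the full suite
within minutes on a single CPU core while leaving the qualitative trends
(noise degrades F1; center jitter barely does) clearly visible.

## Known limitations

* Pure-numpy training is single-threaded BLAS-bound; wall-clock cost grows
  steeply with base width and window size. The architecture is the point,
  not the throughput.
* No cross-class suppression by default (each class is post-processed on
  its own binary map); crowded multi-class scenes may yield overlapping
  picks of different classes.
* The simulator's additive-noise model understates the difficulty of real
  in-situ data (missing wedge, structured background).
* STAR output covers the coordinate loop (plus class and score tags) only;
  it is not a general STAR round-tripper.
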