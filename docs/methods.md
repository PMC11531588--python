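# Methods

## Problem and data model

A 3D acoustic-coring scan of one sediment bucket is a non-negative
reflection-intensity grid `I(x, y, z)` — 125 × 100 scan positions at 2 mm
pitch, 693 envelope samples deep. The usable region of each A-scan lies
between the bright sediment-surface reflection and its *multiple* (the
spurious second copy of the surface echo from re-reflection); buried clams
appear there as localized backscatter. The analysis estimates, per
25 × 25-pixel column ("local voxel"), whether clams are present and how
many (0 / 1 / "2 or more"), and integrates the per-tile counts of a
bucket's 5 × 4 non-overlapping tiling into an abundance estimate.

## Synthetic volumes

The simulator generates the structures this analysis relies on, not the
acoustic physics below the envelope:

* **Reflection bands.** Gaussian bands along z (σ = 4 samples) at
  `surface_z` (amplitude 1.0) and `multiple_z` (amplitude 0.35). The
  multiple is *not* sediment-attenuated: its extra path is through the
  water column.
* **Targets.** Each clam is an anisotropic Gaussian blob
  (σ_xy = 1.5 px ≈ the 4 mm beam width at 2 mm pitch, σ_z = 8 samples,
  amplitude 0.6); confounders (mussels/stones, for M/AM buckets) are
  smaller and dimmer (σ_xy = 1.0, amplitude 0.3), which makes AM buckets
  harder than A. Centers are rejection-sampled with a minimum pairwise
  separation of 8 px; an over-dense request fails loudly.
* **Depth placement.** Clam depths are uniform over the 15–60 % band of
  the surface→multiple gap: clams burrow in the upper sediment, and
  deeper targets would vanish under attenuation anyway.
* **Attenuation.** Two-way amplitude decay of 100 dB/m below the surface
  at 0.15 mm sediment depth per z sample, applied to target amplitudes.
* **Noise.** Additive Gaussian noise (σ = 0.05) clipped at zero, mimicking
  envelope output.
* **Study composition.** `simulate_study` builds 5 buckets per type
  (C/A/M/AM). A/AM buckets receive 40 clams each before *retention*: the
  per-bucket measured count is Binomial(40, 0.9), because placed clams
  die, escape, or elude identification — with identical true counts the
  count-correlation analysis would be degenerate.

What the simulator does **not** emulate: waveform-level time series,
focal-zone diffraction, shell-material contrast, speckle, probe
artifacts, clam-shaped (non-Gaussian) backscatter, and spatial clustering
of clams. Passing tests therefore demonstrate that the pipeline's
machinery is correct and that the method recovers abundance when its
assumptions hold — not that the trained models transfer to measured
volumes.

## Preprocessing

The depth profile `P(z) = Σ_{x,y} I(x,y,z)` is smoothed with a 5-sample
moving average; its two most prominent local maxima (scipy peak
prominence, threshold 10 % of the profile span) are the surface and
multiple reflections. The analysis window excludes a 15-sample band
margin around each peak; fewer than two prominent peaks raises a
windowing error carrying the profile for diagnosis. The cropped depth
range is linearly resampled to a fixed 693-sample grid (the coordinate
map is monotone, so depth ordering is preserved), and intensities are
divided by the volume maximum. Normalization is configurable
(`none | max | zscore`); per-volume max was kept as the default after
comparison — disabling it degraded every cross-validated metric on
simulated studies.

## Labeling

Windows of 25 × 25 scan pixels slide at stride 1 (101 × 76 = 7,676
origins per bucket). A clam at integer (x, y) is attributed to a window
iff it lies inside the footprint `[x0, x0+24] × [y0, y0+24]` or its
Euclidean point-to-rectangle distance is strictly less than 11 px
(backscatter near a border still contributes signal); a Chebyshev metric
is available behind a config switch. Presence = ≥ 1 attributed clam;
count labels collapse ≥ 3 to "2 or more". Clam depth is ignored for
labeling (positions are annotated in the horizontal plane). Balanced
datasets draw a fixed number of windows per label stratum, seeded,
without replacement; an undersized stratum is included in full with a
logged warning.

At 40 clams per bucket the 11-px halo makes "0" and "1" windows rare in
A/AM buckets and concentrates them near bucket edges; this scarcity, not
model capacity, is what makes the count task slow to converge in some
folds (see Training).

## Models

Two sequential 3D-CNNs (presence: 2 classes; count: 3 classes) built from
Conv3D → ReLU → MaxPool blocks, global average pooling, and a dense
softmax head. The default architecture is

    conv1: 8 ch, kernel 3×3×5, stride 2×2×4 — pool 2×2×2
    conv2: 16 ch, kernel 3×3×3             — pool 2×2×2
    global average pool — dense head

(≈ 3.9 k parameters). The first block strides aggressively along z
because the depth axis is ~28× deeper than the scan footprint. All layers
implement explicit backpropagation in numpy (im2col + GEMM convolutions,
col2im scatter for input gradients); gradients are verified against
central differences in the test suite. Loss is cross-entropy; the
optimizer is Adam.

Training defaults follow the bucket-study protocol — batch size 3,
learning rate 1e-6, at most 50 epochs (30 for the count model), early
stopping after 10 epochs without validation-loss improvement, restoring
the best-validation weights. "No improvement" is measured on validation
loss (configurable); patience counts consecutive non-improving epochs,
so patience 0 halts at the first one.

## Cross-validation and metrics

Stratified Group 5-fold CV with buckets as groups
(sklearn `StratifiedGroupKFold`, seeded): in fold *f* the buckets of fold
*f* are test, those of fold *f+1 (mod 5)* are validation, the remaining
three train — whole-bucket assignment realizes the 60/20/20 split at fold
granularity, which is the only consistent reading when every sample of a
bucket must share a role. Headline metrics are computed on the pooled
test predictions concatenated across folds (per-fold and per-bucket
accuracies are also logged); pooling was chosen because single ROC curves
over all held-out predictions are the natural summary, and is documented
rather than assumed. Binary tasks report F1 and ROC-AUC of the presence
class; the count task reports macro-F1 and one-vs-rest macro ROC-AUC.
Single-class inputs raise an undefined-metric error rather than returning
a number. A no-learning baseline (per-voxel mean/max intensity as score)
is provided for comparison.

## Abundance integration

Bucket counts sum the predicted classes of the 20 non-overlapping tiles
(0 → 0, 1 → 1, "2 or more" → `ge2_value`, default 2 — the class's lower
bound, chosen because overlapping reflections make higher counts
unresolvable; an expected-count mode over class probabilities is
provided). Each bucket is predicted by the model of the fold that held it
out. Errors: MAE per type; MRE only for clam-holding types (relative
error is undefined at zero truth; omissions are warned); Pearson
correlation overall and restricted to A+AM.

## Grad-CAM

For a chosen convolutional layer (default: the last conv block), the
gradient of the target-class logit w.r.t. the feature map is averaged
spatially into per-channel weights; the rectified weighted sum of feature
maps is trilinearly upsampled to the input shape and normalized by its
maximum (per volume, not per panel, so brightness is comparable across
depth). A zero gradient yields an all-zero map with a warning instead of
a division by zero. Display averages volumes in 10-sample blocks along z
(70 panels for a 693-deep voxel); block averaging conserves the
slice-count-weighted mean.

## Reduced-size reference experiment

The reference experiment (`desk_scale_config`, used by
`scripts/acceptance.py`) keeps the full scan geometry and study
composition — 20 buckets, 40 clams per A/AM bucket before retention — and
scales only the training arithmetic: model input depth mean-pooled 4-fold
(693 → 173), learning rate 1e-3, batch 4, per-label targets of 40
(presence) / 60 (count) windows, presence 25 epochs / patience 10, count
70 epochs / patience 15. The count model trains longest because "1"
windows are scarce and bucket-concentrated (see Labeling); folds whose
training buckets hold few of them need more epochs to converge. The whole
experiment is deterministic given its seed and runs in minutes on one
CPU.

## Known limitations

* The mapping of the 250 × 200 mm scan area onto the 580 × 155 mm bucket
  footprint is not modeled; the grid is treated as the full region of
  interest.
* Whether the 693-sample depth describes the raw or the standardized
  grid is ambiguous for measured scans; it is treated as the
  standardized target, and the resampling mechanism (linear
  interpolation) is this package's choice.
* Per-bucket dataset totals of measured bucket scans are not reproduced:
  they depend on an unseeded random extraction.
* Bucket-level count estimates are capped at 2 per tile, so true counts
  far above 2 per tile would be systematically underestimated.
* Simulated performance does not transfer to measured volumes; see the
  simulator's non-goals above.
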