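# Methods

## The model

`corticalhue` implements a four-stage feedforward model of local hue
representation in the primate ventral stream.  All stages share one
piecewise-linear rectifier

    phi(P) = tau            if m*P + b < tau
             m*P + b        if tau <= m*P + b <= s
             1              otherwise

with slope `m = 1` and base rate `b = 0` unless noted.  Receptive fields are
normalized isotropic Gaussians; convolution is "same"-size with
edge-replication padding, and kernel sides follow the doubling schedule
19, 38, 76, 152 px for mLGN, mV1, mV2, mV4 (even sides are bumped to the next
odd number so the kernel centre is a pixel).  Inputs are 256 x 256 LMS cone
images.

**mLGN** — six single-opponent centre–surround types (L/M/S x on/off).  The
centre is a single cone (weight 1, sigma = rf/8); the surround draws on L and
M (never S) with balanced weights such that centre and surround drives cancel
exactly at the white point, so achromatic uniform input is silent
(sigma = rf/4).  Off-cells are sign-flipped on-cells.  The rectifier uses
`tau = -1, s = 1`, keeping mLGN linear in cone contrast.

**mV1** — Gaussian smoothing of each mLGN map followed by half-wave
rectification (`tau = 0, s = 1`); six types.

**mV2** — fourteen types.  Six "additive" (single-opponent) cells repeat the
mV1 computation at double the receptive field; on spatially uniform stimuli
they replicate mV1 responses to floating-point accuracy.  Eight
"multiplicative" cells are products of a smoothed L/M-opponent mV1 signal and
a smoothed S-opponent mV1 signal ({L-on, L-off, M-on, M-off} x {S-on, S-off}),
rectified.  Multiplication is quadratic in cone contrast, which narrows
tuning and rotates peaks to intermediate hue directions.

**mV4** — six types targeting the HSL hues 0, 60, ..., 300 (red, yellow,
green, cyan, blue, magenta).  Each is a rectified weighted sum of smoothed
mV2 maps; the weight from mV2 cell j to mV4 cell i is a Gaussian
(sigma = 30 deg, configurable) of the circular distance between the mV2
cell's measured tuning-peak hue and the target hue, both expressed as
MacLeod-Boynton (MB) angles, with each row normalized to sum to 1.

## Colour conventions

Stimuli are HSL colours converted to sRGB, gamma-linearized, mapped to CIE
XYZ (D65) and then to LMS with a Stockman–Sharpe-based matrix.  Cone
fundamentals have arbitrary per-cone scale; the S row is multiplied by a
frozen calibration constant (0.27787...) chosen once so that the HSL red
primary lands at 18 deg in the MB plane — the conventional anchor for this
stimulus set.  The same scaled cones feed the network, which brings the
S-opponent channel into the same response range as the L/M-opponent
channels.  Hue angle is atan2 of (l_mb - l_w, -(s_mb - s_w)) relative to the
mid-grey white point, placing lime at the top of the circle.  A consequence
of linearity is that complementary HSL hues are exactly opposite in the MB
plane (cyan = red + 180 deg).  The HPE matrix can be substituted through
`rgb_to_lms_matrix`; downstream peak positions shift by several degrees with
the choice of fundamentals.

## Calibration

`HueModel.calibrate()` runs the 60-hue tuning protocol (saturation 1,
lightness 0.5) in closed form and fixes, in order:

1. the **multiplicative gain** (default auto): raw products of rectified
   mV1 signals are roughly 20x weaker than additive responses, and the
   population read-outs (winner-take-all, reconstruction) need commensurate
   magnitudes; the gain equates the strongest multiplicative peak with the
   strongest additive peak.  Tuning peak positions and bandwidths are
   invariant to this scaling in the unsaturated regime.
2. the **pooled-cell thresholds**: the pooling variant window-averages the
   same-type single-opponent mV2 map (3 x 3 default) and subtracts a
   threshold equal to half the cell's maximal pooled response over the
   stimulus set before half-wave rectification (the iceberg effect).  This
   narrows every cell's tuning without moving its peak.  A saturating
   formulation was rejected: clipping the top of a tuning curve widens the
   half-height bandwidth rather than narrowing it.
3. the **mV2 peak hues** (plateau-of-maxima resolved by circular mean) and
   the **mV2→mV4 weight matrix**.

Because kernels are normalized and borders replicate edge pixels, a uniform
stimulus stays uniform through the whole cascade, so the closed form used in
calibration is exactly the spatial model evaluated at any pixel; tests pin
the equivalence at 1e-10 against full 256 x 256 runs.

## Analyses

**Tuning** — responses at the image centre over 60 uniform hue fields,
indexed by stimulus MB angle (non-uniformly spaced; curves are linearly
interpolated on the circle).  **Bandwidth** follows the half-height
convention for V2 colour cells: per side, the threshold is halfway between
the peak response and the response 90 deg away; the bandwidth is the mean of
the two crossing offsets (the symmetric estimate; a one-sided variant would
shift means by a few degrees).  **Peaks** use the circular mean of a
contiguous plateau of maxima.  **Unique-hue distances** compare layer peak
sets to four reference angles shipped as an editable config block — they are
placeholders for psychophysical unique-hue measurements, not asserted
values.

**Hue-distance correlation** — 12 hues at 30 deg HSL spacing; the six mV4
maps are stacked (magenta, red, yellow, green, cyan, blue) so each spatial
column is a model cluster; per hue the maximally activated patch at the
central cluster is found and, over all 66 hue pairs, the absolute patch-index
distance is correlated (Pearson) with an ordinal hue distance (values 0 to
5.5 in 0.5 steps, magenta = 0).  The patch distance is non-cyclic, matching
the non-cyclic ordinal values.

**Hue reconstruction** — for a fixed hue, 500 (saturation, lightness) pairs
drawn independently and uniformly on (0, 1); each sample's six mV4 centre
responses are divisively normalized (population normalization — the raw
responses share a common saturation/lightness envelope that otherwise
dominates a constant-target regression), the target is the hue as a number
in (0, 2*pi], and weights solve an L1-penalized least squares (lambda = 0.03
on the normalized design; the dominant weights are stable across
lambda in [0.03, 0.1]).  Reported weights are normalized to sum to 1.  The
random draws are the package's only stochastic component and are governed by
an explicit seed.

## What the synthetic stimuli do and do not cover

All experiments use spatially uniform colour fields (plus a hue-wheel demo
image).  Uniform stimuli isolate the chromatic pathway: spatial structure,
double-opponency, luminance edges and natural-image statistics are outside
the model, so passing results say nothing about spatial chromatic processing
or about responses to textured scenes.  The hue circle enters all analyses
through one calibrated colour conversion; quantities tied to absolute MB
angles (peak anchors, the lavender read-out split) are sensitive to the
choice of cone fundamentals at the several-degree level.

## Numerical choices and limitations

- Tolerances: spatial/closed-form equivalence 1e-10; weight-row
  normalization 1e-12; bandwidth crossing scan step 0.05 deg with linear
  refinement.
- Ties in `tuning_peak` are resolved by the circular mean of the contiguous
  run of maxima containing the argmax (tolerance 1e-9 relative to the peak).
- Degenerate inputs raise typed errors (achromatic hue angle, zero L+M,
  constant tuning curves, all-zero reconstruction designs, zero-variance
  correlation variables).
- The auto-calibrated multiplicative gain equates population maxima, not
  per-cell maxima; individual mV4 cells therefore differ in absolute
  response scale, and the yellow mV4 cell's peak sits closer to the green
  flank than its target.  Only relative (normalized) read-outs are used
  downstream.
- With the shipped conversion, the lavender (HSL 270) read-out is dominated
  by the blue mV4 cell rather than magenta; the blue peak (262 deg) is the
  nearest neighbour of lavender (270 deg) on our MB circle.  See the
  calibration sensitivity note above.
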