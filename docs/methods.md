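# Methods

This note records the models, conventions and numerical choices behind
`choroseg`, and what the phantom-based tests do and do not demonstrate.

## Coordinates and data model

Images are 8-bit grayscale grids with row 0 at the top (inner retina) and
one A-scan per column; indices are 0-based and crops half-open.  Boundary
traces give, per column, the inner choroidal boundary (ICB, the RPE/Bruch
complex) and outer choroidal boundary (OCB, the choroid–sclera
transition), with `icb[c] ≤ ocb[c]`.  Label maps take exactly three
values — interstitial, lumen, sclera — stored in color label images as
grey 0, grey 255 and RGB (127,0,0) respectively; the codec is byte-exact
and label images are written only as lossless PNG, since any lossy format
would corrupt the mask color.

## Flattening

Local binarization needs a rectangular analysis region, but the posterior
eye is curved.  Each A-scan is shifted up by its integer ICB row (no
sub-pixel resampling — shifts are a pure permutation, so 8-bit values are
preserved exactly and flattening is invertible on in-range pixels), then a
fixed-height rectangle is cropped.  The crop height is computed once per
dataset as the maximum `ocb − icb` over all columns of all images plus a
scleral margin, and applied identically to every image.  The margin
defaults to 15 rows; it is an explicit parameter because "how much sclera
to keep" is a choice, not a derived quantity, and the evaluation treats
sclera as its own category.  The 6 mm subfoveal strip is
`round(6000 / lateral scale in µm)` columns centered on the fovea
(429 columns at the 14 µm transverse sampling assumed by default).

## Niblack binarization

The threshold map is `T = m + k·σ` over a square sliding window, with
population (divide-by-N) standard deviation and `k = −0.05`.  Numerical
conventions, all pinned so two implementations agree bit-for-bit:

* borders are handled by symmetric (edge-mirroring) padding so every
  window is full — Niblack is notoriously noisy in windows that contain a
  single class, and truncated border windows would make this worse;
* even window sizes center at offset `floor(w/2)` inside the window;
* windowed moments come from integral images computed on globally
  centered values (`x − mean(x)`), which keeps the cumulative sums small
  enough that the map matches a naive per-window evaluation to below
  1e−9 in double precision;
* ties (`intensity == T`) classify as interstitial: only strictly
  sub-threshold, i.e. genuinely hypo-reflective, pixels are lumen.  This
  also gives the noise-free phantom the right behaviour (zero-variance
  windows classify as stroma rather than arbitrarily);
* lumen maps to white (255) in encoded labels, so the CVI counts "white
  pixels over choroid pixels".

The window-size sweep evaluates the full chain (threshold → classify →
CVI over the choroid region) for windows 20–75 and, in the pipeline
default, on the subfoveal strip; whether to sweep the full flattened
width instead is a flag at the CLI level.  `select_window` replaces the
interactive window choice with an explicit criterion: with a reference
fraction, the window whose CVI is nearest to it; without one, the left
edge of the flattest stretch of the CVI-vs-window curve (smallest
absolute slope between consecutive windows, smallest window on ties).
The fixed-window baseline is 51 pixels.

## Ground truth and dataset assembly

Flattened scans are resampled to the 224×896 network grid (bilinear for
intensities, nearest-neighbour for labels and boundary rows; the resize
kernel is a documented package choice).  The network input replicates the
grayscale to three channels and paints scleral pixels with the same
(127,0,0) color used in the labels; this "highlighted region" makes the
sclera trivially learnable and concentrates the model's capacity on the
lumen/interstitium distinction.  A `paint_sclera=False` variant exists
precisely so the effect of the mask can be measured.  Each 224×896
image/label pair is split into four non-overlapping 224×224 tiles at
column offsets 0/224/448/672; tiling is a partition, and every evaluation
is computed on reassembled full-width images, never on tiles, so tile
boundaries cannot bias metrics.  Subjects are assigned whole to
train/validation/test (60/20/20 by default, largest-remainder rounding,
deterministic under a seed), so no subject's scans straddle partitions.
Per-image category percentages and CVI are summarized as mean ± SD per
partition; an image with no choroidal pixels reports CVI as missing,
never 0, so degenerate images cannot bias partition means.

## Segmentation networks

Both architectures use a depth-4 encoder with the filter count doubled at
each pooling stage (encoder filters `f·{1,2,4,8}`, bottleneck `f·16` for
the U-Net) and a per-pixel 3-class softmax head.  The U-Net concatenates
each encoder stage into the matching decoder stage and upsamples with
learned 2×2 transposed convolutions; the SegNet-style variant has no
skips and upsamples by max-unpooling with the indices memorized by the
encoder's 2×2 pooling layers, trained from random initialization.  The
stack is implemented directly on numpy: convolutions are evaluated as
nine channel-mixing GEMMs (one per kernel tap) accumulated at the tap's
shift, which keeps all BLAS operands contiguous and is several times
faster on one core than an im2col formulation; backward passes are
hand-written and verified against float64 directional derivatives to
relative error below 1e−5.  Argmax ties resolve to the lowest class
index.

Training uses Adam, unweighted cross-entropy, shuffling every epoch and
mini-batches of 10.  Two profiles exist:

* **full-scale**: 64 base filters, 15 epochs, learning rate 1e−4 — the
  regime intended for a real multi-thousand-tile dataset;
* **desk**: 16 base filters, 5 epochs (default), learning rate 1e−3 —
  sized for phantom experiments on one CPU.  The higher rate is needed
  because a desk run takes only ~100 optimizer steps: at 1e−4, Adam's
  per-step displacement is too small to move a randomly initialized
  network into a useful regime in that budget.

A replicate helper trains several runs with identical hyper-parameters
and consecutive seeds so results can be reported as mean ± SD.

## Evaluation statistics

Accuracy is recall-style `TP/(TP+FN)` per class; total accuracy is the
correct fraction over all pixels.  IoU is `TP/(TP+FP+FN)`; the mean skips
classes absent from both maps, and any metric with an empty denominator
returns missing (NaN) rather than raising or returning 0.  CVI excludes
sclera by definition and is therefore invariant to anything that happens
below the OCB.  Repeatability between the two same-visit scans is
`R = |P1 − P2|/p × 100` with `p` the total pixel count; it is a
pseudometric (non-negative, symmetric, zero on identical maps).  Paired
per-eye measurements use ICC(2,1) — two-way random effects, absolute
agreement, single measures, the standard model for test–retest of one
instrument (computed via pingouin; tests validate it against the
closed-form variance ratio σ²_b/(σ²_b+σ²_w) on simulated data) — and
Bland–Altman mean difference with 95 % limits of agreement
`±1.96 × SD(differences)` using the sample (n−1) SD.

## Phantom generator

The generator emulates the features of an averaged EDI-OCT B-scan that
this pipeline actually exercises: a smoothly curved ICB (parabola plus a
mild sinusoid, amplitude ~20 rows), a choroid band of mean thickness 45 ±
8 rows, dark elliptical vessel lumina (semi-axes 3–8 px laterally,
flattened vertically) placed by rejection sampling until the luminal area
fraction is within half a point of the programmed target (default 0.60,
matching the ~60 % CVI of healthy eyes) — overlapping vessels merge by
union so the truth fraction is an exact pixel count — a dimmer scleral
band below the OCB, a thin bright retinal band above the ICB for visual
context, and multiplicative gamma speckle (mean 1, SD 0.25, clipped to
8 bits).  The speckle level is moderate by design: clinical acquisitions
of this kind average ~30 frames, which strongly suppresses raw speckle
contrast.  Repeat pairs render one master phantom a few columns wider
than requested and expose two laterally offset windows with independent
speckle draws — same tissue, different scan.  A corpus mirrors a
longitudinal design (per subject and visit: one repeat pair in each of
two scan orientations) with per-subject anatomy held fixed across visits.
Everything is bitwise deterministic under the spec seed.

What the phantoms do **not** model: real speckle correlation, retinal
layers, shadowing and attenuation with depth, boundary-segmentation
error, or vessel shapes beyond ellipses.  Passing tests therefore
demonstrate that the algorithms are implemented correctly and recover
known parameters under controlled conditions — not that clinical-grade
accuracy would be achieved on patient data, and the desk-scale network
results make no claim about full-scale training behaviour.

## Degenerate inputs and failure modes

Boundary traces with `ocb < icb` are rejected at construction; a crop
height smaller than the deepest choroid warns rather than failing;
requesting a subfoveal strip that leaves the image raises; a phantom spec
whose vessels cannot fit the band fails with a generation error after a
bounded number of attempts; label images containing any off-palette pixel
fail decoding with the offending pixel named.
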