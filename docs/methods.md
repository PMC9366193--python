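# Methods

This note records the model, the parameter choices, and what the tests
do and do not establish. It is the package's own account of its design;
all numbers mentioned are computed by the test suite or
`scripts/acceptance.py`.

## Coordinate and raster conventions

All modules share one convention: 0-based `(row, col)` integer pixel
coordinates, row increasing downward, each pixel a unit square centred
on its integer coordinates. Where a chord direction is computed,
`x ≡ col` and `y ≡ row`. Rasters are conceptually padded with
background (0) for erosion footprint tests and edge extraction, so
foreground touching the image border counts as boundary. The
erosion/dilation duality `dilate(m, s) = ¬erode(¬m, reflect(s))`
requires the complement's exterior to be foreground; the `border`
argument of `erode` exists for exactly that case.

## Coarse boundary stage

The input is the delineated mask (a grayscale image is first binarized
at the 256-bin Otsu threshold; `skimage.filters.threshold_otsu` is the
implementation, and an independent exhaustive variance scan is the test
oracle). The morphological clean-up uses the two fixed templates — a
2×2 all-ones element (anchor top-left, since an even-sized footprint
has no centred pixel) and a 5×5 disk (Euclidean radius 2.5, centre
anchor) — arranged as *opening with the 2×2 square followed by closing
with the disk*. Opening removes one-pixel protrusions and stray
delineation pixels; closing bridges gaps up to about four pixels and
fills notches. Both operations are bias-free on smooth shapes, which
matters at 64×64 phantom scale: any variant that traces a dilated edge
band displaces the contour by ~2 px and costs ~15 IOU points on a
blob of radius ~17. A raw erode-then-dilate sequence applied to a thin
edge raster would annihilate it outright (no 2×2 block fits inside a
one-pixel curve), so the clean-up acts on the region and the single
edge extraction follows it.

Edges of a binary raster are defined as the inner morphological
boundary (foreground pixels with a 4-neighbour in background); this is
exact and oracle-checkable. Grayscale inputs go through Canny with
defaults sigma 1.0, thresholds 0.1/0.2 on [0,1] intensities — the
algorithm's conventional operating point; all are configurable.

Contour tracing uses Moore-neighbour tracing of the filled loop,
clockwise, starting from the topmost-then-leftmost pixel. Only the
largest closed loop is kept (ties broken by that same start pixel);
components with open endpoints are counted and reported in the
`OpenContourError` when no loop exists.

## Key-point refinement

Per column, only the minimum-row and maximum-row contour points are
retained before seeding — this discards the "disturbing" interior
points of thick delineations while keeping the vertical extremes that
define the shape. The four seeds are the extreme points in the four
axis directions, ties broken by smaller column then smaller row; a
point already selected for an earlier direction is skipped, because on
flat-sided shapes (a square) the bare tie-break hands two directions
the same corner pixel and would degenerate the seed set.

Each refinement round visits every adjacent key-point pair and inserts
the contour point of the *open cyclic arc between them* that minimises
the distance to the chord's perpendicular bisector, i.e. minimises
|(q − m)·D| with m the chord midpoint and D the unit chord vector.
Restricting candidates to the arc prevents the bisector's far-side
intersection from being chosen. Ties fall back to the smaller distance
to the midpoint, then the smaller cyclic index — a deterministic total
order. Empty arcs (the bottleneck case on narrow shapes) simply skip
insertion; refinement stops at the target count, when a round inserts
nothing, or after a hard cap of 10 rounds.

On 50 default phantoms the 16-point polygon reaches median IOU ≈ 0.96
against the source mask, the chord-length coefficient of variation is
roughly three times smaller than uniform-random contour sampling, and
median IOU grows monotonically over 4 → 8 → 16 points.

## Supervision maps

Key points are stamped as hard disks of radius 2 (value 1). Hard disks
keep the cross-entropy targets binary; no Gaussian smoothing is
applied. The alternative supervision variant marks the full one-pixel
inner boundary of the mask. One full-resolution ground-truth map is
shared by all heads — the heads upsample to input resolution rather
than the target being downsampled, so supervision is identical at every
stage.

## Network and losses

A classic U-Net: `depth` encoder blocks (two 3×3 convolutions + ReLU,
then 2×2 max pooling), a bottleneck block, and `depth` mirrored decoder
blocks (nearest upsampling, 3×3 channel-halving convolution, skip
concatenation, two 3×3 convolutions). Channel widths double per level
from `base_channels` (desk default 16; the reference description leaves
widths unspecified). No normalisation layers — the smallest faithful
reading of a "convolution block"; per-image input standardisation
replaces them. Input sizes must divide by 2^depth so the bottleneck
resolution is integral.

Heads are zero-initialised 1×1 convolutions followed directly by
nearest-neighbour upsampling; the final segmentation layer is likewise
a zero-initialised 1×1 convolution with sigmoid. Zero initialisation
makes every initial probability exactly 0.5, so the first-epoch loss
sits at the chance level (ln 2 per stage) and early optimisation is
driven by the learned boundary signal instead of random initial logits
— important at the reference learning rate of 1e-4, where weights move
on the order of only `lr × steps`.

Losses are pixel-mean binary cross-entropies with probabilities clipped
to [1e-7, 1 − 1e-7] (the logs are undefined at 0/1): the map loss is
the sum over stages of per-stage pixel means, the segmentation loss a
single pixel mean, the total their exact sum. Per-pixel means keep the
scale resolution-independent while preserving the additive multi-stage
structure. Gradients enter at the logits as `(p − target)/n_pixels`,
which is exact and immune to clipping.

Training uses Adam (β 0.9/0.999, ε 1e-8) on mini-batches shuffled by a
seeded generator; the retained checkpoint is the epoch with the lowest
validation total loss (training loss when no validation split is
given). Desk defaults — depth 4, base 16 channels, 64×64 inputs, 30–50
epochs, batch 4 — keep a full smoke run around one minute on one CPU
core; the full-scale schedule (lr 1e-4, 1200 epochs, batch 8, 10-fold
cross-validation) is reachable through `TrainingConfig`.

## Phantom generator

Each phantom is a star-convex region `r(θ) = r_ellipse(θ)(1 + Σₖ aₖ
cos(kθ + φₖ))`, k ≤ 3, with semi-axes drawn from 12–22 px in a 64×64
raster, centre jitter ±2 px, and total perturbation amplitude capped at
0.15 of the radius (keeps the curve simple and the region star-convex).
Rendering multiplies a piecewise-constant base (fg 0.55, bg 0.35) by
unit-mean gamma speckle (shape 4 — a standard fully-developed-speckle
proxy chosen over additive Rayleigh noise because only the low-contrast
regime matters here), followed by Gaussian blur (σ 1) and clipping.
With these defaults the fg/bg intensity histograms overlap
substantially (Bhattacharyya coefficient well above 0.1), i.e. the
boundary is genuinely ambiguous. Every sample is a pure function of
`(seed, index)` via `numpy.random.SeedSequence`.

What the phantoms do **not** emulate: physical ultrasound point-spread
functions, attenuation gradients, shadowing, anisotropic speckle, or
multi-pixel observer delineation noise. Passing tests therefore show
the pipeline's correctness and the method's qualitative behaviour
(equidistant key points beat random sampling; boundary supervision
trains), not clinical-grade accuracy on real prostate ultrasound.

## Problem sizes and numerical choices

Fixture studies use 50 phantoms; training smoke runs use 20 training
and 5 held-out phantoms for 30 epochs at batch 4 — sizes chosen so the
complete suite runs on a single CPU core in minutes while every
comparison still has stable statistics. Polygon rasterization uses the
pixel-centre even-odd rule with boundary pixels counted inside, with
exact integer arithmetic for the on-segment test; zero-area polygons
are rejected. Metric edge cases (two empty masks, empty class unions)
raise typed errors rather than returning conventions.

## Known limitations

- Single-object scenes only; the largest closed loop wins.
- Key points are pixel-resolution; no sub-pixel localisation.
- Open curves are unsupported by design (closed anatomy).
- The per-column filter assumes a roughly horizontal-major orientation;
  strongly vertical elongated shapes retain fewer lateral points.
- The NumPy network is single-threaded and desk-scale; no
  augmentation, mixed precision or GPU path.
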