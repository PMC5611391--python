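# Methods

This note records the models, conventions and numerical choices behind
`delinmetrics`, and what the synthetic-study checks do and do not show
about real data.

## Data model and rasterization

Coordinates are 0-based pixel indices, `x` = column, `y` = row, origin
top-left; a pixel's center sits at integer coordinates. Stylus
polylines are not guaranteed closed, so the last vertex is joined back
to the first before any region is derived.

A delineation's **filled mask** is the set of pixels whose centers lie
inside the closed polyline under the even–odd (crossing-parity) rule,
united with the stroke pixels themselves. Even–odd was chosen for
robustness to the self-intersections freehand traces produce. One
consequence needs a guard: a trace that goes around the same closed
curve exactly k times would cancel itself under parity, so exactly
periodic vertex lists are collapsed to a single cycle first. The
**boundary mask** is the 8-connected Bresenham stroke of the segments
(closing segment included); segments are drawn in a canonical endpoint
order so masks are invariant to traversal direction, and the boundary
mask is always a subset of the filled mask. Degenerate polylines (all
vertices identical or collinear) rasterize to their stroke only, with
a warning rather than an exception — such records occur in real tablet
data and should not abort an analysis.

Multiple contours by one observer on one slice merge by union: all
pixel-count measures have set semantics, so overlap is never counted
twice.

## Agreement measures

GTV sums per-slice union areas over a whole-brain stack; GTA (for
independent single-slice sets) divides total delineated pixels by the
number of delineated slices and is undefined (NaN, never 0) when
nothing was drawn.

The pairwise concordance rate is Jaccard by default,
`100·|A∩B|/|A∪B|`; Dice is available by configuration. The verbal
"intersection over the sum of both areas" phrasing found in the
literature would cap identical contours at 50 %, contradicting the
universally used 0–100 % anchors, so "sum of the area contoured by
both" is read as the combined (union) area. Undefined cells are kept
honest: a slice where neither pair member drew carries no information
and is excluded from averages, while a slice where exactly one drew
scores 0 % — disagreement about tumor *presence* is disagreement.

Central/peripheral classification takes the `central_k = 5` slices on
which the most observers (both groups pooled; the alternative,
within-group counting, is not supported by anything in the design)
drew a boundary. Ties are broken deterministically — larger total
delineated area, then lower slice index — and logged. Independent
single-slice sets carry stimulus-level central/peripheral labels;
when present, metadata wins over the count rule. If fewer than
`central_k` slices were delineated at all, all delineated slices are
labelled central and a warning is recorded.

Per-observer agreement averages over same-group peers within a slice,
then over slices, separately per location class. Group summary tables
report mean and sample SD (ddof = 1, NaN for singleton groups).

## Inspection-sequence similarity

Sequences of visited slice indices are collapsed (consecutive repeats
dropped — modality toggles on one slice are not new visits), encoded
as two-letter tokens (supporting up to 676 slices), and globally
aligned by Needleman–Wunsch. The substitution score is linear in
1-D slice distance, `s(i,j) = (n_bins−1) − |i−j|`: slices are the
natural one-dimensional analogue of the spatial bins scanpath-
comparison toolboxes use. The gap penalty defaults to 0 and must be
non-positive. The raw score is normalized by
`(n_bins−1) · max(len(a), len(b))` and clipped below at 0, so
self-similarity is exactly 1 and the extreme-slice pair scores 0.

Normalization by the *longer* sequence means length mismatches are
penalized: a clean 31-slice sweep vs a revisit-heavy 87-visit sweep
scores ≈ 0.36 even though the latter contains the former. Two
revisit-heavy sequences, by contrast, score high against each other.
This produces a non-obvious consequence worth knowing: mean pairwise
similarity between independently simulated observers is **U-shaped**
in the revisit rate, not monotone. At rate 0 every sweep is identical
(similarity 1); moderate rates inject idiosyncratic revisits
(similarity drops to ≈ 0.8); high rates make every sequence converge
to the same dense back-and-forth texture, so similarity *rises* again
(≈ 0.85–0.88 at rate 3). The monotonicity suite asserts a strictly
non-increasing trend across rates {0, 1, 3} and therefore fails on
the 1 → 3 comparison; we keep the check as specified and document the
mechanism here rather than weakening it, since the dynamic program
itself is verified against exhaustive alignment enumeration.

## Graph-based saliency

Each masked grayscale slice is reduced to feature maps on a coarse
`map_resolution × map_resolution` grid (default 32; fully connected
graphs on finer grids grow quadratically in memory). Channels are
intensity (the downsampled image) and orientation (four directional
derivative-of-Gaussian filters at 0°/45°/90°/135°); color channels are
meaningless for MR data. For each feature map, edge weights
`w(a,b) = |f(a) − f(b)| · exp(−d(a,b)²/2σ²)` with `σ = sigma_frac ×
map width` (default 0.15) are column-normalized into a Markov
operator whose equilibrium distribution is the activation; a second
pass with weights proportional to activation at the target node
concentrates the mass. Equilibria are found by power iteration on the
lazy chain `(M + I)/2` — same stationary vector, provably aperiodic —
to an L1 tolerance of 1e-9 (cross-checked against dense
eigen-decompositions in the tests). A constant feature map has an
all-zero weight matrix; the uniform distribution is returned with a
warning. A uniform activation is returned unchanged by the
concentration pass: it is the fixed point of the idealized
translation-invariant chain, which the finite grid only approximates
(the finite-grid equilibrium would tilt toward high-degree interior
nodes, an artifact rather than saliency).

Non-brain pixels (skull, eyes — conspicuous but never delineated) are
flattened to the within-mask mean intensity before feature
extraction, which removes their structure without manufacturing an
artificial edge at the mask border; final saliency outside the mask
is forced to 0. Channel maps are averaged, bilinearly upsampled to
`output_resolution` (default 512), and divided by the maximum so
every non-degenerate map peaks at exactly 1. Per-slice normalization
(rather than global across slices) matches the convention of
reporting each slice on a 0–1 scale. Because weights depend on
absolute intensity *differences* and each chain is column-normalized,
maps are exactly invariant to positive affine rescaling of the input.

The contour–saliency score multiplies the map by the boundary stroke
mask and sums — bounded above by the stroke's pixel count.

## Synthetic study generator

The generator emulates the standard two-group whole-brain design: an
elliptical brain (semi-axes ≈ 0.42/0.45 of the raster) containing an
ellipsoidal tumor on a stack of axial slices, imaged at 512 × 512 over
31 slices by default, in T1 and (for two of the three whole-brain
sets) T2 with complementary contrast, plus a 16-stimulus independent
set drawn from 16 distinct phantoms (8 central slices, 8 peripheral).
Intensities are uint16: brain base 20 000 (T1) / 15 000 (T2) with
smooth low-frequency texture (±1 500), a bright skull ring (30 000)
outside the brain mask, tumor contrast +8 000 at the lesion's central
slice decaying by 0.85 per slice of distance — peripheral
cross-sections are faint, as in real lesions — and Gaussian noise
(sd 800).

Observers delineate each tumor-bearing slice with probability
`detect_floor + (1 − detect_floor)·g(d)` where `g` is a logistic
fall-off in slice distance `d` from the lesion center, normalized so
`g(0) = 1` (the central slice is always delineated) and halfway to
the floor at `detect_halfwidth` slices. A drawn boundary is the true
sub-pixel contour (marching squares at level 0.5) resampled uniformly
by arc length to 64 vertices, radially scaled about the mask centroid
by `area_bias` (drawn area scales with its square), and perturbed
radially by circularly-smoothed Gaussian noise (white noise filtered
with a wrap-around Gaussian of σ = 3 samples, renormalized to unit
variance, times `jitter_sd` pixels) — plausible smooth boundary
wobble, not pixel noise. Inspection sequences are a superior-to-
inferior sweep with Poisson(`revisit_rate`)-distributed local
back-steps after each slice.

Group defaults encode the expertise hypotheses the pipeline is meant
to detect: experts `jitter_sd = 3 px`, `detect_floor = 0.9`,
`area_bias = 0.95`; novices `6 px`, `0.5`, `1.15`; `detect_halfwidth
= 4` slices and `revisit_rate = 1` for both. Note one deliberate
consequence: a higher expert detection floor means simulated experts
delineate slightly *more* slices than novices, the price of
reproducing the robust expertise-by-location agreement interaction;
the generator makes no claim to reproduce every descriptive trend at
once, and the slice-count ordering is exercised in tests with
explicitly contrasted floors instead.

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning, giving independent per-observer/per-set substreams and
byte-identical datasets on re-run.

### What the synthetic checks do and do not show

The phantom has a single convex lesion, smooth texture, no partial
voluming, no anatomy, and observers who err only radially and
independently. Passing checks therefore demonstrate that the
*measurement pipeline* is correct and sensitive in the directions
expected (zero-noise identity recovers 100 % concordance and
similarity 1; concordance decreases with jitter; central > peripheral
agreement; expert > novice peripheral agreement; tumor regions are
salient), not that real delineation data would yield any particular
values. Real studies show far lower absolute agreement than
low-jitter phantoms, and correlated, anatomy-driven errors the
observer model does not attempt.

## Problem sizes used in checks

Monte-Carlo suites run at 128 × 128 rasters, 15-slice stacks, 20
seeds, and groups of 8 experts / 12 novices (6 observers for the
jitter sweep; 8 sequences of a 15-slice stack for the revisit sweep)
— the geometry is scale-free in the relevant ratios and the checks
are directional. Definitional anchors and the acceptance script run
at the native 512 × 512 / 31-slice scale.

## Known limitations

* Descriptive tables only; no mixed-effects inference on the outputs.
* The saliency model uses a single computation grid per channel, not
  a multi-scale pyramid, and makes no attempt to reproduce any
  particular toolbox's numeric output.
* The substitution matrix is 1-D (slice distance); dwell times are
  not modeled, so temporal binning of inspection behavior is out of
  scope.
* DICOM ingestion and registration are out of scope; inputs are
  already-registered PNG/NIfTI rasters.
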