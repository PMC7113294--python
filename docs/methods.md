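# Methods

## Coordinate and unit conventions

Volumes are indexed (z, y, x) with z = 0 at the substratum and z increasing
toward the bulk. OCT stacks are usually stored probe-side first, so the
TIFF reader reverses page order by default (`flip_z=True`). All lengths are
micrometres internally; millimetres appear only at the CLI boundary.
Voxel spacing comes from user configuration, never from TIFF resolution
tags (vendor tags are unreliable; a >1 % disagreement with informative tags
is logged as a warning). 16-bit stacks are min-max rescaled to 8-bit
globally over the stack on load, because every threshold in the pipeline
(120, 150, 50, ≥1) is defined on the 8-bit scale.

The effective axial voxel height in a medium of refractive index n is
Δz = Δz_air / n. The instrument-like defaults use Δz_air = 2.793 µm with
n = 1.33 (water), giving Δz = 2.1 µm; whether a vendor-quoted axial figure
is optical resolution or digital pitch varies by instrument, so Δz_air is
always user-supplied.

## Image processing

**Mean filter.** Disc footprint, pixel included when its centre distance is
≤ radius (the radius-2 disc has 13 pixels); arithmetic mean, rounded to the
nearest integer; borders replicate edge values. Volumes are filtered
slice-wise in xy, since the workflow this reimplements filtered 2D images.

**Binarization.** Inclusive threshold: value ≥ t → 255. A `dark_target`
flag inverts polarity first so dark-on-light printed targets become
foreground; the complement-symmetry `binarize(img, t) ==
binarize(255−img, t, dark_target=True)` is tested.

**Three-class labeling.** Biomass voxels → 150. The default `column` void
rule labels any zero voxel strictly below its column's topmost biomass
voxel as void (50); everything else is background (0). A stricter
`floodfill` alternative labels as void only zero voxels unreachable from
the top slice through zeros by 6-connectivity. The column rule is the
default because it is deterministic, cheap, and matches a per-A-scan
reading of "voids within the structure"; the floodfill rule treats
under-overhang water channels as background instead.

A consequence worth knowing: under the `column` rule every non-biomass
voxel beneath the interface is a void, so Φ_global equals Φ_intrinsic
exactly. The two diverge under `floodfill`, where open channels beneath
overhangs count toward Φ_global but not Φ_intrinsic.

## Structural parameters

Local thickness uses the column-sum rule L_F,i = (Σ binary values)·Δz/255
(`thickness_mode="sum"`), so internal voids do not add thickness; the
interface alternative ((top index + 1)·Δz, voids included) is available as
`thickness_mode="interface"`. Mean thickness averages over all N columns,
biomass-free columns counting as zero. With voids present, mean thickness
≤ mean interface height — asserted as a property test.

Substratum coverage counts projection pixels ≥ 1. Porosities return NaN
(serialized as an empty CSV cell) when the denominator is empty — the
missing-value convention used throughout.

Textural entropy is computed from the table of ordered intensity pairs
(a, b) at a pixel offset (default (0, 1)); probabilities are the
normalised counts, entropy is natural-log with zero-probability entries
skipped, reported in nats. Native 256 gray levels by default with optional
binning; an option averages the four standard offsets (0,1), (1,0), (1,1),
(1,−1), and a `symmetric` flag adds transposed counts. TE is evaluated on
the **filtered grayscale** MIP, not the binary one: a binary projection has
a ≤2×2 co-occurrence table and nearly saturates, whereas grayscale MIPs
give the meaningful 2–5 nat range. Note that uncorrelated sensor noise
alone produces nonzero TE on a biofilm-free grayscale MIP; the analytic
zero holds for a homogeneous (noise-free) image.

`structure_report` chains crop → mean filter → binarize → label → MIP →
parameters and records every setting used. The OCT biomass threshold is a
method parameter (instruments and media differ); the package default is ≥1
(any signal is biomass, matching the coverage rule on clean data). On
noisy data a threshold at half the biomass signal level is the principled
choice: the mean filter crosses half-amplitude exactly at a step edge, so
erosion and dilation of object boundaries cancel to first order. The
synthetic recovery runs use 90 (half of the phantom's 180-count biomass
signal) with a 1 px filter on the coarse 20 µm grid — physically the same
footprint as a 2 px disc on an 8 µm instrument grid.

## Positioning accuracy

Target detection: RGB mean filter (r = 2) → BT.601 luminance → threshold
120 with dark-target polarity → 8-connected components → particle-size gate
at [25 %, 400 %] of the nominal disc area π(d/2)²/(px_x·px_y), d = 1 mm
(excludes dust while tolerating threshold-driven size change) → unweighted
centroid of the largest survivor, reported at pixel centres in µm. Several
surviving components within 10 % of each other's area raise an ambiguity
warning; the largest is still chosen.

Deviations are taken from the series mean per axis, so they sum to zero by
construction. Quartiles use linear interpolation between order statistics
(NumPy default; Tukey hinges are not used), outliers are flagged outside
[Q1 − 1.5·IQR, Q3 + 1.5·IQR], and the accuracy verdict is pass when ≥ 75 %
of movements per axis fall within the tolerance (default 8 µm, the optical
resolution).

## Replicate statistics

The two-sided Grubbs statistic G = max|xᵢ − x̄|/s is compared against the
closed-form critical value G_crit = (n−1)/√n · √(t²/(n−2+t²)) with
t = t_{α/(2n), n−2}, rather than lookup tables. Removal is iterative until
no outlier remains, capped at ⌈n/4⌉ removals to avoid stripping genuine
heavy tails; a zero-spread sample has no outlier. SD is the sample SD
(n−1); even-count medians average the two central order statistics. Days
with fewer than 3 values skip the test and are flagged unreliable but
still summarised. Monte-Carlo calibration (10,000 clean normal samples at
n = 24) confirms a false-positive rate within ±0.01 of α = 0.05.

Heat-map CSVs store values at `repr` precision so re-reading reproduces the
matrix exactly; outliers carry a trailing " o", missing cells are blank.

## Synthetic phantoms

**Biofilm series.** Colonies are spherical caps seeded at Poisson-random
positions (default 0.8 colonies/mm²/day) growing linearly in base radius
(110 µm/day) and cap height (45 µm/day), clipped at the 450 µm channel
ceiling; overlapping colonies union. Ellipsoidal pores (1.5–3.5 voxel
semi-axes, so they survive voxelisation and filtering) are carved strictly
below each column's top until the requested void share (default 15 %) of
the original biomass volume is reached. Biomass voxels get intensity 180;
clipped additive Gaussian noise (σ = 8 counts) models sensor noise —
speckle, attenuation with depth, and refraction artifacts are *not*
modelled, so passing recovery tests demonstrates correctness of the
computation, not robustness to every real-world artifact. These defaults
produce near-complete coverage and ≈150–200 µm mean thickness by day 5–6
on a 1 mm² patch, the scale of a mature flow-cell biofilm. Ground truth
(coverage, thickness, under-roof void share) is computed by direct voxel
counting inside the generator, independent of the analysis code paths; in
the noise-free, void-free, unfiltered limit pipeline and ground truth agree
exactly, which the tests assert.

**Target images.** 1600 × 1200 px, 6.7 × 5.0 mm² field of view (4.19 ×
4.17 µm/px), red disc of 1 mm diameter rendered with distance-based
anti-aliasing at an arbitrary sub-pixel centre, plus optional 1–3 px dark
dust specks. Binarizing the anti-aliased edge keeps the centroid
quantisation error far below the 4 µm jitter used in recovery tests.

## Problem sizes and numerics

Tests and examples run the phantom on a coarse grid (20 µm lateral, 15 µm
axial in water, ≈30×50×50 voxels) — the parameter definitions are
resolution-independent, and a coarse grid exercises them identically while
keeping the suite quick. Oracle-equivalence checks use 100 random volumes
up to 32³ against plain-loop counting implementations at 1e-9 absolute
tolerance. Positioning recovery uses 100 full-size target images with
σ = 4 µm jitter and accepts the per-axis SD within 15 %. Floating-point
ties: thresholds are inclusive (≥), rounding is banker-free `rint` on
half-integer filter means, and −0.0 entropies are normalised to 0.0.

## Known limitations

- The column void rule makes Φ_global ≡ Φ_intrinsic (see above); use
  `void_mode="floodfill"` when the distinction matters.
- TE on noisy grayscale projections does not reach the analytic 0 for
  biofilm-free channels; denoise or threshold first if that matters.
- No speckle/attenuation modelling in the phantom; no refraction or
  dispersion correction beyond Δz = Δz_air/n in the analysis.
- Grubbs testing assumes approximate normality of replicate values; the
  ⌈n/4⌉ cap is a pragmatic guard, not a statistical guarantee, and masking
  by multiple symmetric outliers can defeat the sequential test.
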