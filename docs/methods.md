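# Methods

`chromadens` assesses bull sperm chromatin integrity from micrographs and
relates the findings to in vitro embryo production (IVEP) outcomes.  This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic phantoms do and do not establish.

## Densitometric model (TB / FR)

Sperm chromatin is normally packed by protamines; decompacted chromatin
binds toluidine blue (TB) metachromatically and takes up more Feulgen
reagent (FR), so decompacted regions stain *darker*.  All intensities are
normalized to [0, 1] by the full scale of the declared bit depth (8 → 255,
16 → 65535; no percentile stretching, so the mapping is affine and
order-preserving), with the fixed polarity **higher = lighter = more
compacted**.  Color images collapse to a scalar pixel value by Rec.709
luminance (0.2126 R + 0.7152 G + 0.0722 B) by default; the policy is
configurable per stain, and inverted-polarity inputs are flipped at load.

**Segmentation.**  Heads are darker than the smear background, so the
foreground of an Otsu threshold (256 bins; fixed-threshold override
available) is the dark side.  8-connected components are filtered by area
(400–20000 px), solidity (≥ 0.85) and eccentricity (≤ 0.95) — bovine heads
are compact ovals, tails are thin and highly eccentric, fused heads are
non-convex — and border-touching components are dropped (their masks may be
truncated).  Each survivor is eroded once by the digital disk of radius 1
(the 4-connected cross) to discard perimeter pixels and smooth the contour;
a head that disconnects under erosion keeps its largest piece.  Per-head
mean intensity and coefficient of variation (population standard deviation,
divisor *n*) are computed **after** erosion; computing them before erosion
is the plausible alternative and would shift means slightly darker because
perimeter pixels are partial-volume mixtures.

**Reference.**  The normally-compacted stain level is estimated from the
sample itself: heads are ranked by mean intensity (descending) and CV
(ascending), the two ranks are summed with equal weight (scale-free, no
tunable coefficient; ties break toward higher mean, then lower label), and
the K = 10 best heads' mean intensities are averaged into one sample-wide
reference.  Samples with fewer than K heads use all heads and warn.

**Deficit and thresholding.**  Each head pixel gets a relative deficit
`(reference − I) / reference` (negative values, lighter than reference, are
retained).  The continuous deficit map is smoothed with a discrete Gaussian
(σ = 2 px, truncated at radius 5, i.e. an 11×11 window renormalized to sum
1) restricted to the head mask: out-of-mask pixels carry zero weight and
the kernel renormalizes over in-mask support, so a constant field is
preserved exactly even at the boundary.  Smoothing before thresholding is
the standard denoising reading; the reverse order (threshold, then smooth
the binary result) would require an extra re-binarization level and is not
used.  The smoothed map is thresholded at a stain-specific τ — **0.07 for
TB, 0.04 for FR** — and 8-connected components smaller than
max(5, 0.5% of head area) pixels are discarded as residual noise.  Because
both stains threshold the same kind of map, the FR set is always a superset
of the TB set on identical inputs (τ-monotonicity).

## Location taxonomy

The head frame comes from the mask's second central moments; length and
width are the extents along the principal axes.  The base is the major-axis
end whose terminal 25% of the length holds more area (bovine heads are
broader at the base); near-symmetric heads (< 1% area difference) get a
deterministic orientation and an ambiguity flag.  Quartiles Q1..Q4 split
the pixels at the 25/50/75 percentiles of their axial projections
(area-based, robust to taper), and the axial band is every pixel within
width/6 of the axis line.

Categories are assigned by a fixed-precedence decision list
(N → TD → BAD → BHD → BD → CAD → DD) with config-exposed cutoffs:

| rule | default |
|---|---|
| N if altered fraction < `f_min` | 0.02 |
| TD if altered fraction ≥ `td_min_fraction` | 0.75 |
| BAD if altered coverage ≥ `bad_end_coverage` in both Q1 and Q4 | 0.25 |
| BHD if ≥ 80% of altered pixels in the basal half and basal coverage ≥ 0.40 | |
| BD if ≥ 80% of altered pixels in Q1 | |
| CAD if ≥ 80% of altered pixels in the axial band | |
| DD otherwise | fallback |

The taxonomy's semantics are location containment; the numeric cutoffs are
this package's own operationalization, declared rather than hidden, and
every one is a YAML config key.  The list is total, so each head gets
exactly one category regardless of input order.

## TEM grading

TEM polarity is inverted: condensed chromatin is electron-dense (dark) and
decompacted areas are clear.  Clear pixels are those at or above an
absolute normalized intensity `clear_tau` (default 0.60).  Components at
most `small_spot_max_fraction` (default 0.02) of the section area count as
small spots; the largest bigger component gives the clear-region fraction.
Grades are closed-form: G4 if the fraction exceeds 1/2; G3 if more than six
spots or fraction over 1/4; G2 if four to six spots or any clear region;
G1 for one to three spots; plus an explicit N0 for heads with no findings,
reported separately so G1–G4 percentages stay comparable.  Grading is
monotone in both inputs.  Because clear regions are lighter than the
background, the TEM pipeline fills holes in the thresholded head mask
before filtering (`SegmentationParams.fill_holes`).

## Acridine orange

After acid denaturation, double-stranded DNA fluoresces green and
denatured single-stranded DNA red; yellow/orange (red overlapping green)
marks the onset of denaturation.  Per head, the mean red and green channel
intensities give `red_fraction = R / (R + G)`; the head is called
*denatured* iff red_fraction ≥ 0.40 (boundary inclusive).  One
parameterized rule serves both confocal and epifluorescence acquisitions.
Heads with zero red+green signal are excluded and logged.

## Synthetic phantoms

Phantoms emulate exactly what the analyzers measure: paddle-shaped head
masks (half-axes a ∈ [26, 30], b ∈ [13, 15] px, apex width tapered by 30% —
roughly a 9 µm bovine head at a ×100 objective with a ×2 intermediate
lens), uniform stain levels (TB/FR: background 0.92, head 0.75; TEM:
background 0.75, head 0.25, clear regions 0.85; AO: green 0.80 or red 0.80
heads on a 0.03 field), stamped decompaction regions darkened by
`deficit_depth` (default 0.15) of the head intensity, additive Gaussian
pixel noise (default σ = 0.01), optional tail-like filaments, and 8-bit
quantization.  Heads never overlap and stay ≥ 5 px from borders (rejection
sampling, 10 000-attempt cap); all randomness flows through one seeded
PCG64 generator, so generation is bitwise reproducible.

Stamps are cut against the analyzer's own frame/partition of the
ground-truth mask with a 2 px margin inside every rule boundary, because
Gaussian smoothing lets an altered set bleed about 1 px past its stamp at
deficit 0.15 and τ = 0.07.  Ground-truth stamped fractions are exact
rasterized ratios, never analytic approximations.

Phantoms deliberately omit optics (no PSF, no chromatic aberration, no
illumination gradients), stain variability between heads, partial-volume
edges and overlapping/touching heads.  Passing the recovery tests therefore
shows the measurement chain is self-consistent — segmentation, reference,
deficit, partition and rules agree with the generative templates under
realistic noise — not that the default cutoffs are optimal on real smears,
where illumination correction and fused-head handling (both out of scope)
would dominate error.

## Statistics layer

* **Rates.** cleavage = 100·cleaved/oocytes; embryonic development =
  100·day-7 embryos/cleaved; blastocyst = 100·blastocysts/oocytes.
  Normalization re-expresses a tested bull's rate as a percentage of the
  reference bull's rate in the same IVEP routine (two decimals, round half
  to even), cancelling uncontrolled plate effects.
* **Pearson.** scipy's estimator; two-sided p from the t transform with
  n − 2 df; exactly (anti)linear data (1 − |r| < 1e-14) reports r = ±1 and
  p = 0.
* **Proportions.** pairwise pooled two-proportion z-tests, unadjusted by
  default with an optional Bonferroni flag.  The published multiple-
  comparisons tables cannot be reproduced because their per-group counts
  are not available; the procedure here is a documented stand-in.
* **Odds ratio.** cross-product (ad)/(bc) with the Woolf log-normal
  interval exp(ln OR ± z·√(1/a+1/b+1/c+1/d)) and a normal p-value; any
  zero cell triggers the Haldane–Anscombe +0.5 correction on all cells,
  flagged in the result.
* **Scott–Knott.** recursive binary partitioning of sorted means.  At each
  node the contiguous split maximizing the between-group sum of squares B₀
  is tested with λ = π/(2(π−2)) · B₀/σ̂₀² against χ²₁₋α at k/(π−2) df,
  where σ̂₀² = (Σ(ȳᵢ−ȳ)² + ν·s²ȳ)/(k+ν) pools the node's dispersion with
  the variance of a treatment mean s²ȳ = MSE·mean(1/rᵢ) from an externally
  supplied error mean square and df (the surrounding ANOVA, normality and
  homogeneity tests are routine and delegated to standard tools).  α → 0
  yields one group; α → 1 with distinct means yields singletons; groups
  are always contiguous in sorted order.

## Problem sizes and tolerances

The test suite and acceptance script run phantom recovery on 200 stamped
heads (eight 700×900 images of 25 heads), τ-monotonicity on 100 single-head
phantoms, and the TEM rule grid exhaustively; these sizes give stable
percentages in a few seconds on one CPU.  Geometric assertions use 5%
relative tolerance for moment-based lengths (rasterization), 2 px for
centroid recovery, and 1e-12 for closed-form statistics.

## Known limitations

* No flat-field/illumination correction; inputs are assumed evenly lit.
* No watershed splitting of touching heads (fused heads are rejected, which
  can undercount heavily crowded smears).
* The location-taxonomy cutoffs are this implementation's declared
  operationalization, not published constants.
* Published correlation/OR tables relating techniques to IVEP outcomes are
  not reproducible from printed information (per-bull alteration
  percentages and 2×2 counts are not available); the pipeline emits tables
  of the same shape from phantom-derived inputs instead.
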