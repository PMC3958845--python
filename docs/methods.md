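# Methods

This note documents the models, conventions and numerical choices behind
`fishstrat`, and what its synthetic-data validation does and does not show
about real micrographs.

## The measurement model

A *section* is a multi-channel 8-bit micrograph of one cryosection of a
square MBBR carrier compartment at depth z (µm into the compartment), with
a pixel scale in µm/pixel (typical acquisitions: 1024 × 1024 px at
3.30 px/µm for structure images; 512 × 512 px at 1.65 px/µm for homogenized
samples). The reference channel (EUB338mix) labels essentially all
bacteria; specific channels label AOB (Nse1472) and anammox (Bfu613).
The quantity of interest is the **biovolume fraction**: the area of a
specific probe's signal divided by the reference area in the same region.
Because each section is a thin (10 µm) slice, area fractions stand in for
volume fractions.

The quantification chain per section:

1. **Threshold** each channel. Fixed cutoff (foreground iff intensity
   ≥ cutoff; the inclusive comparison is a deliberate convention so a
   cutoff of 30 keeps pixels at exactly 30), or RATS — the gradient-weighted
   mean intensity T = Σ(w·I)/Σw with w = |∇I| (central differences). RATS
   is undefined on flat images and raises. A tile-local RATS variant
   (per-tile thresholds, global fallback for flat tiles) is available
   behind a flag for unevenly illuminated images.
2. **Noise reduction**: one pass; a foreground pixel survives iff its
   8-neighborhood contains at least 1 foreground pixel (parameter).
   Neighbor counts are taken on the input mask, so removals cannot cascade;
   the single-pass semantics is the contract.
3. **Downscale** oversized binary masks to at most 1 megapixel
   (1 MP = 2²⁰ px, so 4096² → 1024²) by area-mean resampling
   (`resize_local_mean`) and re-thresholding at 50% coverage; the pixel
   scale grows by the same factor. Coverage is conserved to ±0.01 for
   geometric masks.
4. **Segment** each specific-channel mask into maximal 8-connected objects.
5. **Dual-channel autofluorescence removal**: an object is removed iff at
   least 50% of its own area overlaps the other specific channel's
   foreground, and symmetrically (both directions evaluated against the
   input masks, so the operation is order-independent). The 50%-of-own-area
   rule avoids removing genuine colonies that merely abut.
6. **Congruency rejection**: congruency = fraction of the object's area
   inside the reference mask. Objects below 0.50 are dropped; the image
   passes QC iff the area-weighted congruency of everything kept is ≥ 0.90.
   A failing image is flagged, never silently dropped — silent dropping
   would bias depth profiles.
7. **Biovolume fraction** = kept specific area / reference area. Values
   above 1 raise (they indicate the congruency filter was skipped) rather
   than being clamped. **Areal density** = reference area / compartment
   area.

## Slicer (wall-distance shells)

Horizontal stratification is quantified on concentric "virtual slices".
Conventions:

- The region outside the image grid counts as background (the grid is
  padded by one background ring before the distance transform), so a
  footprint that fills the grid still has a wall.
- Wall distance is measured from the pixel *center* to the wall:
  EDT − 0.5 px. This makes a 1000 µm square at 1 µm/px produce exactly five
  100 µm shells with the innermost a 200 px square, and it is the
  convention the brute-force oracle in the tests reproduces independently.
- Shell index = floor(distance / 100 µm); the innermost shell may be
  thinner than nominal. Labels partition the footprint exactly.
- **Baseline smoothing (default 20%)** is interpreted as smoothing the
  compartment boundary contour with a circular moving average whose window
  spans 20% of one side length (perimeter/4) before the distance transform;
  footprint pixels shaved off by the smoothed baseline are assigned to
  shell 0 so the partition survives. The exact semantics of the original
  interactive tool are not published; the fraction is an exposed parameter
  and 0 disables smoothing.
- Distance is anchored to the compartment wall, not the biofilm edge,
  matching how concentric regions are drawn from the wall inward.
- Cross-section aggregation reports per-shell mean, t-based 95% CI and n;
  sections lacking reference signal in a shell are *missing* there (n
  shrinks), not zero. n = 1 yields a mean with an undefined, flagged CI.

## Geometry

- Compartment dimensions come from the minimal-area bounding rectangle
  (rotating calipers via shapely) of the foreground convex hull, computed
  on pixel corners (centers ± 0.5 px) so an axis-aligned 600 px square
  measures exactly 600 px. Rotation changes measured sides by < 1%
  (rasterization), translation not at all; line-like masks raise.
- Shrinkage = measured/reference side (linear) and area ratios, reported
  per depth because the physical carrier narrows toward its mid-depth
  "waist".
- Thickness: eight rays — four from side midpoints along inward normals,
  four from corners along inward diagonals. A measurement is the extent of
  contiguous foreground from the wall, sampled at 0.5 px steps;
  gaps narrower than the channel-skip width (default 10 µm) are treated as
  biofilm channels and ignored, a wider gap ends the ray. Side rays cap at
  half the compartment width, corner rays at half the diagonal (a solid
  compartment measures side/2). Rays with no foreground at the wall report
  0 and are flagged.

## Depth-trend statistics

OLS of fraction on depth within an explicit window (the 180–400 µm anammox
window is a parameter, not hard-coded). Significance is the two-sided
t-test on the slope, equivalent to the F-test for simple regression; R², n
and α are reported. Perfectly flat data are returned as slope 0, R² = 0,
p = 1 (the t statistic is 0/0 there). Fits require ≥ 3 points in the
window. The implementation is statsmodels OLS; the tests check it against
a normal-equations oracle to 1e-10 relative.

## Stoichiometry

- HRT = volume/flow; reported values round half away from zero to one
  decimal (7.5 L / 1.2 L h⁻¹ = 6.25 → 6.3 h).
- Nitrogen removal% = (influent NH₄ − Σ effluent N species)/influent × 100;
  nitrate ratio% = effluent NO₃ / (influent NH₄ − effluent NH₄) × 100. By
  construction removal% plus the effluent share equals 100% exactly. Note
  that ratios of period-average concentrations differ from period averages
  of instantaneous ratios; this package computes the former (the averages
  314; 71/14/25 mg N L⁻¹ give 64.97% and 10.29%).
- Stoichiometric nitrate fraction: with anammox consuming 1.32 NO₂⁻ and
  producing 0.26 NO₃⁻ per NH₄⁺ (standard literature coefficients), and AOB
  supplying exactly that nitrite, the coupled balance gives
  0.26/(1 + 1.32) × 100 ≈ 11% of removed ammonium-N appearing as nitrate.
- Depth coverage: sections advance from each carrier surface to the
  mid-depth waist, so maximum biofilm depth is half the carrier depth;
  an 800 µm series covers 80% (2 mm carrier) or 53% (3 mm carrier).

## Synthetic generator

The generator emulates the structural features that drive the analysis,
with pixel-exact ground truth:

- **Geometry**: a square compartment footprint (default 1 mm at 2 µm/px)
  centered on the grid; optionally biomass confined to a wall band whose
  corner thickness exceeds its side thickness by the corner-thickening
  factor (default 336/235 ≈ 1.43, the observed mature-biofilm contrast).
- **Composition**: `aob_profile(z, d)` and `amx_profile(z, d)` are target
  biovolume fractions of the reference biomass at depth z and wall distance
  d; the "other bacteria" class fills the remainder so shares sum to 1 and
  measured fractions equal targets. Defaults: AOB falling linearly
  0.40 → 0.05 over 0–800 µm and slightly depleted near walls; anammox
  rising 0 → 0.30 over 180–400 µm (flat deeper) and slightly enriched near
  walls. `biomass_density(z)` sets reference areal density (default
  0.20 → 0.35 over 0–400 µm, then flat).
- **Colonies**: filled discs with Gaussian-blurred edges (σ = 0.6 px),
  radius ~ N(8, 3) µm clipped at 2 µm, Poisson count chosen so the union
  covers the target density (coverage 1 − e^(−λ)); each colony's class is
  drawn from the profile values at its center; overlaps resolve to the
  later colony. No published shape statistics exist for the microcolonies,
  so discs are the deliberate minimal model.
- **Intensities**: foreground N(180, 30), background N(10, 3) on the 8-bit
  scale — straddling the fixed cutoff 30 so thresholding is genuinely
  exercised. Tests that need mask-exact ground truth use a noise-free
  variant (foreground N(200, 10), background N(5, 2), no blur).
- **Artifacts**: autofluorescent discs planted with identical footprints in
  both specific channels and absent from the reference, Poisson count,
  placed with a clearance margin from genuine biomass so artifact and
  colony objects never merge. **Speckle**: isolated bright pixels at a
  configured rate per 10⁴ px.
- **Determinism**: each section uses `default_rng([seed, section_index])`;
  fixed seed gives bit-identical stacks (regression-tested).

`expected_profile` integrates the target profiles over the pixel grid
(area-weighted means per shell and per section) without touching rendered
images, giving an analytic expectation for parameter-recovery tests.

What the generator does *not* emulate: irregular colony morphology,
intensity gradients with depth of imaging, optical blur beyond the edge
softening, uneven illumination, partial probe hybridization, or real
compartment-wall roughness. Passing recovery tests therefore demonstrate
the pipeline's correctness on images satisfying the stated model, not
robustness to all real-world imaging pathologies.

## Experiment sizes and calibration

The package's default validation experiments are sized for interactive
runs: trend recovery uses 20 stacks of 41 sections on a 500 µm compartment
at 2 µm/px, which recovers the planted AOB decline (negative slope,
significant at α = 0.01, mean R² > 0.9) and the windowed anammox rise in
≥ 19/20 seeds; the null calibration uses 200 stacks of 15 sections on a
256 µm compartment with depth-constant composition, where the rejection
rate of the slope test at α = 0.05 falls inside the central 95% interval
of Binomial(200, 0.05). Per-section measurement noise under the model is
dominated by the finite colony count (binomial class sampling), which is
approximately normal and i.i.d. across sections — the regime in which the
t-test is exact.

## Known limitations

- "RATS-L" local thresholding is implemented as a straightforward tile-local
  variant; the original's exact local scheme is unpublished.
- The 90% aggregate-congruency rule is applied per image (flagging, not
  dropping); a per-batch variant would need pooling rules the source data
  do not pin down.
- Thickness rays are fixed to side-normals and corner-diagonals; an
  interactive operator may have chosen slightly different directions.
- Shell profiles are computed per section and aggregated; there is no 3-D
  shell construction across sections.
- The depth regression pools per-section means without compartment-level
  random effects.
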