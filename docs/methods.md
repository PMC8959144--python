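# Methods

This note records the models, conventions and numerical choices behind each
pipeline, what the synthetic generators do and do not emulate, and the known
limitations.

## Atlas-masked cell counting

**Model.** Labelled somata appear as bright, roughly round spots on a slowly
varying background. The pipeline is: optional Gaussian noise suppression
(σ = 1 px default; 0 disables) → white top-hat background subtraction (disk
structuring element, default radius 15 px) → global threshold (Otsu default,
scalar override) → 8-connected component labelling → shape gate
(circularity 0.5–1, minimum area 4 px²) → centroid-based region assignment
against the colour-coded atlas plate.

**Choices and rationale.**

- *Top-hat vs rolling ball.* The white top-hat with a disk is the
  morphological equivalent of rolling-ball background subtraction and is
  exactly testable against a brute-force grayscale opening. The disk is
  factored with an exact "crosses" decomposition (verified pixel-identical
  to the monolithic footprint) for speed. The top-hat preserves pixel-scale
  noise entirely, which is why the pipeline smooths first: without it a
  global threshold sits inside the noise on sparsely labelled sections. The
  smoothing radius (1 px) is well below the blob radius, so somata survive
  essentially unchanged.
- *Perimeter.* Boundary-following (Moore neighbourhood) contour length with
  √2 for diagonal steps, the particle-analysis convention; circularity is
  clamped at 1.0 because rasterization can push 4πA/P² above 1 for small
  objects. Single pixels fall back to the unit-square perimeter 4.
- *Minimum area 4 px².* Licensed by the intensity-and-shape gate; isolated
  suprathreshold noise pixels are single-pixel components whose clamped
  circularity (1.0) would otherwise pass the gate.
- *Region assignment* is by the centroid pixel; colour matching is exact
  (plates are label images). Colours present in the plate but missing from
  the lookup go to an explicit unassigned bucket that is reported, never
  silently dropped, and the per-section identity
  Σ region counts + unassigned = objects kept always holds.
- *Monotonicity caveat.* "A higher threshold never yields more objects"
  holds when object supports are disjoint (the planted-blob regime); for
  arbitrary images a rising threshold can split a connected component and
  transiently raise the count.

**Normalizations.** Per-section counts divide each animal's per-region total
by the number of sections analysed for that animal. The M/S percentage
normalization uses only motor and somatosensory counts, so %M + %S = 100
exactly per animal; a zero M+S total is a hard error naming the animal.

## Tract morphometry

Widths are measured along image columns of registered sagittal sections
(dorso-ventral = row axis): total = last − first signal row + 1, fibre =
number of signal rows, gap = total − fibre, all in integer pixels before µm
conversion, so fibre + gap = total is exact. An empty column measures
(0, 0, 0). Measurement sites are single columns by default, with an optional
±k-column median for robustness to single-column dropouts. µm offsets
(250/500) convert to columns with round-half-away-from-zero. The area under
a width profile is the trapezoid rule over medio-lateral position; entries
flagged missing are skipped with a warning and fewer than two valid entries
is an error.

The fasciculation index is fibre/total, chosen so that a lower index means a
more defasciculated (spread) tract; the reciprocal reading is available via
a flag. A zero total width leaves the index undefined (NaN), not 0.

## 3D point clouds

Coordinates are atlas µm with x rostral→caudal, y dorsal→ventral, z
left→right; all I/O records name the axes explicitly.

- *Recording.* Each density-map pixel contributes
  Poisson(rate · density) points placed uniformly within the pixel;
  the section index maps to the section mid-plane
  z = (index + ½)·spacing. Ordinal density classes (low/medium/high) are
  available via histogram edges.
- *z-jitter.* Uniform on (−gap/2, +gap/2) about the section plane — the
  least-informative choice consistent with "displaced within the gap". A
  one-sided (0, gap) mode covers the alternative reading. x, y and the
  point count are untouched; gap 0 is the identity; everything is seeded.
- *Slabs.* Membership is the half-open interval
  [centre − t/2, centre + t/2) along the slab normal (z for sagittal, x for
  frontal, y for horizontal), so tiling slabs partition a cloud with no
  duplicates or omissions.
- *Centroid shift.* Component-wise difference of centroids (B − A) with a
  percentile bootstrap CI (default 95%, 1000 resamples of each cloud,
  seeded, chunk-vectorized). Translation-equivariant and antisymmetric by
  construction.
- *Density overlap.* Histogram intersection of per-voxel point densities,
  each normalized to sum 1 inside the region mask: 1 for identical
  densities, 0 for disjoint support.

## Histogram matching

Classical discrete CDF-quantile assignment: source intensity s maps to the
smallest reference intensity r with CDF_ref(r) ≥ CDF_src(s); plateaus
resolve deterministically to the lowest attaining intensity and a small
guard (10⁻¹²) keeps shared quantiles fixed under self-matching. The lookup
is monotone non-decreasing, so within-image intensity ranks are preserved
(ties may merge), and reapplying the map against the same reference is the
identity. The residual mismatch after matching is bounded by the
quantization step plus the largest reference bin mass. Matching applies to
whole images by default; crop-then-match is a caller decision.

## Group statistics

Two-way ANOVA uses Type II sums of squares computed from nested
least-squares fits (SS_A = RSS(B) − RSS(A+B), etc.), appropriate for the
unbalanced animal numbers typical of mouse cohorts and identical to the
classical partition when balanced; the implementation is verified against
statsmodels' `anova_lm(typ=2)` on an unbalanced design. Empty cells make
the interaction inestimable and raise. Residual sums below 10⁻¹⁰ of the
total SS are snapped to zero so noise-free designs report their degenerate
limits (p = 0 for a real effect, p = 1 for an absent one) instead of
round-off-driven F values. The Bonferroni family is all pairwise
genotype contrasts within the plotted panel (declared in the result), with
marker tiers *P<0.05 and ***P<0.005. For two groups the one-way F equals
the pooled t² identically.

## Synthetic data: what it emulates, what it does not

- *Sections* (default 640×700 px, 1.29 µm/px, 16-bit, 7 vertical-strip
  areas of 100 px): somata are isotropic Gaussian blobs (σ = radius/3,
  truncated at 3σ), peak 20 000 on background 2000, optional linear
  background gradient and additive Gaussian noise clipped to the bit range.
  Centroids are kept ≥ 3·blob_radius apart (at 2·radius, neighbouring
  thresholded blobs occasionally merge under 10 %-of-peak noise, which
  would break the exact-count oracle) and ≥ radius + 2 px inside their
  region so a detected centroid cannot cross a boundary. Placement is
  rejection sampling with a capacity error when a region cannot hold the
  requested count. The default cohort profiles are a motor-dominant graded
  control (60, 160, 80, 50, 40, 30, 20 across
  PFC/M/S/A/V/RSC/GC; M:S = 2:1) versus a flattened mutant (63 per area),
  with per-animal Poisson variation around the profile.
- *Tracts*: per-column disjoint row intervals rasterized to binary images;
  ground truth (total/fibre/gap) is interval arithmetic, exact by
  construction. Serial variation is a rigid per-section vertical jitter
  that changes positions but not widths.
- *Clouds*: Gaussian clusters (default sd 120 µm — a focal projection
  cluster; large enough clusters are visibly truncated by the volume
  boundary, which biases the realized mean shift away from the planted
  value) rejection-sampled inside a voxelized ellipsoid
  (semi-axes 900×500×700 µm, 25 µm voxels), z snapped to 100 µm section
  mid-planes before the membership test, and the shifted group re-drawn
  from the translated process under the same seed policy.

Not emulated: optical blur anisotropy, autofluorescence and vascular
artefacts, section-to-section registration error, layer structure within
areas, and real somatic shape variation. Passing the planted-truth tests
therefore demonstrates correctness of the measurement machinery, not
detection performance on real tissue; on real images the threshold,
background radius and smoothing need tuning, and counts are estimates, not
exact recoveries.

## Problem sizes

The shipped verification runs use 20 two-section sets for count recovery,
50 random convex shapes for the circularity oracle, 10⁵ points for slab
geometry, 100 replicates of n = 10⁴ clouds for shift-recovery coverage,
10 000 simulations for ANOVA null calibration, and 6 + 4 animals × 2
sections for the cohort comparison — sizes chosen so the whole battery
completes in a few minutes on one CPU while keeping Monte-Carlo error well
inside the asserted bands.

## Known limitations

- Detection counts particles (connected components); optional local-maxima
  splitting of touching cells is not enabled by default, so heavily
  overlapping somata under-count.
- The counting unit for statistics defaults to per-animal aggregates;
  within-animal section correlation is not modelled (no mixed effects).
- Straight-column width measurement does not follow tract curvature.
- Exact-colour ROI matching assumes clean label plates; anti-aliased plates
  need re-quantization first.
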