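# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic test substrate does and does not show about
real data.

## Platform conventions

A *rhizoslide* is a plexiglass sheet covered on both sides (front/back)
with germination paper (49 × 61 cm); one plant grows per slide with roots
visible on both papers, each split by a vertical wax barrier into a high-N
and a low-N compartment.  Conventions used throughout:

* **Day indexing**: day 0 = sowing; nutrient-solution change (start of the
  split-N treatment) at day 14; harvest at day 26; imaging every 2 days.
  Growth-model time axes are re-origined to the solution change.
* **Coordinates**: origin at the paper's top-left corner, x rightward,
  y downward, cm units (real-valued, so there is no 0/1-based ambiguity).
* **Image scale**: 0.13 mm per pixel (the root camera's resolution);
  RSML pixel coordinates convert to cm as `px · (mm/px) / 10`.
* **Genotypes**: identified by panel EU_ID integers; names are display
  metadata.  A genotype with zero surviving replicates (a cross that never
  germinated) is a valid design entry.

## Imaging

**Minimum tonal fusion.** "Minimum tonal value" is applied per pixel *and
per channel* — the natural reading for producing one 24-bit RGB output, and
the only one that reduces channel-wise glare independently.  No
registration is performed: the two exposures are taken without moving slide
or camera, so pixel alignment is a precondition.  No background subtraction
precedes fusion.

**Shoot segmentation.** The excess-green map `f = 2G − R − B` is computed
in signed 32-bit arithmetic (no 8-bit wraparound), optionally after
subtracting a plant-free reference image of the imaging station (skipped
when no reference is supplied).  The coarse mask marks `f ≥ 55` (55 is a
fixed platform constant, not re-estimated per image).  Otsu's threshold is
searched over the *full signed histogram* of values actually present, not
a 0–255 rescaling; candidate thresholds are the observed values, foreground
is `f ≥ t`, and ties in between-class variance break toward the lower
threshold.  Region merging uses 8-connectivity — the conservative choice
for thin leaf tips — and keeps a fine component if it overlaps the coarse
mask *or touches it diagonally*, because a strict-overlap rule fails when
the coarse mask sits one pixel inside an anti-aliased edge; the output also
retains the coarse pixels themselves, so it is a sub-mask of `s_c ∪ s_f`.
The canopy proxy averages the foreground counts of whichever of the four
views are available (front/back side views and two top views).

## Root traits

**Eligibility.** A crown root enters the growth analysis only if it exists
at the baseline timepoint, never crosses the wax barrier, and keeps its
final tip ≥ 0.5 cm (configurable; the edge margin is a package choice) from
the paper's side and bottom edges.  Compartment assignment is by the
x-coordinate of the root's base relative to the barrier.  An empty
eligible set on a side is a reported outcome, not an error.

**Length series.** One (t, L) pair per timepoint with t in days since
solution change (negative pre-treatment values allowed).  A drop of more
than 0.5 cm between timepoints is retained but flagged (tracing noise);
a single-timepoint root is excluded with a QC entry.

**Branching zone.** Proximal end = insertion position of the most distal
lateral present at solution change; distal end = most distal lateral at
harvest; both are *arc* distances along the parent (the along-root reading
of the zone length; a straight-line ruler reading would differ on curved
roots).  The zone splits into two equal-length segments; a lateral inserted
exactly at the midpoint belongs to the distal segment (fixed tie-break).
Per segment: lateral count, maximum length, median length and count per cm.
`Med_Lat` is defined as the *median* lateral length (lower of the two
middle values for even counts) — the deterministic counterpart of an
operator picking one "medium sized" lateral; outputs record
`medlat_rule=median` semantics via this documentation.  Root whorl class
(`crown_whorl1`/`crown_whorl2`) is carried through so either pooling of
first- and second-whorl roots can be reproduced.

## Growth model

Each eligible crown root and each plant's shoot proxy is fitted by
ordinary least squares, `L(t) = a + b·t`, with `t = 0` at the solution
change so that `a` is the size at treatment start.  Pre-treatment points
are excluded from root fits by default (the line models the response to
the split application); shoot fits stop at the leaf-overflow day, after
which the proxy saturates.  Roots first observed after the solution change
get a slope only — the intercept is not extrapolated.  Points with
studentised residual > 4 are flagged, never removed.  No robust, weighted
or nonlinear alternatives are offered: residual diagnostics of the data
this models are adequately linear, and per-unit plain OLS keeps the trait
definition transparent.

## Mixed model and heritability

The full model for a split-root trait is
`y_ijkl = µ + G_i + N_j + GN_ij + R_k + S_l + GR_ik + ε_ijkl`, with the
genotype-by-replicate (slide) term random and a separate residual variance
per N level; whole-plant traits reduce to genotype + replicate fixed with
one residual variance.  Square-root transformation is applied before
fitting to `ER_Cr`, `IC_Cr`, `Med_Lat*`, `Max_Lat*`, `No_Lat*` and `DW_R`;
heritabilities and BLUPs are reported on the transformed scale and never
back-transformed.  Traits whose distributions resist normalisation
(branching-zone length and start, branching densities) are computed and
exported but excluded from the default model run.

**Estimation.** A dense REML engine covers every model here: one optional
random intercept term plus stratified residuals.  Variances are
parameterised on the log scale (non-negativity for free), the restricted
likelihood is maximised by L-BFGS-B with its analytic gradient and then
polished by damped Newton steps to tight KKT conditions; a variance on the
lower bound with outward gradient is a boundary solution and is reported
as exactly 0.  The homogeneous no-random-term case uses the closed form
`σ̂² = RSS/(n − p)`, which makes the fixed-model Wald F statistics equal
classical ANOVA F exactly.  Missing cells are simply absent rows — the
likelihood handles them; nothing is imputed.

**Tests and means.** Fixed effects get Wald F statistics with containment
denominator degrees of freedom: terms constant within slides (genotype,
replicate) are tested against the slide stratum, all others against the
residual stratum.  Software using different approximations (e.g.
Kenward–Roger) will give slightly different p-values; F statistics agree.
Predicted genotype means weight the other factor levels equally; `avsed`
is the mean standard error of a pairwise difference of those means, and
Tukey's HSD takes the studentised-range quantile `q` as *input* (degrees
of freedom are the analyst's choice, not computed here) with
`MSE = n·avsed²/2`.

**Heritability.** `H² = σ²_g/(σ²_g + σ²_e/r)` per trait and N level, with
`r` = number of replicates.  The per-N components come from per-stratum
REML fits with genotype random (replicate and side fixed): in the joint
heterogeneous-variance model with genotype and genotype×N random, the
per-stratum genotypic variance is `σ²_G + σ²_GN(stratum)`, which the
per-stratum fit estimates directly — a simpler route to the same quantity.
Negative estimates are clamped to 0 first, so `σ̂²_g = 0 ⇒ H² = 0`.  Note
that clamping makes the estimator's *mean* over replicated simulations
strictly positive even when the true genotypic variance is zero; its
median and mode are 0.  Genotype BLUPs from the same fits (BLUEs are
obtainable by moving genotype to the fixed part) feed the
correlation/PCA diversity summaries: traits are centred and unit-scaled,
correlations are Pearson on pairwise-complete genotypes, the PCA is the
eigendecomposition of the correlation matrix, and component signs are
fixed by making each component's largest-magnitude loading positive.

## Synthetic data

The generators target pipeline testability, not biology: no tropisms,
nutrient fields or leaf optics.

* **Root scenes** (default 512 × 512 px at 0.13 mm/px — desk scale rather
  than the platform's 22-megapixel frames): roots are random downward
  polylines fanning out from the top centre (where the seed sits), drawn
  dark (intensity 60) on textured bright paper (200 ± blurred Gaussian
  texture, σ = 8) and softened with a σ = 1 px blur.  Each exposure adds a
  one-sided glare ramp (default 140 gray levels at the lit edge, linear
  decay to zero at the image centre, integer-valued so it commutes with
  8-bit quantisation, clipped at 255 like real sensor saturation) plus
  independent Gaussian noise (σ = 3).  The RSML trace matches the planted
  polylines exactly.
* **Shoot scenes**: a stem rectangle plus triangular leaves in shoot green
  (45, 150, 55) on the blue imaging background (30, 60, 170) with
  per-channel Gaussian noise σ = 10; truth is the exact polygon pixel
  count per view.  Real shoots add specular leaf highlights, shadows and
  occlusion that these scenes do not model, so a passing 2 % proxy-recovery
  check demonstrates correctness of the segmentation algebra, not
  field-robustness.
* **Growth series**: `a + b·t` plus iid Gaussian noise at 7 timepoints
  (days 0–12, 2-day interval).
* **Trial tables**: the full effects model with sum-to-zero effects,
  per-stratum genotype-effect vectors (allowing per-N genotypic variances
  and hence the high-N/low-N heritability asymmetry), shared slide
  effects, per-N residuals, and missing-completely-at-random record loss
  (default 10 %, emulating plants without a traceable crown root).
  Default trait parameters mirror the published 24-genotype trial:
  crown-root elongation ~1.60 cm/d under high N (genotype means spanning
  roughly 1.44–1.77), a 26 % mean reduction under low N, genotypic
  variance sized for H² ≈ 0.41 at r = 4 on the high-N side and set to 0 on
  the low-N side; intercepts ~11–12 cm with near-zero heritability;
  first-segment lateral counts ~50 (high) vs ~27 (low).  Simulated values
  of non-negative traits are clipped at 0 (a < 0.1 % truncation at these
  settings).

All generators are deterministic in their seed and emit their truth
alongside the outputs.

## Problem sizes in the test and acceptance runs

The shipped checks use desk-scale sizes chosen to exercise every code
path with comfortable statistical margins: 100 random 16 × 16 images for
the fusion/Otsu algebra, 100 random 64 × 64 mask pairs for the region
merge, 20 noisy shoot scenes for proxy recovery, 500 series for slope
recovery, and 300 simulated trials (24 genotypes × 4 replicates × 2 sides)
for heritability recovery.  The acceptance script averages trial
statistics over 10 independent simulated trials.

## Known limitations

* The REML engine supports one random term plus stratified residuals —
  exactly the models here — not arbitrary random-effect structures.
* Containment degrees of freedom are a simple approximation; small-sample
  p-values differ from Kenward–Roger/Satterthwaite software.
* RSML reading assumes laterals nested inside their parent root element
  (the common export form); flat files with `parent` attributes pointing
  outside the enclosing root are rejected rather than re-linked.
* The scene generators make no attempt at photorealism; conclusions about
  real-image robustness require real images.
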