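# Methods

`icbrad` implements a preclinical MRI response-assessment pipeline for
immune-checkpoint-blockade (ICB) studies in orthotopic mouse glioma: a
volumetric translation of the clinical RANO/iRANO criteria for serial
T2-weighted scans, a fixed 423-feature 3D radiomic extractor, a
gradient-boosted response classifier evaluated against the no-information
rate, a set of small immunology statistics, and a synthetic cohort
generator that gives every stage a self-contained test surface.

## Volumetric response criteria

The study design has three scans per animal: baseline (MRI1, day 13),
on-therapy (MRI2, day 19) and post-therapy (MRI3, day 26).  Clinical RANO
measures the product of two perpendicular lesion diameters; for a spherical
lesion that product scales as d² and volume as d³, so a fractional area
change a maps to a volume change (1+a)^{3/2} − 1.  The mandated +25% area
increase (progression) and −50% decrease (partial response) convert to
+39.75% and −64.64%, rounded to the conventional ±5% grid: **+40%** and
**−65%**.  Rounding happens only in the threshold-derivation utility; the
classifier uses the configured thresholds directly.

Categories on %V(MRI3–MRI1), written %V31:

* CR: %V31 = −100 (an exactly empty segmentation; volumes are
  segmentation-derived so exact zero is meaningful and no epsilon band is
  used),
* PR: %V31 ≤ −65 **or** %V(MRI3–MRI2) ≤ −65 (late responders),
* PD: %V31 ≥ +40, unless %V(MRI3–MRI2) ≤ −30, in which case the
  enlargement is treated as unconfirmed progression (pseudoprogression)
  and the animal is rescued to SD,
* SD: everything between.

CR/PR/SD are grouped as responders; PD as non-responders.  Boundary
conventions: exactly −65% is PR, exactly +40% enters the PD branch (then
rescue applies).  Growth patterns are the sign pairs of
(%V21, %V32): G1 (−,−), G2 (+,−), G3 (+,+), G4 (−,+).  Zero change is
folded into the non-growth branch so every trajectory gets a pattern; a
strict mode labels exact zeros `indeterminate` instead.  A lesion that
vanished at MRI2 and regrew at MRI3 has no defined %V32; the category then
comes from %V31 alone and the pattern is `indeterminate`.

The percent change is computed as `100 * ((v_to - v_from) / v_from)` —
ratio first — so total regression is exactly −100 in floating point.

The biperpendicular diameter product is measured on the axial slice with
the largest cross-section as the maximal pixel-center pairwise distance
times the maximal extent perpendicular to it, with a pixel-extent fallback
for degenerate directions (a single voxel at 1 mm spacing measures 1 mm²).
Center-to-center measurement keeps a digitized 20 mm sphere at 400 mm²;
including the full rasterized footprint would overshoot by the staircase
corners and not converge.

## Radiomic extractor

Input is a `LabeledVolume`: 3D intensities, a binary lesion mask, and the
physical voxel spacing (anisotropy is honored everywhere; nothing is
resampled).  The roster is frozen at 423 names in four blocks; the exact
composition is a package convention (documented below), with the block
cardinalities and the named volume-to-surface feature as the stable
contract.  A SHA1 of the ordered names (`DEFAULT_ROSTER.version`) is
emitted with every extraction CSV.

* **First order (146)** — 15 base statistics of the masked intensities
  (moments, order statistics, energies, dispersions), the percentile grid
  p01…p99 (linear interpolation between order statistics), and 8 histogram
  statistics (entropy, uniformity, max probability, mode, and four
  bin-center moments) at each of 8/16/32/64 fixed bins over the masked
  range.  Degenerate constant regions define entropy 0, uniformity 1.
* **Shape (33)** — voxel-count volume, mesh volume, mesh surface area,
  voxel-face surface area, surface↔volume ratios, the
  sphericity/compactness family, principal-axis lengths (4√λ of the
  coordinate covariance), elongation/flatness, bounding box and extent,
  convex-hull volume/area/solidity/convexity, radius of gyration, and the
  RANO diameters (max axial, perpendicular, product).  The mesh is the 0.5
  isosurface of the mask indicator smoothed by a fixed 1-voxel Gaussian:
  the raw binary isosurface carries a ~8% staircase area bias that does not
  shrink with resolution, while the smoothed surface converges (sphere V/S
  error 2.4% at 1 mm → 0.3% at 0.5 mm).  The cost is that sharp-edged
  objects are measured slightly rounded (a 10 mm cube's mesh area reads
  ~490 mm² against 600 mm² of exposed faces at 1 mm voxels); tumors are
  blob-like, and the exact voxel-face area is also in the roster.
* **Texture (200)** — gray levels are discretized to a fixed bin count over
  the masked intensity range (determinism over adaptivity).  Families:
  co-occurrence matrices merged over the 13 unique 3D unit offsets at 16
  and 32 levels (20 statistics each), per-offset co-occurrence at 16
  levels (7 statistics × 13 offsets), run-length matrices summed over the
  13 directions at 16/32 levels (16 statistics), size-zone matrices
  (26-connected zones, 16 statistics, 16/32 levels) and the neighborhood
  gray-tone-difference family (5 statistics at 16 levels).  Single-level
  regions take their closed-form degenerate values (contrast 0,
  homogeneity 1, correlation 1).
* **Curvature (44)** — principal curvatures κ1 ≥ κ2, mean H and Gaussian K
  at each boundary-mesh vertex, summarized by 11 statistics each.
  Curvatures come from the implicit surface: the mask indicator is smoothed
  with a 2-voxel Gaussian, and H and K are evaluated from the gradient and
  Hessian of that field (H from the divergence of the outward normal, K
  from the adjugate-Hessian form), interpolated at the vertices of its 0.5
  isosurface.  This is fully vectorized and convergent — a per-vertex
  quadric fit over 1-ring neighborhoods was considered and rejected as
  O(vertices) Python-loop work with no accuracy advantage at these mesh
  sizes.  Sign convention: a sphere has H = 1/r > 0.  On digitized r=10 mm
  spheres the mean H is within 2% and mean K within 4%, improving with
  resolution; discrete Gauss–Bonnet (∑ K·A ≈ 4π) holds within 10% on
  irregular blobs.

Longitudinal **delta features** are |f(MRI2) − f(MRI1)| per feature, names
suffixed `.delta`; a combined table is the 423 baseline columns followed by
the 423 delta columns.  **z-scoring** uses per-column sample mean/sd;
zero-variance columns map to 0 and are flagged; the fitted state can be
applied to held-out rows and inverted (round-trips to 1e−10).

## Response prediction

The learner is a from-scratch stage-wise gradient-boosting machine on
binomial log-loss: F₀ is the prior log-odds; each stage fits a
depth-limited CART regression tree (scikit-learn's
`DecisionTreeRegressor`, used purely as the split finder) to the residual
y − p, replaces each leaf value with the Newton step Σr / Σp(1−p), and
adds the tree scaled by the shrinkage.  Tuning parameters: iterations
(default 100), depth (2), shrinkage (0.1), minimum terminal-node size
(10); the default tuning grid is {50,100,150} × {1,2,3} × {0.1} × {5,10},
selected by inner-CV accuracy with ties broken toward fewer iterations,
then shallower trees.  Feature importance is the total squared-error
reduction per feature over all splits, normalized to sum 1.

Evaluation is two-times-repeated stratified 5-fold CV; all held-out
predictions are pooled (each animal counted `repeats` times; per-repeat
averaging is available).  By default z-scoring is fitted on the training
folds only and applied to the held-out fold — the leakage-free protocol;
`paper_mode=True` z-scores the whole table once up front (the common
global-normalization variant) for comparison.  Metrics: accuracy at
probability cutoff 0.5 with exact Clopper–Pearson 95% CI; sensitivity with
the responder as the positive class (the minority class under treatment);
specificity; rank-statistic AUROC with midrank tie handling; NIR = the
majority-class proportion; and a one-sided exact binomial test of
#correct against NIR.  Rates are stored as fractions in [0,1]; `summary()`
prints percentages.

## Immunology statistics

* Signature score: exp(mean(log(x + pseudocount))) over a gene set;
  pseudocount defaults to 1 (count-scale data, keeps zeros finite).
* Immunogram: per-feature log2(R/NR group means), z-scored across features
  (sample sd; all-equal input gives all zeros).
* Top-clone share: percentage of productive sequences in the 10 most
  frequent clones (count ties broken lexicographically).
* Productive clonality: 1 − H/ln R (Shannon entropy over clone
  frequencies, normalized by log richness); a single clone is 1 by
  convention.
* Shared CDR3 motifs: single-linkage clusters of equal-length CDR3s at
  Hamming distance ≤ 1 (substitutions only, no indels) spanning ≥ 2
  samples.
* Specific lysis: (experimental − effector spontaneous − target
  spontaneous + background) / (target maximum − target spontaneous), the
  kit-standard LDH correction; scale-invariant in the OD readings.

## Synthetic cohorts

Trajectories are drawn from four archetypes with log-normal growth factors
for v2/v1 and v3/v2 (rejection-sampled until the realized growth pattern
and responder status match): direct responder (G1; medians 0.55/0.40, 5%
chance of complete regression), pseudoprogressor (G2; 1.70/0.35),
progressor (G3; 1.70/1.80) and late progressor (G4; 0.55/2.80).  Defaults:
responder rate 0.476 with responders split ~78:20 G2:G1 (the observed
mix), non-responders 80:20 G3:G4; baseline volume log-normal with median
12 mm³ (a ~2.8 mm lesion at day 13) and log-sd 0.4.

Two deliberate symmetries make the δ=0 cohort a genuine null: the
MRI1→MRI2 growth-factor distribution is identical for pseudoprogressors
and progressors, and the shrinking minorities (G1 among responders, G4
among non-responders) have matching size and dynamics — so the two
observable scans carry no label information unless the radiomic signal is
injected.

Phantoms are star-convex blobs: a sphere of matched volume whose radius is
modulated by band-limited real spherical-harmonic noise (degrees 2–6,
coefficients ~N(0,1)/l, normalized to unit RMS), voxelized on a 64³ grid
at 0.1 mm (defaults) with the base radius rescaled until the voxel volume
is within 3% of the request.  One coefficient set is drawn per animal and
reused across time points, so longitudinal shape change is attributable to
the irregularity amplitude alone.  Lesions too large for the field of view
are rendered at isotropically coarsened spacing rather than truncated, so
volume features stay faithful.  Intensities are 100 ± a correlated
Gaussian texture (correlation length 0.3 mm, sd 15) inside the mask over a
background of 20.

The response signal enters through the MRI1→MRI2 irregularity change:
responders drop by δ (default 0.12 on a baseline of 0.25 ± 0.05),
non-responders rise by δ/4, both jittered by the noise level (0.02).
Because delta features are *absolute* differences, an equal-and-opposite
shift would be invisible — |Δ| of a sign-symmetric shift has the same
distribution in both groups — so the responder shift is deliberately
larger in magnitude, consistent with response being the larger
morphological event.  The δ default is a synthetic calibration chosen so
the recovery/null properties are comfortably separated; it is not a
biological effect size.

What the generator does not emulate: MR physics (coil profiles, partial
volume, motion), multi-lesion animals, registration error between time
points, and segmentation variability.  Passing the recovery test shows the
pipeline can find a shape-borne longitudinal signal at realistic cohort
sizes; it says nothing about effect sizes in real scanners.

## Problem sizes used by the test suite

The pipeline-recovery check runs 10 signal and 10 null replicates of
50-animal cohorts on 48³ grids at 0.12 mm spacing (two rendered time
points per animal, 846 features, 2×5-fold CV), with pass levels at the
90%/10% detection rates (≥9/10 and ≤1/10).  Closed-form phantom checks use
digitized r = 10 mm spheres at 1.0 and 0.5 mm voxels.  The exact-test
oracle sweep covers every 2×2 table with margins ≤ 12.

## Known limitations

* The roster's feature *identities* beyond the block counts are a package
  convention; two radiomics toolkits rarely agree feature-by-feature.
* The smoothed-isosurface estimators bias sharp-edged (non-biological)
  shapes; use the voxel-face features for such objects.
* The boosted learner has no early stopping or subsampling; cohorts of a
  few hundred animals with ~10³ features are its design envelope.
* `shared_cdr3_motifs` is O(n²) per length stratum — fine for repertoires
  of a few thousand distinct sequences, not for full deep-sequencing runs.
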