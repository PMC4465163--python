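# Methods

## Overview

`pettex` re-implements, as a tested pipeline, a pre-treatment FDG-PET
texture analysis for early-stage non-small-cell lung cancer treated with
stereotactic body radiotherapy (SBRT): fixed-SUV isocontour tumor
segmentation, conventional SUV metrics, second-order 3-D texture features,
and the statistical battery relating them to recurrence and survival.
Because no patient imaging of this kind is publicly available, the package
includes a synthetic phantom-and-cohort generator with known ground truth;
every analysis stage is validated against it.

## Segmentation

The tumor volume of interest (VOI) is the connected component of voxels
with `SUV >= threshold` containing the hottest voxel (SUV 2.0 by default;
SUV 2.5 for the stability analysis). Two conventions the clinical
description leaves open are surfaced as configuration rather than fixed
silently:

* **Connectivity** — 26-neighborhood by default; 6 and 18 available. The
  choice can change component membership on noisy data.
* **Threshold comparison** — closed (`>=`), so a voxel at exactly SUV 2.0
  belongs to the 2.0 isocontour.

Manual VOI correction by a physician is replaced by an optional
caller-supplied mask accepted at the feature-extraction interface; there is
no interactive editing. Coordinates are 0-based voxel indices; physical
units enter only through the voxel spacing (MTV in ml).

Because the seed voxel is the global uptake maximum and is contained in the
VOI at any threshold, SUVmax is invariant to the isocontour level by
construction. This is the one quantity of the study that is exactly
reproducible and it anchors the acceptance check (Pearson r = 1 between
SUVmax at 2.0 and 2.5 across any cohort).

## Features

Nine parameters per lesion. Conventional metrics are computed on
floating-point SUV data: SUVmax, SUVmean, MTV (voxel count x voxel volume),
and COV (population SD / mean). For texture, VOI SUVs are rescaled to 64
gray levels:

    R(x) = 64 * (I(x) - SUVmin) / (SUVmax - SUVmin)
    bin(x) = clamp(floor(R(x)) + 1, 1, 64)

The rescaling formula is fixed by the source method; the rounding rule is
not, so floor-plus-one with clamping was chosen: the VOI minimum maps to
bin 1, the maximum to bin 64, and a flat VOI (zero denominator) maps
everything to bin 1.

**GLCM** (gray-level co-occurrence): ordered voxel pairs one step apart
along the 13 unique 3-D directions, both endpoints inside the VOI, counted
and symmetrized (transpose added). The default `merged` aggregation pools
counts over all 13 directions before normalizing; `averaged`
(per-direction normalization, then mean over directions with at least one
pair) is available because the source method states only "13 directions".
Offsets are one voxel in index space; the grid anisotropy (4.06 mm
in-plane vs 5.0 mm axial) is ignored when forming offsets, a known bias of
pure matrix methods, documented rather than corrected. From the matrix
p(i,j):

* entropy = -Σ p log₂ p (bits; the log base is configurable and recorded,
  since conventions differ),
* contrast = Σ (i-j)² p(i,j),
* correlation = Σ (i-μ)(j-μ) p(i,j) / σ², with μ, σ the marginal moments
  (marginals coincide by symmetry). At σ = 0 (single occupied gray level)
  correlation is defined as 1 and a warning is emitted.

**NGTDM** (neighborhood gray-tone difference), Amadasun–King form: for
each VOI voxel with at least one in-mask 26-neighbor, the absolute
difference between its gray level and the mean gray level of its in-mask
neighbors accumulates into s_i; p_i is the occupancy of level i among
valid voxels. Neighborhoods are restricted to in-mask voxels — the VOI
boundary is a tissue boundary, not an image border, so it contributes no
gray tones. Then

* coarseness = 1 / (ε + Σ p_i s_i), ε = 1e-6, capped at 1/ε for a flat VOI,
* busyness = Σ p_i s_i / Σ_{i≠j} |i·p_i − j·p_j| over occupied pairs,
  defined as 0 with a single occupied level.

The clinical study's vendor software reports busyness in 0.43–0.71 and
entropy in 4.6–7.5; the standard definitions implemented here produce
different scales on comparable inputs (busyness orders of magnitude
smaller, entropy of a 64-bin joint distribution up to 12 bits). This is
consistent with a rescaled or variant vendor implementation; the
discrepancy is documented, not reconciled, and does not affect any
rank-based or correlation-based conclusion.

All GLCM/NGTDM code is validated exactly against naive triple-loop
enumeration oracles on randomized small grids, and the 13-direction merged
GLCM is checked to be invariant under 90° volume rotations (the offset set
is closed under the rotation group modulo sign).

## Synthetic cohort

The generator defines the study conditions and is not tuned per analysis.

* **Geometry**: spherical (optionally mildly ellipsoidal) lesions on a
  24 x 32 x 32 grid of 5.0 x 4.06 x 4.06 mm voxels — the clinical
  reconstruction grid. Diameters are log-normal with median 30 mm,
  truncated to 17–68 mm, matching the reported T1 (17–30 mm) and T2
  (31–68 mm) ranges; the 30 mm cut defines the T1/T2 subgroups.
* **Uptake**: background SUV 0.5 (aerated lung); tumor mean SUV log-normal
  with median 8, truncated to 4–25, keeping every lesion segmentable at
  SUV 2.5.
* **Texture**: an additive Gaussian random field inside the tumor —
  white noise smoothed with an isotropic (in mm) Gaussian kernel of SD
  `heterogeneity_length_mm` (6–12 mm across patients), rescaled to SD
  `heterogeneity_amplitude` (0.2–2.5 SUV across patients). Nothing is
  known about the true spatial statistics of intratumoral FDG uptake
  beyond reported feature ranges; a correlated Gaussian field is the
  minimal model with tunable heterogeneity. Independent voxel noise
  (SD 0.15 SUV) is added everywhere and SUVs are clipped at 0.
* **Outcomes**: with z the cohort-standardized GLCM entropy, local
  recurrence is Bernoulli(expit(α + β_LR·z)); disease-specific death time
  is exponential with hazard h₀·exp(β_DSS·z); other-cause death is an
  independent exponential (the dominant mortality in this comorbid
  population); censoring is uniform on 3–72 months (mimicking the
  reported 3.1–71.1 month follow-up); observed survival is the earliest
  of the three with its cause recorded. Nodal and distant relapse are
  Bernoulli draws independent of texture, reflecting the study's negative
  finding for those endpoints. Defaults: α = logit(7/45),
  p_LN = p_DM = 11/45, h₀ = 0.015/month, other-cause 0.02/month
  (reproducing the reported pattern of more other-cause than disease
  deaths), β_LR = 1.6 and β_DSS = 1.0 per entropy SD (chosen once to give
  discrimination and dichotomized hazard ratios of the reported order).

Everything is a pure function of parameters and seed; cohorts are
reproducible bit-for-bit under a master seed.

**What the phantoms do not emulate**: respiratory-motion blurring, scanner
point-spread/reconstruction effects, partial-volume effects, lobulated or
infiltrative shapes, and any real relationship between tumor biology and
image texture. Passing tests therefore demonstrate correctness of the
measurement and statistics machinery and internal consistency of the
modeled effects — not clinical validity on patient data.

### Entropy vs heterogeneity amplitude

A subtlety of min–max rescaled binning: independent voxel noise alone
spreads the 64 bins over pure noise and yields near-maximal co-occurrence
entropy, so in a noise-dominated regime *increasing* the correlated-field
amplitude can lower joint entropy. The monotonicity property (mean entropy
non-decreasing in heterogeneity amplitude) is therefore evaluated with
voxel noise disabled, isolating the amplitude effect: a flat tumor has
entropy 0, any positive amplitude produces high entropy, and pure
amplitude scaling cancels in the min–max normalization.

## Statistics

All tests are two-sided at the 5% level.

* **ROC**: AUC is the Mann–Whitney statistic with ties counted ½. The
  95% CI uses DeLong's distribution-free variance (implemented here; no
  installed package provides it), with Hanley–McNeil as an option since
  the original SPSS-era tooling may have used it. Significance of an AUC
  is a normal test against 0.5 on the same variance. The optimal decision
  threshold minimizes the Euclidean distance from the ROC curve to the
  (0,1) corner, ties broken toward higher specificity; it is validated
  against an exhaustive threshold scan.
* **Survival**: Kaplan–Meier curves, two-sample log-rank, and Cox
  proportional-hazards fits (Efron tie handling) via `lifelines`. Both the
  restricted mean (to the largest observed time) and the median survival
  are always reported, since summaries of this kind are ambiguous in
  clinical tables; a never-reached median is reported as NaN. Multivariate
  Cox models are capped at 3 covariates, the restriction appropriate to
  ~12 events in a 45-patient cohort. MTV enters Cox models log-transformed
  by convention. Non-convergence and non-finite standard errors raise
  errors rather than returning silent estimates.
* **Dichotomization** for survival analysis uses the ROC optimal cutoff
  determined for the matching endpoint label, as in the source procedure.
* **Stability / size dependency**: per-feature Pearson r (with range and
  mean ± SD per VOI definition) between SUV 2.0 and 2.5 feature tables,
  and of each feature against MTV. Zero-variance features are flagged, not
  silently dropped.
* No multiple-testing correction is applied, matching the original
  reporting; Benjamini–Hochberg can be layered on by the caller.

### Covariate pools in the pipeline

For Cox models the pipeline exposes texture both ways: clinical-style
`high_*` indicators (dichotomized at the endpoint's ROC cutoff) and
standardized continuous `z_*` values. The dichotomized indicator is a
coarse surrogate: when the hazard is driven by a continuous feature, the
residual signal left by binarization is partially absorbed by correlated
covariates (notably MTV, which correlates with entropy through lesion
size). The default study report uses `high_entropy` + log MTV + dose
stand-in, mirroring the clinical table; the parameter-recovery validation
enters entropy continuously so that the fitted model matches the
generating model and adjustment covariates behave as true nulls.
"Cumulative dose" has no phantom analogue and is replaced by an
independent normal stand-in covariate (mean 40, SD 8, Gy-like scale),
declared in configuration.

## Pipeline and reproducibility

`run_study(StudyConfig)` executes: cohort generation (or NIfTI/DICOM
ingestion with body-weight SUV conversion) → segmentation and feature
extraction at each configured threshold → ROC per parameter x endpoint
(LR, LR within T2, LN, DM, DSS, OS) → cutoff-dichotomized KM/log-rank →
univariate and restricted multivariate Cox → stability and
size-dependency tables. Every stage is logged into the report's
provenance block together with the master seed and a configuration hash;
identical configurations produce byte-identical report files. Errors in a
stage propagate with the stage name; partial reports are never written
silently (the writer probes the output directory first).

## Problem sizes

Validation runs use cohorts of 45 (the clinical cohort size; default),
100 lesions for the end-to-end effect-recovery check (power), n = 1000
subjects for Cox parameter recovery, 500 replicates for log-rank
permutation-null calibration, 100 random ≤8³ grids for texture oracle
equivalence, and 50 seeds per amplitude for the entropy monotonicity
property. These sizes make the full suite run in a couple of minutes on
one CPU while keeping Monte-Carlo error well inside the asserted bands.

## Known limitations

* Feature scales (entropy, busyness, coarseness) are not comparable to
  the vendor implementation used clinically; only relative/ordinal
  structure is.
* The GLCM offset metric ignores voxel anisotropy.
* Competing risks are handled by cause attribution only (disease vs
  other), matching the source analysis; no Fine–Gray modeling.
* Phantom realism is loosely calibrated: spherical lesions, Gaussian
  texture, no imaging-chain physics.
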