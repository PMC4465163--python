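# pettex — FDG-PET tumor texture analysis for early-stage NSCLC

Patients with early-stage non-small-cell lung cancer treated with
stereotactic body radiotherapy (SBRT) have excellent local control on
average, but a minority recur locally, and conventional PET metrics
(SUVmax, SUVmean) predict this poorly. Spatial heterogeneity of FDG
uptake — *texture* — is a candidate biomarker. This package implements
the full measurement-and-statistics chain needed to study that question,
for imaging scientists and radiation oncology researchers:

* **Segmentation** — the tumor VOI as the connected SUV-isocontour
  component around the hottest voxel (SUV 2.0 default, 2.5 for stability
  analysis).
* **Features** — nine PET parameters per lesion: SUVmax, SUVmean, MTV,
  COV on floating-point SUV; and, after rescaling VOI uptake to 64 gray
  levels by R(x) = 64·[I(x) − SUVmin]/[SUVmax − SUVmin]: entropy
  (−Σ p log₂ p), correlation and contrast (Σ(i−j)²p(i,j)) from 13-direction
  3-D gray-level co-occurrence matrices, and Amadasun–King coarseness and
  busyness from 26-neighborhood gray-tone difference matrices.
* **Statistics** — ROC/AUC with DeLong CIs and minimum-corner-distance
  optimal cutoffs; Kaplan–Meier with log-rank tests on dichotomized
  groups; univariate and restricted (≤3 covariate) multivariate Cox
  proportional-hazards models; Pearson stability and size-dependency
  tables.
* **Synthetic cohorts** — tumor phantoms with controlled diameter, uptake
  and correlated texture on the clinical 4.06 × 4.06 × 5.0 mm voxel grid,
  plus outcomes generated from a logistic (recurrence) and
  proportional-hazards (disease-specific death) dependence on entropy,
  with independent comorbidity mortality and censoring. Every downstream
  stage is testable with known ground truth.

Volumes are read from NIfTI or from DICOM PET series (with body-weight
SUV conversion from the dose/weight/decay tags); tables are plain CSV.

## Worked example

Run the numbered analysis scripts in order (each prints what it found and
writes its tables under `results/`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_recurrence_roc.py
python analysis/03_survival_analysis.py
python analysis/04_stability_and_size.py
python analysis/05_full_study.py      # everything in one reproducible call
```

`01` simulates the default 45-patient cohort (seed 0):

```
cohort of 45 patients (seed 0)
  T1/T2 split: 20/25
  local recurrences: 11
  nodal relapse: 13, distant: 15
  deaths: 33 (16 disease, 17 other cause)
```

`02` asks which PET parameters predict local recurrence (LR). In this
cohort entropy leads (AUC 0.818), volume measures follow — and inside the
T2 subgroup (diameter > 3 cm), where size can no longer explain
recurrence, only texture survives; nodal and distant relapse, generated
independently of texture, are correctly not predicted:

```
significant LR predictors (whole cohort):
  entropy      AUC 0.818 (0.650-0.987)
  mtv_ml       AUC 0.777 (0.609-0.945)
  diameter_mm  AUC 0.773 (0.604-0.941)
  ...
significant LR predictors within T2: entropy
significant LN predictors: none
significant DM predictors: none
```

`03` runs the survival battery. Patients above the entropy cutoff die of
disease much earlier (mean 18.7 vs 59.7 months), and in the multivariate
Cox model adjusted for log MTV and an independent dose stand-in, only the
high-entropy indicator remains significant:

```
multivariate DSS model (entropy vs log MTV vs dose stand-in):
  high_entropy     HR 17.07 (1.74-166.94) p=0.015 *
  log_mtv_ml       HR 1.75 (0.66-4.59) p=0.258
  dose_proxy       HR 0.94 (0.88-1.01) p=0.107
```

`04` quantifies feature robustness across VOI definitions (SUV 2.0 vs
2.5 isocontours) and size dependence. SUVmax is exactly threshold-invariant
(the hottest voxel is in the VOI at any threshold), and the remaining
parameters correlate at r ≥ 0.99 across definitions:

```
stability across VOI definitions (SUV 2.0 vs 2.5):
  suv_max      r=1.000   2.0: 11.4 +/- 3.71   2.5: 11.4 +/- 3.71
  suv_mean     r=1.000   2.0: 8.06 +/- 2.86   2.5: 8.08 +/- 2.84
  mtv_ml       r=0.999   2.0: 23.5 +/- 19.9   2.5: 23.3 +/- 19.9
  entropy      r=0.998   2.0: 9.78 +/- 0.465  2.5: 9.79 +/- 0.463
  ...
correlation with MTV:
  entropy      r=+0.629  p=3.63e-06 *
  coarseness   r=-0.698  p=9.64e-08 *
  cov          r=-0.058  p=0.706
  ...
```

The same pipeline runs from the shell (`pettex simulate`, `pettex
features`, `pettex analyze`, `pettex run --seed 0 --out results/study`)
and on real data (`StudyConfig(mode="files", volume_paths=...,
outcomes_csv=...)`).

See `docs/methods.md` for the model assumptions, parameter defaults,
numerical conventions and known limitations.

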