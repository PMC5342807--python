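# collalign

Quantitative pathology of stromal collagen alignment, built for the
question: *does highly aligned peritumoral collagen predict poor survival
after curative-intent resection?* In desmoplastic tumors such as
pancreatic ductal adenocarcinoma, fibrillar collagen around malignant
ducts reorganizes from a wavy, isotropic mesh into straightened, parallel
tracks; second-harmonic-generation (SHG) microscopy images that collagen
label-free, and the degree of local alignment is a candidate prognostic
biomarker.

The package implements the full workflow and a synthetic-data module that
generates every input with known ground truth, so each stage is testable
without any external data:

* **Fiber quantification** — segment fibers from SHG-style images
  (smooth → threshold → skeletonize → split at branch points) and score
  each 400 × 400 μm ROI with the circular mean resultant length on doubled
  axial angles, R = |n⁻¹ Σ exp(2iθ)| ∈ [0, 1].
* **Registration** — extract collagenous stroma from H&E color
  (decorrelation stretch + K-means), then recover the affine H&E → SHG map
  by multiresolution mutual-information maximization; transfer
  pathologist ROIs through the fitted transform. Tile stitching with
  feathered overlaps is included.
* **Stain quantification** — Beer–Lambert optical density, color
  deconvolution with unit stain vectors, DAB positivity
  `n_DAB / (n_DAB + n_hematoxylin)`, an ordinal stromal score
  (1: <10%, 2: 10–50%, 3: >50%), and per-cell E-cadherin/vimentin
  double-positivity for EMT.
* **Cohort statistics** — patient-level ROI averaging with inclusion
  rules, an X-tile-style log-rank cutoff scan with a permutation guard,
  Kaplan–Meier / log-rank / Cox (Efron ties) via lifelines, backward
  selection around forced clinical covariates, Fisher exact, Spearman, and
  Shapiro–Wilk-gated nonparametric group tests.

See `docs/methods.md` for the statistical model, parameter defaults, and
known limitations.

## Worked example

The end-to-end demo generates a synthetic study (fiber fields, a
registered H&E/SHG pair, IHC slides, a 70-patient training cohort and a
114-patient validation cohort), runs every stage, and writes tables and a
report under a run directory:

```bash
collalign demo --seed 0 --out collalign_run
```

Equivalently, the numbered scripts under `analysis/` run the same study
step by step. On this machine `python analysis/01_simulate_study.py`
through `05_survival_analysis.py` print, among other things:

```
training cohort (n=70): cutoff 0.585 (chi2 7.98, permutation-adjusted p 0.0999)
validation cohort (n=114): 15 high / 99 low; median OS 12.4 vs 28.2 months;
log-rank chi2 7.17, p 0.0074
...
final multivariable Cox model (backward-selected, clinical core forced):
high        1.0926  2.9821    1.4691    6.0530  0.0025
```

Read: the scan on the training cohort picked an alignment cutoff of 0.585
(the generative threshold is 0.60); dichotomizing the validation cohort at
that cutoff labels 15 of 114 patients high-alignment, whose median overall
survival is 12.4 months against 28.2 for the rest (log-rank p = 0.0074);
and in the multivariable Cox model with pT, pN, margin and grade forced
in, high alignment remains an independent predictor with hazard ratio 2.98
(95% CI 1.47–6.05) — the generative hazard ratio of 2.25 sits inside the
interval. The registration stage of the same study recovers a known
4° rotation + (8, −5) px translation to 0.08 px over the full frame, and
deconvolved DAB positivity matches the drawn fractions to ≤ 0.01.

A `collalign` CLI exposes the individual stages (`synth`, `register`,
`fibers`, `stains`, `survive`, `demo`); run `collalign --help`.

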