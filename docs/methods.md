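# Methods

`collalign` implements a quantitative-pathology workflow for stromal
collagen: quantify fiber alignment in SHG-style images, register
brightfield histology onto the SHG frame, score stain positivity, and test
whether an alignment dichotomy predicts overall survival. Because no
public dataset accompanies the workflow, a synthetic-data module generates
every input with known ground truth; all validation statements below are
about what the package computes on those inputs.

## The alignment statistic

Fiber orientations are axial: θ and θ + 180° describe the same fiber. The
alignment of a set {θᵢ} is the circular mean resultant length computed on
doubled angles,

    R = | (1/n) Σᵢ exp(2iθᵢ) |  ∈ [0, 1],

which is 0 for an isotropic field (and for the antipodal pair {0°, 90°})
and 1 when every fiber is parallel. Doubling is the standard embedding of
axial data onto the circle; an `axial=False` flag exposes the undoubled
variant for sensitivity analysis, and optional weights allow
length-weighted scoring (default: one vote per fiber, matching per-fiber
outputs of common fiber-tracking tools). Numerically the implementation
centers angles on the first entry before converting to radians, which
keeps the statistic exact (R = 1.0, not 1 − ε) for degenerate parallel
fields and costs nothing in the general case.

## Fiber extraction

A deliberately simple, fully specified segmenter stands in for external
fiber-tracking software: Gaussian smoothing (σ = `smoothing_scale`,
default 1.5 px) → Otsu or fixed threshold → morphological skeletonization
→ deletion of branch points (≥ 3 skeleton neighbors) so the skeleton
falls apart into simple paths → per-path orientation from the principal
axis of its pixel coordinates, length from the extent along that axis.
Paths shorter than `min_length_px` (default 30) are dropped. The segmenter
is monotone in the generative concentration κ and reproduces ground-truth
R within a few hundredths for moderately-to-strongly aligned fields; in
near-isotropic fields the finite segment count inflates measured R by
~0.05–0.1 (the usual small-sample bias of resultant-length estimates), so
comparisons across conditions should hold segment counts roughly constant.
Crossing fibers are split at intersections, which shortens segments; ROI
membership is by segment centroid.

ROIs are axis-aligned squares, half-open `[x, x+side) × [y, y+side)`,
0-based, with `side = round(400 μm / pixel_size_um)`.

## Registration

Brightfield-to-SHG registration is the classic two-step recipe. Step one
isolates collagenous stroma from the H&E image: decorrelation stretch
(whiten the 3×3 channel covariance, re-expand each channel to its original
standard deviation) followed by K-means clustering in the stretched color
space (k = 4 by default, k-means++ with a fixed seed, fit on ≤ 50 000
subsampled pixels). The collagen cluster is the one whose mean optical
density is closest in cosine distance to a reference stain vector — by
default the eosin vector, since collagen is eosinophilic. Step two
maximizes mutual information between that collagen image and the SHG image
over a 6-parameter affine map.

MI is computed from a joint histogram (32 bins) of a seeded random sample
of pixel pairs (20% by default). Inside the optimizer the histogram uses
bilinear bin spreading (each sample deposits tent-kernel weight into the
2×2 neighboring bins), making the objective continuous in sub-pixel
parameter changes; the public `mutual_information` defaults to hard
binning so that MI(x, x) equals the histogram entropy of x exactly.

Optimization is coarse-to-fine over a factor-2 Gaussian pyramid (3 levels).
At the coarsest level an exhaustive rotation × translation search (±12° in
3° steps × ±24 px at full resolution) seeds the estimate. Each level then
maximizes the sampled MI with Powell's direction-set method in scaled
coordinates (linear part 0.005 per unit, translation 1 px per unit). An
earlier implementation followed the textbook alternative — steepest ascent
with central-difference gradients and step halving — but with a sampled MI
objective the finite-difference gradients are corrupted by samples
entering and leaving the overlap region, and the ascent stalls far from
the optimum at finer levels; Powell's per-direction line searches are
robust to this and keep the per-level MI trace monotone, which the test
suite asserts. If the final MI does not beat the identity map the identity
is returned with a warning flag. On synthetic H&E/SHG pairs the full
pipeline recovers translations ≤ 20 px, rotations ≤ 10°, and anisotropic
scales in 0.95–1.05 to ≲ 0.2 px / 0.05° / 0.1%.

Transforms map moving (H&E) coordinates to fixed (SHG) coordinates,
`p_fixed = A p + t`, acting on (x right, y down) column vectors, 0-based.
ROI transfer maps the four corners, re-imposes an axis-aligned square on
the bounding box (side = mean of the box dimensions, which is exact for
rigid maps), and clips-and-flags ROIs leaving the target frame. Tile
stitching places tiles on the regular grid implied by the overlap fraction
and blends overlaps with linear feathering, which reconstructs a
consistently-cut scene up to interpolation error.

## Stain quantification

Brightfield color is modeled by Beer–Lambert: `OD_c = −log10(I_c / I0_c)`
per channel (I0 = 255 default; zero intensities clamp to 1 count), and a
`StainModel` holds three unit OD row vectors (Ruifrok–Johnston values for
hematoxylin, eosin, DAB; the third row is their cross product).
Deconvolution is per-pixel matrix inversion, `c = OD · V⁻¹`, with negative
concentrations clipped to zero and counted. The forward + inverse round
trip is exact to 1e-6 in float; after 8-bit rendering the error stays
below 0.02 for stain densities up to ~0.9 OD. Near-opaque pixels (total
OD ≳ 1.5) are quantization-limited — one 8-bit count at I ≈ 2 is a ~20%
intensity error — which is physics, not a solver property.

DAB positivity classifies a pixel as DAB if its DAB concentration is
≥ `od_threshold` (default 0.15 OD, configurable) and exceeds hematoxylin,
as hematoxylin analogously (ties to hematoxylin), else background;
the score is `n_DAB / (n_DAB + n_hematoxylin)`, undefined (flagged) when
no pixel is stained, and invariant to background area. The ordinal stromal
scale maps fractions to {1: < 10%, 2: 10–50% inclusive, 3: > 50%}; both
boundaries fall in bin 2, and independent reviewer scores are averaged.
EMT scoring operates on a per-cell table (upstream segmentation is assumed
done): the fraction of epithelial cells with both marker intensities at or
above their thresholds.

## Synthetic data

* **Fiber fields** — axial von Mises orientations: 2θ ~ von Mises(2μ, κ),
  θ = half, so κ = 0 is uniform and κ = ∞ (flagged degenerate) puts every
  fiber at μ. The population resultant length is I₁(κ)/I₀(κ), the oracle
  the generator is tested against. Fibers are anti-aliased straight
  segments (length ~ N(60, 15²) px clipped at 8, width 2 px) at uniform
  positions; background Gaussian noise σ = 3 on a 0–200 intensity scale,
  optional Poisson shot noise. Curvature is out of scope — the statistic
  consumes one angle per fiber.
* **H&E pairs** — eosin concentration proportional to the normalized SHG
  scene, random hematoxylin nuclei disks, composed by Beer–Lambert, then
  resampled through a known affine map (stored in the result) so that
  H&E coordinates map to SHG coordinates through exactly that transform.
* **IHC slides** — tissue as a union of random disks; exactly
  `round(f · n_tissue)` tissue pixels get DAB stain (concentration
  U(0.5, 0.9)), the rest hematoxylin, so the realized positive fraction is
  recorded without estimation error and re-measurement from the rendered
  8-bit image agrees to ~0.01.
* **Cohorts** — n = 114 patients by default, an exact `round(0.12 n)` of
  them above the alignment cutoff 0.60. Patient-level alignment is
  truncated normal: low group N(0.47, 0.07²) on [0.289, 0.60), high group
  N(0.635, 0.03²) on [0.60, 0.712], matching the observed range and the
  ~12% highly-aligned tail of the modeled setting. Each patient receives
  2–4 tumor-region cores (regions sampled from low grade / high grade /
  core / edge) with 1–2 ROIs each, ROI values recentered so their mean
  equals the patient value exactly, plus usually one normal-adjacent core
  (N(0.35, 0.05²)) that aggregation must ignore. Ten binary covariates are
  Bernoulli with margins loosely matching the modeled cohort (e.g. 46%
  female); by default they carry no survival effect, so the alignment
  indicator is the only signal and marginal and adjusted hazard ratios
  coincide. Survival is exponential with hazard
  `ln 2 / 26.9 months · exp(β·1[high] + Σ covariate effects)`,
  β = ln 2.25 by default. Censoring times are independent exponentials
  whose rate is solved (Brent) so the expected censored share equals
  `censor_fraction` (default 0.40) given the realized hazards; empirical
  censoring lands within 0.05 of target for n ≥ 100.

What the generator does **not** emulate: real H&E texture and stain
variability, fiber curvature and width variation, necrosis/vessels/nerves,
non-exponential baseline hazards, covariate–survival and
covariate–alignment dependence (unless configured), and measurement error
in the alignment → survival link (the generative effect acts on the exact
dichotomy). Passing tests therefore demonstrate internal consistency and
correct algorithmic behavior, not clinical performance on real tissue.

## Cohort statistics

Patient aggregation averages all tumor-region ROI values (normal excluded)
and excludes patients with fewer than two distinct tumor cores, with the
reason recorded. Averaging is over ROIs directly rather than per-core
means first; the choice is exposed because either reading is defensible.

The cutoff scan evaluates the two-group log-rank χ² at every unique
observed value inside the 10th–90th percentile window, subject to both
groups holding ≥ max(5, 10% of n) patients, and returns the argmax. The
inner χ² is a vectorized O−E / hypergeometric-variance sum shared across
candidates (cross-checked against lifelines to machine precision). Because
the scan optimizes the statistic, the nominal p at the maximum is
optimistic; `n_permutations > 0` adds a permutation-adjusted p (the null
distribution of the *maximal* statistic under label permutation, add-one
estimator), and the `significant` flag uses the adjusted p when available.
A scan of this kind is consistent — median |cutoff − 0.60| falls from
~0.04 at n = 70 to ~0.006 at n = 1000 in simulation — but at n = 70 with a
hazard ratio of 2.25 carried by ~8 patients it localizes the threshold
within one observed-value grid step in only ~45% of replicates; the
log-rank profile is flat and noisy enough that its maximum frequently sits
several grid steps from the true boundary. Users should treat small-cohort
cutpoints as approximate and lean on the permutation guard.

Kaplan–Meier estimation, the two-group log-rank test, and Cox regression
are delegated to lifelines (Efron tie handling; Wald CIs,
`exp(β ± 1.96·SE)`); the KM median is the smallest t with S(t) ≤ 0.5,
undefined (NaN) when the curve never reaches 0.5. Note that the Efron
partial likelihood is *not* invariant to duplicating every subject (Breslow
is); the test suite pins the Efron estimate on tied data to a brute-force
partial-likelihood oracle instead. Backward selection starts from the
univariate screen (p < 0.25) plus a forced clinical core (pT, pN, margin,
grade by convention), repeatedly drops the worst non-forced covariate at
p ≥ 0.25, and never drops forced covariates. Fisher's exact test
(two-sided, sum of hypergeometric probabilities ≤ observed), Spearman
rank correlation (midranks), Shapiro–Wilk-screened Mann–Whitney U /
Kruskal–Wallis come from scipy; "unknown" covariate levels are excluded
per-test and models use complete-case rows. All p-values are two-sided
with α = 0.05.

## Numerical and degenerate-input conventions

Empty angle lists, blank ROIs, and unstained images yield flagged-undefined
results rather than exceptions; truly invalid input (ROI outside the
image, singular stain matrix, constant registration images, k < 2,
degenerate cutoff grids) raises `ValueError`. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; fixed seeds
give byte-identical pipeline outputs. Simulation sizes in the test suite
(500 cohorts for Cox calibration, 100 training cohorts for the cutoff
scan, 20 seeded registration cases at 256×256) were chosen as the smallest
sizes at which the Monte-Carlo error is comfortably below the tolerances
being asserted.

## Known limitations

* The fiber segmenter is a stand-in: no curvelet filtering, no fiber
  linking across crossings, no width estimation. Its R values are
  comparable within the package, not calibrated to any external tool.
* Registration assumes a global affine map; serial-section deformations
  that need B-splines are out of scope, and capture range is bounded by
  the coarse-level search (±24 px, ±12°).
* The stain model assumes exactly two chromogens plus residual and a
  shared background intensity; no cross-slide stain normalization.
* The cutoff scan reports uncorrected and permutation-adjusted evidence
  but does not reproduce any proprietary cutpoint software's internal
  cross-validation.
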