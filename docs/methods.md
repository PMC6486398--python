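# Methods

This note records the models and procedures implemented in `habitatseg`, the
assumptions behind them, the defaults that matter, and what the synthetic
tests do and do not demonstrate.

## Habitat segmentation

**Model.** Each subject's lesion is treated as its own ecological system:
thresholds are quartiles of the pooled voxel distributions *within that
subject's CE ROI*, never cohort-global absolute cutoffs. Low perfusion is
the lowest rCBV quartile; restricted and elevated diffusivity are the lowest
and highest ADC quartiles; the two habitats are their intersections with the
low-perfusion mask, and all remaining CE voxels form the CEC control. The
partition `ADC_L-rCBV_L ∪ ADC_H-rCBV_L ∪ CEC = CE` holds exactly by
construction, and the two habitats are disjoint whenever the ADC values in
CE are non-constant (q1 < q3).

**Inputs and registration.** All maps and masks must share one voxel grid;
the package refuses mixed grids (shape or voxel size differing by more than
1e-6 mm) rather than resampling, because silent resampling would change
quartile populations. Co-registration is upstream of this package.

**Normalization.** Parametric maps are divided by the arithmetic mean over
the NAWM mask. The result is scale-invariant: any positive rescaling of the
raw map yields the same normalized map, and therefore identical habitat
masks (quartile masks are invariant under strictly increasing transforms).

**Numerical choices.**
- Quantile definition: linear interpolation between order statistics (the
  common scientific-software default); configurable via `quantile_method`.
- Threshold inclusivity: low masks use `value <= q1`, high masks
  `value >= q3`. With heavy ties this over-selects; tie counts at each
  threshold are recorded in the result and a warning is emitted when more
  than 1% of ROI voxels tie a threshold. On a constant map the "quartile"
  masks degenerate to the whole ROI — reported, not hidden.
- ADC and rCBV quartiles are both computed from voxels pooled within CE
  (not from the whole map), keeping the two thresholds on the same
  population.
- CE masks smaller than `min_ce_voxels` (default 64) are flagged as
  unreliable for quartile estimation; volumes are still computed.
- Volumes: `count x voxel volume / 1000` (cm³); proportional volumes are
  percentages of CE volume.
- Dice of two empty masks is defined as 1.0 (agreement on absence),
  configurable via `empty_value`.

## MRSI aggregation

Spectroscopic voxels are modelled as non-overlapping axis-aligned blocks of
image-grid voxels (one 2D slab, mirroring 2D-MRSI acquisition); in-plane
spectral interpolation is not modelled — coverage is counted at image-grid
resolution. A spectroscopic voxel contributes only if its block lies
*completely* inside the tumor mask and passes quality control (an explicit
`qc_pass` flag, or a relative-SD column thresholded at 20% by default).
Weights are compartment coverage fractions renormalized to sum to one, and
the compartment value is the weighted mean of the per-voxel ratios. The
renormalization is deliberate: a raw weighted sum would scale with
compartment size, which is meaningless for a concentration ratio. The
weighted mean always lies in the convex hull of contributing ratios and
reduces to the plain mean when coverage is uniform. Subjects with no
eligible spectroscopic voxel receive an explicit missing record and drop
out of metabolite analyses.

## DTI p/q decomposition and invasive phenotypes

p = √3·MD measures isotropic diffusion magnitude and q the Euclidean
deviation of the eigenvalue triple from isotropy. q is invariant under
eigenvalue permutation and vanishes iff the tensor is isotropic; for a
cylindrically symmetric tensor (a, b, b), q = √(2/3)·|a−b|. Negative
eigenvalues (noise) are clamped to zero with a count; non-finite voxels are
masked to NaN.

Phenotype classification compares the maximal physical extent (Euclidean
distance transform, respecting anisotropic voxel spacing) of p- and
q-abnormality beyond the CE boundary: *minimal* if both margins are below
`t_min` (default 10 mm), *diffuse* if the p-margin exceeds the q-margin by
more than `t_diff` (default 10 mm), *localized* otherwise. **These
thresholds are provisional**: the originating clinical criteria are not
restated here, so the defaults are configurable and externally adjudicated
labels can override the rule. Abnormality masks are inputs, or can be
derived by a configurable z-score rule (>2 SD from the NAWM distribution).

## Cohort statistics

- Group comparisons: Welch t (scipy), Wilcoxon rank-sum (asymptotic,
  tie-corrected), Kruskal–Wallis; Benjamini–Hochberg step-up adjustment
  (statsmodels) for multiplicity.
- `surv_cutpoint`: maximally selected standardized log-rank statistic.
  Candidate thresholds are midpoints between consecutive unique covariate
  values; splits must leave at least `minprop` (default 0.1) of subjects on
  each side; ties in the maximal statistic resolve to the smaller
  threshold. The implementation enumerates every admissible split exactly —
  no approximation — and is validated against independent per-split
  log-rank computation. The naive post-dichotomization log-rank p-value is
  reported as-is for descriptive use, with the caveat that maximal
  selection inflates type-I error; `cutpoint_permutation_pvalue` provides a
  permutation-corrected alternative.
- Kaplan–Meier and log-rank via lifelines; with zero events the statistic
  is defined as 0 (p = 1).
- Cox models: lifelines provides the initial fit (Efron tie handling); the
  estimate is then polished by Newton steps on the in-package Efron partial
  likelihood until the score norm is below 1e-9, and Wald inference (SE,
  95% CI, p) is taken from the observed information at that optimum. This
  keeps estimates in numerical agreement with lifelines (~1e-5) while
  guaranteeing a vanishing score. AIC is the partial-likelihood AIC,
  −2·logPL + 2k; the null model's logPL has the closed form
  −Σ_j Σ_{l<d_j} log(n_j − l).
- Stepwise selection: greedy AIC. Forward starts from the null model (its
  first accepted step is the best single-covariate model, so the procedure
  "starts from the model with one covariate"); backward starts from the
  full model; either stops when no single add/drop lowers AIC. The step
  trace is kept on the returned fit. Greedy search can in principle miss
  the best subset when the AIC surface has no monotone path to it; on
  simulated 4-covariate designs agreement with exhaustive best-subset
  search exceeds 95%.
- Missing covariates (e.g. MGMT status) are handled by complete-case
  analysis per model with counts recorded; nothing is imputed silently.
- Censoring convention: event flag 1 = observed event, 0 = censored at the
  recorded time.

## Synthetic data

**Phantom.** A rim-enhancing ellipsoidal lesion (default 17x14x11 mm radii
on a 64x64x32 grid at 1 mm isotropic; ~1.1e4 CE voxels) whose innermost
quarter of CE voxels (by normalized ellipsoid radius) forms the
low-perfusion core, split evenly into restricted- and elevated-diffusivity
subregions. Region intensities are truncated Gaussians (±2 SD) with
deliberately disjoint supports — core rCBV 0.5±0.1 vs rim 2.5±0.4;
restricted ADC 0.70, rim 1.10, elevated 1.50 (×10⁻³ mm²/s, SDs 0.03–0.05) —
so the planted core is exactly the lowest pooled rCBV quartile and recovery
is a sharp correctness check rather than a statistical one. An
`disjoint_supports=False` mode removes the truncation for
graceful-degradation experiments. NAWM is a contralateral 5 mm-radius
sphere; eigenvalue maps set MD equal to the ADC map with anisotropy 0.6
outside and 0.1 inside the lesion; p/q abnormality extends configurable
physical margins (defaults 15 and 5 mm) beyond CE. A single mid-lesion
slice carries the MRSI slab (8x8x1 image-voxel blocks, ~an order of
magnitude coarser in-plane), with per-block ratios equal to the block mean
of a compartment-wise constant metabolite map plus Gaussian noise
(SD 0.05).

Because 8x8 blocks mix compartments, the coverage-weighted value of a
compartment is a mixture of compartment means, not the pure planted
constant. The generator therefore also returns the noise-free
geometry-implied expected weighted value per compartment
(`truth["expected_weighted"]`), and recovery tests compare against that
quantity; exact-equality checks use noise-free phantoms with a constant
planted everywhere. All randomness flows from the single spec seed; equal
seeds give bit-identical bundles.

**Cohort.** Clinical covariates mirror a rim-enhancing glioma population
(age ~59±11 y clipped to 22–76, 75% male, lognormal volumes with CE
~53 cm³ and compartments ~5.7/2.3 cm³), with survival times exponential in
the planted linear predictor (default baseline: median PFS 265 days, OS 455
days; default planted effects: partial resection log-HR ln 2.8, MGMT
methylation ln 0.62, CE volume 0.008 per cm³, compartment Lac/Cr ln 2).
Censoring is independent with per-subject rate calibrated so each subject
is censored with exactly the target probability (default 0.3). About 3.6%
of MGMT values are set missing to exercise complete-case handling.

**What passing tests show — and don't.** The phantoms verify algorithmic
correctness (set logic, weighting arithmetic, threshold placement,
estimator calibration), not clinical performance: real lesions have
overlapping intensity distributions, partial-volume effects, registration
error and non-ellipsoidal geometry, so Dice ≈ 1 on phantoms says nothing
about segmentation accuracy on patients. Survival simulations use
proportional-hazards exponential models, the best case for Cox estimation.

## Problem sizes in the validation suite

Property sweeps use compact randomized phantoms (48x48x24 grid, jittered
geometry, core fraction 0.2–0.3) so a hundred phantoms run in well under a
minute; the default-geometry phantom (~1.1e4 CE voxels) backs the
fraction-accuracy and end-to-end checks. Survival recovery uses 50 cohorts
of n = 500 with 30% censoring; stepwise-vs-exhaustive agreement uses 50
(tests) / 30 (script) cohorts of n = 150 with four candidates; log-rank
calibration uses 1000 null simulations of n = 100. At n = 500 with ~350
events the sampling SD of the log hazard ratio is ≈ 0.107, so a window of
[1.7, 2.35] around a true HR of 2 corresponds to ~±1.5 SE and an expected
per-run hit rate of ~0.87 — the hit rate the suite and script report should
be read against that statistical ceiling.

## Known limitations

- MRSI geometry is block-based; real spectroscopic point-spread and
  chemical-shift displacement are not modelled.
- Phenotype thresholds are placeholders pending externally validated
  criteria; prefer supplied labels where available.
- The cutpoint's naive log-rank p is anti-conservative by construction;
  use the permutation option for inference.
- Cox modelling assumes proportional hazards and right-censoring
  independent of covariates; no time-varying effects, competing risks or
  frailty.
- The pipeline never resamples: inputs on mismatched grids are rejected,
  not harmonized.
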