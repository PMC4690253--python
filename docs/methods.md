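# Methods

## Signal model and T2 estimation

Each myocardial pixel is modelled as a mono-exponential transverse decay
sampled at nine echo times TE_i = 15 + 7.7·i ms (i = 0…8):

    nu_i = A · exp(−TE_i / T2)

Magnitude reconstruction turns the complex Gaussian acquisition noise into
Rician noise, whose density for magnitude M at true signal ν is

    p(M | ν, σ) = (M/σ²) · exp(−(M² + ν²)/(2σ²)) · I₀(Mν/σ²).

Two estimators are provided.

**Log-linear least squares** regresses log M on −TE. It is exact on
noiseless data and fast, but the Rician noise floor (E[M] → σ√(π/2) as
ν → 0) lifts late-echo magnitudes and biases T2 upward as SNR falls; it
serves as the baseline and as the initialiser for the MLE.

**Rician maximum likelihood** maximises the joint log-likelihood of
(A, T2, σ) per pixel. σ is estimated per pixel rather than from a
background region, so the fit is self-contained on phantoms that have no
calibrated background; a fixed-σ variant can be obtained by passing an
explicit initial value and bounds. Numerical choices:

* parameters are optimised on the log scale (positivity by construction)
  with a damped (Levenberg) Newton iteration, vectorised across pixels;
  the Hessian is a finite difference of the analytic gradient;
* the likelihood is evaluated through the identity
  −(M²+ν²)/(2σ²) + Mν/σ² = −(M−ν)²/(2σ²) and through the exponentially
  scaled Bessel function I₀ᵉ, so neither tiny σ nor Bessel arguments of
  order 10¹² lose precision or overflow;
* convergence: relative log-likelihood change < 10⁻⁸ (default), at most
  200 iterations; steps are accepted only if the likelihood does not
  decrease, so the returned optimum is never below the initialiser;
* T2 is constrained to (1, 500] ms (physiological range plus headroom for
  edema); pixels ending on a T2 bound are flagged non-converged;
* a pixel whose initial fit already reproduces the data to a relative
  residual of 10⁻⁸ is in the degenerate σ → 0 regime where the likelihood
  is unbounded; it is returned directly as the exact log-linear solution
  with σ at its floor (10⁻⁶).

At SNR 20 (A/σ), 10⁴ simulated pixels at T2 = 60 ms give a mean MLE
estimate within 2% of truth with a smaller absolute bias than the
log-linear fit on the same draws; the per-pixel scatter (≈ 7% median
absolute error at SNR 20) is set by the information in nine echoes, not by
the optimiser, so accuracy claims are about central tendency.

## AHA segmentation

Pixels whose centres fall inside the epicardial and outside the endocardial
polygon form the myocardium. The angle of each pixel about the epicardial
centroid, measured counterclockwise from the anterior RV-insertion ray,
assigns it to a sector: six 60° sectors on basal and mid slices (anterior,
anteroseptal, inferoseptal, inferior, inferolateral, anterolateral), four
90° sectors apically; segment ids are 1–6 (basal), 7–12 (mid), 13–16
(apical). A chirality flag flips the direction for mirrored orientations.

Six short-axis slices map onto the three levels as (1,2) basal, (3,4) mid,
(5,6) apical; the two slices of a level are pooled before statistics, so
each subject yields exactly 16 rows. Per segment the arithmetic mean of the
converged pixels' T2 and their sample standard deviation (n−1 denominator)
— the "pixel-SD" — are recorded, along with the pixel count; segments with
fewer than 10 pixels (configurable) are flagged and excluded from feature
extraction unless a partial mode is requested. No endo/epicardial erosion
is applied by default (phantom contours are exact); contoured real data
would typically exclude the trabeculated layer before reaching this stage.

## Heterogeneity features

With x_j the 16 segmental values of a subject,

    mad(x; log) = (1/k) Σ_j |y_j − ȳ|,   y_j = ln x_j  (or x_j without log)

* madSD applies the log transform to the pixel-SDs, making it invariant to
  a common rescaling of all pixel-SDs;
* madT2 uses the raw segmental T2 means (ms) and is invariant to a common
  T2 offset;
* maxT2/maxSD are the plain maxima, sensitive to a focus confined to a
  single segment; globalT2/globalSD are the across-segment means.

Strictly 16 segments are required by default (the defining equations assume
k = 16); a documented partial mode recomputes with the available k. A
pixel-SD of exactly 0 (possible in degenerate noiseless phantoms) is
clamped to 10⁻⁶ ms with a warning before the log.

Note on scales: the raw-scale madT2 of realistic cohorts is of order
2–5 ms. Published madT2 values of order 0.07–0.09 are only consistent with
a log-scale computation; this package follows the raw-scale definition for
madT2 and the log-scale definition for madSD, and the feature-level cohort
sampler treats published summary values purely as moments to draw from.

## Synthetic data

**Image level.** The left ventricle is an annulus (endocardial radius
22.5 mm, wall 10 mm) on a 128×128 grid of 2 mm pixels, six slices. Pixel
T2 = subject baseline + segment offset + within-segment texture + lesion
elevation, clipped at 1 ms. Amplitude is uniform (A = 500) and σ = A/SNR.
Lesions are angular wedges with a two-pixel raised-cosine edge, occupying
the subepicardial `transmural_fraction` of the wall, on a chosen set of
slices. All randomness derives from one seed via `SeedSequence` spawning
(tissue and noise streams are independent).

**Cohort population model** (`CohortImagingParams`). Healthy baselines are
N(58.7, 4.2²) ms, matching the healthy global-T2 reference; ACM baselines
N(60, 5.5²). Between-segment offsets have SD 5.5 ms and within-segment
texture is lognormal across segments (median 7.4 ms, log-SD 0.30) at
SNR 60, calibrated once so that simulated healthy cohorts reproduce the
published healthy feature moments (globalT2 ≈ 58.7, globalSD ≈ 7.7 ms,
maxT2 ≈ 69 ms, madSD ≈ 0.22). ACM subjects receive 1–3 subepicardial
lesions (transmural fraction 0.3–0.7 — partial-thickness involvement is
what raises within-segment pixel-SD), spanning one level ± one slice, with
angular extent 60–140° and T2 elevations drawn from U(12, 40) ms. The
upper end exceeds the 10–20 ms remote-vs-edema contrast often quoted for
averaged regions because published ACM cohorts show segmental means up to
~119 ms; elevations capped at 20 ms cannot produce the reported ACM maxT2
distribution (80.5 ± 16.8 ms), which the calibration targets.

**Feature level.** `generate_cohort_features` draws the six features from a
truncated multivariate normal with the published group means/SDs as default
moments and a configurable correlation (default: 0.5 between maxT2 and
madSD, reflecting their reported collinearity; all coordinates are
constrained non-negative by rejection). It is a marginal-moment emulator:
it does not enforce logical couplings such as maxT2 ≥ globalT2 and carries
no spatial structure.

**What passing tests show.** The phantoms are motion-free annuli with
exact contours, uniform receive field, single-coil Rician noise and
piecewise-smooth lesions. Tests passing on them validate the estimators,
the segment bookkeeping, the feature algebra and the classifier mechanics —
not robustness to contouring error, through-plane motion, B1 shading,
multi-coil noise statistics or realistic lesion morphology.

## Statistics and classifiers

* Welch's t (unequal variances, Welch–Satterthwaite df) and the Wilcoxon
  rank-sum test (midranks; tie-corrected, continuity-corrected normal
  approximation; exact enumeration of all C(n, n₁) assignments when
  n₁+n₂ ≤ 12), both two-sided at α = 0.05.
* Effect size r = Z/√N from the rank-sum deviate (the standard companion of
  the rank test); r = √(t²/(t²+df)) is available as an alternative — which
  of the two a given publication used is rarely stated, so both are exposed
  and neither is asserted as canonical.
* Logistic regression by IRLS with Wald standard errors from the observed
  information; complete separation is detected (fitted probabilities pinned
  to the labels, or exploding coefficients) and flagged instead of returning
  arbitrarily large estimates. Odds ratios with 95% CIs are
  exp(b ± 1.96·SE); `odds_factor(feature, delta) = exp(b·delta)`.
* Classification trees: greedy binary recursive partitioning minimising the
  weighted Gini impurity 1 − Σp², candidate thresholds at midpoints of
  consecutive sorted unique values, ties broken toward the lower feature
  index and lower threshold, default depth 2 and minimum leaf 5.
* Random forests: bootstrap-resampled trees with ⌊√p⌋ features considered
  per node; variable importance is the mean per-tree sum of
  (n_node/n)·(parent − weighted child impurity), seed-deterministic.
* Cross-validation: stratified k-fold (round-robin within class after a
  seeded shuffle), pooled accuracy.
* ROC: AUC by the Mann–Whitney rank formulation with half credit for ties;
  sensitivity/specificity at every distinct score under the
  "positive iff score ≥ threshold" convention. The score for the combined
  two-feature model is the logistic predicted probability.
* Reference-range baseline: a subject is positive when any segment's mean
  T2 exceeds its layer's normal mean + k·SD (basal 56.7 ± 4.1, mid
  58.1 ± 4.2, apical 62.2 ± 5.2 ms; k ∈ {2, 3}); the any-segment
  aggregation is this package's documented choice.
* Cut-off rule: ACM iff madSD > 0.22 AND maxT2 > 68 ms, strict
  inequalities. Descriptions of this rule are ambiguous between conjunction
  and disjunction; the conjunctive reading matches "values below both
  cut-offs represent HV" and is the default, with `combine="or"`
  selectable.

## Design notes and limitations

* A depth-2 Gini tree fitted to moment-matched Gaussian cohorts places its
  madSD threshold near the class-density crossing (~0.26–0.27), not at the
  healthy-group mean 0.22 that tree fits to the original patient data
  reported; recovering a published tree cut-off therefore depends on the
  real data's distribution shape, not only on its first two moments.
* The problem sizes used by the test suite (e.g. 2 000-pixel recovery
  batches, 20 phantom-cohort replicates of 61 subjects, 100-tree forests)
  were chosen as the smallest sizes at which the sampling error of each
  checked quantity is well below its tolerance.
* Out of scope by design: visual/semi-quantitative T2-weighted reading,
  contrast-enhanced imaging, cine volumetry, DICOM/scanner formats,
  multi-coil (non-central chi) noise, stimulated-echo and B1 corrections,
  automatic contour detection, the 17-segment apical-cap model, and
  multinomial logistic regression.
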