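# cardiomad

Quantitative analysis of myocardial edema from cardiac T2 maps, built around
tissue-*inhomogeneity* statistics rather than absolute T2 alone.

Acute myocarditis (ACM) is often focal: small edematous regions raise the T2
relaxation time of parts of some left-ventricular segments while global
myocardial T2 barely moves out of the healthy range. `cardiomad` implements a
complete, tested pipeline for studying this problem on synthetic data:

1. **Simulation** — short-axis multi-echo GraSE phantoms of the left
   ventricle (nine echoes, TE₁ = 15 ms, ΔTE = 7.7 ms; 2 × 2 × 10 mm³) with
   focal wedge lesions and Rician magnitude noise, plus a fast feature-level
   cohort sampler.
2. **T2 fitting** — pixel-wise mono-exponential fits
   ν(TE) = A·exp(−TE/T2), either log-linear least squares or a joint
   (A, T2, σ) maximum-likelihood fit under the Rician noise model, which
   removes the noise-floor bias of the log-linear fit.
3. **AHA segmentation** — endo/epicardial contours plus an RV-insertion
   reference angle give the standard 16-segment model (6 basal, 6 mid,
   4 apical); each segment yields a mean T2 and the within-segment
   "pixel-SD".
4. **Heterogeneity features** — per subject: globalT2, globalSD, and

   * maxT2, maxSD — the single highest segmental value,
   * madT2 = Σ|x_j − x̄|/k over the k = 16 segmental T2 means,
   * madSD = Σ|y_j − ȳ|/k with y_j = ln(pixel-SD_j) — the mean absolute
     deviation of log-transformed pixel-SD, a scale-free
     heterogeneity-of-heterogeneity statistic.
5. **Diagnostics** — the combined cut-off rule (ACM iff madSD > 0.22 AND
   maxT2 > 68 ms), multiple logistic regression (IRLS, Wald odds-ratio CIs),
   Gini classification trees and random-forest importance, stratified
   cross-validation, Mann–Whitney ROC/AUC, and the layer-specific
   reference-range (mean + k·SD) baseline classifier.

The intended audience is researchers developing or validating quantitative
CMR tissue-characterisation methods who need a ground-truthed testbed for
segmental heterogeneity statistics.

## Worked example

```python
import numpy as np
from cardiomad import (generate_cohort_features, DiagnosticLogit,
                       apply_cutoff_rule, roc)

cohort = generate_cohort_features(n_hv=30, n_acm=31, seed=42)
fit = DiagnosticLogit.from_dataframe(cohort, ["maxT2", "madSD"]).fit()
print(fit.summary())
print(f"odds factor, madSD +0.1 : {fit.odds_factor('madSD', 0.1):.2f}")

pred = apply_cutoff_rule(cohort)            # madSD > 0.22 AND maxT2 > 68
pos, hit = cohort["label"] == "ACM", pred == "ACM"
print(f"cut-off rule: sensitivity {(hit & pos).sum() / pos.sum():.2f}, "
      f"specificity {(~hit & ~pos).sum() / (~pos).sum():.2f}")
print(f"logistic-score AUC: "
      f"{roc(fit.predict(cohort[['maxT2', 'madSD']]), cohort['label']).auc:.2f}")
```

prints

```
Multiple logistic regression (IRLS)
  converged: True   separation: False
  log-likelihood: -31.0474
  term                B       SE         OR       2.5%      97.5%
  Intercept       -6.61     2.14
  maxT2            0.01     0.03      1.007     0.9496      1.068
  madSD           24.43     8.03  4.054e+10       5909  2.782e+17
odds factor, madSD +0.1 : 11.50
cut-off rule: sensitivity 0.68, specificity 0.67
logistic-score AUC: 0.82
```

The 61-subject cohort is drawn from the published healthy/ACM feature
moments, so the fitted coefficients scatter around the published model
(madSD ≈ 20, maxT2 ≈ 0.03): madSD dominates the discrimination (an increase
of 0.1 multiplies the ACM odds roughly tenfold here) while maxT2 adds little
once madSD is in the model, and the fixed cut-off pair classifies about two
thirds of subjects correctly at this sample size.

Image-level phantoms run through the same stages:

```python
from cardiomad import (PhantomSpec, LesionSpec, generate_phantom_subject,
                       fit_map, contours_from_spec, ImageGrid,
                       build_segment_masks, segment_statistics,
                       compute_features)

spec = PhantomSpec(seed=1, lesions=[LesionSpec(slice_indices=(2, 3),
                                               angular_center_deg=40,
                                               angular_extent_deg=120,
                                               transmural_fraction=0.5,
                                               delta_T2_ms=18)])
series, truth = generate_phantom_subject(spec)
t2map = fit_map(series, method="rician_mle")
labels = build_segment_masks(contours_from_spec(spec),
                             ImageGrid(shape=series.grid_shape))
features = compute_features(segment_statistics(t2map, labels))
```

A command-line umbrella mirrors the library:
`cardiomad simulate|fit|segment|features|compare|classify|evaluate|run`.

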