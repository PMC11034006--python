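# Methods

This note documents the models, conventions and numerical choices behind
`pwcgen`, and what the synthetic study conditions can and cannot show.

## Generative model

Each subject's connectome is generated in Fisher-z space, where the
effects are additive, and mapped through tanh so every entry is a valid
correlation:

```
z_ij = site_scale · ( base_ij
                      + s·(δ/2)·[edge ij incident to a signal parcel]
                      + β_age·(age − midpoint)·[edge ij in the age-edge set] )
       + site_offset + ε_ij,     ε_ij ~ N(0, noise_sd²) symmetric

C = tanh(z),  diag(C) = 1
```

with s = +1 for female and −1 for male subjects. Design points:

- **Symmetric ±δ/2 coding.** The pooled mean equals `base` regardless of
  the sex ratio, so the effect size is not confounded with a global
  offset. δ is the female-minus-male difference in Fisher-z units on
  edges incident to the signal parcels (default δ = 0.4).
- **Age effect on the signal parcels' edges** (default
  β_age = 0.004 z/year). Because sites differ in age range, this
  deliberately confounds age with the sex signal across sites — the
  situation the CV-consistent confound regression must neutralize.
- **Site effects** are an additive offset (z units), a multiplicative
  scale, and subject-level edge noise (SD in z units). They model the
  scanner/acquisition/preprocessing differences between datasets. No
  quantitative site-effect magnitudes are available for the real
  cohorts, so the defaults are *illustrative*: offsets ±0.05…0.2,
  scales 0.90…1.10, noise SD 0.45…0.65. They were chosen once so that
  site heterogeneity is comparable in magnitude to the biological
  effect — the regime in which training-sample composition matters,
  which is the phenomenon the experiment module probes. With
  noise_sd = 0.5 the per-edge effect size is d = δ/noise_sd = 0.8, so a
  signal parcel's profile (all P−1 edges informative) is easy to
  classify while a background parcel (only |S| informative edges) is
  substantially harder — accuracy maps have genuine spatial structure.
- **Default five-site layout.** Four training-eligible sites mirror the
  age structure of the real design (two young narrow-range sites, two
  wide-range sites reaching ~85 years) plus a young, slightly
  female-skewed unseen site used only for external testing.
- **Determinism.** Every dataset draws from a sub-seed
  `sha256(master_seed | name) & 0x7fffffff`, so adding or reordering
  datasets never perturbs another dataset's draws, and all results are
  bit-reproducible under a fixed master seed.

A time-series path (`generate_parcel_timeseries`) draws T×P series from
a zero-mean multivariate normal whose correlation matches a target
connectome (nearest-PSD repair by eigenvalue clipping; strongly
indefinite targets, min eigenvalue < −0.01, are rejected). Two nuisance
series (white-matter and CSF mean-signal analogs) are mixed in with
known loadings, so `clean_timeseries` is verifiable exactly: the OLS
residual of the observed series equals the residual of the latent
series. Voxel-level simulation, motion and physiological artifacts are
out of scope.

## What the generator does *not* emulate

Real resting-state data have spatially structured, heavy-tailed,
temporally autocorrelated noise; site effects that interact with brain
region; preprocessing-pipeline differences that are not reducible to
offset/scale/noise; and unmeasured confounds (brain size, hormonal
state). Passing tests on generator data therefore demonstrate that the
*pipeline* is correct and that the compound-training advantage follows
from the modeled site-heterogeneity mechanism — they do not certify
effect sizes or accuracies on real cohorts, whose headline numbers
require the original five datasets.

## Sample assembly

- **Age matching**: greedy 1:1 nearest-age female–male pairing without
  replacement; candidate pairs ranked by age difference (ties by row
  order), pairs beyond the caliper (default 3 years) dropped. Greedy
  (rather than optimal) matching is deterministic and auditable; the
  original matching procedure is not specified anywhere, so a simple
  documented substitute is preferable.
- **Holdout**: train size = ⌊train_fraction·n⌋ per dataset. Floor is the
  rounding that reproduces all four printed held-out counts
  (220/214/48/250) from the printed matched sizes (878/854/190/1000).
  Splits are stratified by sex × age quartile; a stratum smaller than 2
  degrades to sex-only stratification with a logged warning.
- **Compound samples**: per-dataset quotas by largest-remainder
  apportionment (quotas sum exactly to the target and are each within 1
  of the unrounded share), stratified subsampling within quota. The
  default compound sizes are (total/2.564, total), preserving the
  2190:854 ratio of the full-scale design. The unseen site's sample is
  used as-is, not sex-balanced; balanced accuracy absorbs the
  imbalance.

## Per-parcel classification protocol

For each parcel independently, on its (n_subjects × P−1) profile block:

1. repeated stratified outer CV (defaults 10-fold × 5 repeats);
2. within each outer training fold: per-feature OLS age model
   (`feature ~ 1 + age`) fitted on the training fold only and applied to
   both the fold and its held-out subjects; then train-fitted z-scoring;
3. inner stratified grid search (default 5-fold) over kernel ∈
   {linear, rbf}, C ∈ {0.01…100}, gamma ∈ {scale, 0.001, 0.01, 0.1},
   selecting by mean balanced accuracy with ties broken by grid order
   (deterministic);
4. refit the winning combination on the outer training fold and score
   the held-out fold with balanced accuracy; the parcel's value is the
   mean over folds × repeats.

Final models refit on the full training sample (confound model,
standardization and hyperparameter selection on the full sample); for
cross-sample application the kernel is restricted to rbf. Applying
models across samples residualizes the *test* features with the
*train*-fitted age model evaluated at the test subjects' ages — the
sample-level analog of the CV-consistent rule (the original description
does not state this case; it is the only choice consistent with
fold-level leakage avoidance). A guard raises if train and test share
subject ids. Standardization before the SVM is our choice (rbf kernels
need comparable feature scales); probability calibration, class
weights and feature selection are deliberately absent. The classifier
is sklearn's C-SVM (libsvm); per-parcel parallelism via joblib uses
fixed per-parcel seeds so results are independent of worker count.

Numerical conventions: degenerate inputs are hard errors rather than
NaNs (constant age, zero-variance series, single-class labels, folds
missing a class); zero-variance features standardize with scale 1
(sklearn convention).

## Consistency and statistics

- Dice thresholds: 0.50–0.70 inclusive in 0.02 steps (11 levels),
  membership by accuracy ≥ t. When both thresholded sets are empty the
  DSC is undefined (NaN) and excluded from wmDice — scoring it 0 or 1
  would bias the summary; undefined markers are preserved in the
  output. wmDice uses the true weighted mean Σ t·DSC / Σ t.
- Top-fraction selection: k = round-half-up(frac·P) (44 parcels at
  frac = 0.10, P = 436); ties at the cut break by ascending parcel
  index.
- Comparisons: pooled-variance two-sample t-tests (Welch behind a
  flag), two-sided p-values, t > 0 when the first mean is larger;
  Bonferroni gates per comparison family (all pairwise tests of one
  pwC across its evaluation samples; all pwCs within one evaluation
  dataset). Parcels are treated as independent observations — a known
  convention of this analysis; the spatial dependence between parcels
  is not corrected.

## Problem sizes

Full scale (P = 436, n ≈ 900/site, 10-fold × 5) is supported but the
shipped study conditions are desk-scale, chosen once: P = 60, n = 200
for null calibration; P = 30, n = 400 for signal recovery; P = 30,
n = 150/site, rbf-only grid (C ∈ {0.1, 1, 10}, gamma = scale,
5-fold × 1 outer, 3-fold inner) for the six-sample generalization
experiment, repeated over five master seeds. At these sizes the top-10%
selection spans 3–6 parcels, enough for stable rankings while a full
experiment run completes in well under a minute per seed.

## Known limitations

- The site model is exchangeable across edges (offset/scale/noise applied
  uniformly); real site effects are regionally specific.
- Greedy matching and largest-remainder apportionment are documented
  substitutes for unspecified original procedures.
- At desk scale, single-site accuracy maps can saturate near 1.0 on
  strongly matched test sites, which makes some pairwise t-tests
  degenerate (zero variance); the orchestrator records those pairs as
  NaN/not-significant instead of failing.
- wmDice inherits the overall accuracy level: maps that are accurate
  everywhere overlap at every threshold, so wmDice comparisons are most
  informative between conditions of similar mean accuracy.
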