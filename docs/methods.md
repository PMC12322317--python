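# Methods notes

This note documents the models behind `npscreen`, the choices made where
the design was genuinely open, and what the synthetic cohorts do and do
not establish about real data.

## 1. Lesion panel, binarization, load

The autopsy panel holds 14 lesions in three domains — amyloid-associated
(ADNC, Braak stage, diffuse plaques, neuritic plaques, CAA),
cerebrovascular-associated (infarcts, microinfarcts,
hemorrhages/microbleeds, arteriolosclerosis, circle-of-Willis
atherosclerosis, white matter rarefaction) and other (Lewy body disease,
hippocampal/MTL sclerosis, TDP-43). Each lesion's ordinal grade scale is
dichotomized low/high (absent/present; Braak none–II vs III–VI;
none,sparse vs intermediate,frequent; none,mild vs moderate,severe). The
rules ship as versioned JSON so a different grading convention is a data
change, not a code change.

*Load* is the count of high-grade lesions (total / amyloid domain /
cerebrovascular domain). Up to 2 missing grades are tolerated (counting
over observed lesions, profile flagged); more marks the participant
unusable for label construction. Rationale: autopsy panels are rarely
complete and discarding every incomplete panel would waste a scarce
labeled set.

**Load levels.** Published cutoff values for the none/low, medium, high
bins were not available, so the default is empirical tertiles of the
labeled cohort's load distribution per target, frozen per run and written
to the run manifest. Cutoffs are fully configurable; analyses that need a
fixed clinical definition should pass explicit cutoffs.

## 2. Cohort construction

Two analysis sets: the *generalized* set (non-autopsy participants aged
60+, one randomly selected visit each — a cross-section of the clinical
landscape) and the *t_minus* set (autopsy participants with 3–7 roughly
annual visits indexed by years before death). The autopsy-age threshold
defaults to 65 years; the alternative value 70 that appears in some
descriptions of this design is available as a parameter
(`autopsy_age_threshold`). Filters are idempotent and warn (never silently
return) on empty results.

**Longitudinal features.** Sequence models are deliberately avoided:
visits are irregular and few, so each numeric feature is summarized per
participant as baseline value, most recent value, least-squares slope per
year of elapsed time (positive = rising toward death), and across-visit
SD; categoricals contribute mode and a change indicator. Participants
need at least 3 visits.

**Preprocessing.** Fit on training folds only: features with more than
30% training missingness are dropped (the threshold is a free parameter —
no published value exists), zero-variance features are dropped, numerics
are median-imputed and standardized, categoricals are mode-imputed and
one-hot encoded. Every drop is recorded in the preprocessor's report.
Median/mode imputation was chosen as the simplest leakage-safe default.

## 3. Synthetic cohorts

The generator is the package's study-condition definition, not a tuning
surface; its defaults are fixed and the tests run against them.

Three participant-level standard-normal latent factors (amyloid,
cerebrovascular, other propensity) drive both sides:

* **Lesions.** Logistic models: amyloid-domain lesions load on the
  amyloid factor, cerebrovascular-domain on the cerebrovascular factor,
  and LEWY/SCL/TDP on unit-norm mixtures (Lewy at the edge of the amyloid
  block; sclerosis and TDP-43 peripheral mixtures). The common loading is
  derived from `within_domain_correlation` (default 0.45), interpreted as
  a latent-liability correlation — the observed binary correlations are
  necessarily smaller, and real lesion–lesion correlation magnitudes are
  not public, so this is a free parameter. Age enters each lesion's logit
  (default slope 0.4 per standardized-age unit; 0.6 for the structural
  vascular lesions, −0.3 for Lewy body disease, whose prevalence declines
  across years lived). Intercepts are solved by Gauss–Hermite x
  Gauss–Legendre quadrature so marginal prevalence matches the configured
  values exactly, whatever the loadings.
* **Severity and diagnosis.** A clinical severity index blends the
  factors additively *and* through a dominant-pathology max term, plus a
  non-negative per-participant drift over visits; thresholds yield the
  clinician cognitive-status labels (normal → dementia), monotone
  non-decreasing within participant by construction. The max term
  reflects that clinical severity tracks the worst pathology rather than
  a pure sum, and makes the feature–label relationship partly nonlinear.
* **Features.** Each schema feature has a loading pattern over the
  factors, age and severity, scaled by `latent_effect_sizes[(driver,
  modality)]`; transforms include saturation (floor/ceiling effects of
  clinical scales). Two *context-interaction channels* carry part of the
  signal with a sign that flips with a context indicator (blood-pressure
  control vs antihypertensive use; subjective-decline reports vs
  informant availability) — their marginal correlations are near zero, so
  this signal is recoverable only by models that capture interactions,
  which is why flexible classifiers outperform the logistic benchmark on
  these cohorts, as reported for the real data. Effect sizes were
  calibrated once so that informative tier-1 features show a standardized
  shift of ≈0.8 between the none/low and high total-load classes, then
  frozen.
* **Null cohort.** `generate_null_cohort` zeroes every feature-side
  effect size *and* the lesion age slopes (age is itself a feature, so
  the age→lesion path must also be cut); lesion prevalence and the lesion
  correlation blocks are untouched. Labels are then statistically
  independent of all features — the negative control for every stage.

What the generator does **not** emulate: real missingness mechanisms
(MCAR only by default), site effects, measurement drift, informative
visit timing or drop-out, demographic realism beyond age/sex/education,
and the native variable dictionaries of real studies. Passing tests on
these cohorts demonstrates correctness and calibration of the machinery
under the assumed structure, not clinical performance on real data.

Unlabeled participants carry 1–5 visits (only the autopsy subset has the
3–7 constraint); semi-supervised longitudinal runs use the unlabeled
participants with ≥3 visits as their pool.

## 4. Clustering and trajectories

A-priori reduction (tier filter, optional whitelist — defaults to all
features in the selected tiers, as no published feature list exists), an
autoencoder (hidden 32 → bottleneck 8 → 32, tanh), then a K=3
full-covariance Gaussian mixture on the bottleneck embedding. The
autoencoder trains full-batch (LBFGS), which makes the fit deterministic
at fixed seed and invariant to row duplication. Components are ranked by
the proportion of cognitively normal members (rank 1 = least impaired);
ties break by component index with a warning.

Assignment is hard (argmax posterior) — verified against a brute-force
Bayes computation in the tests. Trajectory classification discards visits
strictly less than 2 years before death (volunteer bias near death); the
window is half-open, so a visit at exactly 2.0 years survives. The group
is decided by the endpoint rule (first vs final surviving rank); a
slope-sign alternative (`rule="mean"`) is provided for sensitivity
analyses because "no net change on average" admits both readings.

## 5. Enrichment against a BCa bootstrap null

For each lesion and trajectory group, the observed within-group
proportion of positive lesions is compared to a bootstrap null built from
the pooled autopsy cohort (default B = 30,000 replicates) with a BCa
interval at 99.9% confidence — the wide level compensates for interval
under-coverage and the 14 x 3 comparisons. z-scores are
(observed − null mean)/null SD.

Two calibration-critical choices:

* **Resample size.** Null resamples are drawn from the pooled cohort *at
  the group's size*. Under the null hypothesis — the group is an
  arbitrary subset — the group proportion then shares the replicates'
  sampling distribution and the nominal 0.1% level is honored (verified
  over 200 simulated null cohorts). Resampling at the pooled size
  (`match_group_size=False`) is retained for comparison but its band is
  ≈ sqrt(n_total/n_group) too narrow for subgroup testing.
* **Domain-level test.** The mean z across a domain's lesions is compared
  with the equal-tail 99.9% band of mean z-scores from simulated null
  groups of matched size; the same simulated groups are reused across the
  domain's lesions so the band reflects their cross-lesion correlation.

Numerical conventions: percentile endpoints use inclusive linear
interpolation (`numpy.quantile` default); a bias fraction of 0 or 1 is
clamped to 1/(B+1) with a warning; identical replicates yield a point
interval flagged degenerate; with zero acceleration and zero bias the
interval reduces exactly to the percentile interval (tested). Restricting
the assignment table to one visit time point yields per-time-point nulls.

## 6. Semi-supervised prediction

The classifier is a two-latent-variable deep generative model: decoder
`p(x|z,y)` (class-conditional Gaussian mean), encoder `q(z|x)` (diagonal
Gaussian), classifier `q(y|x)`. Two deliberate departures from the most
literal formulation, both made because the load labels are *tertile
boundaries on a continuous spectrum* rather than separated clusters:

* the encoder is label-free and shares its inference trunk with the
  classifier, so unlabeled reconstruction shapes the shared
  representation directly;
* the classifier head reads the encoder mean `mu(x)` (the compressed,
  denoised representation) rather than the raw input.

With these choices the unlabeled pool yields a consistent AUC gain over
supervised-only training at ~10% labels (tested over 10 seeded cohorts);
with a label-conditional encoder and a raw-input classifier the
marginalized-ELBO gradient alone produced no reliable gain on
boundary-type labels in our experiments.

Defaults: latent 16, trunk widths (64, 32) (decoder mirrored), tanh
activations, Adam (lr 2e-3, weight decay 1e-5), batch 128, 60 epochs,
classification weight `alpha = 1 + n_unlabeled/n_labeled` so supervision
scales with the pool. Early stopping monitors cross-entropy on a 15%
validation split carved from the training rows; if that split would hold
fewer than 30 rows the stopping point is a lottery, so the model falls
back to the fixed epoch budget. Non-finite loss aborts with diagnostics.
All gradients are manual backprop through the reparameterized sample,
checked against finite differences to ~1e-9 in the tests.

Baselines: multinomial logistic regression (the benchmark), random forest
(400 trees, min leaf 3) and histogram gradient boosting (depth 3,
learning rate 0.08, 250 rounds, leaf 20, L2 1.0) — defaults sized for
desk-scale tabular cohorts.

**Evaluation.** Macro one-vs-rest ROC-AUC; a class absent from a fold is
skipped with a warning and the macro runs over the defined classes.
Per-class precision/recall/F1 and the confusion matrix are emitted and
mutually consistent (tested). The condition grid shares one stratified
5-fold partition per target across all tier/visit cells and freezes the
single-visit draw per participant, so fold-level AUCs are paired. The
two-way repeated-measures ANOVA uses fold as the blocking unit, each
effect tested against its own effect x fold interaction (df (2,8), (1,4)
and (2,8) at 5 folds); sums of squares below 1e-12 x max(1, grand mean²)
are treated as the floating-point residue of a constant table (F = 0).
Sphericity corrections are not applied (with 2–3 levels per factor and 5
folds the uncorrected test is the conventional choice); the post-hoc tier
test within each visit mode is an ordinary one-way ANOVA over fold AUCs
(df (2,12) at 5 folds).

## 7. Feature importance

LOCO retrains the model per fold without one feature (the faithful,
expensive reading — no refit-free shortcut); permutation importance
shuffles one raw column in held-out folds before preprocessing, so
derived one-hot/summary columns stay consistent, and shares LOCO's
normalization by the full model's AUC. Confidence intervals are
percentile *bootstrap CIs of the mean* importance over fold replicates
(LOCO) or repeat replicates (permutation): this keeps the percentile
construction while making the interval tighten as replicates grow —
a raw percentile over replicates would widen instead. Significance =
CI entirely above zero.

## 8. Association screen

Pairwise Pearson correlations (binarized lesions as 0/1 numerics, i.e.
point-biserial), pairwise-complete observations with per-pair n reported,
two-sided p-values against a Bonferroni threshold of 0.05 / (pairs in the
screened panel) — the family is the panel, and the family size is
recorded. Matrix ordering is average-linkage hierarchical clustering on
the correlation distance 1 − r (deterministic); on the synthetic cohorts
it cleanly separates the amyloid block from the cerebrovascular block
with sclerosis/TDP between them.

## 9. Problem sizes

The default test-suite and acceptance sizes are desk-scale stand-ins
chosen to preserve the structure of the design rather than its absolute
scale: 800 labeled / 3,000 unlabeled for the headline prediction
controls (vs tens of thousands in large consortium data sets), 200–800
participants for bootstrap calibration and power checks, B = 2,000
bootstrap replicates in repeated-simulation settings vs 30,000 in a
single analysis run. Config defaults are n_unlabeled = 5,000 /
n_labeled = 800.

## 10. Known limitations

* The synthetic generator's nonlinearities (max-blend severity,
  sign-flip interaction channels) are stylized; real clinical
  interactions are richer and weaker.
* Tertile load levels depend on the labeled cohort at hand; cross-cohort
  comparisons need frozen cutoffs.
* The SSL advantage is demonstrated for the low-label regime; at
  generous label counts the unlabeled pool neither helps nor hurts
  materially.
* Hard GMM assignment discards posterior uncertainty; participants near
  component boundaries can flip trajectory groups under resampling.
* Per-time-point enrichment nulls are supported but the headline
  analysis aggregates over trajectory groups at the participant level.
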