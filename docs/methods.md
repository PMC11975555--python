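# Methods

## The cohort model

The package studies a single-center gastrointestinal-tumor registry of 300
patients, of whom 267 are analysis-eligible after three exclusion rules
(tumors elsewhere in the body, neoadjuvant chemotherapy, anticoagulant use
within three months; 10/13/10 records).  The eligible cohort splits into 158
malignant and 109 benign cases; the malignant arm is partitioned two
independent ways, by anatomic stage (TNM I+II: 84 vs III+IV: 74) and by
histologic grade (G1+G2: 91 vs G3+G4: 67).

Patient-level data are not public; only per-group summary statistics are.
The generator therefore draws each variable from its published per-group
Gaussian `(mean, sd)` (binary covariates from per-group proportions,
right-skewed tumor markers from moment-matched lognormals), with exact group
sizes and deterministic seeding (one master seed; all draws flow from a
single `numpy` Generator).  Key assumptions and their consequences:

- **Marginals, not joints.**  Within a group, variables are independent by
  default.  Every per-variable AUC in the published tables depends only on
  the two group marginals, so those targets are unaffected; multivariate
  results (stepwise selection, the classifier benchmark) are demonstrations
  on a plausible joint, not reproductions.  An optional correlation block
  (Gaussian copula over chosen continuous variables) and a *structural* CI
  mode (CI computed from R, K, α-angle, MA via a standard linear TEG
  composite plus Gaussian noise) restore the dependence needed for the
  collinearity and mediation demonstrations.  The structural coefficients
  (−0.6516, −0.3772, 0.0759, 0.1224, −7.7922) are a standard linear CI
  formula adopted as a package default; the source analysis states only that
  CI is a composite of the four parameters.
- **Two cross-cutting partitions cannot both be matched.**  The TNM-group
  and grade-group moments describe the same 158 malignant patients, so one
  cohort cannot reproduce both sets exactly.  `generate_cohort` takes
  `stratify_by` ("g" default, "tnm", "malignancy") selecting which
  partition's moments drive malignant sampling.  The default is "g" because
  the grade-group mixture reproduces the published malignant-arm means
  almost exactly (e.g. K: (91·1.692 + 67·1.282)/158 = 1.518, the printed
  malignant mean), and the grade contrast carries the headline results.
- **No truncation by default.**  Several published moments imply occasional
  negative draws (e.g. FIB 7.468 ± 6.703).  Truncating would distort the
  moments that the AUC checks depend on, so values are left untruncated;
  per-variable truncation bounds are configurable.
- **Categorical baseline rows are unreliable.**  The published
  binary-covariate counts are internally inconsistent (column totals exceed
  the stated group sizes).  The text-stated group sizes govern; binary
  proportions are taken as within-column normalized fractions and should be
  treated as indicative only.
- **Variables without published moments.**  The tumor markers (CEA, AFP,
  CA19-9, CA72-4), tumor length/area, Caprini VTE score and nutritional
  screening score appear in the published regressions but with no
  distributional summaries anywhere in the text.  The generator ships
  clinically plausible defaults for them (lognormal markers; see
  `cohort._AUX_VARIABLES`).  They feed only the stepwise-linear
  demonstration; no quantitative check depends on them.

What passing tests on this generator do and do not show: they verify the
statistical machinery (AUC, mediation, selection, the classifier) against
known ground truth under the published group structure; they do not validate
any claim about real patients, whose joint distribution, measurement error
and missingness the generator does not emulate.

## ROC analysis

Empirical AUC uses the midrank (Mann–Whitney) formulation, which equals the
tie-corrected concordant-pair fraction; an exhaustive pair-counting oracle
confirms this on all small inputs.  AUCs are *oriented*: if the raw AUC is
below 0.5 the direction flips to `lower_is_positive` and AUC := 1 − AUC,
matching diagnostic tables in which every entry exceeds 0.5.  Confidence
intervals use DeLong's placement-value variance (Hanley–McNeil behind a
flag); the p-value tests AUC = 0.5 with the DeLong standard error.  The
Youden cutoff maximizes sensitivity + specificity − 1 over observed
thresholds, breaking ties toward higher sensitivity.  When both classes are
Gaussian the closed form Φ(|μ₂−μ₁|/√(σ₁²+σ₂²)) is the analytic oracle; the
mean empirical AUC over replicate simulated cohorts agrees with it to < 0.01
at the study's sample sizes.

One published figure resists this replay: the grade-stage R-value prints AUC
0.682, but its own printed moments (4.537 ± 0.953 vs 3.985 ± 0.863) give a
binormal AUC of ≈ 0.666.  The discrepancy is irreducible from summary data
(it may reflect the propensity-matched analysis population hinted at in the
source's figure captions), so grade-stage R is excluded from the
reproduction targets and documented here instead.

## Trend test

The published "one-way trend" analysis is implemented as the
Jonckheere–Terpstra test (sum of pairwise Mann–Whitney counts over ordered
group pairs, tie-corrected normal approximation), with Kruskal–Wallis and
Bonferroni-adjusted pairwise Mann–Whitney comparisons as companion output.
Mann–Whitney p-values are exact (full enumeration with midranks) when the
combined sample size is ≤ 12, asymptotic with continuity correction
otherwise.

## Mediation

Product-of-coefficients with percentile bootstrap (default 2,000 resamples;
seeded and reproducible).  Effects are on the raw scale — log-odds for the
logistic outcome — because the published effect magnitudes are consistent
with unstandardized log-odds; standardization is a flag.  Since only the
effect-percentage ratios (indirect/total, direct/total) are scale-free, those
are the quantities checked against the published decomposition (0.800 and
0.245 for the R pathway; 1.421 and −0.343 for MA).  With a logistic outcome
the decomposition is non-collapsible: total ≠ direct + indirect in general,
and the gap is reported (`additivity_gap`) rather than hidden — consistent
with the published table, where −0.0415 + 0.172 ≠ 0.121.  The fully linear
analogue restores exact additivity and serves as the internal oracle.
Classification: *complete* if the indirect CI excludes 0 while the direct CI
covers 0; *partial* if both exclude 0; *none* otherwise.  Separated logistic
fits raise rather than returning silent estimates; failed bootstrap
replicates are dropped and counted.

## Selection

VIF screening regresses each predictor on the rest (VIF = 1/(1−R²)),
removing the largest until all fall below the threshold (default 10,
commonly tightened to 5); exactly collinear columns are flagged infinite and
removed first.  Stepwise selection is SPSS-style forward with a backward
re-check after every entry — single-df likelihood-ratio tests for logistic
models, partial-F for linear — with p_enter = 0.05, p_remove = 0.10 and
deterministic tie-breaks (smaller p, then alphabetical).  The pipeline
encodes one explicit rule: if CI is classified a complete mediator for the
grade contrast, it is excluded from that multivariate model, so the
mediator's collinear shadow cannot absorb the R/MA effects.  Propensity
matching is 1:1 greedy nearest-neighbor without replacement on the logit
propensity (ridge-regularized logistic propensity model, stable under
separation), caliper = 0.2 SD of the logit propensity by default; default
covariates age, sex, BMI, smoking (the source never lists them).

## RFCBC

The published architecture narrative contains two dimensional
inconsistencies, resolved as follows:

1. "Processed again through FC3 and FC4" cannot reuse FC3's weights (the
   first concatenation is 320-wide, FC3 expects 128).  Canonical resolution:
   fresh dimension-matched layers FC3′ (320→256) and FC4′ (256→512).  A
   weight-sharing variant (learned 320→128 projection feeding the original
   FC3/FC4) is available via `shared_reprocessing=True`.
2. "FC6 reduces the feature dimension from 512 to 2" conflicts with the
   640-wide second concatenation.  Canonical resolution: FC6: 640→2; the
   alternative 640→512→2 head is available via `wide_head=True`.

Training defaults (unstated in the source, documented here as package
choices): ReLU activations, dropout 0.1, Adam at 1e-3, batch 32, early
stopping on validation loss with patience 20, per-feature standardization
fitted on the training data.  No class reweighting.  Backpropagation through
the two concatenation junctions is hand-written and validated against
finite-difference gradients; training is bit-reproducible given the seed on
a single thread.  The evaluation protocol behind the published accuracy
figures is ambiguous ("for all samples"), so the harness reports both
repeated stratified CV (default 5-fold × 10 repeats) and resubstitution
accuracy; the published 87.56% / 88.6% are not treated as reproducible
targets, because they depend on the unavailable patient-level data.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to keep Monte-Carlo error well
inside the asserted tolerances: 200–500 replicate cohorts for AUC means
(MC SE ≈ 0.002), 200 seeds × 8 predictors for the stepwise null calibration,
60 replicates for mediation-CI coverage, 2,000-patient chains for mediation
recovery.  Bootstrap CIs are percentile with n_boot ≥ 200 enforced.  Exact
Mann–Whitney enumeration switches on at combined n ≤ 12.  Degenerate inputs
(zero-variance t-tests, single-class labels, all-tied trend values,
rank-deficient designs) raise typed errors rather than returning NaNs.
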