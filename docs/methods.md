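# Methods

## Model

The unit of analysis is the within-sample ordering of two genes.  For an
ordered pair p = (A, B) and sample s, the indicator x_{p,s} equals 1 when
A's expression strictly exceeds B's in s, and 0 otherwise — ties score 0
(they fall under the "otherwise" branch), compared with exact float
equality and no tolerance, so the transform is fully deterministic.  One
canonical orientation is kept per unordered pair, with gene A preceding
gene B in the supplied gene-list order; the reverse orientation is
redundant (complementary up to ties) and would only add collinearity.

Survival follows a Cox proportional-hazards model on the pair indicators:

    h(t | s) = h0(t) · exp( Σ_p β_p x_{p,s} )

The risk score is the linear predictor Σ_p β_p x_{p,s} (no intercept — the
Cox model has none).  Binary covariates are never standardized: their
coefficients are already on a common per-indicator scale.

Because x depends only on within-sample ranks, the entire downstream
pipeline — scores, risk groups, every survival statistic — is invariant
under arbitrary strictly increasing per-sample transformations of the
expression matrix.  This is the precise sense in which the method is
robust to batch and platform effects, and the test suite asserts it
bit-for-bit rather than approximately.

## Pipeline stages and their parameters

**Frequency filter** (`min_minor_freq`, default 0.20).  A pair is kept iff
its 1-frequency lies in the closed interval [0.20, 0.80]: "minor state in
fewer than 20% of samples" deletes a pair, so exactly 20% is retained.
Frequencies are computed on the training cohort only; a signature is
applied to validation cohorts through its fixed pair list regardless of
local frequencies.

**Univariate screen** (`alpha`, default 0.05).  One Cox fit per pair with
the indicator as sole covariate; candidates have two-sided Wald p < alpha.
Wald (rather than likelihood-ratio or score) p-values are used because
they are what standard survival-package summaries report.  Pairs that are
constant among survival-complete samples, or whose likelihood separates,
are flagged inestimable and excluded without aborting the screen.

**LASSO-Cox** (`n_folds` = 10, seeded).  The coefficient path is computed
by coordinate descent (scikit-survival's Coxnet, convergence tolerance
1e-9) over a glmnet-style grid: 100 log-spaced penalties from the smallest
all-zero-coefficient λ down to 0.001 of it, unless a grid is supplied.  A
user-forced λ of exactly 0 is mapped to 1e-9, the smallest penalty the
coordinate-descent solver accepts; the resulting fit agrees with the
unpenalized Newton fit to ~1e-4.  The cross-validation criterion is the
partial-likelihood deviance in its V&VH form,
−2·[pl(all samples; β_−k) − pl(training fold; β_−k)], averaged over folds,
with λ chosen at the minimum (lambda.min, per "lowest partial likelihood
deviance"; not the 1-SE rule).  Folds are stratified by event status —
with moderate event counts unstratified folds can land with too few events
to anchor the deviance — and derived deterministically from the seed via
a shuffled stratified K-fold split.

**Cutoff selection.**  The classification threshold is the marker value
maximizing Youden's J = sensitivity + specificity − 1 on a time-dependent
ROC curve, ties broken toward the smallest threshold; a flat curve returns
the smallest threshold with a warning.  The default horizon is the longest
evaluation horizon (5 years in day units), configurable via
`cutoff_horizon`.  Classification is strict: score > cutoff is high-risk,
score = cutoff is low-risk.  The shipped bladder-cancer signature carries
its cutoff (0.538) as a constant of the model rather than re-deriving it,
since the exact ROC variant and horizon behind it are not recoverable.

**Time-dependent ROC.**  The cumulative-case / dynamic-control estimator
with Kaplan–Meier conditioning: with Ŝ the KM estimate and X the marker,

    sens(c, t*) = (1 − Ŝ(t* | X > c)) · P̂(X > c) / (1 − Ŝ(t*))
    spec(c, t*) =       Ŝ(t* | X ≤ c) · P̂(X ≤ c) /       Ŝ(t*)

evaluated at every observed marker value plus ±∞ endpoints, conditional
curves estimated by stratum-wise KM with right-continuous steps (a subject
with an event exactly at t* counts as a case).  This is the estimator of
the classical survivalROC approach, not the incident/dynamic or
IPCW-weighted variants.  Finite-sample KM conditioning can overshoot
[0, 1] slightly; estimates are clipped.  The AUC is a trapezoid integral
taken in descending-threshold order — the curve's natural monotone
traversal — because sorting vertices by false-positive rate lets
floating-point noise in tied FPR values scramble vertically stacked points.
On uncensored data the estimator reduces exactly to the empirical ROC and
its AUC to the Mann–Whitney statistic, which the tests assert at 1e-10.

**Unpenalized Cox fits.**  Newton–Raphson with step-halving on the Breslow
partial likelihood, converged at gradient sup-norm < 1e-8, at most 100
iterations; 95% CIs are exp(β ± 1.96·SE) with SEs from the inverse observed
information.  Breslow tie handling is used throughout (including the
penalized path, which is also Breslow) because it is simple, deterministic
and ties are rare at day resolution.  A coefficient exceeding 50 in
absolute value aborts the fit as monotone-likelihood separation, naming
the covariate.

**Log-rank test.**  The two-group O−E statistic with hypergeometric
variance, 1 df.  On tie-free data it coincides with the Cox score test for
the group indicator (asserted at 1e-8).

**Association statistics.**  Clinical 2×2 tables use the standard
two-sided Fisher exact test (sum of hypergeometric probabilities ≤ that of
the observed table); a zero-margin table is uninformative and returns
p = 1 with a warning.  Continuous associations use Pearson correlation
with the t-distribution p-value.  Group comparisons of per-sample features
(e.g. immune-cell fractions between risk groups) use the two-sided
Wilcoxon rank-sum test — exact when both groups have ≤ 10 observations
and no ties, normal approximation with tie correction otherwise; the test
behind such published comparisons is typically unnamed, and rank-sum is
the field convention for deconvolution fractions, so this is a documented
assumption.  Feature associations are reported as raw (r, p) pairs without
multiplicity adjustment by default, matching common reporting practice; a
`fdr` flag adds Benjamini–Hochberg q-values.

**Tumor mutation burden.**  TMB = qualifying variant count divided by the
interrogated exonic territory, default 38 Mb (the conventional captured
exome; the denominator is configurable since capture sizes vary).  The
default counts all coding classes including synonymous — "somatic
mutations" without qualification — and `NONSYNONYMOUS_CLASSES` is provided
as a preset for the stricter convention.  Samples on the cohort roster
with no variant calls get count 0.

## The synthetic-data generator

`simulate_cohort` emulates exactly the structure the pipeline assumes:

- **Expression**: log-normal per gene — gene locations drawn N(0, 1),
  within-gene log-scale noise `noise_scale` (default 1.0).  This produces
  pair-orientation frequencies spread over (0, 1), like real cohorts.
- **Signal pairs**: `n_signal_pairs` (default 5) pairs drawn gene-disjoint
  among pairs with orientation frequency in [0.3, 0.7], so the implanted
  effects are informative, mutually independent given the design, and
  guaranteed to survive the 20% filter (otherwise recovery experiments
  would be ill-posed).  Effects default to magnitude 0.8 with alternating
  sign.
- **Survival**: exponential baseline hazard h0 = 1e-3 per day (median
  survival ≈ 693 days at zero risk, a realistic bladder-cancer scale),
  times sampled by closed-form inversion from
  h(t|s) = h0·exp(Σ β_p x_{p,s}).  The exponential is the simplest member
  of the proportional-hazards family, and the analysis assumes nothing
  beyond proportional hazards.
- **Censoring**: independent Uniform(0, c_max), with c_max solved by
  Brent root-finding so the expected censoring fraction hits the target
  (default 0.30).
- **Mutations**: per-sample Poisson counts with log-mean linear in the
  standardized true linear predictor; the slope is solved in closed form
  (under a normal linear-predictor approximation) to hit a target
  count–risk correlation, default −0.11 with mean 150 mutations per sample
  (~4/Mb over 38 Mb, a typical exome burden for this tumor type).
  Records are expanded one row per mutation with placeholder genes, a
  fixed coding-class mix, and random positions.
- **Monotone distortions** (`apply_monotone_distortion`): per-sample
  strictly increasing maps — positive affine, log1p, power, or a random
  strictly increasing piecewise map of each sample's observed values —
  used to exercise the rank-invariance guarantee end-to-end.

All generators are deterministic given their seed.

What the generator does **not** emulate: negative-binomial count noise and
library-size artifacts of real RNA-seq, correlated co-expression modules,
non-proportional or time-varying hazards, informative censoring,
covariate-dependent mutation rates, and real mutation spectra.  Passing
tests therefore demonstrate correctness of the statistical machinery under
the model's own assumptions, not robustness to their violation on real
cohorts.

## Evaluation designs used by the tests and acceptance script

Chosen as the package's reference experiment sizes:

- **Recovery**: 20 cohorts of n = 300, 5 true pairs at |β| = 0.8, ~30%
  censoring; candidate sets of 40 pairs formed as the 5 signal pairs plus
  35 gene-disjoint null pairs from the same cohort
  (`make_candidate_profile`), then screen (α = 0.05) + LASSO.  Building
  candidates from every possible gene combination instead would fill the
  candidate set with gene-sharing proxies of the signal pairs and turn the
  experiment into a test of collinearity resolution rather than of
  signal recovery.  Success = ≥ 4/5 true pairs selected with correct signs.
- **Null calibration**: 1000 independent Bernoulli null pairs against an
  n = 200 null-survival cohort for the screen's type-I error; 20 cohorts
  of n = 500 with an independent normal marker for the null AUC.
- **Rank invariance**: 5 cohorts × 4 distortion families × 5 distortion
  seeds, asserting bit-identical profiles, scores and groups.

## The shipped signature

`blca_irgp30.json` holds the 30-pair bladder-cancer signature (30 distinct
genes) with its published coefficients, cutoff 0.538 and λ = 0.03253915.
Coefficients are published to three decimals; the CSF2RB|GZMB coefficient
is given only as "< 0.001" and is stored as 0.0005 — the midpoint of the
reportable interval, kept positive because a LASSO-selected pair has a
nonzero coefficient.  The known clinical contingency tables distributed
with the signature are used as fixed test inputs; two of their published
p-values (age, gender) are not reproducible by a two-sided Fisher exact
test on the published counts (they match a Pearson chi-square without
continuity correction instead), and the corresponding acceptance checks
fail by design rather than silently adopting a different test.

## Known limitations

- Exact reproduction of the original training run (λ = 0.03253915, the 652
  → 104 → 30 pair counts, cohort AUCs) requires the TCGA-BLCA expression
  and follow-up data and the original fold assignment, none of which are
  shipped; the packaged signature is distributed as a fitted artifact.
- The time-dependent ROC variant and horizon behind the shipped cutoff are
  not documented upstream; 0.538 is treated as a model constant.
- The KM-conditioned ROC estimator is not guaranteed monotone under heavy
  censoring; its AUC is the trapezoid integral of the estimated curve.
- `fit_lasso_cox` requires at least as many events as folds and does not
  currently support penalty factors or elastic-net mixing.
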