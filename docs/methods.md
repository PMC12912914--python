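# Methods

This note documents the models, the synthetic data-generating
processes, the numerical choices, and the limits of what the test suite
can establish.

## Synthetic cohorts

### Screening cohort (`astraj.cohorts.generate_screening_cohort`)

One row per community participant: a severity class drawn from the
prevalence vector (normal 96.2%, mild 3.4%, moderate/severe 0.4%), a
score drawn from a class-specific beta law, a PCP-HF risk covariate
weakly correlated with the score, and two outcome processes
(AS hospitalisation, heart failure).

**Score laws.**  Each class's beta parameters are fitted by least
squares to a (q1, median, q3) target with the median residual
up-weighted 4:1.  The targets are the published per-class quartile
triplets 0.52 [0.36, 0.67] (normal), 0.62 [0.47, 0.78] (mild), 0.74
[0.66, 0.85] (moderate/severe).  The first triplet is exactly
beta-attainable (all three quantile residuals < 0.005); the second and
third are slightly skewer than any two-parameter beta allows (best-fit
residuals ≈ 0.009 and 0.015), so `fit_beta_to_quartiles` enforces a
0.005 tolerance by default — raising `ConvergenceError` with the
residuals — while the generator uses the best-effort fit, which keeps
the class medians within 0.008 of their targets.

**Outcomes.**  Exponential event times with annual baseline hazards
0.004 (AS hospitalisation) and 0.010 (HF) for screen-negative subjects;
subjects whose score is at or above the screening threshold (default
0.67) carry hazard ratios 4.05 and 1.52 respectively.  Administrative
censoring at 6.2 years.  Tying the hazard to the *score threshold*
rather than the latent class is deliberate: it is the false-positive vs
true-negative contrast the screening analysis tests.  The baseline
rates were chosen once to produce event counts (tens per arm at
n = 3632) at which the log-hazard-ratio standard error (~0.17) keeps
the configured 4.05 ratio recoverable inside its reference interval
(2.25–7.28).

### Trajectory cohort (`astraj.cohorts.generate_trajectory_cohort`)

Time is years before the procedure, t ∈ [0, 10], with t = 0 the
procedure date (plots read right-to-left).  Each subject gets:

* a latent class with proportions (0.193, 0.236, 0.571) and mean curve
  — **StableLow**: constant 0.475; **AcceleratedProgression**: plateau
  0.58 for t > 2, linear ramp to 0.85 at t = 0; **PersistentlyHigh**:
  linear from 0.78 at t = 10 down to 0.715 at t = 0 (always above
  0.70);
* a visit schedule: visit count = 1 + NegBinom(r = 0.8, mean = 3.8),
  whose quartiles are exactly (2, 3, 6); the last-ECG gap is
  lognormal(median 0.55 y, log-SD 2.5) truncated at 9 y, and earlier
  visits are uniform on [gap, 10].  This matches the targeted
  median/IQR visit summaries; it implies a mean of ~4.7 ECGs per
  subject (~9,900 observations at n = 2040, slightly above a cohort
  with a lighter-tailed visit law);
* scores = class curve + subject intercept (SD 0.04) + observation
  noise (SD 0.05), clipped to [0, 1].  Published sources report no
  within-class variance, so these defaults were chosen once for
  plausible cluster overlap and are exposed as config fields;
* survival: exponential with class hazard ratios (1, 1.28, 1.43) and a
  lognormal frailty (log-hazard coefficient 0.35) shared with the
  surgical risk scores (so STS/EuroSCORE II are genuinely prognostic,
  C ≈ 0.55–0.6); uniform administrative censoring on (0, 4.2 y); the
  baseline hazard is solved (Brent root-finding over the closed-form
  class/frailty mixture) so the expected event fraction is 23%,
  giving a median follow-up near 2.1 y;
* covariates: lognormal STS (median 4.2%) and EuroSCORE II
  (class-dependent medians 5.3/6.3/6.2%), valve size ∈ {23, 26, 29},
  Agatston ≈ N(2460, 1320) truncated at 0, valve type
  (34.5% self-expanding), lognormal BMI (median 27.8), pacemaker rates
  (10.7/16.4/17.3%) by class.

**What the generator does not emulate:** real ECG waveforms or model
features, informative visit timing (sicker patients being measured more
often), non-proportional hazards, competing risks, and measurement
drift across ECG hardware.  Tests passing on these cohorts demonstrate
that the estimators recover known structure under the stated model;
they cannot certify behaviour under real-data violations of it.

## Screening metrics

AUROC is the rank-based (Mann–Whitney) statistic with ties counted
half, CI by case/control-stratified bootstrap (2000 resamples,
percentile).  The Youden cutpoint scans the observed score values with
the rule `score ≥ c → positive`, ties in J broken toward the larger
cutpoint (fewer positives).  Proportion CIs are Wilson score intervals.
Mild AS is a non-case: the detection task is moderate/severe disease.

The prevalence projection is the exact closed form.  Sensitivity and
specificity are accepted on the closed interval [0, 1] (a perfect test
is a legitimate operating point; degenerate 0/0 corners raise), while
prevalence must be interior.  **Operating-point discrepancy:** the
published projection table's footnote states "specificity 74.6%" next
to "accuracy 76.4%", yet every printed PPV/NPV/screen-rate value in
that table is consistent only with specificity 76.4%.  The projection
API takes specificity as an explicit argument; reproduction uses 0.764.

False-positive prognosis fits Cox models (FP indicator ± PCP-HF) on
the non-case subset; all non-moderate/severe subjects are included
(prevalent mild AS is not excluded).

## Trajectory clustering

**Centroids** are penalized cubic B-splines on the fixed domain
[0, 10]: basis dimension 8 (uniform interior knots), second-order
difference penalty, smoothing parameter chosen by GCV over a 31-point
log-spaced grid, with a tiny ridge (1e-10) for identifiability when a
cluster's data do not span the domain.  In one dimension this is the
same class of smoother as a low-rank thin-plate regression spline.
Clusters with fewer than four distinct time points fall back to a line
or constant (with a warning).  Effective degrees of freedom are the
hat-matrix trace.

**EM.**  From a seeded uniform random partition, alternate the spline
M-step and the nearest-centroid E-step (subject-level MSE distance,
ties to the lowest index) until the assignment vector repeats, the
relative objective change is below 1e-6, or 50 iterations.  The
objective is the pooled within-cluster MSE.  Two safeguards keep the
recorded objective non-increasing: (i) a refitted centroid is kept only
if it does not raise its cluster's residual sum on the current members
(the penalized fit optimizes a smoothed criterion, not raw RSS);
(ii) an emptied cluster is re-seeded with the globally worst-fit
subject — never a cluster's sole member — and its centroid refitted to
that subject before the objective is recorded.  Membership is hard
throughout; there is no probabilistic E-step.

**Model-count diagnostics.**  BIC uses the Gaussian working likelihood
`N·ln(RSS/N) + p_eff·ln(N)` with `p_eff` = (sum of centroid edf) + k
variance terms.  Silhouette is centroid-based:
`s = (b − a)/max(a, b)` with a the distance to the own centroid and b
the minimum distance to any other.  `select_k` picks the k maximizing
mean silhouette and reports BIC, flagging disagreement.  Silhouette has
precedence because the pooled-observation BIC is structurally biased
upward in k for this model class: hard assignment lets each subject
choose the closer of two split centroids, and subject-level intercepts
plus heterogeneous visit windows give real within-class residual
structure, so RSS keeps falling faster than the `ln N` penalty — in
simulation BIC selects k ≥ 4 even on well-separated, zero-intercept
three-class data, while silhouette recovers k = 3 reliably there.

At the *default* overlap (noise 0.05, intercept 0.04) the two elevated
phenotypes overlap enough that even silhouette can favour merging them
into k = 2.  The pipeline therefore treats the phenotype count as a
design constant (k = 3) and reports the k-scan as a diagnostic.  For
the same reason there is a ceiling on agreement with the latent truth:
assigning subjects by the *true* generating curves yields ARI ≈ 0.75 on
the default cohort (the exact Bayes rule with intercept covariance and
class priors reaches 0.80), so the fitted EM's ARI ≈ 0.75 is the
nearest-centroid optimum, not an optimization failure; recovered class
proportions and hazard ratios are unbiased.

Stability is summarized as pairwise ARI across random restarts plus ARI
between the reference fit and refits on subject-level bootstrap
resamples (restricted to shared subjects).  Single-observation subjects
are clustered (their distance is one squared residual); a `min_obs`
filter supports ≥3-ECG sensitivity analyses.

**Semantic labels** for k = 3: lowest mean centroid level → StableLow;
of the rest, the larger rise over the final two years
(centroid(0) − centroid(2)) → AcceleratedProgression; the other →
PersistentlyHigh.  Ties warn and break by index.

## Survival and reclassification

The Cox ladder (lifelines, Efron ties) uses StableLow as reference:
Model 1 unadjusted; Model 2 + STS score, valve size, Agatston score,
device type; Model 3 + BMI and pacemaker.  Harrell's C counts
concordant comparable pairs (earlier event vs later event or longer
survivor; risk ties half).  Absolute risk at a horizon is
`1 − S0(t)^exp(lp)` with the Breslow baseline; horizons beyond follow-up
warn and extrapolate flatly.

**Categorical NRI** bins both models' predicted mortality at
(<5, 5–7.5, 7.5–10, >10)% and computes
`NRI_events = P(up|event) − P(down|event)` and
`NRI_non-events = P(down|non-event) − P(up|non-event)`.  Censoring
before the horizon is handled by Kaplan–Meier estimation of the event
probability within the up-/down-/un-moved groups, which reduces exactly
to plain counting under full follow-up; a `complete_case` option drops
subjects censored early.  Confidence intervals are subject-level
bootstrap percentiles (default 1000 resamples; the analysis driver uses
300).

**Probability scale.**  Two modes convert a surgical risk score to
binned probabilities.  `refit` re-anchors the score via a univariate
Cox fit and the Breslow baseline — well calibrated, but in a cohort
with ~30% three-year mortality every calibrated prediction exceeds the
10% top bin and the categorical NRI is structurally zero.
`face_value` (the pipeline default) keeps the score's own percentage
scale — the scale the bins were designed for, which systematically
underestimates this population's mortality exactly as the calibration
table shows — and derives the augmented model by tilting the base
survival probability with the mean-centered cluster component of a Cox
fit on score + cluster: `p_aug = 1 − (1 − p_base)^exp(g)`.

## Threshold timing

First crossing = the chronologically earliest (largest years-before)
observation strictly above the threshold — not a sustained-crossing
rule; subjects who never cross stay in the denominator report but out
of the mean; CI is the normal approximation.  Time-point proportions
select each subject's nearest observation within ±0.5 y (ties toward
the more recent) and use contributing subjects as the denominator,
reported with n.

## Pipeline

Stages exchange plain CSV/JSON; every stochastic step derives from one
master seed; `manifest.json` records the config hash (output location
excluded), seeds, package version and artifact checksums, so identical
configs give identical bytes.  CLI exit codes: 0 ok, 2 config error,
3 data error, 4 numerical failure.

## Problem sizes in the test suite

The suite exercises the full default cohort sizes where the check
demands them (screening n = 3632; trajectory n = 2040 with best-of-10
EM restarts) and smaller seeded cohorts elsewhere (n = 100–600 for the
EM contract, null-model and bootstrap checks; n = 250 low-noise cohorts
for cluster-count recovery), keeping the whole suite near one minute
while leaving every estimator's behaviour at the sizes that matter
covered.

## Known limitations

* Hard-assignment EM cannot use class priors or within-subject
  correlation; near the phenotype overlap this costs accuracy that a
  mixed-effects mixture model would partially recover (explicitly out
  of scope).
* The BIC definition is a working-likelihood construction; it is
  tested against its own arithmetic oracle and reported, but not used
  as the deciding model-selection rule (see above).
* The NRI's KM-within-group censoring adjustment assumes censoring is
  independent of the reclassification group.
* The quartile-fit tolerance (0.005) is unattainable for two of the
  three published score triplets under any two-parameter beta; the
  generator documents and accepts the best fit.
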