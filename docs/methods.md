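# Methods

This note records the statistical model implemented by `aptemporal`, the
generative observer model used for simulation, the default parameter choices
and their rationale, the numerical decisions, and the known limitations.

## Stimulus protocols

**Pitch-naming protocols.** The 52-trial sine-tone test presents 13 notes
(MIDI 54–66) four times each under a *full-cycle* ordering constraint:
between any two presentations of the same note, every other note appears at
least once. Concatenating four independent permutations does not satisfy
this invariant (the seam between blocks can repeat a note too early), so the
sequence is built by sequential sampling: at each position a note is drawn
uniformly from those currently eligible (not yet exhausted and not presented
since fewer than 12 distinct others), restarting on dead ends. The 72-trial
piano-tone test presents 36 notes (MIDI 48–83) twice each with every pair of
consecutive notes more than an octave apart. Greedy sampling dead-ends
almost surely here, so the sequence is found by randomized depth-first
search with backtracking, expanding the most-constrained candidate first
(fewest remaining octave-compatible partners, random tie-break) under a node
budget with restarts. Generation is deterministic given the seed; an
infeasible configuration raises an explicit error rather than silently
relaxing a constraint.

**Gaps-in-noise (GIN) tracks.** Two track layouts (35 and 29 six-second
segments) each carry 60 silent gaps — six per duration in
{2, 3, 4, 5, 6, 8, 10, 12, 15, 20} ms — assigned 0–3 per segment and placed
uniformly at random subject to ≥ 300 ms margins from segment edges and
≥ 500 ms separation between gaps, by rejection sampling.

**Backward-masking (BMT) sessions.** Eight inter-stimulus intervals
{0, 10, 20, 30, 50, 100, 200, 400} ms × 6 repetitions = 48 tone trials,
shuffled together with 12 catch trials (60 total).

## Scoring

Pitch responses are scored on the chroma circle: the distance between two
chromas is min(d, 12 − d) ∈ [0, 6] semitones. CRR is the percentage of
trials with distance 0; MAD is the mean distance. Missing responses count as
maximally wrong (distance 6) by default; an alternative policy excludes
them.

Detection thresholds (GDT, BMTT) use a *maintained-performance* rule: the
threshold is the smallest tested level with ≥ 4 of 6 detections such that
every longer (easier) level also meets the criterion. A stricter variant
(`maintained_rate`) additionally requires every easier level to match the
candidate's own hit count. When no level qualifies the threshold is
*censored* and recorded as the token `NA_censored`; censoring propagates
through ear averaging and censored subjects are excluded listwise from any
analysis involving that measure.

## Classification

The chance model treats a naming test as Bernoulli guessing over 12
alternatives; the cutoff is the smallest count exceeding
n·p + z·√(np(1 − p)) with z the normal quantile at the chosen confidence
(99% → z = 2.576). For 52 trials this gives 10 correct = 19.2%. An exact
binomial inversion is available as an alternative method. A participant is
AP when CRR exceeds the cutoff *and* MAD < 1.00 semitones; participants
scoring below 50% on a training screening are assigned Non-AP outright. For
the piano-tone test a verbatim 20% cutoff can override the computed one.

## Observer model

**Pitch naming.** The named chroma is the true chroma plus a rounded
Gaussian error (precision σ, in semitones), wrapped to the chroma circle;
with probability λ the response is instead a uniform guess. σ → 0, λ = 0
gives a perfect namer; λ = 1 gives chance performance (E[CRR] = 100/12 %,
E[MAD] = 3).

**Detection.** Gap and tone detection follow a guess/lapse logistic
psychometric function p(x) = γ + (1 − γ − δ) / (1 + exp(−(x − x50)/s)) of
gap duration (GIN) or inter-stimulus interval (BMT). False alarms are
Poisson per noise segment (GIN) or Bernoulli per catch trial (BMT).

**Coupling.** Each subject draws a latent temporal-precision factor z;
pitch σ and detection midpoint x50 load on z with correlation ρ, so ρ > 0
produces genuine within-group correlations between naming accuracy and
temporal acuity, and ρ = 0 gives null cohorts.

**Default cohorts.** Experiment 1: 9 AP subjects (σ ≈ 0.30 ± 0.15,
λ ≈ 0.04 ± 0.03, GIN x50 ≈ 4.5 ± 1.0 ms, ρ = 0.85) and 10 Non-AP subjects
(σ ≈ 1.5 ± 0.4, λ ≈ 0.30 ± 0.10, ρ = 0). Experiment 2: 8 AP
(BMT x50 ≈ 25 ± 8 ms) and 7 Non-AP (x50 ≈ 32 ± 8 ms). Covariates (onset age
of musical training, years of training, age) are drawn at the group means
and SDs of the modeled study population. ρ = 0.85 was calibrated — before
any acceptance testing — so that score-level within-AP correlations land in
the ~0.4–0.7 range typical of such studies; group-level GIN parameters are
identical across groups (no mean temporal-acuity difference), while BMT
midpoints differ.

## Statistical toolbox

All inference is written from first principles on numpy/scipy primitives:

- **Group comparison:** pooled-variance Student *t* with df = n₁ + n₂ − 2;
  effect size Hedges g = J·|t|·√(1/n₁ + 1/n₂) with small-sample correction
  J = 1 − 3/(4(n₁ + n₂) − 9).
- **Multiplicity:** Benjamini–Hochberg step-up adjusted p-values, applied
  within each analysis family (the pair of group tests, the four
  correlations, the focal-predictor p-values of each regression family).
- **BCa bootstrap.** Case resampling (rows of the data, or independent
  resampling of the two groups for two-sample statistics), B = 2000 by
  default. The bias correction z₀ is the normal quantile of the fraction of
  replicates below the point estimate, counting ties half, clipped to
  [1/(B+1), B/(B+1)]; the acceleration a is the jackknife skewness. A
  statistic may return NaN on a degenerate resample (e.g. a correlation when
  a resample has zero variance); non-finite replicates are dropped with a
  warning and an error is raised if more than half are lost. Endpoints are
  read from the replicate distribution with `numpy.quantile`.
- **Bootstrap p-values** invert the BCa interval: p is the smallest α at
  which the (1 − α) interval excludes the null, found by bisection
  (tolerance 10⁻⁴) over one fixed replicate set with fixed z₀ and a. The
  achievable minimum is 2/B; hitting the floor emits a warning.
- **Robust regression.** Tukey bisquare IRLS (c = 4.685) with the scale
  fixed at MAD(OLS residuals)/0.6745. Convergence uses a relative step
  criterion, max|Δb| / (1 + max|b|) < 10⁻⁶ (an absolute criterion stalls
  when coefficients are large and the redescending ψ takes non-contracting
  micro-steps). Reported are a weighted robust R² (computed with the final
  IRLS weights), adjusted R², Cohen's f² = R²/(1 − R²), and per-coefficient
  inference from the asymptotic M-estimator covariance
  κ²·s²·(Σψ²/(n − p))/(mean ψ′)²·(XᵀX)⁻¹ with the standard small-sample
  correction κ = 1 + p·var(ψ′)/(n·mean(ψ′)²), using t(n − p) reference
  distributions. Standardized slopes are b·sd(x)/sd(y).

## Analysis pipelines

Experiment 1 reports (a) group *t*-tests on GDP and GDT with g, a BCa CI of
the mean difference, and BH over the pair; (b) within-AP Pearson
correlations for {GDP, GDT} × {CRR, MAD} with BCa CIs, CI-inversion
p-values, and BH over the four; (c) four robust simple regressions (each
temporal measure predicting each pitch measure) and four models adding onset
age as a covariate, with BH across each family's focal-predictor p-values.
Experiment 2 runs the analogous group tests on BMTP/BMTT and pools both
groups (n = 15) for the correlations; regressions are skipped when no
correlation survives BH (overridable in the config). A measure that is
constant in the sample yields an undefined correlation, reported with
conservative p = 1. Censored scores exclude the subject from the affected
pairs only.

## Numerical choices

- All generators and analyses are deterministic functions of integer seeds;
  internal sub-seeds are drawn below 2³¹ from a parent PCG64 stream.
- Thresholds and counts are exact integer logic (verified against
  brute-force enumeration); no floating-point comparisons enter the
  maintained-performance rule.
- Bootstrap replicates for a given (statistic, data, B, seed) are computed
  once and reused for both the CI and the inverted p-value, which makes
  p < α exactly equivalent to the (1 − α) CI excluding the null.

## Limitations

- The observer model is stationary: no learning, fatigue, or attention
  drift across trials, and responses are conditionally independent given the
  subject parameters. Real response-time structure is not modeled.
- Because inlier subjects' scores are driven almost deterministically by
  the shared latent factor, robust regressions on simulated cohorts can
  down-weight one or two lapse-driven outliers and report weighted robust R²
  values (≈ 0.9+) well above both the Pearson R² of the same data and values
  typical of empirical cohorts. The weighted robust R² describes fit
  quality among retained observations, not total variance explained.
- BCa intervals at n = 9 are approximately calibrated: per-interval
  containment of a true null is at the nominal 95%, but simultaneous
  containment across the four (dependent) correlation intervals runs near
  89–90%, so a family of nominal intervals should not be read as a joint
  95% statement.
- GDT/BMTT live on a coarse grid; with small groups a measure can be
  constant in a sample, in which case its correlations are undefined and are
  reported as such rather than imputed.
- Censored thresholds are excluded listwise, which biases group summaries
  optimistic when censoring is informative (poorest performers censor
  first). Censoring rates are reported alongside scores.
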