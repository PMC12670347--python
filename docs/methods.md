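# Methods

This note records the models the package implements, the assumptions behind
them, the defaults and why they were chosen, and what the synthetic-data
validation does and does not demonstrate.

## Estimands and identification

For each therapy (IMV, vasopressors) treated as a point exposure assigned in
the first 24 h of the ICU stay, the target quantity is the average treatment
effect ψ = E[Y(1)] − E[Y(0)] — a risk difference for in-hospital mortality,
a difference in days for 28 hospital-free days — and, separately, the
counterfactual mean E[Y(0)] ("baseline" outcome with the therapy withheld).
Identification rests on the usual trio: conditional exchangeability given
the measured covariates, positivity within every analysis stratum (checked
empirically by exhaustive cross-tabulation), and consistency/no-interference.
None of these are testable on real data; the negative-control outcome
(odd/even event hour) probes for gross violations.

### Immortal-time handling

Treatment arms are decided by a fixed eligibility window: A = 1 iff
initiation occurs at hour ≤ 24 from ICU admission (boundary inclusive — the
protocol wording "within the first 24 h" does not fix the boundary, and an
initiation recorded at exactly 24.0 h is an in-window clinical decision).
Later initiators remain in the control arm and no row is dropped, so treated
stays are not conditioned on surviving to treatment.

### Outcome definitions

- `Y_mortality` = in-hospital death OR discharge to hospice (hospice
  discharge is a terminal disposition and excluding it would differentially
  censor the sickest stays).
- `Y_hfd` = 0 on death, else max(0, 28 − ceil(LOS days)) — the prevailing
  clinical-trials convention for "days alive and out of hospital"; the cap
  and the death-imputation-to-zero are part of the estimand.
- `Y_parity` = 1 iff the death/discharge hour-of-day is even. No plausible
  mechanism lets a first-day therapy move event-hour parity, so any
  confident non-null estimate indicates residual bias in the pipeline.

### Cancer categorization

Diagnosis codes are mapped through a configurable two-column table to
{solid, hematological, metastasized} and reduced by the total order
metastasized ≻ hematological ≻ solid, so a stay carrying several cancer
codes lands in its prognostically dominant category. Unmapped codes are
ignored with a debug log line. The packaged table is a toy stand-in for an
expert ICD-10 grouping, sufficient because the categorizer's logic — not a
real dictionary — is what is under test.

### Severity stratification

The integer severity score (an OASIS/APACHE-style acuity index) is mapped to
a predicted mortality probability PMP = expit(a + b·score). The calibration
(a, b) must be supplied explicitly — published score calibrations vary by
database and era, and a silent default would silently reshuffle strata.
Strata are empirical tertiles (low/moderate/high) or half-open probability
bands [e_i, e_{i+1}); a full-range "0%–100%" stratum is always reported.

## Nuisance estimation: stacking ensemble

All nuisance regressions (outcome regressions and propensities) use k-fold
cross-validated stacking over a five-member library: constant mean,
unpenalized GLM, lasso-penalized GLM with internal CV for the penalty,
random forest (500 trees, min leaf 5), and an additive MARS implementation
(forward hinge selection to 15 terms, GCV backward pruning, per-term
complexity charge 2). Weights are the simplex minimizer of out-of-fold risk
(squared error, or binomial negative log-likelihood for binary outcomes),
found by SLSQP from the uniform start followed by a vertex sweep, so the
ensemble's CV risk is never worse than the best single member's. Folds are
stratified by outcome for binomial loss to avoid empty-class folds in small
strata. A library member that fails to fit is dropped with weight 0 and a
logged warning rather than aborting the analysis.

The outcome-regression design is [X, A, A·X]: appending
treatment-by-covariate products lets the linear members express effect
modification (the generator's treatment × severity interaction) without
relying solely on the tree/spline members.

For bounded-continuous outcomes the binomial library is inapplicable;
squared-error loss is used and predictions are clipped into (0, 1) before
the logit-scale targeting step.

## TMLE

One-step TMLE with a single fluctuation coefficient ε on the combined clever
covariate H(A, X) = A/ĝ(X) − (1 − A)/(1 − ĝ(X)) (single-arm H for
counterfactual means), fit by Newton's method on the offset-logit
(quasi-)binomial likelihood to |score|/n < 1e−12, which leaves the efficient
influence curve's score equation solved to machine precision. Propensities
are truncated to (0.025, 0.975) by default — the conventional guard against
practical positivity violations, configurable. Initial outcome predictions
are clipped to [1e−4, 1 − 1e−4] so the offset logit is finite. Inference is
Wald: SE = sd(IC)/√n, CI = estimate ± 1.96·SE; no bootstrap. Nuisances are
fit on the full analysis sample (no outer cross-fitting), matching common
applied practice for this estimator; the donsker-class caveat that motivates
cross-fitting is immaterial for the mostly-linear ensembles the validation
uses. Hospital-free days are scaled to [0, 1], targeted on the logit scale
(the standard bounded-outcome device), and back-transformed to days.

Stratified reporting runs one TMLE per treatment × cancer category
(including "any" and "all") × PMP stratum (including full-range). A stratum
whose positivity tabulation shows an empty arm is emitted as a skip record
with the reason; estimation errors likewise become skip records, never
silent omissions.

## Allocation-disparity odds ratios

The propensity booster uses depth-3 trees, learning rate 0.3, 60 rounds,
subsample 0.9 — small enough to be stable on 20% training shares, recorded
in the run manifest. Attributions are exact tree-path TreeSHAP values on the
log-odds margin. The category OR exponentiates the difference in mean
attribution between category members and non-members; with no other
features and a logistic truth this estimates the same log-odds gap as a
logistic regression coefficient.

The resampling procedure shuffles rows into 5 folds per iteration, trains on
each fold (a 20% share) and attributes on the complement; `invert_split`
provides the conventional train-on-80% reading. Fold ORs are averaged on the
log scale (the coherent average for ratios) into an iteration OR; the point
estimate is the median over 100 iterations. The 95% interval is taken over
the *fold-level* ORs, before the within-iteration averaging: averaging the
five subsample-trained fold estimates first collapses the very sampling
variability the interval is supposed to reflect (measured null coverage
collapses to ~20%), whereas the fold-level percentiles restore valid,
slightly conservative null coverage. This reading of the procedure is an
implementation choice and is flagged as such.

## Synthetic cohort and oracle

The generator emulates the statistical structure the analysis assumes, not
any real database. Defaults (chosen once, as a package design decision):
~10.5% cancer prevalence split 4/2.5/4% solid/hematological/metastasized;
severity ~ rounded Gamma(4, 6) (mean 24, SD 12 — an OASIS-like range); age
~ N(66, 14) clipped to [18, 95]; lab/vital covariates from simple lognormal
and normal families; logistic propensities with severity as the dominant
driver (log-odds ≈ 0.9 per severity SD) and modest negative cancer effects;
a logistic composite-mortality model with severity (1.1 per SD), cancer
(0.3/0.6/0.9), treatment main effects (0.25 IMV, 0.20 vasopressors) and
treatment × severity interactions (0.25, 0.15); LOS = 1 + lognormal (median
≈ 5 days, so every clean row passes the ≥ 1 day filter and exclusion counts
are pure functions of the contamination fractions); 12% of composite-
positive stays exit as hospice discharges. These coefficients produce ~16%
baseline mortality, a true overall IMV ATE of ≈ +4.3 points, and a naive
treated-minus-control mortality gap of ≈ +19 points — i.e. a designed
confounding bias of ≈ 0.15, far above the ±0.01 recovery tolerance, so
deconfounding failures cannot hide.

The outcome model acts on the *effective* exposure (ever treated AND started
within 24 h); late starts occur among ever-treated stays (12% for IMV) and
land in the control arm exactly as the eligibility rule dictates, so the
generator's structural effect coincides with the analysis estimand.

`compute_truth` is a brute-force oracle: it redraws covariates and cancer,
forces each treatment on/off, and averages the *exact* conditional death
probabilities (Rao-Blackwellized over outcome noise; hospital-free days are
simulated with common random numbers across arms). Monte-Carlo SEs are
reported per stratum. Event-hour parity is drawn independently of
everything; an adversarial switch instead wires parity to the first
treatment's arm to verify the negative control can fail loudly.

What the generator does **not** emulate: longitudinal chart/lab series (24 h
aggregates are drawn directly; the aggregation operator is unit-tested on
explicit time-stamped values), code-status dynamics, inter-hospital
practice variation, informative missingness, and any realistic covariate
correlation structure. Passing tests therefore demonstrate estimator
correctness under the stated structural model — not robustness to the full
messiness of credentialed ICU databases.

## Numerical and validation choices

- Simulation sizes: TMLE recovery uses 100 seeds at n = 20,000 (the
  seed-averaged estimate must sit within ±0.01 of oracle truth); CI
  coverage uses 200 replicates at n = 2,000 (nominal 95%, accepted range
  92–98%); negative-control coverage uses 100 seeds at n = 10,000
  (accepted ≥ 90); disparity calibration uses n = 10,000 with 100
  iterations against a true conditional OR of 2.0 (accepted point estimate
  1.7–2.3) and 10 null experiments at n = 4,000 (≥ 9 intervals must contain
  1.0). Repeated-fit studies use the {mean, GLM} sub-library — the
  generator's propensities and outcomes are logistic, so the GLM member is
  well-specified and the thousands of refits stay cheap; the full
  five-member library is exercised in the unit suite at smaller n.
- Quantile convention: linear interpolation (type 7) everywhere, including
  the summary table's medians and IQRs.
- Percentages print to one decimal.
- Missing covariates: median imputation plus a per-variable missingness
  indicator appended to X (keeps N intact and passes the signal to the
  learners).
- Inclusion filters run in a fixed order (age, sepsis, first stay,
  discharge location, LOS) so the exclusion log is deterministic; a record
  failing several criteria is counted under the earliest.
- Degenerate inputs: all-equal PMP collapses tertiles to one stratum with a
  warning; a single-arm stratum raises an explicit positivity error (or a
  skip record in stratified runs); negative start hours and out-of-range
  outcomes raise record-level errors naming the offending rows.

## Known limitations

- The TreeSHAP OR is exactly calibrated only when the category indicator is
  independent of the other features; correlated confounders shift
  attributions between columns, so the OR should be read as an
  adjusted-association summary, not a causal effect.
- The one-step single-ε fluctuation targets the ATE; collaborative or
  iterative targeting variants are out of scope.
- Treatments are point exposures by design; time-varying treatment-
  confounder feedback requires longitudinal TMLE, which this package does
  not implement.
- Influence-curve CIs are asymptotic; at stratum sizes near the n ≥ 50
  floor they can undercover.
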