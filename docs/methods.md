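# Methods

`mscox` estimates the effect of *aggressive* antihypertensive therapy
(≥ `t` concurrent drugs, primary `t = 3`) versus *conventional* therapy
(≤ `t − 1` drugs) on the hazard of a serious cardiovascular event, in a
longitudinal cohort where systolic blood pressure (SBP) is a
time-dependent confounder: uncontrolled SBP raises both the chance of
stepping up therapy and the event hazard, while therapy in turn lowers
SBP.  Standard covariate adjustment fails here — conditioning on
post-treatment SBP blocks part of the effect, not conditioning leaves
confounding — so the package implements the g-method solution: a
marginal structural Cox model (MSCM) estimated by inverse probability of
treatment and censoring weighting, alongside the standard (unweighted)
time-dependent Cox comparator whose bias the MSCM is designed to remove.

## Data model

Follow-up is a discrete grid of up to 14 nominally equal visit intervals
(`k = 0..13`).  Interval `k` spans `(visit k, visit k+1]`; the event flag
stored on a visit record refers to the interval that visit *opens*, so
events are attributed to the exposure and confounder state measured at
the start of their interval.  SBP is coded into three control categories,
left-closed/right-open: tight `< 120` mm Hg, usual `[120, 140)`,
uncontrolled `≥ 140`.  Missed visits are imputed by last observation
carried forward (LOCF) up to the last attended visit; nothing is
extrapolated past it (a subject who stops attending is censored at the
last visit).  Exposure is recoded to be monotone — once a subject's drug
count first reaches the threshold they are treated as exposed until the
end of follow-up, an intention-to-treat view of treatment initiation; the
fraction of person-periods recoded is reported as a diagnostic.  A
subject's person-periods end at the first event, at dropout, or at the
administrative end of the study; person-time after a first event is
discarded.  The lagged SBP category at `k = 0` is defined as the baseline
category, so the lag term exists at every row.

## Weights

All weight models are pooled logistic regressions on the person-period
table.

**Treatment (IPTW).**  Among subjects still unexposed at the previous
visit, the probability of initiating at visit `k` is modelled twice: the
*numerator* conditions on the full baseline covariate vector (age, sex,
race/ethnicity, randomized strategy, eight comorbidity flags, baseline
SBP category) plus per-visit indicators; the *denominator* adds the SBP
category at visits `k` and `k−1`.  The stabilized weight is the running
product over a subject's visits of the ratio of numerator to denominator
probabilities of the treatment state actually observed — the probability
of remaining unexposed before initiation, of initiating at the initiation
visit — and is frozen from initiation onward (under monotone exposure the
probability of continuing is one).

**Censoring (IPCW).**  Dropout at the end of interval `k` is modelled the
same way; both models additionally condition on current exposure, and the
denominator adds the time-dependent SBP terms.  Every interval
contributes the ratio of the probabilities of *remaining uncensored*;
event intervals count as uncensored, and the administrative study end is
not treated as dropout.  The analysis weight is `sw_treat × sw_cens`.

Numerical safeguards: fitted probabilities are clipped to
`[1e−6, 1 − 1e−6]` before ratios (clip counts logged; with clipping
disabled, a fitted probability at machine 0/1 raises a positivity error
naming the row); visit strata with no initiations (or no dropouts) are
merged into the nearest earlier stratum before building the per-visit
indicator basis, which otherwise separates; optional percentile
winsorization of the combined weight is available but off by default.
Under correct specification the stabilized weights average ≈ 1 at every
visit — checked continuously in the test suite.

## Outcome models

The MSCM is approximated by a weighted pooled logistic regression of the
interval event indicator on current exposure, the baseline covariates,
and a saturated visit-indicator baseline (14 intervals make smoothing
unnecessary).  With per-interval event probabilities well below 2% the
exponentiated exposure coefficient is a hazard ratio.  The standard
comparator is the identical regression without weights — covariates,
including SBP, fixed at baseline; exposure time-varying.  An alternative
comparator that adds the current SBP category (adjusting away part of the
mediated effect) is available behind a flag.

Fitting uses Newton-Raphson for unweighted models and iteratively
reweighted least squares (warm-started at the unweighted solution,
relative tolerance 1e−8, max 100 iterations) for weighted ones.

**Variance.**  Default confidence intervals use the cluster-robust
(by subject) sandwich, treating the estimated weights as fixed — the
conventional, conservative choice for weighted pooled-logistic marginal
structural models.  The implementation's sandwich was cross-checked
against an independence-working-correlation GEE fit of the same weighted
model (agreement to the fourth decimal; a unit test keeps it that way).
The alternative is a subject-level nonparametric bootstrap (minimum 50
replicates) that re-estimates all four weight models inside every
replicate, so weight-estimation uncertainty is included; replicate
failures are skipped, counted, and abort the run above 10%.

**Partial-likelihood cross-check.**  A time-varying-covariate Cox model
(lifelines, Efron ties) fitted on the same counting-process intervals
validates the discrete-time approximation: in the rare-event regime
(< 1% per interval) the two log hazard ratios agree within 0.002 in the
shipped experiments, an order of magnitude inside the 0.02 bound asserted
by the validation suite.  This fit uses a reduced covariate set (age,
sex, baseline SBP category) in *both* routes so the comparison is exact
and affordable.

## Synthetic cohorts

Because the motivating trial's individual-level data are not public, the
package ships a generator that emulates the data structure rather than
any real records.  Per subject: baseline covariates drawn to match the
published enrollment marginals (age truncated-normal 66.1 (9.8), ≥ 50
years; 52.1% women; race/ethnicity 48.4/13.4/35.6/2.6; strategy 49.9%;
the eight comorbidity prevalences; baseline SBP normal 149.5 (19.7)
mm Hg).  Untreated SBP then follows an AR(1) pull toward a setpoint
(default 148 mm Hg, autoregression 0.7, innovation SD 8); treatment
subtracts a constant level shift (default 7 mm Hg) from the visit after
initiation onward.  The level-shift form is deliberate: the full mediated
effect is reached within one visit, so the counterfactual hazard depends
on treatment only through the *current* state and the binary
current-exposure marginal model is correctly specified up to the single
initiation interval — parameter-recovery tests are then clean, and
residual recovery error genuinely shrinks with n.  Initiation, the event,
and dropout are Bernoulli draws per interval on the logit scale, each
driven by the current SBP category (usual control as reference), with
the event model also carrying age and prior-MI terms and a direct
treatment effect, and the dropout model a treatment term.  Events take
precedence over dropout within an interval; either terminates the
series.  Dropout is only drawn at attended, non-terminal visits.  Missed
visits (5% by default, independent of SBP so LOCF is benign) are emitted
as absent rows, except that an event after a missed visit is still
recorded, carrying the last observed SBP with `observed = 0`.

Drug counts: conventional subjects take 1 or 2 drugs (fixed at
baseline); at initiation the aggressive count resolves to 3 or 4, the
fourth drug more likely when SBP is uncontrolled at that visit.  The
threshold-3 exposure therefore coincides exactly with the initiation
indicator, while thresholds 2 and 4 define progressively different — and
at 4, more strongly confounded — contrasts, which is what makes the
threshold sensitivity analysis informative (the gap between naive and
weighted estimates grows with the threshold).

All randomness is pre-drawn in a fixed order from one seeded generator:
a `(config, seed)` pair reproduces a cohort bit for bit, and
counterfactual regimes consume identical random numbers.

**Truth oracle.**  The true marginal hazard ratio — the
treat-everyone-from-baseline versus treat-no-one contrast — is computed
by simulating the same subjects under both forced regimes with dropout
and missed visits disabled (common random numbers across arms, which
removes most Monte Carlo variance; under a null configuration the two
arms are *identical* and the oracle equals 1 exactly), then fitting an
unconfounded discrete-time model of event counts on regime and visit.
The oracle requires at least 10,000 subjects and defaults to 500,000;
the scenario library freezes oracles computed at 200,000 (Monte Carlo SE
of the log hazard ratio ≈ 0.01 there), with the generating seed recorded
so the frozen values are exactly reproducible.

**Scenario library.**  `invest_like` (confounded step-up therapy,
protective total effect with oracle HR 0.8024, informative dropout,
cumulative event incidence ≈ 10%); `null_confounded` (no treatment
effect anywhere, initiation and dropout strongly SBP-driven — the
setting in which the naive estimator is biased away from the null by
≈ +0.21 on the log scale at the shipped strength); `no_confounding`
(initiation and dropout independent of SBP, effects present — the two
estimators coincide); `mediation_only` (no direct effect).  The
null-scenario confounding strength was placed so that, at the 2,000-
subject replicate size used in the validation suite, the naive bias is
comfortably detectable while the weighted estimator's weights remain
stable enough for near-nominal coverage; the invest-like scenario was
calibrated to a ≈ 0.80 true hazard ratio and ≈ 10% incidence.

## Validation experiment sizes

The shipped experiments use: 200 replicates of n = 2,000 (null
coverage), 10 cohorts of n = 50,000 plus a 200,000-subject oracle
(recovery), 100 replicates of n = 10,000 (bias direction), and single
cohorts of n = 20,000–50,000 for the weight-mean, equivalence, and
Cox-cross-check properties.  These sizes keep each experiment's Monte
Carlo error an order of magnitude below the property bounds it asserts.

## Known limitations

* The generator and estimators share the package's category-based SBP
  coding; a flag for continuous-SBP hazards exists for misspecification
  experiments, but the shipped recovery results hold under correct
  specification and say nothing about robustness to coding choices on
  real data.
* The MSCM residual recovery error (median |log HR error| ≈ 0.03–0.04
  at n = 50,000) is dominated by the initiation-visit interval, whose
  person-time carries no mediated effect yet, plus mild LOCF exposure
  misclassification — both attenuate toward the null, mirroring the
  direction such imperfections take in real cohorts.
* Robust CIs treat weights as fixed (conservative); the bootstrap
  alternative is exact but ~B times the cost.
* Single time-dependent confounder by design; multi-confounder
  generation (diastolic pressure, heart rate) is out of scope.
* Unstabilized weights are available only as a diagnostic, not an
  estimation path.
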