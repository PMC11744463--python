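# Methods

This package implements a two-part economic evaluation of laparoscopic
cholecystectomy (LC) versus conservative management (CM) for uncomplicated
symptomatic gallstones: a within-trial cost-utility analysis over 24 months of
follow-up, and a Markov cohort model extrapolating to a 10-year horizon. A
seeded synthetic-data generator emulates the statistical structure of the
underlying randomized trial so that every stage of the pipeline can be tested
for parameter recovery without access to participant-level data.

## Synthetic trial generator

The generator draws two arms of `n_per_arm = 217` participants from 20
centres, with age ~ truncated normal(50.5, 13) years, 71% women, and baseline
SF-6D-style utility ~ truncated normal(0.70, 0.12) on the instrument range
[-0.59, 1].

**Surgery.** Each participant undergoes cholecystectomy with probability
0.705 (LC) or 0.295 (CM) by month 24, matching the trial's cumulative uptake.
Months-to-surgery follow a gamma distribution truncated at 24 months
(shape 2, scale 2.5 for LC; shape 2, scale 6 for CM), reflecting the
right-skewed waits of NHS elective practice and the slower conversion of
conservatively managed participants.

**Utility trajectories.** Utilities are measured at months 0, 3, 6, 12, 18
and 24 (the trial's schedule is unpublished; this is a conventional follow-up
grid). The latent mean is piecewise constant: baseline level until surgery, a
post-operative dip of 0.10 for 3 months, then a steady state of baseline +
0.045 (CM) or baseline + 0.055 (LC); the 0.01 arm difference in post-surgery
steady state induces a small QALY difference of the magnitude seen in
pragmatic trials of this comparison. Observed utilities add truncated
Gaussian noise (s.d. 0.08) within the instrument range. The noise truncation
is to the fixed instrument interval, which keeps the closed-form expectation
tractable (see *Truth oracle*).

**Resource use.** Theatre minutes (mean(s.d.) 72(42) LC, 83(49) CM) and
hospital-stay days (0.63(1.3) LC, 1.4(3.4) CM) are drawn for operated
participants from moment-matched gamma distributions — non-negative and
right-skewed, and their configured means enter the truth oracle exactly.
Readmission is Bernoulli (9.7% LC, 12.9% CM). A&E attendances are Poisson
(0.22 LC, 0.47 CM, the trial's observed rates). Primary-care visits are
Poisson with means 3 (LC) and 4 (CM) — unpublished, chosen as a plausible
two-year contact rate with heavier primary-care use under conservative
management — shifted to a 1 + Poisson(mean − 1) form so every participant has
at least one contact, which keeps total costs strictly positive (the support
required by the optional gamma cost model). Centre effects enter as one
zero-mean normal draw per centre on the log of hospital durations
(s.d. 0.10), i.e. a multiplicative "efficiency" effect; an additive GBP
offset could produce negative costs and has no column in the participant
schema.

**Missingness.** Post-baseline utility entries are masked MCAR or MAR;
baseline is never masked. Under MAR the per-participant masking probability
is logistic in baseline utility (slope −3 per utility unit) and arm (+0.5
logit for CM), with the intercept solved by root-finding so the expected
marginal rate equals the configured `missing_rate` (default 0.25) exactly.
The trial's visit-level nonresponse pattern is unpublished; the default rate
is an assumption, and it is configurable.

**Truth oracle.** `truth_summary` returns per-arm expected discounted costs
and QALYs implied by the parameters, integrating over baseline utility
(Gauss–Legendre quadrature over its truncated-normal density), surgical
uptake and gamma-truncated timing (pre/dip/post state probabilities per
visit), truncated measurement noise (analytic truncated-normal means), the
centre log-normal duration multiplier (exp(sigma^2/2)), and the same
discounting conventions as the costing layer. It is an analytic computation,
not a simulation, so it serves as an independent recovery target; a test
confirms simulated per-arm means converge to it.

**What the generator does not emulate.** No informative (MNAR) dropout, no
serial correlation in measurement noise beyond the shared baseline level, no
COVID-era disruption of surgical scheduling, no distinct complication events
beyond the readmission indicator, and no SF-36 item responses (utilities are
generated directly). Passing recovery tests therefore show the estimation
pipeline is correct under MAR with a well-specified-enough imputation model —
not that the trial's own missingness was MAR.

## Outcomes and costing

QALYs are the trapezoidal area under the utility-time curve in years. Each
trapezoid is discounted by the year containing its midpoint, with year one
undiscounted and 3.5% per year thereafter — the standard UK convention.
Costs price resource counts with a bundled unit-cost table (GBP, 2019–2020
price year; illustrative NHS-scale magnitudes, **not** published reference
costs: surgery episode £2050, theatre minute £12, bed-day £350, A&E
attendance £180, readmission £1500, primary-care visit £39). Surgery-episode
components are discounted by the year of surgery; recurring items are
apportioned evenly across follow-up years (mean of the yearly discount
factors). These unit costs were chosen once so that the per-arm expected
totals sit at the scale reported for NHS cholecystectomy pathways.

## Within-trial analysis

**Estimand.** Adjusted incremental cost and QALY for CM minus LC at 24
months, with covariates fixed by the trial's minimization factors: centre
(fixed effects; centres left with a single participant after resampling are
pooled into the reference stratum), age, sex, and baseline utility.

**Models.** The QALY model is linear. The cost model is linear by default:
under randomization the arm coefficient of an OLS fit is an exactly unbiased
GBP-scale incremental even for skewed costs. A gamma GLM with log link is
available (`cost_family="gamma-log"`), reporting the average marginal
(recycled-prediction) effect with a delta-method standard error and falling
back to OLS on non-convergence or non-positive costs. It is not the default
because this cost distribution is a sharp two-component mixture (surgical
versus non-surgical pathways), and the package's own recovery suite showed
the gamma marginal effect biased by roughly −12% at the trial's sample size
while OLS was unbiased with nominal bootstrap coverage.

**Missing data.** Chained-equations multiple imputation (default m = 20),
with proper Bayesian draws: each conditional linear model samples sigma^2
from its scaled inverse-chi-square posterior, beta from its conditional
normal, and adds posterior-predictive noise. Imputation models are fitted
separately within each arm — a single pooled model forces common
visit-to-visit slopes across arms whose correlation structures differ
through surgical uptake, which measurably attenuated the QALY delta —
and condition on centre, age, sex, baseline utility, surgery status and
timing, and the other current visit values. Imputed utilities are clipped to
the instrument range. Point estimates pool across imputations by Rubin's
rules. A small residual attenuation (~5% of the QALY delta) remains from
approximating the non-linear post-operative dip with linear conditionals; it
sits inside the 3-Monte-Carlo-s.e. band of the recovery suite at 250
replicates.

**Uncertainty.** Non-parametric bootstrap (default B = 1000), resampling
participants with replacement stratified by arm; each resample receives a
single proper stochastic imputation before re-estimation
(bootstrap-then-impute), so draws carry sampling and imputation uncertainty
jointly. Intervals are 2.5th/97.5th percentiles of the draws. Resamples
whose models fail are redrawn; more than 1% redraws aborts the run. ICERs
are always reported with their cost-effectiveness-plane quadrant (a
south-west ratio is savings per QALY forgone); a zero QALY delta yields a
flagged-undefined ICER rather than an exception. The CEAC reports, at each
threshold λ (defaults £13 000, £20 000, £30 000), the fraction of draws with
λ·ΔQ − ΔC > 0, ties counting one half.

## Markov extrapolation

States: NoSurgery → RecoveryTunnel → {SymptomsResolved, SymptomsPersist},
with Death absorbing and reachable from every state. Monthly cycles, 120-cycle
horizon, cohort starting age 50.5 with 71% women. The tunnel is encoded as
expanded sub-states so its dwell time (default 1 month) is exact. The surgery
hazard is a per-cycle schedule; the default is constant over months 1–24,
calibrated so the mortality-free cumulative uptake matches 70.5% (LC) and
29.5% (CM), and zero afterwards (no reliable information on later surgeries;
configurable). Mortality comes from a bundled synthetic Gompertz life table
(ONS-style layout, ages 40–100), sex-mix-weighted by default with a
sex-stratified mode available. Accrual uses cycle-start occupancy (no
half-cycle correction by default — monthly cycles make the bias small; a flag
enables it), with the same year-1-undiscounted convention applied by the
calendar year containing each cycle. The surgical episode cost is charged on
entry into the tunnel.

Default state values are calibrated to the trial's observable margins only:
post-surgery states sit at a common population-norm-like utility (0.70), the
NoSurgery state carries a small decrement (0.695) representing reduced
quality of life while symptomatic and awaiting surgery, and the tunnel dips
to 0.60 for its single month. Resolved and persistent states share one
utility in the base case, which makes the resolution probability irrelevant
to QALY totals — asserted by a test. Episode costs default to the trial's
mean theatre/stay margins priced at the bundled unit costs (LC £3135,
CM £3536). Per-cycle state costs (£12 NoSurgery, £50 tunnel, £8 post-surgery)
represent ongoing primary-care and symptom-management contact.

**PSA.** Parameters are drawn independently: beta for probabilities, beta on
the rescaled [-0.59, 1] support for utilities, gamma for costs, all fitted by
method of moments from (mean, s.e.); a zero s.e. collapses the draw to its
mean, reproducing the deterministic result exactly. Utilities up to month 48
may be supplied per cycle (carried forward thereafter), which is the
mechanism for the trial-adjusted-utilities sensitivity analysis.

**Validation.** A vectorized individual-level microsimulation runs the
identical transition process (same weighted mortality, same accrual
convention) and must agree with the cohort totals within 3 Monte-Carlo
standard errors at n = 100 000 — checked on three specifications in the test
suite.

## Numerical conventions and edge cases

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; child streams come from `SeedSequence.spawn`, so every stage is
  reproducible bit-for-bit.
- Imputation linear algebra uses a 1e-8 ridge on X'X for stability with many
  centre dummies.
- `auc_qaly` rejects missing utilities with a message directing callers to
  the imputation layer; baseline utility may not be missing anywhere.
- Transition rows are validated to sum to one; a surgery hazard plus
  mortality exceeding one raises a specification error rather than being
  renormalized.
- Quadrant labels for zero cost deltas: a zero-cost QALY gain is labelled
  dominant ("free gain"); a zero QALY delta is flagged undefined.

## Problem sizes used in the automated checks

The recovery suite runs 120 replicates of the full pipeline at the default
study conditions (217 per arm, 25% MAR nonresponse, m = 20, B = 200); the
3-s.e. acceptance bands are computed from the replicate count actually run.
The acceptance script uses B = 1000 bootstrap draws and 1000 PSA draws.
These sizes are the package's choice of Monte-Carlo effort; raising them
tightens the bands without changing any default study condition.

## Known limitations

- The bundled unit costs and life table are synthetic fixtures; absolute
  cost and survival levels are illustrative.
- The imputation engine uses normal linear conditionals (with clipping), not
  predictive-mean matching; count variables are imputed continuously and
  clipped at zero.
- The PSA draws parameters independently; correlated draws (e.g. a shared
  utility level) are not implemented.
- The cohort model carries no patient-level heterogeneity beyond the sex
  mix; that is deliberately the microsimulation oracle's job.
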