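# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and what the tests do and do not establish.

## Effect measures

**QALYs.** The EQ-5D-5L descriptive system (5 dimensions × 5 levels,
3125 states) is scored with an additive value set: index = 1 − Σ
decrement(dimension, level), with zero level-1 decrements so full
health scores exactly 1.  The shipped value set is a synthetic stand-in
shaped like the German tariff — same structure, same range
[−0.661, 1], invented coefficients — because the original coefficient
table is licensed; a real tariff drops in as a CSV of (dimension,
level, decrement).  QALYs are the trapezoidal area under the linearly
interpolated index across the four assessments, with reference days
30 / 150 / 180 between consecutive waves (total 360), divided by an
annual denominator of 365 days.  The published point estimates cannot
adjudicate between 360, 365 and 365.25 as the denominator; 365 is the
default and is exposed as an argument of `qaly_auc`.  Under a linear
trend assumption the trapezoid is exact, so the only approximation is
the linearity of health between waves.

**Depression-free days.** The day-level probability of being
depression-free is 1 for PHQ-9 ≤ 5, 0 for ≥ 15, and (15 − s)/10 in
between.  At s = 5 the interpolation formula equals 1, so the
open/closed boundary is immaterial; it is implemented as ≤ 5 → 1.  The
PHQ-9 is interpolated linearly in continuous time within each segment
and the composed piecewise-linear function is integrated exactly by
splitting each segment at the crossings of 5 and 15.  A
10,000-step trapezoid quadrature serves as the independent oracle in
the tests (agreement < 1e-6 days on random trajectories).  DFDs are
reported in days so that €/DFD thresholds apply directly; the €/DFD
willingness-to-pay threshold itself is accepted as configuration, not
derived.

## Costing

Each resource category is costed as count × unit cost, with unit costs
CPI-inflated from their price year to 2022.  The unit-cost table is a
synthetic stand-in for a standard unit-cost compendium and retail drug
prices (medication is costed per item per window); real tables drop in
as CSV.  Productivity losses value sick-leave days at a gross daily
labour cost (human capital approach); informal care values hours at a
professional substitute's gross hourly wage plus a non-wage loading
(replacement cost approach), both fixture-configured.  The societal
perspective sums direct + informal care + indirect costs; the payer
perspective keeps direct costs only.  Intervention costs are never
added: the interventions differ only by printed sheets of paper, and
any induced care shows up in measured service use.  Baseline service
use (GP visits, in-patient days, medications, sick days) is covariate
only and never costed into follow-up totals.  Whether presenteeism or
unpaid-work losses belong in indirect costs is an open question in the
source material; only absenteeism is implemented.

## Synthetic trial generator

The generator is the test bed standing in for the unavailable trial
data.  Its defaults encode the study conditions: three arms of 329;
5 centres, 64 practices nested in them; baseline PHQ-9 ≥ 10 with mean
≈ 13.5, s.d. ≈ 3.3 (the excess over the screening cut-off is drawn
from a capped exponential with mean 3.5 — the moment pair is not
attainable by a truncated normal above a floor of 10); baseline
EQ-5D-5L index mean ≈ 0.675, s.d. ≈ 0.26; 62.2% female, age
39.5 ± 15.3 (clipped to 18–85, which trims the realised s.d. to ~14).

Latent health follows a random-intercept trajectory on the utility
scale: mean path (0.675, 0.700, 0.760, 0.825), centre / practice /
person intercepts (s.d. 0.03 / 0.05 / 0.22), occasion noise 0.07, and
a slope of −0.030 utility per baseline PHQ-9 point above 13.5 linking
the instruments.  Observed 5-digit states are produced by adding
dimension-level noise (s.d. 0.22) to 1 − health and thresholding at
(0.10, 0.36, 0.68, 0.98) — downstream code therefore consumes genuine
states, not indices.  Discretisation attenuates configured additive
utility shifts by roughly a quarter, which is why the
estimator-calibration suites use direct outcome-level simulators
(`trialcea.simulate`) where the truth is exact, while generator-level
tests assert the analytic null (the latent contrast of a null
configuration is exactly zero).

PHQ-9 items are allocated from the total by drawing the total's points
uniformly over the 27 item-points, so item sums always equal totals
and land in the configured band.  Resource use is a two-part draw per
category and window: a structural zero with configured probability,
else a gamma intensity whose mean scales with the window length
(windows of 1, 5 and 6 months tile the year; recall windows are not
reported in the source setting, so tiling is an assumption), a
participant log-normal frailty shared across categories, a practice
cost effect, and the arm's cost ratio.  The MINI diagnosis at one
month is Bernoulli with a severity-linked probability.  Arm effects
default to null; a `StratumEffect` confines them to one stratum for
heterogeneity studies.

**Missingness.** Whole follow-up assessments (participant × wave
blocks) go missing with probability logistic in fully observed
baseline fields only — non-native speaker, smoking, baseline EQ-5D-5L
index, baseline PHQ-9, baseline GP visits, addiction — with a
time-increasing offset; the intercept is calibrated by bisection to
the target overall rate (default 20%).  This is MAR by construction.
Block-level (rather than item-level) missingness mirrors missed
assessments and yields a complete-case share of ≈ 0.8³ ≈ 51% at the
default rate.  Item-level nonresponse within an attended assessment is
not modelled.

**Seeds.** One master seed; generation, missingness and imputation use
deterministic substreams (`SeedSequence((seed, stage))`), and the
imputation stream spawns one child per imputation.

## Imputation

Chained equations at the score level: EQ-5D index, PHQ-9 total,
resource counts, sick days, informal-care hours per wave, and the MINI
flag.  Outcomes (QALYs, costs) are always re-derived from imputed
assessments.  Continuous and count variables use type-1
predictive-mean matching with k = 5 nearest donors (ties broken by a
seeded uniform draw); because donors are observed rows, imputed values
automatically satisfy the type invariants, and companion columns (the
5-digit state, the nine items) are copied from the donor so datasets
stay internally consistent.  The binary MINI flag uses a
ridge-stabilised Bayesian logistic draw.  The predictor matrix is all
baseline covariates + arm + practice dummies (which span the nested
centres) + the same score at the other waves; variables are visited in
ascending missing-fraction order for 10 sweeps by default.  The
imputation level, sweep count and conditional models are declared
design choices — the source setting does not document them.  A chain
trace (per-iteration means/variances of imputed values) is recorded
and a drift heuristic warns on apparent non-convergence.
Missing-not-at-random sensitivity analysis is out of scope.

## Estimation

All mixed models share one backend: a two-level nested random-intercept
linear mixed model fitted by REML, written in-package as a profiled
2-parameter optimisation using the Woodbury identity (`estimation._lmm`).
Each fit costs a few milliseconds, which the NBR grids (λ ×
imputations × scenarios × subgroups) and the replicate suites require;
statsmodels MixedLM is the independent oracle in the tests
(coefficients and standard errors agree to ~1e-3 relative, and the
zero-variance boundary reduces exactly to OLS).  Wald tests use a t
reference with residual degrees of freedom n − p, declared in the
output metadata; with 5 centres the centre-level variance is often
estimated at the boundary, which is flagged, not hidden.

Gamma log-link mixed models for cost aggregates are fitted by
penalised quasi-likelihood: for the log link the gamma IRLS weights
are constant, so each PQL step is an unweighted nested LMM on the
working response, with adaptive damping (the step halves whenever the
coefficient update grows).  On well-specified gamma data PQL converges
in ~5–15 steps; on extremely heavy-tailed mixtures the fixed point can
fail to stabilise, and the documented fallback is a gamma GLM with
practice-clustered robust covariance, tagged in the result.  Exact
zero totals are replaced by €0.50 (half the smallest plausible unit)
and counted, never dropped — zero handling under the gamma family is
undocumented in the source setting, so this is a declared choice.

Single cost categories use a two-part model: logistic occurrence
(practice-clustered covariance) and gamma-log intensity on the
positives; the marginal arm effect on log E[Y] combines
Δlog P(Y > 0) at the covariate means with the intensity coefficient,
with a delta-method standard error treating the parts as independent.
A category with all-zero or all-positive outcomes in an arm is flagged
as a separation risk; with no zeros at all the model collapses to the
plain gamma fit.

Rubin pooling: Q̄ = mean estimate, T = W̄ + (1 + 1/M)·B, two-sided p
from a t reference with Barnard–Rubin adjusted degrees of freedom
(complete-data df = n − p); B = 0 reduces exactly to the
single-dataset analysis.  Pooling across heterogeneous model
specifications is rejected.

Baseline balance uses OLS for continuous, logistic for binary, and
multinomial logistic regressions with a joint Wald test per arm
contrast for categorical variables, always against the no-feedback
reference; degenerate fits (constant variables, separation under
permutation) are flagged with NaN p-values rather than raised.
Significance is 5%, two-sided, with no multiple-testing adjustment.

## Decision analytics

Unadjusted ICERs divide the difference in raw arm means of
across-imputation-averaged per-participant costs and effects; ΔE = 0
yields an undefined ratio tagged cost-minimisation.  CEACs come from
net-benefit regression: per λ and per imputed dataset, NB = λ·E − C is
regressed with the same linear mixed model and covariates as the
effect model; the arm coefficient is Rubin-pooled **before** the
half-p rule is applied to the pooled p (pooling probabilities instead
was considered and rejected — the pooled-coefficient route is the one
consistent with pooling model results).  The probability is 1 − p/2
for a positive coefficient, p/2 for a negative one, exactly 0.5 at
zero; the t reference of the pooled test is the default (a normal
reference differs negligibly at these df).  Comparisons are strictly
pairwise against no feedback.

Scenarios: payer (direct costs only; baseline sick days leave the
covariate list), complete case (participants with all 12-month
societal-cost and QALY inputs observed in the pre-imputation data; a
single unpooled analysis — the diagnostics are not re-derived),
and DFD (PHQ-9-based effects on the €/DFD grid).  Subpopulation
analyses split each imputed dataset on its own (possibly imputed)
level of the splitting variable, drop pregnancy, breastfeeding and
living situation from the covariates, binarise city size, drop the
splitting variable itself, and run the same pipeline; empty or
too-small levels (e.g. the low-frequency diverse-gender category) are
skipped with a warning.

## What the tests show — and what they do not

The synthetic generator reproduces the marginal structure the analysis
assumes (severity floor and moments, index distribution, skewed
zero-inflated costs, nested clustering, calibrated MAR rate), so
passing suites establish that the pipeline is internally correct and
calibrated **under its own assumptions**: CI coverage 92–98% per model
family at n = 900 over 200 replicates, type-I error 5% ± 2 points over
500 permutation replicates, imputation-pipeline bias within
Monte-Carlo error of zero under the generator's MAR mechanism (200
replicates at n = 300, M = 20, chained sweeps reduced to 4 and the
imputation restricted to the QALY-relevant block to keep the suite
fast), CEAC contract checks, and byte-identical end-to-end runs.  They
do not establish robustness to what real trial data add: MNAR
dropout, item-level nonresponse, instrument response styles,
non-linear health trajectories within long windows, or cost
distributions outside the two-part gamma family.

One property was re-stated from its natural phrasing: under a null
effect the per-replicate CEAC is itself approximately uniform via the
half-p rule (P(curve ∈ [0.3, 0.7] at one λ) = P(p ≥ 0.6) ≈ 0.4), so
the suite asserts the Monte-Carlo **mean** CEAC per λ lies in
[0.3, 0.7] — its expectation under the null is exactly 0.5.

Problem sizes in the suites (n = 900 for recovery, n = 300 for
permutation and imputation replicates, n = 150 for the end-to-end
reproducibility run) are the package's choices for routine runs; all
drivers accept the full 987-participant design, which
`scripts/acceptance.py` exercises.
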