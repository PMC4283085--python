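# Methods

## The concurrent cost model

The pipeline estimates a *concurrent* model: the same year's morbidity
classification explains the same year's annual primary-care pharmaceutical
expenditure per patient, C (Euros). Because C is right-skewed with a point
mass at zero, the response is `y = ln(C + 1)`; the +1 keeps zero-cost
patients in the sample (y = 0) and gives sub-Euro costs a positive log.
Estimation is ordinary least squares under the usual normality,
homoscedasticity and linearity assumptions; goodness of fit is reported as
the corrected (adjusted) R², with the unadjusted value alongside. The
regression sample includes healthy non-users (they are part of the insured
population the budget must cover); callers who want to model users only can
filter before fitting.

Six specifications are registered (`MODEL_SPECS`): (i) age and sex;
(ii) age, sex and the eight core-status dummies; (iii) status dummies only;
(iv) status dummies on the paediatric cohort; (v) on the adult cohort;
(vi) status and severity dummies plus age and sex on the adult cohort.
Status 1 (healthy) and severity level 1 are the baselines. The paediatric
boundary is age ≤ 14 — the age band attended by paediatricians in Spanish
primary care. Weights are derived from the status-only specification (iii)
by default: operationally it needs nothing but the ACRG3 code, and its
weights are directly communicable to clinicians. A severity-augmented
sensitivity path exists (`severity_multipliers`), multiplying the status
weight by the retransformed severity offset from specification (vi).

Dummy columns with no members after the cohort filter are *retained* and
reported as not estimable (NaN coefficient plus a `NotEstimableWarning`)
rather than silently dropped: the budget weights need all nine statuses, so
a missing status must be loud. Rank deficiency beyond such empty columns
raises. The OLS solve itself is delegated to statsmodels, which handles
designs of millions of rows; an independent normal-equations solve backs it
in the tests.

Split-sample validation fits on a random 70% (exact partition by shuffled
index, with its own seed so the partition is reproducible independently of
the data seed) and evaluates R²/MSE on the held-out 30% using the training
coefficients.

## Retransformation and weights

Exponentiating ln-scale predictions underestimates Euro-scale means; Duan's
smearing estimator corrects this nonparametrically with
`γ = mean(exp(residuals))`, computed on the residuals of the same fit that
supplies the coefficients. For mean-zero residuals Jensen's inequality
guarantees γ ≥ 1 (asserted as a property test). Under the generator's
normal ln-scale noise the closed form is γ = exp(σ²/2), which serves as the
independent oracle for the estimator.

The weight chain per core status i: `a_i = β₀ + β_i` (a₁ = β₀),
`b_i = γ·e^{a_i} − 1` Euros (undoing the +1 of the transform; floored at 0
because a capitation weight cannot be negative — the floor only binds in
degenerate configurations), and `c_i = b_i / b_1`, so a healthy patient
weighs exactly 1. Weights for the malignancy and catastrophic statuses
(8–9) understate true pharmaceutical burden wherever hospital pharmacies
dispense most of those medicines; this is a property of primary-care data,
not of the method.

## Case mix and budget allocation

District j's adjusted patients are `Σᵢ N_ij·c_i`; its case mix is adjusted
patients over head count. The standard price divides the overall budget
(optionally scaled by a price-adjustment fraction such as −0.15, reflecting
falling medicine prices and rational-use measures) by the region's adjusted
patients; district budgets are price × adjusted patients, which makes the
uncapped allocation budget-neutral to the cent by construction. An optional
cap bounds the standard price; a binding cap leaves part of the budget
unallocated, which is reported, not redistributed — the minimal reading of
a price ceiling. Whether the cap applies before or after the price
adjustment is configurable (`cap_before_adjustment`, default after).
Weights enter allocation only through ratios, so rescaling all weights by a
constant leaves every district budget unchanged. Euro outputs are computed
at full precision and rounded to 2 decimals only at serialisation. Annual
recalibration refits the chosen specification on the new year's records,
re-derives γ and the weights, and reports per-status drift against the
prior table.

## The synthetic generator

The generator emulates the 2012 stratification of a 4.65-million-person
regional population (44 ACRG3 codes): multinomial group membership with the
observed shares, per-group truncated-normal ages on [0, 105] with the
observed moments, uniform-or-tilted assignment to 24 districts, and costs

    ln(C + 1) = a_g + ε,  ε ~ Normal(0, σ), C floored at 0,

with homoscedastic normal ln-scale noise. Three zero-cost mechanisms
coexist in the realistic default (`default_config`): the healthy non-user
stratum (code 11, 16.85% of the population, cost 0 by definition), an
additional 8% zero-cost fraction among everyone else (`zero_cost_extra_rate
= 0.08`), and the cost floor itself, which zeroes patients whose
`a_g + ε < 0` (about 4.5% within the healthy statuses, where a ≈ 1.74).
Defaults: σ = sqrt(2·ln 1.693) ≈ 1.026, so the generator's implied smearing
factor equals the published 1.693; per-code `a_g` is the status-level
predicted ln(C+1) of the published weight chain; male fraction 0.49 and
co-payment rate 0.7 (plausible regional values — neither enters the cost
model); the district tilt is a fixed linear gradient of ±0.15 on chronic
statuses, chosen by a censored-mass calculation to give an inter-district
case-mix spread of roughly ±15%, the order of the published district range.

Three population cells of the published stratification table are
typographically truncated; they are repaired from the share column, which
is internally coherent. The published zero-cost count (8%) is itself
inconsistent with the non-user share (16.85%); the package reads the 8% as
the additional zero-cost fraction outside the non-user stratum.

`model_recovery_config` is the configuration under which the regression is
exactly the data-generating process: the non-user stratum is removed, no
extra zeros are injected, and each group's location is *de-censored* — the
floor turns y into `max(a_g + ε, 0)`, whose mean exceeds a_g, so the
generator solves `E[max(Normal(m, σ), 0)] = β₀ + β_i` for m (closed-form
censored-normal mean, inverted by Brent's method). Without this, OLS on
floored data recovers the healthy-status intercept with a structural bias
of ≈ +0.019 (≈ 4 standard errors at n = 100,000). With it, every
coefficient is recovered within Monte-Carlo noise, which is the
parameter-recovery surface the tests assert.

What the generator does *not* emulate: longitudinal multi-year
trajectories, co-payment behaviour, hospital-dispensed costs, age-cost
correlation within groups (age affects only the cohort split), and the
heavy non-normal residual tails of real cost data. Consequently a passing
recovery test shows the estimator and weight chain are correct, not that
real data satisfy OLS assumptions; the adjusted R² on recovery populations
(≈ 0.79) is mechanically higher than values observed on real data (≈ 0.55),
where zero inflation and unmodelled heterogeneity dilute fit. Published
figures are reproduced exactly only where the computation is deterministic
(the weight chain from published coefficients; district report arithmetic).

## Numerical choices and problem sizes

Seeds: the generator seed lives in the config and is recorded in output
manifests; the validation split takes a separate seed. All randomness flows
through `numpy.random.default_rng`. Tolerances in tests: deterministic
reproductions of published tables at the tables' printed rounding (±0.5% on
the weight chain, ±0.01 Euro on report columns); stochastic checks at 3
standard errors or explicit Monte-Carlo bands. Test populations use
20,000–100,000 patients and the budget-neutrality sweep uses 50 populations
of 1,500 — sizes at which every Monte-Carlo band above is comfortably
resolved while the suite stays quick.

## Known limitations

- ACRG3 codes are taken as given input; the proprietary grouper that maps
  diagnoses to CRGs is out of scope, as are the ACRG1/ACRG2 tiers.
- Plain OLS on ln(C+1) with a single smearing factor: no two-part hurdle
  model, no GLM with log link, no subgroup-specific (heteroscedastic)
  smearing, no robust standard errors.
- The paediatric cohort genuinely defeats a status-only model (the
  classification carries little cost signal for children); the package
  reproduces this failure mode rather than fixing it — a dedicated
  paediatric model is future work.
- Physician-level budgets and incentive design are out of scope; the
  allocation stops at the district.
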