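# crgbudget

Risk adjustment of primary-care pharmaceutical expenditure with Clinical
Risk Groups (CRG), and budget-neutral prospective budget allocation to
health districts.

Regional health authorities that finance primary-care prescribing by
capitation need to know how much of the variation in per-patient medicine
cost is explained by morbidity, and how to turn that into defensible
district budgets. This package implements a concurrent case-mix pipeline
for populations stratified by CRG core health status and severity level
(ACRG3: nine core statuses, 1 healthy … 9 catastrophic, with severity
levels 1–6): it models annual cost, derives standardized per-status
weights, and allocates a fixed overall budget by *adjusted patients*. A
synthetic-population generator reproduces the statistical structure of a
4.65-million-person regional population so the whole pipeline is testable
without access to patient data.

## The model

Annual cost C is heavily skewed with a point mass at zero, so the
dependent variable is `y = ln(C + 1)` and the concurrent model is OLS on
health-status dummies (status 1, healthy, is the baseline):

    y = β₀ + Σᵢ₌₂⁹ βᵢ · 1[status = i] + ε

Six specifications combine age, sex, the eight status dummies and five
severity dummies on the whole population or on the paediatric (age ≤ 14)
and adult cohorts. Predictions are retransformed to Euros with Duan's
nonparametric smearing estimator,

    γ = (1/n) Σₖ exp(εₖ),

which corrects the downward bias of exponentiating a log-scale mean under
homoscedastic errors. The weight chain per core status i is

    aᵢ = β₀ + βᵢ      (ln-scale predicted value; a₁ = β₀)
    bᵢ = γ·e^{aᵢ} − 1  (retransformed expenditure, Euros)
    cᵢ = bᵢ / b₁       (standardized weight; healthy patient = 1)

District j's case mix is `CM_j = Σᵢ N_ij·cᵢ / N_j`; dividing the overall
budget by the region's total adjusted patients `Σ_j Σᵢ N_ij·cᵢ` gives the
standard price of one adjusted patient, and multiplying back gives each
district a budget-neutral prospective budget. An optional price-adjustment
factor (e.g. −15%) scales the budget, and an optional cap bounds the
standard price (a binding cap leaves a reported unallocated remainder).

## Worked example

```python
import crgbudget as cb

# population whose ln-cost model is exactly the status-only linear DGP
config = cb.model_recovery_config(n_patients=100_000, seed=42)
patients = cb.generate_population(config)

fit = cb.fit_model(patients, "iii")          # status dummies only
gamma = cb.duan_smearing(fit.residuals)
weights = cb.derive_weights(fit, gamma)

agg = cb.aggregate_districts(patients, weights)
budget = float(agg["real_cost"].sum())       # finance observed spend exactly
allocation = cb.allocate_budget(agg, total_budget=budget)
report = cb.compare_real_predicted(allocation.districts)
```

This prints (via the obvious `print` calls):

```
model iii: n=100000, adjusted R^2=0.788
smearing factor gamma = 1.680 (100000 residuals)
                a        b       c
core_status
1            1.73     8.46    1.00
2            3.55    57.56    6.80
3            4.17   107.48   12.70
4            5.44   384.51   45.44
5            5.53   422.61   49.95
6            6.73  1399.57  165.42
7            7.52  3095.18  365.82
8            6.65  1294.25  152.97
9            6.22   845.89   99.98
total budget: 30,554,719.92 EUR
standard price: 8.5480 EUR per adjusted patient
11 districts spent less than predicted, 13 more
```

Reading the output: a patient with chronic disease in two or more organ
systems (status 6) costs about 165 healthy-patient equivalents; the
standard price converts each district's adjusted patients into its
prospective budget, and the per-district `difference` column (average real
minus average predicted cost per person, Euros) shows which districts
spend more or less than their morbidity predicts. The adjusted R² here
(0.79) is higher than on real data because this generator configuration
contains no zero-cost strata; `cb.default_config()` produces the realistic
mixture (healthy non-users and an extra zero-cost fraction) instead.

The same pipeline is available from a shell:

```
crgbudget simulate --n 100000 --seed 42 --out patients.csv
crgbudget fit --model iii --input patients.csv --out fit_iii/
crgbudget weights --fit fit_iii/ --out weights.csv
crgbudget allocate --patients patients.csv --weights weights.csv \
    --budget 1301898792.80 --adjustment -0.15 --out report.csv
crgbudget report --patients patients.csv --weights weights.csv
```

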