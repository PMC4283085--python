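"""District aggregation, budget allocation, comparison reports, recalibration."""

import numpy as np
import pandas as pd
import pytest

from crgbudget import (
    ValidationError,
    aggregate_districts,
    allocate_budget,
    compare_real_predicted,
    default_config,
    derive_weights,
    duan_smearing,
    fit_model,
    generate_population,
    recalibrate,
    region_aggregate,
)
from crgbudget.population import attach_status
from crgbudget.reference import SMEARING_FACTOR_2012, WEIGHTS_2012


@pytest.fixture(scope="module")
def weights():
    """Published standard weights as a per-status series."""
    return pd.DataFrame(WEIGHTS_2012).T.rename_axis("core_status")


@pytest.fixture(scope="module")
def aggregates(small_population, weights):
    return aggregate_districts(small_population, weights)


def _records(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "age", "sex", "district_id",
                                     "acrg3", "annual_cost", "copayment_flag"])
    return attach_status(df)


def test_all_healthy_district_has_case_mix_one(weights):
    recs = _records([("a", 30, 0, 1, 10, 12.0, 1), ("b", 40, 1, 1, 15, 30.0, 0)])
    agg = aggregate_districts(recs, weights)
    assert agg.loc[1, "case_mix"] == pytest.approx(1.0)


def test_two_patient_case_mix_hand_computed(weights):
    recs = _records([("a", 30, 0, 1, 10, 12.0, 1), ("b", 40, 1, 1, 20, 90.0, 0)])
    agg = aggregate_districts(recs, weights)
    assert agg.loc[1, "case_mix"] == pytest.approx((1 + 6.75) / 2)


def test_region_case_mix_is_count_weighted_mean(aggregates):
    region = region_aggregate(aggregates)
    weighted = ((aggregates["case_mix"] * aggregates["population"]).sum()
                / aggregates["population"].sum())
    assert region["case_mix"] == pytest.approx(weighted, rel=1e-12)


def test_counts_partition_population(aggregates):
    status_cols = [f"n_status_{s}" for s in range(1, 10)]
    assert (aggregates[status_cols].sum(axis=1)
            == aggregates["population"]).all()


def test_uncapped_allocation_is_budget_neutral(aggregates):
    alloc = allocate_budget(aggregates, total_budget=5_000_000.0)
    assert alloc.districts["predicted_cost"].sum() == pytest.approx(
        5_000_000.0, abs=0.01)
    assert alloc.unallocated == pytest.approx(0.0, abs=0.01)


def test_price_adjustment_scales_every_district(aggregates):
    base = allocate_budget(aggregates, 5_000_000.0)
    cut = allocate_budget(aggregates, 5_000_000.0, price_adjustment=-0.15)
    assert cut.districts["predicted_cost"].to_numpy() == pytest.approx(
        0.85 * base.districts["predicted_cost"].to_numpy())
    assert cut.effective_budget == pytest.approx(0.85 * 5_000_000.0)


def test_equal_districts_get_equal_budgets(weights):
    recs = _records([("a", 30, 0, 1, 10, 12.0, 1), ("b", 70, 1, 1, 61, 900.0, 0),
                     ("c", 30, 0, 2, 10, 15.0, 1), ("d", 71, 1, 2, 61, 880.0, 0)])
    alloc = allocate_budget(aggregate_districts(recs, weights), 1000.0)
    pc = alloc.districts["predicted_cost"]
    assert pc.loc[1] == pytest.approx(pc.loc[2])


def test_binding_cap_reports_unallocated_remainder(aggregates):
    uncapped = allocate_budget(aggregates, 5_000_000.0)
    cap = uncapped.standard_price * 0.8
    capped = allocate_budget(aggregates, 5_000_000.0, cap=cap)
    assert capped.cap_binding
    assert capped.standard_price == pytest.approx(cap)
    assert capped.unallocated == pytest.approx(0.2 * 5_000_000.0, rel=1e-9)
    loose = allocate_budget(aggregates, 5_000_000.0,
                            cap=uncapped.standard_price * 2)
    assert not loose.cap_binding


def test_cap_before_adjustment_flag(aggregates):
    cap = allocate_budget(aggregates, 5_000_000.0).standard_price * 0.9
    after = allocate_budget(aggregates, 5_000_000.0, price_adjustment=-0.15,
                            cap=cap)
    before = allocate_budget(aggregates, 5_000_000.0, price_adjustment=-0.15,
                             cap=cap, cap_before_adjustment=True)
    # -15% already brings the price under the cap, so the cap only binds
    # when applied to the pre-adjustment price
    assert not after.cap_binding
    assert before.cap_binding
    assert before.standard_price == pytest.approx(cap * 0.85)


def test_weight_scale_invariance(small_population, weights):
    scaled = weights.copy()
    scaled["c"] = scaled["c"] * 7.0
    a1 = allocate_budget(aggregate_districts(small_population, weights),
                         1_000_000.0)
    a2 = allocate_budget(aggregate_districts(small_population, scaled),
                         1_000_000.0)
    assert a2.districts["predicted_cost"].to_numpy() == pytest.approx(
        a1.districts["predicted_cost"].to_numpy())


def test_more_morbidity_raises_own_budget_lowers_others(weights):
    rows = [("a", 30, 0, 1, 10, 10.0, 1), ("b", 70, 1, 1, 61, 900.0, 0),
            ("c", 30, 0, 2, 10, 10.0, 1), ("d", 70, 1, 2, 61, 900.0, 0)]
    base = allocate_budget(aggregate_districts(_records(rows), weights), 1e6)
    rows_more = rows + [("e", 75, 1, 1, 71, 2000.0, 0)]  # high-weight status 7
    more = allocate_budget(aggregate_districts(_records(rows_more), weights),
                           1e6)
    assert (more.districts.loc[1, "predicted_cost"]
            > base.districts.loc[1, "predicted_cost"])
    assert (more.districts.loc[2, "predicted_cost"]
            < base.districts.loc[2, "predicted_cost"])


def test_zero_budget_and_empty_aggregation_rejected(aggregates, weights):
    with pytest.raises(ValueError):
        allocate_budget(aggregates, 0.0)
    with pytest.raises(ValueError):
        aggregate_districts(_records([]).iloc[0:0], weights)


def test_compare_identical_real_and_predicted_gives_zero_differences(aggregates):
    alloc = allocate_budget(aggregates, float(aggregates["real_cost"].sum()))
    table = alloc.districts.copy()
    table["predicted_cost"] = table["real_cost"]
    out = compare_real_predicted(table)
    assert out["difference"].abs().max() == pytest.approx(0.0, abs=1e-9)
    assert out.loc["region", "difference"] == pytest.approx(0.0, abs=1e-9)


def test_compare_region_row_uses_column_sums(aggregates):
    alloc = allocate_budget(aggregates, 3_000_000.0)
    out = compare_real_predicted(alloc.districts)
    region = out.loc["region"]
    assert region["real_cost"] == pytest.approx(
        aggregates["real_cost"].sum())
    assert region["avg_predicted"] == pytest.approx(
        3_000_000.0 / aggregates["population"].sum())
    summary = out.attrs["summary"]
    assert summary["n_districts"] == len(aggregates)
    assert (summary["n_spent_less_than_predicted"]
            + summary["n_spent_more_than_predicted"]) <= summary["n_districts"]


def test_recalibration_on_same_distribution_is_stable(weights):
    pop = generate_population(default_config(n_patients=30_000, seed=21))
    fit = fit_model(pop, "iii")
    prior = derive_weights(fit, duan_smearing(fit.residuals))
    new_pop = generate_population(default_config(n_patients=30_000, seed=22))
    table = recalibrate(prior, new_pop)
    assert table.loc[1, "c"] == 1.0
    assert np.isfinite(table["drift"]).all()
    # drift is Monte-Carlo noise only; rare statuses (7-9 are <1% of the
    # population each) are inherently noisy, so bound the well-populated ones
    counts = new_pop["core_status"].value_counts()
    common = [s for s in range(1, 10) if counts.get(s, 0) >= 500]
    assert len(common) >= 5
    assert table.loc[common, "drift"].abs().max() < 0.25


def test_recalibration_detects_cost_shift(weights):
    pop = generate_population(default_config(n_patients=30_000, seed=23))
    fit = fit_model(pop, "iii")
    prior = derive_weights(fit, duan_smearing(fit.residuals))
    shifted = pop.copy()
    mask = shifted["core_status"] == 6
    shifted.loc[mask, "annual_cost"] *= 4.0
    table = recalibrate(prior, shifted)
    assert table.loc[6, "drift"] > 0.10
    others = table.drop(index=6)["drift"].abs()
    assert (others < table.loc[6, "drift"]).all()


def test_recalibration_requires_nonempty_valid_data(weights, small_population):
    prior = pd.DataFrame(WEIGHTS_2012).T.rename_axis("core_status")
    with pytest.raises(ValidationError):
        recalibrate(prior, small_population.iloc[0:0])
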