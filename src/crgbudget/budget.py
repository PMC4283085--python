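"""District case mix, prospective budget allocation and real-vs-predicted reports.

The case mix of health district j is the morbidity-weighted average burden

    CM_j = sum_i N_ij * W_i / N_j

where N_ij is the district's head count in core health status i and W_i the
status's standardized weight (healthy = 1).  The numerator is the district's
number of *adjusted patients*.  Dividing a fixed overall budget by the
region's total adjusted patients gives the standard price of one adjusted
patient; multiplying back by each district's adjusted patients yields
budget-neutral prospective budgets.  The health authority may scale the
budget by a price-adjustment factor (for instance -15% to reflect falling
medicine prices and rational-use measures) and may cap the standard price;
a binding cap leaves part of the budget unallocated, which is reported, not
redistributed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .population import validate_records
from .regression import MODEL_SPECS, ModelSpec, fit_model
from .smearing import derive_weights, duan_smearing

__all__ = [
    "aggregate_districts",
    "region_aggregate",
    "BudgetAllocation",
    "allocate_budget",
    "compare_real_predicted",
    "recalibrate",
    "write_district_report",
]

_STATUS_COLS = [f"n_status_{s}" for s in range(1, 10)]


def _weight_series(weights: pd.DataFrame | pd.Series) -> pd.Series:
    w = weights["c"] if isinstance(weights, pd.DataFrame) else weights
    missing = [s for s in range(1, 10) if s not in w.index]
    if missing:
        raise ValueError(f"weight table lacks statuses: {missing}")
    return w.astype(float)


def aggregate_districts(records: pd.DataFrame,
                        weights: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Per-district counts by core status, case mix and adjusted patients.

    Returns a frame indexed by district_id with the nine status head counts,
    total population, real cost, adjusted_patients = sum_i N_ij * W_i and
    case_mix = adjusted_patients / population.
    """
    if len(records) == 0:
        raise ValueError("no records to aggregate")
    w = _weight_series(weights)
    counts = (
        records.pivot_table(index="district_id", columns="core_status",
                            values="patient_id", aggfunc="count",
                            fill_value=0)
        .reindex(columns=range(1, 10), fill_value=0)
    )
    counts.columns = _STATUS_COLS
    agg = counts.copy()
    agg["population"] = counts.sum(axis=1)
    if (agg["population"] == 0).any():
        raise ValueError("district with zero population")
    agg["real_cost"] = records.groupby("district_id")["annual_cost"].sum()
    adjusted = counts.to_numpy() @ w.loc[range(1, 10)].to_numpy()
    agg["adjusted_patients"] = adjusted
    agg["case_mix"] = agg["adjusted_patients"] / agg["population"]
    return agg


def region_aggregate(aggregates: pd.DataFrame) -> pd.Series:
    """Region-total aggregate (sums of counts; case mix from the sums)."""
    total = aggregates[_STATUS_COLS + ["population", "real_cost",
                                       "adjusted_patients"]].sum()
    total["case_mix"] = total["adjusted_patients"] / total["population"]
    total.name = "region"
    return total


@dataclass
class BudgetAllocation:
    """A prospective allocation of ``total_budget`` across districts.

    ``effective_budget`` = total_budget * (1 + price_adjustment).  If the cap
    binds, ``unallocated`` is the part of the effective budget not assigned.
    """

    total_budget: float
    price_adjustment: float
    effective_budget: float
    standard_price: float
    cap: float | None
    cap_binding: bool
    unallocated: float
    districts: pd.DataFrame = field(repr=False)


def allocate_budget(aggregates: pd.DataFrame, total_budget: float,
                    price_adjustment: float = 0.0,
                    cap: float | None = None,
                    cap_before_adjustment: bool = False) -> BudgetAllocation:
    """Budget-neutral allocation by adjusted patients.

    standard_price = effective budget / total adjusted patients, optionally
    capped; predicted_cost_j = standard_price * adjusted_patients_j.  With
    ``cap_before_adjustment`` the ceiling applies to the pre-adjustment price
    (the capped price is then scaled by 1 + price_adjustment).
    """
    if total_budget <= 0:
        raise ValueError("total_budget must be positive")
    total_adjusted = float(aggregates["adjusted_patients"].sum())
    if total_adjusted <= 0:
        raise ValueError("zero adjusted patients in the region")
    effective = total_budget * (1.0 + price_adjustment)

    binding = False
    if cap is not None and cap_before_adjustment:
        raw = total_budget / total_adjusted
        capped = min(raw, cap)
        binding = capped < raw
        price = capped * (1.0 + price_adjustment)
    else:
        price = effective / total_adjusted
        if cap is not None and price > cap:
            price = cap
            binding = True

    districts = aggregates.copy()
    districts["predicted_cost"] = price * districts["adjusted_patients"]
    allocated = float(districts["predicted_cost"].sum())
    return BudgetAllocation(
        total_budget=float(total_budget),
        price_adjustment=float(price_adjustment),
        effective_budget=effective,
        standard_price=price,
        cap=cap,
        cap_binding=binding,
        unallocated=effective - allocated,
        districts=districts,
    )


def compare_real_predicted(district_table: pd.DataFrame) -> pd.DataFrame:
    """Per-district averages and the real-minus-predicted difference.

    Input needs columns real_cost, predicted_cost and population (indexed by
    district; an allocation's ``districts`` frame qualifies, as does a table
    of published figures).  Adds avg_real = real/N, avg_predicted =
    predicted/N and difference = avg_real - avg_predicted (Euros per person),
    plus a ``region`` totals row computed from the column sums.  Attaches a
    summary dict in ``result.attrs``: districts that spent less than
    predicted (difference < 0) and more (difference > 0).
    """
    needed = ["real_cost", "predicted_cost", "population"]
    missing = [c for c in needed if c not in district_table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    keep = [c for c in ["case_mix"] + needed if c in district_table.columns]
    out = district_table[keep].copy()

    totals = out[needed].sum()
    region = {c: totals[c] for c in needed}
    if "case_mix" in out.columns and "adjusted_patients" in district_table.columns:
        region["case_mix"] = (district_table["adjusted_patients"].sum()
                              / totals["population"])
    elif "case_mix" in out.columns:
        # head-count-weighted mean of district case mixes
        region["case_mix"] = float(
            (out["case_mix"] * out["population"]).sum() / totals["population"]
        )
    out.loc["region"] = pd.Series(region)

    out["avg_real"] = out["real_cost"] / out["population"]
    out["avg_predicted"] = out["predicted_cost"] / out["population"]
    out["difference"] = out["avg_real"] - out["avg_predicted"]

    per_district = out.drop(index="region")
    out.attrs["summary"] = {
        "n_districts": int(len(per_district)),
        "n_spent_less_than_predicted": int((per_district["difference"] < 0).sum()),
        "n_spent_more_than_predicted": int((per_district["difference"] > 0).sum()),
        "region_avg_real": float(out.loc["region", "avg_real"]),
        "region_avg_predicted": float(out.loc["region", "avg_predicted"]),
    }
    return out


def recalibrate(prior_weights: pd.DataFrame, new_records: pd.DataFrame,
                model: str | ModelSpec = "iii") -> pd.DataFrame:
    """Annual recalibration: refit on the new year, re-derive weights.

    Returns the fresh weight table with a ``prior_c`` column and the relative
    per-status drift ``drift = c / prior_c - 1``.  Raises if the new data are
    empty, invalid, or missing any core status.
    """
    validate_records(new_records)
    fit = fit_model(new_records, model)
    gamma = duan_smearing(fit.residuals)
    new_weights = derive_weights(fit, gamma)
    prior_c = _weight_series(prior_weights)
    new_weights["prior_c"] = prior_c
    new_weights["drift"] = new_weights["c"] / prior_c - 1.0
    return new_weights


def write_district_report(comparison: pd.DataFrame, path: str | Path,
                          manifest: dict | None = None) -> None:
    """District report CSV (Euro columns at 2 decimals) plus a JSON manifest."""
    out = comparison.reset_index(names="district_id")
    for col in ["real_cost", "predicted_cost", "avg_real", "avg_predicted",
                "difference"]:
        out[col] = out[col].round(2)
    if "case_mix" in out.columns:
        out["case_mix"] = out["case_mix"].round(2)
    out.to_csv(path, index=False)
    if manifest is not None:
        sidecar = Path(path).with_suffix(".manifest.json")
        payload = dict(manifest)
        payload.update(comparison.attrs.get("summary", {}))
        sidecar.write_text(json.dumps(payload, indent=2, default=str))
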