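"""Patient-level population container, validation and CSV interchange.

A population is a :class:`pandas.DataFrame` with one row per person-year:

========== ============================================================
column      meaning
========== ============================================================
patient_id  opaque identifier
age         integer years >= 0
sex         1 male, 0 female
district_id health district, 1..J
acrg3       two-digit ACRG3 code (taxonomy)
core_status first digit of acrg3 (derived)
severity    severity level 1-6 (derived)
annual_cost annual primary-care pharmaceutical expenditure, Euros >= 0
copayment_flag 1 if the person pays part of the medicine cost
========== ============================================================

Healthy non-users (ACRG3 code 11) have, by definition, zero pharmaceutical
expenditure; validation enforces this.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .taxonomy import HealthStatusTaxonomy, load_taxonomy

__all__ = [
    "COLUMNS",
    "CSV_COLUMNS",
    "PopulationConfig",
    "ValidationError",
    "validate_records",
    "attach_status",
    "read_patients_csv",
    "write_patients_csv",
]

#: full in-memory column set
COLUMNS = [
    "patient_id", "age", "sex", "district_id", "acrg3",
    "core_status", "severity", "annual_cost", "copayment_flag",
]

#: on-disk interchange columns (core_status/severity are derived on read)
CSV_COLUMNS = [
    "patient_id", "age", "sex", "district_id", "acrg3",
    "annual_cost", "copayment_flag",
]

#: the non-user code whose cost is structurally zero
NON_USER_CODE = 11


class ValidationError(ValueError):
    """Raised when a population fails validation and the pipeline must stop."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__(
            "population failed validation:\n  " + "\n  ".join(violations)
        )


@dataclass
class PopulationConfig:
    """Parameters of the synthetic population generator.

    ``group_ln_cost_mean`` is the per-code location of ln(cost + 1) for
    cost-incurring patients; ``ln_noise_sd`` the homoscedastic ln-scale noise
    standard deviation.  ``zero_cost_extra_rate`` is the probability that a
    patient *outside* the non-user stratum still incurs zero cost in the year.
    ``district_skew`` optionally tilts chronic morbidity (statuses 4-9)
    towards high-skew districts to create case-mix spread.
    """

    n_patients: int
    group_proportions: dict[int, float]
    group_age_mean: dict[int, float]
    group_age_sd: dict[int, float]
    group_ln_cost_mean: dict[int, float]
    ln_noise_sd: float
    zero_cost_extra_rate: float = 0.0
    n_districts: int = 24
    district_skew: list[float] | None = None
    male_fraction: float = 0.49
    copayment_rate: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.ln_noise_sd <= 0:
            raise ValueError("ln_noise_sd must be positive")
        props = np.array(list(self.group_proportions.values()), dtype=float)
        if (props < 0).any():
            raise ValueError("group proportions must be nonnegative")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"group proportions must sum to 1 (got {props.sum():.12f})"
            )
        if not 0 <= self.zero_cost_extra_rate < 1:
            raise ValueError("zero_cost_extra_rate must be in [0, 1)")
        if self.district_skew is not None and len(self.district_skew) != self.n_districts:
            raise ValueError("district_skew length must equal n_districts")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PopulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("group_proportions", "group_age_mean", "group_age_sd",
                    "group_ln_cost_mean"):
            data[key] = {int(k): float(v) for k, v in data[key].items()}
        return cls(**data)


def attach_status(df: pd.DataFrame,
                  taxonomy: HealthStatusTaxonomy | None = None) -> pd.DataFrame:
    """Derive core_status and severity columns from acrg3 via the taxonomy."""
    taxonomy = taxonomy or load_taxonomy()
    status_map = {e.acrg3: e.core_status for e in taxonomy.entries}
    severity_map = {e.acrg3: e.severity for e in taxonomy.entries}
    out = df.copy()
    out["core_status"] = out["acrg3"].map(status_map).astype("Int64")
    out["severity"] = out["acrg3"].map(severity_map).astype("Int64")
    return out


def validate_records(df: pd.DataFrame,
                     taxonomy: HealthStatusTaxonomy | None = None,
                     raise_on_error: bool = True) -> list[str]:
    """Validate a patient table; return the list of violations found.

    Checks: non-empty input, required columns, unknown ACRG3 codes, negative
    costs, negative ages, and non-users (code 11) carrying positive cost.
    With ``raise_on_error`` (default) any violation raises
    :class:`ValidationError` so no downstream stage runs on bad data.
    """
    taxonomy = taxonomy or load_taxonomy()
    if df is None or len(df) == 0:
        raise ValidationError(["empty population: no patient records"])

    violations: list[str] = []
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        violations.append(f"missing columns: {missing}")
        if raise_on_error:
            raise ValidationError(violations)
        return violations

    unknown = set(df["acrg3"].unique()) - set(taxonomy.codes)
    if unknown:
        violations.append(f"unknown ACRG3 codes: {sorted(unknown)}")
    n_neg = int((df["annual_cost"] < 0).sum())
    if n_neg:
        violations.append(f"negative cost for {n_neg} record(s)")
    n_neg_age = int((df["age"] < 0).sum())
    if n_neg_age:
        violations.append(f"negative age for {n_neg_age} record(s)")
    bad_nonuser = int(((df["acrg3"] == NON_USER_CODE)
                       & (df["annual_cost"] > 0)).sum())
    if bad_nonuser:
        violations.append(
            f"non-user (code {NON_USER_CODE}) with positive cost: "
            f"{bad_nonuser} record(s)"
        )
    if violations and raise_on_error:
        raise ValidationError(violations)
    return violations


def write_patients_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write the interchange CSV (costs at 2 decimals, derived columns dropped)."""
    out = df[CSV_COLUMNS].copy()
    out["annual_cost"] = out["annual_cost"].round(2)
    out.to_csv(path, index=False)


def read_patients_csv(path: str | Path,
                      taxonomy: HealthStatusTaxonomy | None = None,
                      validate: bool = True) -> pd.DataFrame:
    """Read a patient CSV, derive status columns, and validate."""
    df = pd.read_csv(path)
    taxonomy = taxonomy or load_taxonomy()
    if validate:
        validate_records(df, taxonomy)
    return attach_status(df, taxonomy)
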