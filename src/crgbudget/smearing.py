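"""Duan smearing retransformation and the standardized case-mix weight chain.

Exponentiating predictions from a log-linear model underestimates the mean on
the Euro scale (E[e^eps] > 1 for mean-zero noise).  Duan's nonparametric
smearing estimator corrects this with the empirical mean of the exponentiated
ln-scale residuals:

    gamma = (1/n) * sum_k exp(eps_k)

For a core health status with ln-scale predicted value a_i, the retransformed
expenditure is  b_i = gamma * e^{a_i} - 1  Euros (undoing the +1 of the
ln(C+1) transform), and the standardized weight is  c_i = b_i / b_1 , so a
healthy (status-1) patient weighs exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regression import FitResult
from .taxonomy import CORE_STATUS_LABELS

__all__ = [
    "SmearingEstimate",
    "duan_smearing",
    "retransform_prediction",
    "derive_weights",
    "severity_multipliers",
    "weights_from_coefficients",
]


@dataclass(frozen=True)
class SmearingEstimate:
    """The smearing factor gamma and the residual count it was computed on."""

    gamma: float
    n: int

    def __float__(self) -> float:
        return self.gamma


def duan_smearing(residuals: np.ndarray) -> SmearingEstimate:
    """Smearing factor: mean of the anti-ln (exp) of the ln-scale residuals.

    For residuals of an intercept-containing OLS fit (mean zero), Jensen's
    inequality guarantees gamma >= 1.
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size == 0:
        raise ValueError("empty residual vector")
    if not np.isfinite(residuals).all():
        raise ValueError("non-finite residuals")
    return SmearingEstimate(float(np.mean(np.exp(residuals))),
                            int(residuals.size))


def retransform_prediction(a, gamma) -> float | np.ndarray:
    """Euro-scale expenditure gamma * e^a - 1 for ln-scale prediction a.

    Floored at 0: a capitation amount cannot be negative (gamma * e^a < 1
    only occurs in degenerate configurations).
    """
    g = float(gamma)
    if g <= 0:
        raise ValueError("gamma must be positive")
    a = np.asarray(a, dtype=float)
    out = np.maximum(g * np.exp(a) - 1.0, 0.0)
    return out if out.ndim else float(out)


def weights_from_coefficients(const: float, status_effects: dict[int, float],
                              gamma) -> pd.DataFrame:
    """Weight chain from an intercept and status-2..9 ln-scale effects.

    Per status i: a_i = const + effect_i (effect_1 = 0 by construction),
    b_i = gamma * e^{a_i} - 1, c_i = b_i / b_1.  Returns the weight table
    indexed by core_status with columns label, a, b, c.
    """
    rows = []
    for status in range(1, 10):
        effect = 0.0 if status == 1 else status_effects[status]
        a = const + effect
        rows.append((status, CORE_STATUS_LABELS[status], a))
    table = pd.DataFrame(rows, columns=["core_status", "label", "a"])
    table["b"] = retransform_prediction(table["a"].to_numpy(), gamma)
    b1 = table.loc[table["core_status"] == 1, "b"].iloc[0]
    if b1 <= 0:
        raise ValueError("healthy-status expenditure b_1 must be positive")
    table["c"] = table["b"] / b1
    return table.set_index("core_status")


def derive_weights(fit: FitResult, gamma) -> pd.DataFrame:
    """Standardized case-mix weights from a status-dummy fit.

    Requires an intercept plus estimable status dummies 2-9 (the status-only
    concurrent specification, model iii, by default; a severity-augmented fit
    may be passed for sensitivity analysis — the extra terms are ignored
    here, see :func:`severity_multipliers`).
    """
    params = fit.params
    needed = ["const"] + [f"status_{s}" for s in range(2, 10)]
    missing = [c for c in needed if c not in params.index]
    if missing:
        raise ValueError(f"fit lacks required terms: {missing}")
    bad = [c for c in needed if c in fit.not_estimable or pd.isna(params[c])]
    if bad:
        raise ValueError(f"not-estimable status coefficients: {bad}")
    effects = {s: float(params[f"status_{s}"]) for s in range(2, 10)}
    return weights_from_coefficients(float(params["const"]), effects, gamma)


def severity_multipliers(fit: FitResult, gamma) -> pd.Series:
    """Multiplicative severity adjustments from a severity-augmented fit.

    Level 1 is the baseline (multiplier 1); level v scales the status weight
    by the ratio of retransformed expenditures with and without the severity
    offset, (gamma * e^{const + delta_v} - 1) / (gamma * e^{const} - 1).
    """
    params = fit.params
    terms = [f"severity_{v}" for v in range(2, 7)]
    missing = [t for t in terms if t not in params.index or pd.isna(params[t])]
    if missing:
        raise ValueError(f"fit lacks severity terms: {missing}")
    const = float(params["const"])
    base = retransform_prediction(const, gamma)
    if base <= 0:
        raise ValueError("baseline retransformed expenditure must be positive")
    mult = {1: 1.0}
    for v in range(2, 7):
        mult[v] = retransform_prediction(const + float(params[f"severity_{v}"]),
                                         gamma) / base
    return pd.Series(mult, name="severity_multiplier").rename_axis("severity")


def write_weights_csv(table: pd.DataFrame, path) -> None:
    """Serialise a weight table (`core_status,label,a_ln_scale,b_euros,c_weight`)."""
    out = table.reset_index().rename(columns={
        "a": "a_ln_scale", "b": "b_euros", "c": "c_weight"})
    out["b_euros"] = out["b_euros"].round(2)
    out.to_csv(path, index=False)


def read_weights_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path).rename(columns={
        "a_ln_scale": "a", "b_euros": "b", "c_weight": "c"})
    return df.set_index("core_status")
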