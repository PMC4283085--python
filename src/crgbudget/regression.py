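"""Concurrent ln-cost regression: design matrices, OLS fits, split validation.

The dependent variable is ln(C + 1), where C is the patient's annual
primary-care pharmaceutical expenditure in Euros; adding 1 keeps zero-cost
patients in the sample (ln 1 = 0) and gives costs below one Euro a positive
log.  Six concurrent specifications combine age, sex, the eight core
health-status dummies (status 1, healthy, is the baseline) and five severity
dummies (level 1 baseline), on the whole population or on the paediatric
(age <= 14) / adult (age >= 15) cohorts:

====  =========================================  ==========
name  regressors                                 cohort
====  =========================================  ==========
i     age, sex                                   all
ii    age, sex, status dummies                   all
iii   status dummies                             all
iv    status dummies                             paediatric
v     status dummies                             adult
vi    status, severity dummies, age, sex         adult
====  =========================================  ==========

Fits are ordinary least squares (via statsmodels); the headline goodness of
fit is the corrected (adjusted) R².  Residuals are retained for the Duan
smearing retransformation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PAEDIATRIC_MAX_AGE",
    "ModelSpec",
    "MODEL_SPECS",
    "FitResult",
    "ln_transform",
    "build_design",
    "fit_ols",
    "fit_model",
    "split_validate",
    "NotEstimableWarning",
]

#: paediatric cohort boundary: "age <= 14" is paediatric, attended by
#: paediatricians in Spanish primary care
PAEDIATRIC_MAX_AGE = 14

STATUS_DUMMIES = [f"status_{s}" for s in range(2, 10)]
SEVERITY_DUMMIES = [f"severity_{v}" for v in range(2, 7)]


class NotEstimableWarning(UserWarning):
    """A dummy column has no members in the sample; its coefficient is NaN."""


@dataclass(frozen=True)
class ModelSpec:
    """One regression specification.

    cohort: 'all', 'paediatric' (age <= 14) or 'adult' (age >= 15).
    """

    name: str
    use_age: bool = False
    use_sex: bool = False
    use_status_dummies: bool = True
    use_severity_dummies: bool = False
    cohort: str = "all"

    def __post_init__(self) -> None:
        if self.cohort not in ("all", "paediatric", "adult"):
            raise ValueError(f"unknown cohort: {self.cohort!r}")

    @property
    def columns(self) -> list[str]:
        cols = ["const"]
        if self.use_age:
            cols.append("age")
        if self.use_sex:
            cols.append("sex")
        if self.use_status_dummies:
            cols.extend(STATUS_DUMMIES)
        if self.use_severity_dummies:
            cols.extend(SEVERITY_DUMMIES)
        return cols

    def cohort_mask(self, records: pd.DataFrame) -> pd.Series:
        if self.cohort == "paediatric":
            return records["age"] <= PAEDIATRIC_MAX_AGE
        if self.cohort == "adult":
            return records["age"] > PAEDIATRIC_MAX_AGE
        return pd.Series(True, index=records.index)


#: The six named specifications.
MODEL_SPECS: dict[str, ModelSpec] = {
    "i": ModelSpec("i", use_age=True, use_sex=True, use_status_dummies=False),
    "ii": ModelSpec("ii", use_age=True, use_sex=True),
    "iii": ModelSpec("iii"),
    "iv": ModelSpec("iv", cohort="paediatric"),
    "v": ModelSpec("v", cohort="adult"),
    "vi": ModelSpec("vi", use_age=True, use_sex=True,
                    use_severity_dummies=True, cohort="adult"),
}


def ln_transform(cost):
    """ln(C + 1) for annual cost C >= 0 (scalar or array)."""
    cost = np.asarray(cost, dtype=float)
    if (cost < 0).any():
        raise ValueError("cost must be nonnegative")
    out = np.log1p(cost)
    return out if out.ndim else float(out)


def build_design(records: pd.DataFrame,
                 spec: ModelSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix and ln(C+1) response for one specification.

    Columns appear in fixed order: const, age, sex, status dummies 2-9,
    severity dummies 2-6 (only those the spec uses).  A dummy column with no
    members after the cohort filter is retained and a
    :class:`NotEstimableWarning` is emitted — the fit will report its
    coefficient as not estimable rather than silently dropping the status.
    """
    sample = records.loc[spec.cohort_mask(records)]
    if len(sample) == 0:
        raise ValueError(f"cohort {spec.cohort!r} has no records")
    X = pd.DataFrame(index=sample.index)
    X["const"] = 1.0
    if spec.use_age:
        X["age"] = sample["age"].astype(float)
    if spec.use_sex:
        X["sex"] = sample["sex"].astype(float)
    if spec.use_status_dummies:
        status = sample["core_status"].astype(int)
        for s in range(2, 10):
            X[f"status_{s}"] = (status == s).astype(float)
    if spec.use_severity_dummies:
        severity = sample["severity"].astype(int)
        for v in range(2, 7):
            X[f"severity_{v}"] = (severity == v).astype(float)

    empty = [c for c in X.columns
             if c != "const" and not X[c].any()]
    for col in empty:
        warnings.warn(
            f"column {col!r} has no members in the sample; "
            "its coefficient will be reported as not estimable",
            NotEstimableWarning,
            stacklevel=2,
        )
    y = ln_transform(sample["annual_cost"].to_numpy())
    return X, y


@dataclass
class FitResult:
    """An estimated specification with diagnostics.

    ``params`` holds NaN for not-estimable columns.  ``r_squared`` is the
    corrected (adjusted) value — the headline goodness of fit —
    ``r_squared_unadj`` the plain one.  ``mse`` is the ln-scale residual mean
    square; ``residuals`` are retained for the smearing estimator.
    """

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    n: int
    r_squared: float
    r_squared_unadj: float
    f_statistic: float
    mse: float
    residuals: np.ndarray = field(repr=False)
    not_estimable: list[str] = field(default_factory=list)

    def predict_linear(self, X: pd.DataFrame) -> np.ndarray:
        """Linear (ln-scale) predictions for a design matrix."""
        cols = [c for c in X.columns if c not in self.not_estimable]
        return X[cols].to_numpy() @ self.params[cols].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.params.index,
            "estimate": self.params.to_numpy(),
            "std_error": self.bse.reindex(self.params.index).to_numpy(),
            "t_value": self.tvalues.reindex(self.params.index).to_numpy(),
        })

    def metrics(self) -> dict:
        return {
            "model": self.spec.name,
            "n": self.n,
            "r_squared": self.r_squared,
            "r_squared_unadj": self.r_squared_unadj,
            "f_statistic": self.f_statistic,
            "mse": self.mse,
            "not_estimable": list(self.not_estimable),
        }


def fit_ols(X: pd.DataFrame, y: np.ndarray,
            spec: ModelSpec | None = None) -> FitResult:
    """Ordinary least squares on a prebuilt design.

    Not-estimable (all-zero) columns are excluded from the solve and reported
    with NaN coefficients; any further rank deficiency raises.
    """
    estimable = [c for c in X.columns if c == "const" or X[c].any()]
    dropped = [c for c in X.columns if c not in estimable]
    Xe = X[estimable]
    rank = np.linalg.matrix_rank(Xe.to_numpy())
    if rank < Xe.shape[1]:
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient beyond empty dummy columns"
        )
    res = sm.OLS(y, Xe).fit()
    params = res.params.reindex(X.columns)
    bse = res.bse.reindex(X.columns)
    tvalues = res.tvalues.reindex(X.columns)
    return FitResult(
        spec=spec or ModelSpec("custom", use_status_dummies=False),
        params=params,
        bse=bse,
        tvalues=tvalues,
        n=int(res.nobs),
        r_squared=float(res.rsquared_adj),
        r_squared_unadj=float(res.rsquared),
        f_statistic=float(res.fvalue),
        mse=float(res.mse_resid),
        residuals=np.asarray(res.resid),
        not_estimable=dropped,
    )


def fit_model(records: pd.DataFrame, model: str | ModelSpec) -> FitResult:
    """Build the design for a named specification and fit it."""
    spec = MODEL_SPECS[model] if isinstance(model, str) else model
    X, y = build_design(records, spec)
    return fit_ols(X, y, spec)


def _holdout_metrics(fit: FitResult, X: pd.DataFrame,
                     y: np.ndarray) -> dict[str, float]:
    pred = fit.predict_linear(X)
    resid = y - pred
    ss_res = float(resid @ resid)
    centred = y - y.mean()
    ss_tot = float(centred @ centred)
    return {
        "n": len(y),
        "r_squared": 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
        "mse": ss_res / len(y),
    }


def split_validate(records: pd.DataFrame, model: str | ModelSpec,
                   train_fraction: float = 0.7,
                   seed: int = 0) -> tuple[FitResult, dict[str, float]]:
    """70/30-style split-sample validation.

    The cohort-filtered sample is partitioned exactly (round(n * fraction)
    training rows) by a shuffled index with its own seed, the model is fit on
    the training part, and holdout R² / MSE are computed on the rest using
    the training coefficients.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    spec = MODEL_SPECS[model] if isinstance(model, str) else model
    sample = records.loc[spec.cohort_mask(records)]
    n = len(sample)
    n_train = int(round(n * train_fraction))
    if n_train == 0 or n_train == n:
        raise ValueError("split leaves an empty partition")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train = sample.iloc[order[:n_train]]
    test = sample.iloc[order[n_train:]]
    fit = fit_model(train, spec)
    X_test, y_test = build_design(test, spec)
    return fit, _holdout_metrics(fit, X_test, y_test)
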