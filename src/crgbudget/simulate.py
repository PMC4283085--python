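"""Synthetic patient populations with the cost structure the analysis assumes.

The generator draws a population whose marginal structure matches the 2012
regional stratification: ACRG3 membership is multinomial with the observed
group shares; age is truncated-normal per group with the observed moments;
annual cost for cost-incurring patients follows

    ln(C + 1) = a_g + eps,   eps ~ Normal(0, sigma),  homoscedastic,

clamped so C >= 0, where ``a_g`` is the group's ln-scale location.  Healthy
non-users (code 11) have cost 0 structurally, and an additional fraction of
the remaining population incurs no cost in the year.  Normal ln-scale noise
gives the closed-form smearing factor gamma = E[e^eps] = exp(sigma^2 / 2), so
sigma = sqrt(2 ln gamma) makes the generator's implied smearing factor equal
to any chosen gamma.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .population import NON_USER_CODE, PopulationConfig, attach_status
from .reference import MODEL_COEFFICIENTS_2012, SMEARING_FACTOR_2012, WEIGHTS_2012
from .taxonomy import POPULATION_2012, load_taxonomy

__all__ = [
    "DEFAULT_LN_NOISE_SD",
    "generate_population",
    "default_config",
    "model_recovery_config",
]

#: ln-scale noise SD whose implied smearing factor equals the 2012 estimate:
#: sigma = sqrt(2 ln 1.693) ~= 1.026.
DEFAULT_LN_NOISE_SD: float = math.sqrt(2.0 * math.log(SMEARING_FACTOR_2012))

_AGE_MAX = 105
_CHRONIC_STATUSES = frozenset({4, 5, 6, 7, 8, 9})


def censored_mean(location: float, sd: float) -> float:
    """E[max(Z, 0)] for Z ~ Normal(location, sd).

    The cost floor C >= 0 turns ln(C+1) = location + noise into a response
    censored at zero; this closed form gives its true conditional mean.
    """
    alpha = location / sd
    return location * stats.norm.cdf(alpha) + sd * stats.norm.pdf(alpha)


def decensor_location(target: float, sd: float) -> float:
    """Location m such that E[max(Normal(m, sd), 0)] equals ``target``.

    Inverts :func:`censored_mean` (strictly increasing in m) so that groups
    whose ln-scale location is small relative to the noise SD still have the
    intended conditional mean of ln(C+1) after the cost floor is applied.
    """
    if target <= 0:
        raise ValueError("target mean must be positive")
    from scipy.optimize import brentq
    lo = target - 5.0 * sd
    return float(brentq(lambda m: censored_mean(m, sd) - target, lo, target,
                        xtol=1e-12))


def _truncnorm_ages(rng: np.random.Generator, mean: float, sd: float,
                    size: int) -> np.ndarray:
    a, b = (0.0 - mean) / sd, (_AGE_MAX - mean) / sd
    ages = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)
    return np.floor(ages).astype(int)


def _assign_districts(rng: np.random.Generator, status: np.ndarray,
                      config: PopulationConfig) -> np.ndarray:
    n = len(status)
    districts = np.arange(1, config.n_districts + 1)
    if config.district_skew is None:
        return rng.choice(districts, size=n)
    skew = np.asarray(config.district_skew, dtype=float)
    if (np.abs(skew) >= 1).any():
        raise ValueError("district_skew entries must lie in (-1, 1)")
    # chronic patients are tilted towards high-skew districts, the rest away,
    # so district populations stay roughly even while case mix spreads out
    p_chronic = (1.0 + skew) / (1.0 + skew).sum()
    p_other = (1.0 - skew) / (1.0 - skew).sum()
    chronic = np.isin(status, list(_CHRONIC_STATUSES))
    out = np.empty(n, dtype=int)
    out[chronic] = rng.choice(districts, size=int(chronic.sum()), p=p_chronic)
    out[~chronic] = rng.choice(districts, size=int((~chronic).sum()), p=p_other)
    return out


def generate_population(config: PopulationConfig) -> pd.DataFrame:
    """Draw a synthetic patient population.

    Returns a validated patient DataFrame (see :mod:`crgbudget.population`)
    with derived status columns attached.  Fully deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    taxonomy = load_taxonomy()

    codes = np.array(sorted(config.group_proportions), dtype=int)
    unknown = [c for c in codes if c not in taxonomy]
    if unknown:
        raise ValueError(f"unknown ACRG3 codes in config: {unknown}")
    props = np.array([config.group_proportions[c] for c in codes], dtype=float)
    props = props / props.sum()

    n = config.n_patients
    acrg3 = rng.choice(codes, size=n, p=props)
    status = acrg3 // 10

    ages = np.empty(n, dtype=int)
    for code in codes:
        mask = acrg3 == code
        m = int(mask.sum())
        if m:
            ages[mask] = _truncnorm_ages(
                rng, config.group_age_mean[code], config.group_age_sd[code], m
            )

    sex = rng.binomial(1, config.male_fraction, size=n)
    district = _assign_districts(rng, status, config)

    a_g = np.array([config.group_ln_cost_mean[c] for c in codes], dtype=float)
    a_by_patient = a_g[np.searchsorted(codes, acrg3)]
    eps = rng.normal(0.0, config.ln_noise_sd, size=n)
    cost = np.maximum(np.exp(a_by_patient + eps) - 1.0, 0.0)

    zero = acrg3 == NON_USER_CODE
    if config.zero_cost_extra_rate > 0:
        extra = rng.random(n) < config.zero_cost_extra_rate
        zero = zero | (extra & (acrg3 != NON_USER_CODE))
    cost[zero] = 0.0

    copay = rng.binomial(1, config.copayment_rate, size=n)

    df = pd.DataFrame({
        "patient_id": [f"P{i:08d}" for i in range(1, n + 1)],
        "age": ages,
        "sex": sex,
        "district_id": district,
        "acrg3": acrg3,
        "annual_cost": cost,
        "copayment_flag": copay,
    })
    return attach_status(df, taxonomy)


def _table1_proportions() -> dict[int, float]:
    total = sum(v["n"] for v in POPULATION_2012.values())
    return {code: v["n"] / total for code, v in POPULATION_2012.items()}


def default_config(n_patients: int = 100_000, seed: int = 0,
                   n_districts: int = 24) -> PopulationConfig:
    """Generator configuration emulating the 2012 regional population.

    Group shares and age moments come from the observed stratification;
    the ln-scale cost location of each code is the status-level predicted
    ln(C+1) of the 2012 weight chain, shared across the status's codes; the
    noise SD makes the implied smearing factor 1.693; 8% of patients outside
    the non-user stratum incur zero cost.  A fixed linear district tilt
    spreads chronic morbidity across the 24 districts to create inter-district
    case-mix variation of the order seen regionally.
    """
    props = _table1_proportions()
    ln_mean = {code: WEIGHTS_2012[code // 10]["a"] for code in props}
    skew = np.linspace(-0.15, 0.15, n_districts).tolist()
    return PopulationConfig(
        n_patients=n_patients,
        group_proportions=props,
        group_age_mean={c: v["age_mean"] for c, v in POPULATION_2012.items()},
        group_age_sd={c: v["age_sd"] for c, v in POPULATION_2012.items()},
        group_ln_cost_mean=ln_mean,
        ln_noise_sd=DEFAULT_LN_NOISE_SD,
        zero_cost_extra_rate=0.08,
        n_districts=n_districts,
        district_skew=skew,
        seed=seed,
    )


def model_recovery_config(n_patients: int = 100_000, seed: int = 0,
                          model: str = "iii",
                          n_districts: int = 24) -> PopulationConfig:
    """Configuration under which the cost model is exactly the linear DGP.

    Every patient's ln(C+1) is the model's linear predictor plus
    homoscedastic normal noise: the non-user stratum (whose cost is
    structurally zero, not linear) is removed and no extra zero-cost mass is
    injected, so an OLS refit is consistent for the generating coefficients.
    Group locations are de-censored (:func:`decensor_location`) so that the
    cost floor C >= 0 does not shift any group's true conditional mean away
    from its linear predictor.  Used for parameter-recovery checks;
    :func:`default_config` is the realistic population.
    """
    coeffs = MODEL_COEFFICIENTS_2012[model]
    if any(k in coeffs for k in ("age", "sex")):
        raise ValueError(
            "recovery config supports status-only specifications"
        )
    props = _table1_proportions()
    props.pop(NON_USER_CODE)
    total = sum(props.values())
    props = {c: p / total for c, p in props.items()}
    ln_mean = {
        code: decensor_location(
            coeffs["const"] + coeffs.get(f"status_{code // 10}", 0.0),
            DEFAULT_LN_NOISE_SD,
        )
        for code in props
    }
    return PopulationConfig(
        n_patients=n_patients,
        group_proportions=props,
        group_age_mean={c: POPULATION_2012[c]["age_mean"] for c in props},
        group_age_sd={c: POPULATION_2012[c]["age_sd"] for c in props},
        group_ln_cost_mean=ln_mean,
        ln_noise_sd=DEFAULT_LN_NOISE_SD,
        zero_cost_extra_rate=0.0,
        n_districts=n_districts,
        district_skew=None,
        seed=seed,
    )
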