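"""Published 2012 Valencian Community calibration of the expenditure model.

These constants are the reference estimates from the regional 2012 study
(N = 4,654,362): OLS coefficients of the six concurrent ln(C+1) model
specifications, the Duan smearing factor, and the derived case-mix weight
table.  They parameterise the synthetic generator's defaults and serve as
fixed inputs when re-deriving the weight chain.
"""

from __future__ import annotations

__all__ = [
    "SMEARING_FACTOR_2012",
    "MODEL_COEFFICIENTS_2012",
    "MODEL_FIT_2012",
    "WEIGHTS_2012",
]

#: Duan smearing factor estimated on the 2012 model-iii residuals.
SMEARING_FACTOR_2012: float = 1.693

#: OLS coefficients by model specification (ln(C+1) Euro-ln scale).
#: Status dummies are relative to core health status 1 (healthy);
#: severity dummies relative to level 1.
MODEL_COEFFICIENTS_2012: dict[str, dict[str, float]] = {
    "i": {"const": 1.159, "age": 0.057, "sex": -0.461},
    "ii": {
        "const": 1.391, "age": 0.016, "sex": -0.324,
        "status_2": 1.751, "status_3": 2.179, "status_4": 3.201,
        "status_5": 3.399, "status_6": 4.352, "status_7": 5.055,
        "status_8": 4.325, "status_9": 4.217,
    },
    "iii": {
        "const": 1.736,
        "status_2": 1.816, "status_3": 2.440, "status_4": 3.691,
        "status_5": 3.799, "status_6": 4.992, "status_7": 5.760,
        "status_8": 4.870, "status_9": 4.493,
    },
    "iv": {
        "const": 1.865,
        "status_2": 1.262, "status_3": 1.548, "status_4": 2.134,
        "status_5": 2.119, "status_6": 3.120, "status_7": 3.920,
        "status_8": 1.891, "status_9": 3.129,
    },
    "v": {
        "const": 1.697,
        "status_2": 1.955, "status_3": 2.537, "status_4": 3.743,
        "status_5": 3.954, "status_6": 5.048, "status_7": 5.801,
        "status_8": 4.946, "status_9": 4.608,
    },
    "vi": {
        "const": 0.906, "age": 0.026, "sex": -0.388,
        "status_2": 1.873, "status_3": 2.214, "status_4": 2.951,
        "status_5": 3.291, "status_6": 3.946, "status_7": 4.400,
        "status_8": 3.713, "status_9": 3.785,
        "severity_2": 0.406, "severity_3": 0.613, "severity_4": 0.701,
        "severity_5": 0.823, "severity_6": 0.878,
    },
}

#: Sample size and corrected R-squared of each 2012 fit.
MODEL_FIT_2012: dict[str, dict[str, float]] = {
    "i": {"n": 4_654_362, "r_squared": 0.275},
    "ii": {"n": 4_654_362, "r_squared": 0.569},
    "iii": {"n": 4_654_362, "r_squared": 0.550},
    "iv": {"n": 739_525, "r_squared": 0.158},
    "v": {"n": 3_914_837, "r_squared": 0.571},
    "vi": {"n": 3_914_837, "r_squared": 0.603},
}

#: 2012 weight chain by core health status: a = predicted ln(C+1);
#: b = gamma*e^a - 1 (Euros); c = b_i / b_1 (standard weight).
WEIGHTS_2012: dict[int, dict[str, float]] = {
    1: {"a": 1.736, "b": 8.607, "c": 1.0},
    2: {"a": 3.552, "b": 58.068, "c": 6.75},
    3: {"a": 4.176, "b": 109.242, "c": 12.69},
    4: {"a": 5.427, "b": 384.212, "c": 44.64},
    5: {"a": 5.535, "b": 427.851, "c": 49.71},
    6: {"a": 6.728, "b": 1413.267, "c": 164.21},
    7: {"a": 7.496, "b": 3048.575, "c": 354.21},
    8: {"a": 6.606, "b": 1250.432, "c": 145.29},
    9: {"a": 6.229, "b": 858.032, "c": 99.69},
}
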