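"""Shared fixtures: taxonomy, synthetic populations, published district table."""

import pandas as pd
import pytest

from crgbudget import (
    default_config,
    generate_population,
    load_taxonomy,
    model_recovery_config,
)

# Published 2013 per-district figures (case mix, real and predicted
# expenditure in Euros, head count, and the printed per-person averages and
# difference) used to verify the report column arithmetic.
_DISTRICT_ROWS = [
    (1, 35.29, 22_404_536.70, 24_714_441.39, 87_448, 256.20, 282.62, -26.41),
    (2, 32.34, 68_608_549.95, 68_793_348.13, 265_636, 258.28, 258.98, -0.70),
    (3, 35.94, 47_720_043.15, 51_816_313.29, 180_051, 265.04, 287.79, -22.75),
    (4, 35.20, 43_430_451.48, 41_221_848.93, 146_219, 297.02, 281.92, 15.10),
    (5, 33.39, 88_177_744.42, 85_893_722.31, 321_192, 274.53, 267.42, 7.11),
    (6, 32.15, 72_489_772.23, 75_357_459.28, 292_715, 247.65, 257.44, -9.80),
    (7, 36.18, 49_825_584.93, 52_580_973.57, 181_468, 274.57, 289.75, -15.18),
    (8, 43.10, 15_989_816.02, 16_733_570.96, 48_479, 329.83, 345.17, -15.34),
    (9, 34.48, 99_701_853.24, 93_549_589.70, 338_770, 294.31, 276.14, 18.16),
    (10, 34.22, 97_918_781.79, 93_218_916.90, 340_151, 287.87, 274.05, 13.82),
    (11, 34.43, 66_559_137.30, 68_259_770.67, 247_529, 268.89, 275.76, -6.87),
    (12, 34.13, 49_736_535.24, 46_595_511.68, 170_456, 291.79, 273.36, 18.43),
    (13, 31.76, 41_575_756.05, 39_612_929.41, 155_755, 266.93, 254.33, 12.60),
    (14, 37.28, 60_142_256.18, 57_547_721.39, 192_759, 312.01, 298.55, 13.46),
    (15, 37.36, 40_973_176.21, 40_243_795.62, 134_490, 304.66, 299.23, 5.42),
    (16, 33.48, 43_043_816.92, 45_423_640.85, 169_389, 254.11, 268.16, -14.05),
    (17, 33.97, 52_476_085.67, 54_889_413.61, 201_780, 260.07, 272.03, -11.96),
    (18, 35.24, 54_265_489.06, 52_482_585.31, 185_984, 291.78, 282.19, 9.59),
    (19, 34.15, 66_260_672.07, 69_172_538.68, 252_932, 261.97, 273.48, -11.51),
    (20, 34.54, 39_467_859.22, 42_750_213.31, 154_533, 255.40, 276.64, -21.24),
    (21, 34.29, 41_080_531.21, 43_366_934.60, 157_932, 260.12, 274.59, -14.48),
    (22, 35.09, 44_150_450.69, 44_686_006.13, 159_031, 277.62, 280.99, -3.37),
    (23, 35.01, 55_746_290.13, 54_498_692.53, 194_401, 286.76, 280.34, 6.42),
    (24, 32.31, 40_153_602.94, 38_488_854.55, 148_732, 269.97, 258.78, 11.19),
]

DISTRICT_COLUMNS = ["district_id", "case_mix", "real_cost", "predicted_cost",
                    "population", "avg_real", "avg_predicted", "difference"]


@pytest.fixture(scope="session")
def district_reference():
    """The 24 published district rows, indexed by district_id."""
    return (pd.DataFrame(_DISTRICT_ROWS, columns=DISTRICT_COLUMNS)
            .set_index("district_id"))


@pytest.fixture(scope="session")
def taxonomy():
    return load_taxonomy()


@pytest.fixture(scope="session")
def small_population():
    """Realistic synthetic population (zero strata included), n = 20,000."""
    return generate_population(default_config(n_patients=20_000, seed=11))


@pytest.fixture(scope="session")
def recovery_population():
    """Population whose ln-cost model is exactly the status-only linear DGP."""
    return generate_population(model_recovery_config(n_patients=60_000, seed=7))
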