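"""ACRG3 taxonomy: Clinical Risk Group core health statuses and severity levels.

The Clinical Risk Groups (CRG) system classifies every person into exactly one
mutually exclusive group from their recorded diagnoses.  At the third
aggregation tier (ACRG3) a person carries a two-digit code whose first digit is
the *core health status* (1 healthy ... 9 catastrophic conditions) and whose
second digit, for statuses 3-9, is a *severity level* 1-6.  Status-1 and
status-2 codes describe qualitatively distinct healthy/acute sub-populations
(non-users, deliveries, pregnancies, ...) and carry no severity gradation;
they are assigned severity 1, which is inert because severity level 1 is the
regression baseline.

This module also embeds the 2012 Valencian Community population stratification
(4.65 million people across 24 health districts): per-code population counts,
shares, mean annual primary-care pharmaceutical expenditure (Euros) and age
moments.  Three population cells of the published stratification are
typographically truncated; they are repaired from the share column, which is
internally coherent (shares sum to ~100%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "TaxonomyEntry",
    "HealthStatusTaxonomy",
    "load_taxonomy",
    "CORE_STATUS_LABELS",
    "POPULATION_2012",
]


@dataclass(frozen=True)
class TaxonomyEntry:
    """One ACRG3 code: (core_status, severity) plus its descriptive label."""

    acrg3: int
    core_status: int
    severity: int
    label: str


#: Human-readable names of the nine core health statuses.
CORE_STATUS_LABELS: dict[int, str] = {
    1: "Healthy",
    2: "History of significant acute disease",
    3: "Single minor chronic disease",
    4: "Minor chronic disease in multiple organ systems",
    5: "Single dominant or moderate chronic disease",
    6: "Chronic disease in 2 or more organ systems",
    7: "Dominant chronic disease in 3 or more organ systems",
    8: "Dominant and metastatic malignancies",
    9: "Catastrophic conditions",
}

# (acrg3, label, N, share, mean expenditure EUR, mean age, sd age).
# N for codes 20, 42 and 94 is repaired from the share column (truncated cells
# in the published table).
_TABLE = [
    (10, "Healthy", 1_633_686, 0.3510, 42.63, 28.56, 19.05),
    (11, "Healthy Non-User", 784_168, 0.1685, 0.0, 36.21, 16.99),
    (12, "Delivery without Other Significant Illness", 28_921, 0.0062, 49.30, 30.56, 8.41),
    (14, "Pregnancy without Other Significant Illness", 19_451, 0.0042, 35.92, 31.26, 6.93),
    (15, "Evidence of Significant Chronic or Acute Diagnosis without Other Significant Illness",
     152_488, 0.0328, 190.76, 40.35, 23.00),
    (20, "History Of Significant Acute Disease", 193_194, 0.0415, 95.96, 33.23, 19.65),
    (22, "Delivery with History of Significant Acute Illness", 15_875, 0.0034, 209.51, 33.87, 10.84),
    (24, "Pregnancy with History of Significant Acute Illness", 7_108, 0.0015, 64.70, 31.83, 5.99),
    (25, "Evidence of Significant Chronic or Acute Diagnosis with History of Significant Acute Illness",
     44_836, 0.0096, 166.72, 38.06, 21.98),
    (31, "Single Minor Chronic Disease Level - 1", 403_148, 0.0866, 190.25, 45.58, 18.58),
    (32, "Single Minor Chronic Disease Level - 2", 41_173, 0.0088, 258.48, 43.19, 19.23),
    (41, "Minor Chronic Disease In Multiple Organ Systems Level - 1", 90_903, 0.0195, 339.85, 55.72, 15.69),
    (42, "Minor Chronic Disease In Multiple Organ Systems Level - 2", 25_134, 0.0054, 515.28, 61.58, 13.52),
    (43, "Minor Chronic Disease In Multiple Organ Systems Level - 3", 34_801, 0.0075, 520.02, 57.91, 15.38),
    (44, "Minor Chronic Disease In Multiple Organ Systems Level - 4", 5_204, 0.0011, 704.89, 59.07, 14.99),
    (51, "Single Dominant Or Moderate Chronic Disease Level - 1", 484_232, 0.1040, 528.68, 54.76, 21.09),
    (52, "Single Dominant Or Moderate Chronic Disease Level - 2", 135_731, 0.0292, 739.94, 54.37, 22.66),
    (53, "Single Dominant Or Moderate Chronic Disease Level - 3", 39_795, 0.0086, 1108.05, 59.30, 19.73),
    (54, "Single Dominant Or Moderate Chronic Disease Level - 4", 5_133, 0.0011, 1061.65, 63.83, 21.39),
    (55, "Single Dominant Or Moderate Chronic Disease Level - 5", 9_556, 0.0021, 1348.04, 66.70, 17.46),
    (56, "Single Dominant Or Moderate Chronic Disease Level - 6", 761, 0.0002, 1961.34, 51.56, 18.79),
    (61, "Significant Chronic Disease In Multiple Organ Systems Level - 1", 217_363, 0.0467, 994.26, 66.93, 15.42),
    (62, "Significant Chronic Disease In Multiple Organ Systems Level - 2", 93_125, 0.0200, 1362.09, 69.14, 14.57),
    (63, "Significant Chronic Disease In Multiple Organ Systems Level - 3", 62_212, 0.0134, 1567.73, 70.90, 13.95),
    (64, "Significant Chronic Disease In Multiple Organ Systems Level - 4", 40_647, 0.0087, 1835.01, 72.87, 13.26),
    (65, "Significant Chronic Disease In Multiple Organ Systems Level - 5", 19_282, 0.0041, 2074.03, 75.06, 13.02),
    (66, "Significant Chronic Disease In Multiple Organ Systems Level - 6", 2_259, 0.0005, 2087.73, 75.24, 13.40),
    (71, "Dominant Chronic Disease In Three Or More Organ Systems Level - 1", 7_202, 0.0015, 1861.56, 73.70, 10.35),
    (72, "Dominant Chronic Disease In Three Or More Organ Systems Level - 2", 5_913, 0.0013, 2159.61, 74.88, 10.54),
    (73, "Dominant Chronic Disease In Three Or More Organ Systems Level - 3", 12_577, 0.0027, 2420.64, 76.04, 10.33),
    (74, "Dominant Chronic Disease In Three Or More Organ Systems Level - 4", 3_587, 0.0008, 2677.64, 77.33, 9.95),
    (75, "Dominant Chronic Disease In Three Or More Organ Systems Level - 5", 2_694, 0.0006, 2784.93, 77.07, 10.08),
    (76, "Dominant Chronic Disease In Three Or More Organ Systems Level - 6", 1_076, 0.0002, 2528.73, 76.05, 10.06),
    (81, "Dominant, Metastatic, And Complicated Malignancies Level - 1", 1_677, 0.0004, 800.04, 61.41, 16.28),
    (82, "Dominant, Metastatic, And Complicated Malignancies Level - 2", 5_692, 0.0012, 1223.61, 62.59, 16.67),
    (83, "Dominant, Metastatic, And Complicated Malignancies Level - 3", 6_419, 0.0014, 1649.05, 66.99, 14.72),
    (84, "Dominant, Metastatic, And Complicated Malignancies Level - 4", 4_878, 0.0010, 2021.68, 69.61, 13.66),
    (85, "Dominant, Metastatic, And Complicated Malignancies Level - 5", 1_389, 0.0003, 2131.74, 70.86, 12.19),
    (91, "Catastrophic Conditions Level - 1", 1_895, 0.0004, 1632.93, 44.83, 22.15),
    (92, "Catastrophic Conditions Level - 2", 3_647, 0.0008, 1164.40, 46.30, 16.97),
    (93, "Catastrophic Conditions Level - 3", 1_857, 0.0004, 1944.29, 53.82, 19.86),
    (94, "Catastrophic Conditions Level - 4", 1_862, 0.0004, 1949.96, 52.68, 16.77),
    (95, "Catastrophic Conditions Level - 5", 976, 0.0002, 2244.09, 63.49, 16.67),
    (96, "Catastrophic Conditions Level - 6", 515, 0.0001, 2368.46, 65.04, 16.37),
]

#: 2012 population stratification by ACRG3 code:
#: ``{acrg3: {"n": ..., "share": ..., "mean_cost": ..., "age_mean": ..., "age_sd": ...}}``
POPULATION_2012: dict[int, dict[str, float]] = {
    code: {"n": n, "share": share, "mean_cost": cost, "age_mean": am, "age_sd": asd}
    for code, _label, n, share, cost, am, asd in _TABLE
}


def _severity_of(code: int) -> int:
    # Statuses 1-2 carry no severity level; the trailing digit distinguishes
    # sub-populations (non-user, delivery, pregnancy), not severity.
    return 1 if code < 30 else code % 10


@dataclass(frozen=True)
class HealthStatusTaxonomy:
    """The 44-code ACRG3 taxonomy with lookup helpers.

    Every code maps to exactly one (core_status, severity) pair.  Built once
    by :func:`load_taxonomy`; instances are immutable.
    """

    entries: tuple[TaxonomyEntry, ...]
    _by_code: dict[int, TaxonomyEntry] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_by_code", {e.acrg3: e for e in self.entries})

    @property
    def codes(self) -> list[int]:
        return [e.acrg3 for e in self.entries]

    def __contains__(self, acrg3: int) -> bool:
        return acrg3 in self._by_code

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, acrg3: int) -> TaxonomyEntry:
        """Return the entry for ``acrg3``; raise KeyError for unknown codes."""
        try:
            return self._by_code[acrg3]
        except KeyError:
            raise KeyError(f"unknown ACRG3 code: {acrg3}") from None

    def core_status(self, acrg3: int) -> int:
        return self.lookup(acrg3).core_status

    def severity(self, acrg3: int) -> int:
        return self.lookup(acrg3).severity

    def codes_for_status(self, core_status: int) -> list[int]:
        """All ACRG3 codes belonging to one core health status."""
        return [e.acrg3 for e in self.entries if e.core_status == core_status]

    def codes_for(self, core_status: int, severity: int) -> list[int]:
        """All codes with the given (core_status, severity) pair."""
        return [
            e.acrg3
            for e in self.entries
            if e.core_status == core_status and e.severity == severity
        ]


def load_taxonomy() -> HealthStatusTaxonomy:
    """Build the full 44-code ACRG3 taxonomy.

    >>> tax = load_taxonomy()
    >>> tax.core_status(61), tax.severity(61)
    (6, 1)
    """
    entries = tuple(
        TaxonomyEntry(code, code // 10, _severity_of(code), label)
        for code, label, *_ in _TABLE
    )
    return HealthStatusTaxonomy(entries)
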