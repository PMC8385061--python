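"""Published clinical composition of the breast-cancer cohort.

The screening study enrolled 36 women with primary breast cancer and 36
age-matched healthy donors. The tables below carry the printed
histology and AJCC/UICC stage counts of the cancer group; they are
inputs for cohort-table arithmetic (fractions of the cohort by histology
or stage), not measurements this package produces.
"""

from __future__ import annotations

COHORT_SIZE = 36

#: histologic type of the 36 breast-cancer cases
HISTOLOGY_COUNTS: dict[str, int] = {
    "invasive ductal carcinoma": 32,
    "invasive lobular carcinoma": 4,
}

#: AJCC/UICC stage of the 36 breast-cancer cases
STAGE_COUNTS: dict[str, int] = {
    "0": 2,
    "I": 22,
    "IIIa": 4,
    "IIIb": 1,
    "IIIc": 3,
    "IVa": 1,
    "undetermined": 3,
}


def percent_of_cohort(counts: dict[str, int], members: list[str], total: int | None = None) -> float:
    """Percentage of the cohort falling in the listed categories,
    rounded to one decimal (the convention of clinical summary tables)."""
    if total is None:
        total = sum(counts.values())
    missing = [m for m in members if m not in counts]
    if missing:
        raise KeyError(f"unknown categories: {missing}")
    return round(100.0 * sum(counts[m] for m in members) / total, 1)
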