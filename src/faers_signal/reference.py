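"""Reference summary counts for CDK4/6-inhibitor infection cases in FAERS.

These are the published per-drug summary counts of primary-suspect
infection-related adverse-event cases for palbociclib, ribociclib and
abemaciclib in FAERS between 2015Q1 and 2022Q3 (892, 337 and 52 cases):
sex, age-band, reporting-year, reporting-country and outcome-event
marginals, plus the severity-by-sex and severity-by-age cross-tables used
for the chi-square comparisons.

:func:`reference_case_sets` rebuilds per-case records from these marginal
counts so the descriptive summaries can be recomputed through the package.
The rebuilt cases are **synthetic reconstructions**: each marginal is
reproduced exactly, but attributes are assigned independently, so joint
distributions (beyond the stated marginals) and per-case ages are
arbitrary.  They are suitable only for checking count/percentage
arithmetic, not for any analysis of joint structure.
"""

from __future__ import annotations

import pandas as pd

from .model import CaseReport, DrugEntry, ReportSet

DRUGS: tuple[str, ...] = ("palbociclib", "ribociclib", "abemaciclib")

#: Sex of enrolled cases per drug.
SEX_COUNTS: dict[str, dict[str, int]] = {
    "palbociclib": {"female": 838, "male": 10, "unknown": 44},
    "ribociclib": {"female": 324, "male": 7, "unknown": 6},
    "abemaciclib": {"female": 44, "male": 0, "unknown": 8},
}

#: Age bands of enrolled cases per drug.
AGE_BAND_COUNTS: dict[str, dict[str, int]] = {
    "palbociclib": {"<40": 24, "40-64": 323, ">=65": 415, "unknown": 130},
    "ribociclib": {"<40": 10, "40-64": 83, ">=65": 115, "unknown": 129},
    "abemaciclib": {"<40": 1, "40-64": 8, ">=65": 15, "unknown": 28},
}

#: Reporting year of enrolled cases per drug.
YEAR_COUNTS: dict[str, dict[int, int]] = {
    "palbociclib": {2015: 21, 2016: 45, 2017: 152, 2018: 134, 2019: 130,
                    2020: 122, 2021: 120, 2022: 168},
    "ribociclib": {2017: 10, 2018: 40, 2019: 58, 2020: 67, 2021: 93, 2022: 69},
    "abemaciclib": {2019: 9, 2020: 12, 2021: 21, 2022: 10},
}

#: Reporting country of enrolled cases per drug ("other" pools the rest).
COUNTRY_COUNTS: dict[str, dict[str, int]] = {
    "palbociclib": {"united states": 768, "germany": 5, "united kingdom": 9,
                    "argentina": 32, "canada": 7, "puerto rico": 12, "japan": 9,
                    "other": 50},
    "ribociclib": {"united states": 60, "germany": 56, "united kingdom": 40,
                   "argentina": 8, "canada": 12, "other": 161},
    "abemaciclib": {"united states": 35, "germany": 3, "united kingdom": 3,
                    "japan": 3, "other": 8},
}

#: Outcome events per drug (mutually exclusive categories).
OUTCOME_COUNTS: dict[str, dict[str, int]] = {
    "palbociclib": {"hospitalization": 210, "death": 50, "life_threatening": 4,
                    "disability": 0, "others": 204, "unknown": 424},
    "ribociclib": {"hospitalization": 152, "death": 62, "life_threatening": 11,
                   "disability": 3, "others": 92, "unknown": 17},
    "abemaciclib": {"hospitalization": 9, "death": 9, "life_threatening": 6,
                    "disability": 1, "others": 14, "unknown": 13},
}

_CATEGORY_TO_OUTCOMES = {
    "hospitalization": frozenset({"HO"}),
    "death": frozenset({"DE"}),
    "life_threatening": frozenset({"LT"}),
    "disability": frozenset({"DS"}),
    "others": frozenset({"OT"}),
    "unknown": frozenset(),
}

_BAND_AGE = {"<40": 35.0, "40-64": 55.0, ">=65": 75.0, "unknown": None}


def severity_by_sex_table() -> pd.DataFrame:
    """Severity-group cross-table by sex (serious vs non-serious columns)."""
    return pd.DataFrame(
        {"serious": [500, 6, 11], "non_serious": [293, 1, 17]},
        index=["female", "male", "unknown"],
    )


def severity_by_age_table() -> pd.DataFrame:
    """Severity-group cross-table by age band."""
    return pd.DataFrame(
        {"serious": [18, 171, 205, 123], "non_serious": [5, 96, 138, 71]},
        index=["<40", "40-64", ">=65", "unknown"],
    )


def _spread(counts: dict, total: int) -> list:
    """Expand a category->count mapping into a per-case list of length total."""
    values = []
    for category, n in counts.items():
        values.extend([category] * n)
    if len(values) != total:
        raise ValueError(f"marginal counts sum to {len(values)}, expected {total}")
    return values


def reference_case_sets() -> dict[str, ReportSet]:
    """Synthetic per-case reconstruction of the reference marginal counts.

    Each drug's cases carry the drug as primary suspect and a single
    placeholder reaction; sex, age band (mapped to a representative age),
    reporting year, country and outcome category each reproduce their
    published marginal exactly, assigned independently across cases.
    """
    out: dict[str, ReportSet] = {}
    for drug in DRUGS:
        total = sum(SEX_COUNTS[drug].values())
        sexes = _spread(SEX_COUNTS[drug], total)
        bands = _spread(AGE_BAND_COUNTS[drug], total)
        years = _spread(YEAR_COUNTS[drug], total)
        countries = _spread(COUNTRY_COUNTS[drug], total)
        outcome_cats = _spread(OUTCOME_COUNTS[drug], total)
        reports = [
            CaseReport(
                case_id=f"{drug[:4]}-{i:04d}",
                version_key=f"{years[i]}Q1-1",
                report_year=years[i],
                drugs=(DrugEntry(name=drug, role_code="PS"),),
                reactions=("infection",),
                outcomes=_CATEGORY_TO_OUTCOMES[outcome_cats[i]],
                sex=sexes[i],
                age_years=_BAND_AGE[bands[i]],
                country=countries[i],
            )
            for i in range(total)
        ]
        out[drug] = ReportSet(reports)
    return out
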