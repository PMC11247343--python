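"""Descriptive and inferential summaries of enrolled case sets.

Covers the downstream analyses run on the primary-suspect infection
cases: the clinical-characteristics table (sex, age bands, reporting year
and country), the outcome-event table, the serious/non-serious severity
split, Pearson chi-square comparisons between severity groups, and the
yearly trend of infection cases as a proportion of all primary-suspect
reports.

Severity is defined on FAERS outcome codes: a case is *serious* when it
carries any of HO (hospitalization), DE (death), LT (life-threatening) or
DS (disability); *non-serious* when its only outcome codes are OT
("other"); *unknown* when it carries no outcome code at all.  For the
outcome table each case is assigned to exactly one category by the
precedence death > life-threatening > disability > hospitalization >
other, so the outcome columns sum to the case totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    CaseReport,
    DegenerateTableError,
    ReportSet,
    SERIOUS_OUTCOMES,
)

AGE_BANDS: tuple[str, ...] = ("<40", "40-64", ">=65", "unknown")

#: Outcome categories in display order, with their outcome codes.
OUTCOME_CATEGORIES: tuple[tuple[str, str], ...] = (
    ("hospitalization", "HO"),
    ("death", "DE"),
    ("life_threatening", "LT"),
    ("disability", "DS"),
    ("others", "OT"),
)

#: Default precedence used to pick a single category per case.
DEFAULT_OUTCOME_PRECEDENCE: tuple[str, ...] = ("DE", "LT", "DS", "HO", "OT")

_CODE_TO_CATEGORY = {code: name for name, code in OUTCOME_CATEGORIES}


def classify_severity(report: CaseReport) -> str:
    """``"serious"``, ``"non_serious"`` or ``"unknown"`` for one case."""
    if report.outcomes & SERIOUS_OUTCOMES:
        return "serious"
    if report.outcomes:
        return "non_serious"
    return "unknown"


def assign_outcome_category(
    report: CaseReport, precedence: Sequence[str] = DEFAULT_OUTCOME_PRECEDENCE
) -> str:
    """Single outcome category per case by precedence; ``"unknown"`` if none."""
    for code in precedence:
        if code in report.outcomes:
            return _CODE_TO_CATEGORY[code]
    return "unknown"


def age_band(age_years: float | None) -> str:
    if age_years is None:
        return "unknown"
    if age_years < 40:
        return "<40"
    if age_years < 65:
        return "40-64"
    return ">=65"


def _counts_frame(
    case_sets: Mapping[str, ReportSet], value_of, categories: Sequence[str] | None = None
) -> pd.DataFrame:
    """Category x drug count table with a total column."""
    drugs = list(case_sets)
    per_drug = {
        drug: pd.Series([value_of(r) for r in cases], dtype=object).value_counts()
        for drug, cases in case_sets.items()
    }
    index = (
        list(categories)
        if categories is not None
        else sorted(set().union(*(set(s.index) for s in per_drug.values())) if per_drug else set())
    )
    df = pd.DataFrame(0, index=index, columns=drugs, dtype=int)
    for drug, counts in per_drug.items():
        for cat, n in counts.items():
            if cat in df.index:
                df.loc[cat, drug] = int(n)
    df["total"] = df.sum(axis=1)
    return df


def percentages(counts: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Column-wise percentages of a count table, rounded to ``decimals``."""
    sums = counts.sum(axis=0)
    return (counts / sums.replace(0, np.nan) * 100).round(decimals)


@dataclass(frozen=True)
class CharacteristicsSummary:
    """Per-drug and total clinical characteristics of enrolled cases.

    Each attribute is a category x drug count DataFrame (last column
    ``total``); ``age_stats`` holds per-drug median / quartiles / range of
    the non-missing ages.
    """

    case_totals: pd.Series
    sex: pd.DataFrame
    age_bands: pd.DataFrame
    age_stats: pd.DataFrame
    years: pd.DataFrame
    countries: pd.DataFrame


def _age_stats(case_sets: Mapping[str, ReportSet]) -> pd.DataFrame:
    rows = {}
    pooled: list[float] = []
    for drug, cases in case_sets.items():
        ages = [r.age_years for r in cases if r.age_years is not None]
        pooled.extend(ages)
        rows[drug] = _age_row(ages)
    rows["total"] = _age_row(pooled)
    return pd.DataFrame(rows).T[["n", "median", "q1", "q3", "min", "max"]]


def _age_row(ages: list[float]) -> dict[str, float]:
    if not ages:
        nan = float("nan")
        return {"n": 0, "median": nan, "q1": nan, "q3": nan, "min": nan, "max": nan}
    arr = np.asarray(ages, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return {
        "n": len(arr),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


def summarize_characteristics(case_sets: Mapping[str, ReportSet]) -> CharacteristicsSummary:
    """Build the clinical-characteristics summary over per-drug case sets.

    Sex and age-band tables keep explicit ``unknown`` rows; countries are
    ordered by total count (missing country grouped as ``unknown``); the
    age median/range uses non-missing ages only.
    """
    case_totals = pd.Series(
        {drug: len(cases) for drug, cases in case_sets.items()}, dtype=int
    )
    case_totals["total"] = int(case_totals.sum())
    sex = _counts_frame(case_sets, lambda r: r.sex, ["female", "male", "unknown"])
    bands = _counts_frame(case_sets, lambda r: age_band(r.age_years), AGE_BANDS)
    years = _counts_frame(case_sets, lambda r: r.report_year)
    countries = _counts_frame(case_sets, lambda r: r.country or "unknown")
    countries = countries.sort_values("total", ascending=False, kind="stable")
    return CharacteristicsSummary(
        case_totals=case_totals,
        sex=sex,
        age_bands=bands,
        age_stats=_age_stats(case_sets),
        years=years,
        countries=countries,
    )


def outcome_table(
    case_sets: Mapping[str, ReportSet],
    precedence: Sequence[str] = DEFAULT_OUTCOME_PRECEDENCE,
) -> pd.DataFrame:
    """Outcome-category x drug count table (one category per case).

    Rows follow the display order hospitalization, death, life-threatening,
    disability, others, unknown; columns sum to the case totals of their
    case sets.
    """
    categories = [name for name, _ in OUTCOME_CATEGORIES] + ["unknown"]
    return _counts_frame(
        case_sets, lambda r: assign_outcome_category(r, precedence), categories
    )


def severity_table(case_sets: Mapping[str, ReportSet]) -> pd.DataFrame:
    """Severity x drug count table (serious / non_serious / unknown rows)."""
    return _counts_frame(
        case_sets, classify_severity, ["serious", "non_serious", "unknown"]
    )


@dataclass(frozen=True)
class ChiSquareResult:
    """Pearson chi-square statistic with df, p-value and the cells used."""

    statistic: float
    df: int
    p_value: float
    cells_used: pd.DataFrame


def pearson_chi_square(
    table: pd.DataFrame, drop_categories: Sequence[str] = ()
) -> ChiSquareResult:
    """Classic Pearson chi-square on a category x group count table.

    ``drop_categories`` removes rows (e.g. an ``unknown`` category) before
    testing.  No continuity correction is applied.  A zero expected cell
    leaves the statistic undefined and raises
    :class:`~faers_signal.model.DegenerateTableError`.
    """
    drop = {str(c).casefold() for c in drop_categories}
    kept = table.loc[[i for i in table.index if str(i).casefold() not in drop]]
    observed = kept.to_numpy(dtype=float)
    if observed.shape[0] < 2 or observed.shape[1] < 2:
        raise DegenerateTableError("chi-square needs at least a 2x2 table after dropping")
    row_sums = observed.sum(axis=1)
    col_sums = observed.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        raise DegenerateTableError("a zero expected cell makes the chi-square undefined")
    res = stats.chi2_contingency(observed, correction=False)
    return ChiSquareResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        cells_used=kept,
    )


def severity_comparison(
    case_sets: Mapping[str, ReportSet],
) -> dict[str, ChiSquareResult]:
    """Chi-square comparisons of serious vs non-serious cases by sex and age.

    Pools the cases of all drugs, cross-tabulates severity against sex and
    against age band, drops the ``unknown`` rows, and tests each table.
    """
    pooled = ReportSet([r for cases in case_sets.values() for r in cases])
    groups = {
        "serious": pooled.filter(lambda r: classify_severity(r) == "serious"),
        "non_serious": pooled.filter(lambda r: classify_severity(r) == "non_serious"),
    }
    out: dict[str, ChiSquareResult] = {}
    sex_table = _counts_frame(groups, lambda r: r.sex, ["female", "male", "unknown"]).drop(columns="total")
    out["sex"] = pearson_chi_square(sex_table, drop_categories=["unknown"])
    age_table = _counts_frame(groups, lambda r: age_band(r.age_years), AGE_BANDS).drop(columns="total")
    out["age"] = pearson_chi_square(age_table, drop_categories=["unknown"])
    return out


def yearly_trend(all_ps_reports: ReportSet, infection_ps_cases: ReportSet) -> pd.DataFrame:
    """Per-year infection-case counts as a proportion of all PS reports.

    Both inputs must be primary-suspect filtered over the same quarter
    window.  The proportion is rounded to 4 decimals and reported as NaN
    (not 0) for a year with no reports at all.
    """
    total = pd.Series([r.report_year for r in all_ps_reports]).value_counts()
    infection = pd.Series([r.report_year for r in infection_ps_cases]).value_counts()
    years = sorted(set(total.index) | set(infection.index))
    rows = []
    for year in years:
        t = int(total.get(year, 0))
        i = int(infection.get(year, 0))
        prop = round(i / t, 4) if t else float("nan")
        rows.append({"year": int(year), "infection_ps": i, "total_ps": t, "proportion": prop})
    return pd.DataFrame(rows, columns=["year", "infection_ps", "total_ps", "proportion"])
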