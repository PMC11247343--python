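"""Disproportionality statistics: 2x2 tables and the reporting odds ratio.

For a target drug and a target preferred term (PT), the classical
pharmacovigilance 2x2 table is

    =============  ==========  ===========
                   target PT   other PTs
    target drug        a           b
    other drugs        c           d
    =============  ==========  ===========

and the reporting odds ratio is ``ROR = (a/c)/(b/d)`` with the Woolf
log-normal confidence interval

    CI = exp( ln(ROR) +/- z * sqrt(1/a + 1/b + 1/c + 1/d) ),  z = 1.96.

A (drug, PT) pair is *screened in* as a signal when the supporting case
count satisfies ``a >= 3`` and the lower 95% confidence bound is strictly
greater than 1.

Two counting conventions are provided for the denominator universe:

``report_pt_pairs`` (default)
    The universe is the set of distinct (report, PT) incidence pairs: a
    report listing k distinct PTs contributes k rows.  ``a + b`` is then
    the drug's total adverse-event count, the convention OpenVigil-style
    extracts print.

``reports``
    The universe is the set of distinct reports; a report counts once
    whatever it lists.

Under either convention a report contributes at most 1 to ``a``: listing
the same PT twice is collapsed (reactions are stored as distinct terms).

Zero cells get no continuity correction: the CI is undefined and the pair
is reported with ``is_signal=False`` (the ``a >= 3`` gate already excludes
the pairs for which a correction would matter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .model import ReportSet, normalize_term

COUNTING_CONVENTIONS = ("report_pt_pairs", "reports")


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """Counts a/b/c/d for one (drug, PT) pair; see module docstring."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def scaled(self, k: int) -> "ContingencyTable":
        return ContingencyTable(self.a * k, self.b * k, self.c * k, self.d * k)


@dataclass(frozen=True, slots=True)
class SignalResult:
    """ROR, CI and screening verdict for one (drug, PT) pair.

    ``ror``/``ci_low``/``ci_high`` are NaN when any cell is zero
    (``ci_defined`` is then False) and ``is_signal`` is False.
    """

    drug: str
    pt: str
    table: ContingencyTable
    ror: float
    ci_low: float
    ci_high: float
    is_signal: bool
    ci_defined: bool = True


def meets_criteria(a: int, ci_low: float, min_a: int = 3, ci_floor: float = 1.0) -> bool:
    """Screening rule: at least ``min_a`` cases and ``ci_low`` strictly above the floor."""
    return a >= min_a and not math.isnan(ci_low) and ci_low > ci_floor


def compute_ror(
    table: ContingencyTable,
    z: float = 1.96,
    *,
    min_a: int = 3,
    ci_floor: float = 1.0,
    drug: str = "",
    pt: str = "",
) -> SignalResult:
    """ROR with Woolf CI and the screening verdict for one table.

    Any zero cell makes the CI (and for b or c = 0, the ROR itself)
    undefined: the result carries NaN statistics, ``ci_defined=False`` and
    ``is_signal=False``.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        nan = float("nan")
        return SignalResult(drug, pt, table, nan, nan, nan, False, ci_defined=False)
    ror = (a / c) / (b / d)
    half_width = z * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = math.exp(math.log(ror) - half_width)
    ci_high = math.exp(math.log(ror) + half_width)
    return SignalResult(
        drug, pt, table, ror, ci_low, ci_high,
        meets_criteria(a, ci_low, min_a=min_a, ci_floor=ci_floor),
    )


def _incidence_frame(reports: ReportSet, drug_synonyms: Iterable[str]) -> pd.DataFrame:
    """Distinct (case_id, pt) pairs with a per-row drug-match flag."""
    wanted = {normalize_term(s) for s in drug_synonyms}
    rows = []
    for r in reports:
        matched = any(normalize_term(d.name) in wanted for d in r.drugs)
        for pt in r.reactions:
            rows.append((r.case_id, pt, matched))
    return pd.DataFrame(rows, columns=["case_id", "pt", "matched"])


def _counts_for_pts(
    reports: ReportSet,
    drug_synonyms: Iterable[str],
    pts: Sequence[str],
    convention: str,
) -> dict[str, ContingencyTable]:
    if convention not in COUNTING_CONVENTIONS:
        raise ValueError(f"unknown counting convention {convention!r}")
    if not len(reports):
        raise ValueError("cannot build contingency tables from an empty ReportSet")
    inc = _incidence_frame(reports, drug_synonyms)
    pts_norm = [normalize_term(p) for p in pts]
    a_counts = inc[inc.matched].groupby("pt").size()
    all_counts = inc.groupby("pt").size()
    if convention == "report_pt_pairs":
        universe = len(inc)
        drug_total = int(inc.matched.sum())
    else:
        universe = len(reports)
        drug_total = int(inc[inc.matched].case_id.nunique())
    out: dict[str, ContingencyTable] = {}
    for pt in pts_norm:
        a = int(a_counts.get(pt, 0))
        c = int(all_counts.get(pt, 0)) - a
        b = drug_total - a
        d = universe - a - b - c
        out[pt] = ContingencyTable(a, b, c, d)
    return out


def build_contingency(
    reports: ReportSet,
    drug_synonyms: Iterable[str],
    pt: str,
    convention: str = "report_pt_pairs",
) -> ContingencyTable:
    """Count the 2x2 table for one (drug, PT) pair over a deduplicated set."""
    return _counts_for_pts(reports, list(drug_synonyms), [pt], convention)[normalize_term(pt)]


def screen_signals(
    reports: ReportSet,
    drug_synonyms: Iterable[str],
    candidate_pts: Sequence[str],
    *,
    convention: str = "report_pt_pairs",
    min_a: int = 3,
    ci_floor: float = 1.0,
    z: float = 1.96,
    drug_name: str = "",
) -> list[SignalResult]:
    """ROR-screen every candidate PT against one drug.

    Returns one :class:`SignalResult` per candidate (non-signals included),
    signals first in descending ROR order, then the rest alphabetically;
    ties broken alphabetically by PT for determinism.
    """
    candidates = [normalize_term(p) for p in candidate_pts]
    if not candidates:
        raise ValueError("candidate PT list must be non-empty")
    synonyms = list(drug_synonyms)
    label = drug_name or normalize_term(synonyms[0])
    tables = _counts_for_pts(reports, synonyms, candidates, convention)
    results = [
        compute_ror(tables[pt], z, min_a=min_a, ci_floor=ci_floor, drug=label, pt=pt)
        for pt in candidates
    ]
    results.sort(key=lambda r: (not r.is_signal, -r.ror if r.is_signal else 0.0, r.pt))
    return results


def signals_frame(results: Iterable[SignalResult]) -> pd.DataFrame:
    """Tabulate results: drug, pt, a, b, c, d, ror, ci_low, ci_high, is_signal."""
    rows = [
        {
            "drug": r.drug,
            "pt": r.pt,
            "a": r.table.a,
            "b": r.table.b,
            "c": r.table.c,
            "d": r.table.d,
            "ror": r.ror,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "is_signal": r.is_signal,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["drug", "pt", "a", "b", "c", "d", "ror", "ci_low", "ci_high", "is_signal"]
    )


def write_signal_table(results: Iterable[SignalResult], path: Union[str, Path]) -> Path:
    """Write the signal table as TSV (ROR/CI printed to 2 decimals)."""
    df = signals_frame(results)
    for col in ("ror", "ci_low", "ci_high"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path
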