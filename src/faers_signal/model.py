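"""Core data model for FAERS-style spontaneous adverse-event reports.

The FDA Adverse Event Reporting System (FAERS) publishes spontaneous case
reports as quarterly table extracts.  Each case links one patient's drug
exposures (with an attribution *role code*: PS primary suspect, SS secondary
suspect, C concomitant, I interacting) to one or more adverse-event
*preferred terms* (PTs, MedDRA's unit concept for an adverse event),
together with demographics and outcome codes.

This module defines the in-memory representation every other module counts
on: :class:`CaseReport`, its :class:`DrugEntry` children, the deduplicated
:class:`ReportSet` collection, and the :class:`PtSocMap` lookup from
preferred term to system organ class (SOC, MedDRA's top-level grouping).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

#: FAERS drug role codes: primary suspect, secondary suspect, concomitant,
#: interacting.
ROLE_CODES: tuple[str, ...] = ("PS", "SS", "C", "I")

#: FAERS outcome codes: hospitalization (initial or prolonged), death,
#: life-threatening, disability, other.  An empty outcome set means the
#: reporter supplied no outcome ("unknown").
OUTCOME_CODES: tuple[str, ...] = ("HO", "DE", "LT", "DS", "OT")

#: Outcome codes counted as serious.
SERIOUS_OUTCOMES: frozenset[str] = frozenset({"HO", "DE", "LT", "DS"})

SEX_VALUES: tuple[str, ...] = ("female", "male", "unknown")


class FaersSignalError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(FaersSignalError):
    """An input table could not be parsed (bad delimiter, missing column...)."""


class MappingConflictError(FaersSignalError):
    """A preferred term is mapped to more than one system organ class."""


class ConfigError(FaersSignalError):
    """A pipeline or simulation configuration failed validation."""


class DegenerateTableError(FaersSignalError):
    """A contingency table has an expected cell of zero."""


def normalize_term(term: str) -> str:
    """Normalize a free-text term: collapse whitespace and case-fold.

    All drug names, preferred terms and SOC names are compared through this
    normalization, so ``"  Pneumonia "`` and ``"pneumonia"`` are the same
    concept.
    """
    return " ".join(str(term).split()).casefold()


_VERSION_RE = re.compile(r"^(\d{4})Q([1-4])-(\d+)$")
_QUARTER_RE = re.compile(r"^(\d{4})Q([1-4])$")


def quarter_key(quarter: str) -> tuple[int, int]:
    """Parse a year-quarter label like ``"2020Q3"`` into ``(2020, 3)``."""
    m = _QUARTER_RE.match(str(quarter).strip().upper())
    if not m:
        raise ConfigError(f"invalid quarter label: {quarter!r} (expected e.g. '2020Q3')")
    return int(m.group(1)), int(m.group(2))


def version_sort_key(version_key: str):
    """Sort key for version keys of the form ``YYYYQn-seq``.

    Well-formed keys order by (year, quarter, sequence number) so that
    ``2020Q3-2`` outranks ``2020Q1-10`` even though the lexicographic order
    would disagree.  Keys in any other format fall back to a plain string
    comparison below every well-formed key.
    """
    m = _VERSION_RE.match(version_key)
    if m:
        return (1, int(m.group(1)), int(m.group(2)), int(m.group(3)), "")
    return (0, 0, 0, 0, version_key)


@dataclass(frozen=True, slots=True)
class DrugEntry:
    """One drug row of a case report: normalized name plus role code."""

    name: str
    role_code: str

    def __post_init__(self) -> None:
        if self.role_code not in ROLE_CODES:
            raise ValueError(
                f"role_code must be one of {ROLE_CODES}, got {self.role_code!r}"
            )


@dataclass(frozen=True, slots=True)
class CaseReport:
    """One spontaneous report.

    Parameters
    ----------
    case_id:
        Stable case identifier.  FAERS publishes follow-up versions of the
        same case; deduplication keeps one report per ``case_id``.
    version_key:
        Orderable string ``YYYYQn-seq`` (receipt quarter plus version
        sequence) used to pick the most recent version of a case.
    report_year:
        Year the report was received.
    drugs:
        Drug entries with role codes; at least one after validation.
    reactions:
        Distinct normalized adverse-event preferred terms; at least one
        after validation.
    outcomes:
        Subset of :data:`OUTCOME_CODES`; empty means unknown outcome.
    sex, age_years, country:
        Demographics; missing values are ``"unknown"`` / ``None``.
    """

    case_id: str
    version_key: str
    report_year: int
    drugs: tuple[DrugEntry, ...]
    reactions: tuple[str, ...]
    outcomes: frozenset[str] = frozenset()
    sex: str = "unknown"
    age_years: float | None = None
    country: str | None = None

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        if self.sex not in SEX_VALUES:
            raise ValueError(f"sex must be one of {SEX_VALUES}, got {self.sex!r}")
        bad = set(self.outcomes) - set(OUTCOME_CODES)
        if bad:
            raise ValueError(f"unknown outcome codes: {sorted(bad)}")
        if self.age_years is not None and self.age_years < 0:
            raise ValueError("age_years must be non-negative")

    @property
    def quarter(self) -> str:
        """Receipt quarter, the ``YYYYQn`` prefix of :attr:`version_key`."""
        return self.version_key.split("-", 1)[0]

    def matches_drug(self, synonyms: Iterable[str]) -> bool:
        """True iff any drug entry's normalized name equals a synonym.

        Matching is exact normalized-name equality, never substring
        matching: ``"palbociclib tablet"`` does not match the synonym
        ``"palbociclib"``.
        """
        wanted = {normalize_term(s) for s in synonyms}
        return any(normalize_term(d.name) in wanted for d in self.drugs)

    def drug_roles(self, synonyms: Iterable[str]) -> frozenset[str]:
        """Role codes under which any synonym-matching drug appears."""
        wanted = {normalize_term(s) for s in synonyms}
        return frozenset(
            d.role_code for d in self.drugs if normalize_term(d.name) in wanted
        )

    def _canonical(self) -> tuple:
        return (
            self.case_id,
            self.version_key,
            self.report_year,
            self.sex,
            self.age_years,
            self.country,
            tuple(sorted((d.name, d.role_code) for d in self.drugs)),
            tuple(sorted(self.reactions)),
            tuple(sorted(self.outcomes)),
        )


class ReportSet:
    """An ordered collection of :class:`CaseReport`.

    Input order is preserved (it is the tie-breaker for deduplication), but
    equality is canonical: two sets holding the same reports compare equal
    regardless of the order they were built in, so any counting defined on
    a ReportSet is reproducible under input shuffling.
    """

    __slots__ = ("_reports",)

    def __init__(self, reports: Iterable[CaseReport] = ()) -> None:
        self._reports: tuple[CaseReport, ...] = tuple(reports)

    @property
    def reports(self) -> tuple[CaseReport, ...]:
        return self._reports

    def __len__(self) -> int:
        return len(self._reports)

    def __iter__(self) -> Iterator[CaseReport]:
        return iter(self._reports)

    def __bool__(self) -> bool:
        return bool(self._reports)

    def case_ids(self) -> set[str]:
        return {r.case_id for r in self._reports}

    def get(self, case_id: str) -> CaseReport:
        """Return the report for ``case_id`` (the last one, pre-dedup)."""
        for r in reversed(self._reports):
            if r.case_id == case_id:
                return r
        raise KeyError(case_id)

    def filter(self, predicate) -> "ReportSet":
        return ReportSet(r for r in self._reports if predicate(r))

    def _canonical(self) -> tuple:
        return tuple(sorted(r._canonical() for r in self._reports))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReportSet):
            return NotImplemented
        return self._canonical() == other._canonical()

    def __hash__(self) -> int:
        return hash(self._canonical())

    def __repr__(self) -> str:
        return f"ReportSet(n={len(self._reports)})"


class PtSocMap:
    """Case-insensitive mapping from preferred term to system organ class.

    Every PT maps to exactly one SOC; building a map from rows that assign
    the same PT to two different SOCs raises :class:`MappingConflictError`.
    """

    __slots__ = ("_entries",)

    def __init__(self, entries: Mapping[str, str] | Iterable[tuple[str, str]] = ()):
        items = entries.items() if isinstance(entries, Mapping) else entries
        self._entries: dict[str, str] = {}
        for pt, soc in items:
            npt, nsoc = normalize_term(pt), normalize_term(soc)
            if not npt or not nsoc:
                raise MappingConflictError(f"empty PT or SOC in row ({pt!r}, {soc!r})")
            if npt in self._entries and self._entries[npt] != nsoc:
                raise MappingConflictError(
                    f"PT {npt!r} mapped to both {self._entries[npt]!r} and {nsoc!r}"
                )
            self._entries[npt] = nsoc

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, pt: str) -> bool:
        return normalize_term(pt) in self._entries

    def get(self, pt: str) -> str | None:
        """SOC for a PT (case-insensitive), or ``None`` if unmapped."""
        return self._entries.get(normalize_term(pt))

    def __getitem__(self, pt: str) -> str:
        soc = self.get(pt)
        if soc is None:
            raise KeyError(pt)
        return soc

    def items(self):
        return self._entries.items()
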