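"""The five-step infection-signal screening procedure.

For each target drug over a fixed receipt-quarter window:

1. extract every preferred term (PT) reported with the drug;
2. group the PTs by system organ class (SOC) via a PT→SOC map;
3. keep PTs from the infection-related SOCs ("infections and infestations"
   and "respiratory, thoracic and mediastinal disorders" by default) and
   ROR-screen them against the full report universe;
4. enrol the PTs that pass the screening criteria (a >= 3, CI lower bound
   > 1);
5. retrieve the cases listing an enrolled PT and restrict them to reports
   where the drug is the *primary suspect* (role code PS) — the case set
   all descriptive analyses run on.

Screening (step 3) deliberately uses reports under *all* role codes; the
primary-suspect restriction applies only to case retrieval (step 5), so
the "all infection AEs" and "infection AEs as PS" stage counts are two
distinct quantities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import deduplicate
from .model import ConfigError, PtSocMap, ReportSet, normalize_term, quarter_key
from .signal import COUNTING_CONVENTIONS, SignalResult, screen_signals

logger = logging.getLogger(__name__)

#: Default infection-related system organ classes.
DEFAULT_INFECTION_SOCS: tuple[str, ...] = (
    "infections and infestations",
    "respiratory, thoracic and mediastinal disorders",
)

DEFAULT_QUARTER_RANGE: tuple[str, str] = ("2015Q1", "2022Q3")


@dataclass(frozen=True, slots=True)
class TargetDrug:
    """A target drug plus the synonym list it is matched under."""

    name: str
    synonyms: tuple[str, ...] = ()

    def all_synonyms(self) -> tuple[str, ...]:
        names = [normalize_term(self.name)]
        for s in self.synonyms:
            ns = normalize_term(s)
            if ns and ns not in names:
                names.append(ns)
        return tuple(names)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one screening run.

    ``min_a`` and ``ci_floor`` are the screening criteria (defaults 3 and
    1.0); ``counting_convention`` picks the denominator universe (see
    :mod:`faers_signal.signal`); ``pt_allowlist``/``pt_denylist`` extend or
    prune the SOC-based candidate selection, since "infection-related" is
    ultimately a clinical judgment the SOC filter cannot fully encode;
    ``require_primary_suspect`` can be switched off to keep cases under any
    role code in step 5.
    """

    target_drugs: tuple[TargetDrug, ...]
    infection_socs: tuple[str, ...] = DEFAULT_INFECTION_SOCS
    quarter_range: tuple[str, str] = DEFAULT_QUARTER_RANGE
    min_a: int = 3
    ci_floor: float = 1.0
    counting_convention: str = "report_pt_pairs"
    pt_allowlist: tuple[str, ...] = ()
    pt_denylist: tuple[str, ...] = ()
    require_primary_suspect: bool = True

    def validate(self) -> "PipelineConfig":
        if not self.target_drugs:
            raise ConfigError("target_drugs must list at least one drug")
        start, end = (quarter_key(q) for q in self.quarter_range)
        if start > end:
            raise ConfigError(
                f"quarter_range start {self.quarter_range[0]!r} is after end {self.quarter_range[1]!r}"
            )
        if self.min_a < 1:
            raise ConfigError("min_a must be >= 1")
        if self.counting_convention not in COUNTING_CONVENTIONS:
            raise ConfigError(f"unknown counting_convention {self.counting_convention!r}")
        return self


@dataclass(frozen=True)
class EnrolledCaseSet:
    """Enrolled PTs for one drug plus the primary-suspect cases listing them."""

    drug: str
    enrolled_pts: tuple[str, ...]
    cases: ReportSet


@dataclass(frozen=True)
class DrugResult:
    drug: str
    signals: tuple[SignalResult, ...]
    enrolled: EnrolledCaseSet
    stage_counts: Mapping[str, int]


@dataclass(frozen=True)
class PipelineResult:
    per_drug: Mapping[str, DrugResult]

    def stage_counts_frame(self) -> pd.DataFrame:
        rows = [
            {"drug": drug, **result.stage_counts}
            for drug, result in self.per_drug.items()
        ]
        return pd.DataFrame(
            rows,
            columns=["drug", "total_aes", "infection_aes", "infection_aes_ps"],
        )


def extract_drug_pts(reports: ReportSet, drug_synonyms: Iterable[str]) -> list[str]:
    """Sorted distinct PTs occurring in at least one report matching the drug."""
    synonyms = list(drug_synonyms)
    pts: set[str] = set()
    for r in reports:
        if r.matches_drug(synonyms):
            pts.update(r.reactions)
    return sorted(pts)


def select_infection_pts(
    pts: Sequence[str], pt_soc_map: PtSocMap, infection_socs: Iterable[str]
) -> list[str]:
    """Keep the PTs whose SOC is one of the infection-related SOCs.

    PTs absent from the map cannot be classified; they are excluded with a
    logged warning rather than silently kept.
    """
    socs = {normalize_term(s) for s in infection_socs}
    selected: list[str] = []
    unmapped = 0
    for pt in pts:
        soc = pt_soc_map.get(pt)
        if soc is None:
            unmapped += 1
            logger.warning("PT %r is absent from the PT→SOC map; excluded", pt)
            continue
        if soc in socs:
            selected.append(normalize_term(pt))
    if unmapped:
        logger.warning("%d PT(s) could not be mapped to a SOC", unmapped)
    return selected


def filter_primary_suspect(reports: ReportSet, drug_synonyms: Iterable[str]) -> ReportSet:
    """Keep reports where the target drug appears as primary suspect.

    A report listing the drug under several role codes is retained as long
    as one of them is PS.
    """
    synonyms = list(drug_synonyms)
    return reports.filter(lambda r: "PS" in r.drug_roles(synonyms))


def filter_quarter_range(reports: ReportSet, quarter_range: tuple[str, str]) -> ReportSet:
    start, end = (quarter_key(q) for q in quarter_range)
    def in_range(r):
        try:
            q = quarter_key(r.quarter)
        except ConfigError:
            return False
        return start <= q <= end
    return reports.filter(in_range)


def run_pipeline(
    config: PipelineConfig, reports: ReportSet, pt_soc_map: PtSocMap
) -> PipelineResult:
    """Run the full five-step procedure for every target drug.

    The result is a pure function of ``(config, reports, pt_soc_map)``:
    rerunning yields identical tables.  Per drug it carries the full signal
    table, the enrolled case set and the stage counts (total AEs under the
    counting convention, infection-AE cases, infection-AE cases as PS),
    which are nested: ``infection_aes_ps <= infection_aes <= total_aes``.
    """
    config.validate()
    reports = deduplicate(filter_quarter_range(reports, config.quarter_range))
    allow = {normalize_term(p) for p in config.pt_allowlist}
    deny = {normalize_term(p) for p in config.pt_denylist}
    per_drug: dict[str, DrugResult] = {}
    for target in config.target_drugs:
        drug = normalize_term(target.name)
        synonyms = target.all_synonyms()
        all_pts = extract_drug_pts(reports, synonyms)
        candidates = select_infection_pts(all_pts, pt_soc_map, config.infection_socs)
        candidates = sorted((set(candidates) | (allow & set(all_pts))) - deny)
        if candidates and len(reports):
            signals = tuple(
                screen_signals(
                    reports,
                    synonyms,
                    candidates,
                    convention=config.counting_convention,
                    min_a=config.min_a,
                    ci_floor=config.ci_floor,
                    drug_name=drug,
                )
            )
        else:
            signals = ()
        enrolled_pts = tuple(sorted(r.pt for r in signals if r.is_signal))
        enrolled_set = set(enrolled_pts)

        drug_reports = reports.filter(lambda r: r.matches_drug(synonyms))
        infection_cases = drug_reports.filter(
            lambda r: bool(enrolled_set.intersection(r.reactions))
        )
        if config.require_primary_suspect:
            cases = filter_primary_suspect(infection_cases, synonyms)
        else:
            cases = infection_cases
        if config.counting_convention == "report_pt_pairs":
            total_aes = sum(len(r.reactions) for r in drug_reports)
        else:
            total_aes = len(drug_reports)
        stage_counts = {
            "total_aes": total_aes,
            "infection_aes": len(infection_cases),
            "infection_aes_ps": len(cases),
        }
        per_drug[drug] = DrugResult(
            drug=drug,
            signals=signals,
            enrolled=EnrolledCaseSet(drug=drug, enrolled_pts=enrolled_pts, cases=cases),
            stage_counts=stage_counts,
        )
    return PipelineResult(per_drug=per_drug)
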