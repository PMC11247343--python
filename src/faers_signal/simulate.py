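"""Seedable generator of FAERS-like spontaneous report databases.

Real spontaneous-report extracts cannot ship with the package, so every
pipeline stage is exercised against synthetic databases with known ground
truth: each report draws one or more drugs (each drug an independent
Bernoulli on its marginal reporting probability, rejection-sampled until
at least one drug is present), then draws each preferred term (PT)
independently with its background probability, multiplied by the relative
reporting rate of any matching planted enrichment (capped at 1) and
rejection-sampled until at least one PT is present.  Role codes,
demographics and outcome codes are drawn independently.  A configurable
fraction of cases emits a follow-up version one quarter later, exercising
deduplication.

The defaults in :func:`default_config` sketch a breast-cancer
pharmacovigilance universe: three CDK4/6 inhibitors at realistic marginal
reporting shares next to common endocrine/chemotherapy comparators, a PT
list spanning the two infection-related SOCs plus frequent non-infectious
events, and planted drug-PT enrichments of relative rate 4-12.

PT draws are independent Bernoulli per report (no PT-PT correlation) — a
deliberate simplification, sufficient for testing counting conventions and
ROR behaviour but not clustering of co-reported events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np

from .io import write_tables
from .model import (
    CaseReport,
    ConfigError,
    DrugEntry,
    PtSocMap,
    ReportSet,
    normalize_term,
)

ROLE_ORDER = ("PS", "SS", "C", "I")
OUTCOME_ORDER = ("HO", "DE", "LT", "DS", "OT", "none")

#: Age sampled uniformly (integer years) within each band.
AGE_BAND_RANGES: Mapping[str, tuple[int, int]] = {
    "<40": (18, 39),
    "40-64": (40, 64),
    ">=65": (65, 95),
}


@dataclass(frozen=True)
class DrugSim:
    """One drug of the simulated universe."""

    name: str
    marginal_p: float
    role_probs: tuple[float, float, float, float] = (0.35, 0.25, 0.30, 0.10)


@dataclass(frozen=True)
class PtSim:
    """One preferred term: name, its SOC, and the background probability."""

    name: str
    soc: str
    background_p: float


@dataclass(frozen=True)
class Enrichment:
    """A planted drug-PT association of given relative reporting rate (>= 1)."""

    drug: str
    pt: str
    rate: float


@dataclass(frozen=True)
class Demographics:
    sex_probs: tuple[float, float, float] = (0.90, 0.03, 0.07)  # female, male, unknown
    age_band_probs: tuple[float, float, float, float] = (0.04, 0.33, 0.42, 0.21)
    country_probs: tuple[tuple[str, float], ...] = (
        ("us", 0.55),
        ("germany", 0.05),
        ("united kingdom", 0.04),
        ("argentina", 0.03),
        ("canada", 0.02),
        ("japan", 0.02),
        ("other", 0.19),
        ("", 0.10),  # missing country
    )
    year_probs: tuple[tuple[int, float], ...] = (
        (2015, 0.06),
        (2016, 0.08),
        (2017, 0.12),
        (2018, 0.13),
        (2019, 0.14),
        (2020, 0.15),
        (2021, 0.16),
        (2022, 0.16),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic report database."""

    n_reports: int
    seed: int
    drugs: tuple[DrugSim, ...]
    pts: tuple[PtSim, ...]
    enrichments: tuple[Enrichment, ...] = ()
    demographics: Demographics = field(default_factory=Demographics)
    #: probabilities over HO, DE, LT, DS, OT, none (no outcome reported)
    outcome_probs: tuple[float, ...] = (0.20, 0.07, 0.015, 0.005, 0.24, 0.47)
    duplicate_fraction: float = 0.05

    def validate(self) -> "SimulationConfig":
        if self.n_reports < 1:
            raise ConfigError("n_reports must be >= 1")
        if not self.drugs or not self.pts:
            raise ConfigError("drugs and pts must be non-empty")
        for d in self.drugs:
            _check_prob(d.marginal_p, f"drug {d.name!r} marginal_p")
            _check_dist(d.role_probs, f"drug {d.name!r} role_probs")
        for p in self.pts:
            _check_prob(p.background_p, f"pt {p.name!r} background_p")
        if not any(d.marginal_p > 0 for d in self.drugs):
            raise ConfigError("infeasible config: every drug probability is 0")
        if not any(p.background_p > 0 for p in self.pts):
            raise ConfigError("infeasible config: every PT probability is 0")
        names = {normalize_term(d.name) for d in self.drugs}
        pts = {normalize_term(p.name) for p in self.pts}
        for e in self.enrichments:
            if e.rate < 1:
                raise ConfigError(f"enrichment ({e.drug}, {e.pt}) rate must be >= 1")
            if normalize_term(e.drug) not in names:
                raise ConfigError(f"enrichment references unknown drug {e.drug!r}")
            if normalize_term(e.pt) not in pts:
                raise ConfigError(f"enrichment references unknown PT {e.pt!r}")
        _check_dist(self.outcome_probs, "outcome_probs")
        _check_dist(self.demographics.sex_probs, "sex_probs")
        _check_dist(self.demographics.age_band_probs, "age_band_probs")
        _check_dist([p for _, p in self.demographics.country_probs], "country_probs")
        _check_dist([p for _, p in self.demographics.year_probs], "year_probs")
        _check_prob(self.duplicate_fraction, "duplicate_fraction")
        return self


def _check_prob(p: float, what: str) -> None:
    if not 0.0 <= p <= 1.0:
        raise ConfigError(f"{what} must be in [0, 1], got {p}")


def _check_dist(probs: Sequence[float], what: str) -> None:
    for p in probs:
        _check_prob(p, what)
    if abs(sum(probs) - 1.0) > 1e-9:
        raise ConfigError(f"{what} must sum to 1, got {sum(probs)}")


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows about a simulated database."""

    enrichments: tuple[Enrichment, ...]
    drugs: Mapping[str, tuple[str, ...]]            # case_id -> drug names
    roles: Mapping[str, Mapping[str, str]]          # case_id -> drug -> role
    pts: Mapping[str, tuple[str, ...]]              # case_id -> PTs
    sex: Mapping[str, str]
    age_band: Mapping[str, str]
    country: Mapping[str, str]                      # "" for missing
    year: Mapping[str, int]
    outcome: Mapping[str, str]                      # one of OUTCOME_ORDER
    duplicated_case_ids: frozenset[str]


def default_config(n_reports: int = 5000, seed: int = 0) -> SimulationConfig:
    """The stock simulated universe (see module docstring)."""
    drugs = (
        DrugSim("palbociclib", 0.05),
        DrugSim("ribociclib", 0.02),
        DrugSim("abemaciclib", 0.01),
        DrugSim("letrozole", 0.15, (0.30, 0.20, 0.40, 0.10)),
        DrugSim("fulvestrant", 0.12, (0.30, 0.20, 0.40, 0.10)),
        DrugSim("anastrozole", 0.12, (0.30, 0.20, 0.40, 0.10)),
        DrugSim("tamoxifen", 0.12, (0.30, 0.20, 0.40, 0.10)),
        DrugSim("capecitabine", 0.30, (0.40, 0.20, 0.30, 0.10)),
    )
    inf = "infections and infestations"
    resp = "respiratory, thoracic and mediastinal disorders"
    pts = (
        PtSim("pneumonia", inf, 0.020),
        PtSim("infection", inf, 0.015),
        PtSim("urinary tract infection", inf, 0.015),
        PtSim("influenza", inf, 0.010),
        PtSim("cellulitis", inf, 0.008),
        PtSim("oral herpes", inf, 0.005),
        PtSim("gastrointestinal infection", inf, 0.003),
        PtSim("mastitis", inf, 0.002),
        PtSim("pneumonitis", resp, 0.006),
        PtSim("organising pneumonia", resp, 0.001),
        PtSim("cough", resp, 0.030),
        PtSim("dyspnoea", resp, 0.040),
        PtSim("neutropenia", "blood and lymphatic system disorders", 0.060),
        PtSim("nausea", "gastrointestinal disorders", 0.100),
        PtSim("diarrhoea", "gastrointestinal disorders", 0.080),
        PtSim("vomiting", "gastrointestinal disorders", 0.050),
        PtSim("fatigue", "general disorders and administration site conditions", 0.090),
        PtSim("headache", "nervous system disorders", 0.050),
        PtSim("alopecia", "skin and subcutaneous tissue disorders", 0.030),
        PtSim("arthralgia", "musculoskeletal and connective tissue disorders", 0.030),
    )
    enrichments = (
        Enrichment("palbociclib", "pneumonia", 5.0),
        Enrichment("palbociclib", "influenza", 4.0),
        Enrichment("ribociclib", "pneumonia", 6.0),
        Enrichment("ribociclib", "cellulitis", 8.0),
        Enrichment("abemaciclib", "pneumonitis", 12.0),
    )
    return SimulationConfig(
        n_reports=n_reports, seed=seed, drugs=drugs, pts=pts, enrichments=enrichments
    )


def pt_soc_map_of(config: SimulationConfig) -> PtSocMap:
    """The PT→SOC map implied by the simulated PT universe."""
    return PtSocMap((p.name, p.soc) for p in config.pts)


_MAX_REJECTION_ROUNDS = 10_000


def _rejection_bernoulli(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Row-wise Bernoulli draws, redrawing rows that come out all-zero."""
    n = probs.shape[0]
    out = rng.random(probs.shape) < probs
    for _ in range(_MAX_REJECTION_ROUNDS):
        bad = ~out.any(axis=1)
        if not bad.any():
            return out
        out[bad] = rng.random((int(bad.sum()), probs.shape[1])) < probs[bad]
    raise ConfigError("rejection sampling failed to produce a non-empty draw")


def generate(config: SimulationConfig, seed: int | None = None) -> tuple[ReportSet, GroundTruth]:
    """Generate a synthetic ReportSet plus its ground truth.

    Identical ``(config, seed)`` yields identical output.  ``seed``
    overrides ``config.seed`` when given.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_reports
    demo = config.demographics

    drug_names = [normalize_term(d.name) for d in config.drugs]
    pt_names = [normalize_term(p.name) for p in config.pts]
    drug_p = np.array([d.marginal_p for d in config.drugs], dtype=float)
    if not (drug_p > 0).any():
        raise ConfigError("infeasible drug probabilities")
    drug_mat = _rejection_bernoulli(rng, np.broadcast_to(drug_p, (n, len(drug_p))).copy())

    # one role draw per (report, drug); only consumed where the drug is present
    role_idx = np.empty((n, len(config.drugs)), dtype=int)
    for j, d in enumerate(config.drugs):
        role_idx[:, j] = rng.choice(len(ROLE_ORDER), size=n, p=d.role_probs)

    base = np.array([p.background_p for p in config.pts], dtype=float)
    factor = np.ones((n, len(base)))
    pt_index = {name: j for j, name in enumerate(pt_names)}
    drug_index = {name: j for j, name in enumerate(drug_names)}
    for e in config.enrichments:
        rows = drug_mat[:, drug_index[normalize_term(e.drug)]]
        j = pt_index[normalize_term(e.pt)]
        factor[rows, j] = np.maximum(factor[rows, j], e.rate)
    pt_probs = np.clip(base * factor, 0.0, 1.0)
    pt_mat = _rejection_bernoulli(rng, pt_probs)

    sex = rng.choice(["female", "male", "unknown"], size=n, p=demo.sex_probs)
    band_labels = list(AGE_BAND_RANGES) + ["unknown"]
    band = rng.choice(band_labels, size=n, p=demo.age_band_probs)
    age_u = rng.random(n)
    countries = rng.choice([c for c, _ in demo.country_probs], size=n,
                           p=[p for _, p in demo.country_probs])
    years = rng.choice([y for y, _ in demo.year_probs], size=n,
                       p=[p for _, p in demo.year_probs])
    quarters = rng.integers(1, 5, size=n)
    outcome = rng.choice(OUTCOME_ORDER, size=n, p=config.outcome_probs)
    dup_mask = rng.random(n) < config.duplicate_fraction

    reports: list[CaseReport] = []
    gt_drugs, gt_roles, gt_pts = {}, {}, {}
    gt_sex, gt_band, gt_country, gt_year, gt_outcome = {}, {}, {}, {}, {}
    width = len(str(n))
    for i in range(n):
        case_id = f"C{i + 1:0{width}d}"
        present = np.flatnonzero(drug_mat[i])
        entries = tuple(
            DrugEntry(name=drug_names[j], role_code=ROLE_ORDER[role_idx[i, j]])
            for j in present
        )
        reactions = tuple(pt_names[j] for j in np.flatnonzero(pt_mat[i]))
        b = band[i]
        if b == "unknown":
            age = None
        else:
            low, high = AGE_BAND_RANGES[b]
            age = float(min(int(low + age_u[i] * (high - low + 1)), high))
        oc = outcome[i]
        outcomes = frozenset() if oc == "none" else frozenset([oc])
        year, q = int(years[i]), int(quarters[i])
        final_year = year  # year of the version that survives deduplication
        report = CaseReport(
            case_id=case_id,
            version_key=f"{year}Q{q}-1",
            report_year=year,
            drugs=entries,
            reactions=reactions,
            outcomes=outcomes,
            sex=str(sex[i]),
            age_years=age,
            country=str(countries[i]) or None,
        )
        reports.append(report)
        if dup_mask[i]:
            ny, nq = (year + 1, 1) if q == 4 else (year, q + 1)
            final_year = ny
            reports.append(
                CaseReport(
                    case_id=case_id,
                    version_key=f"{ny}Q{nq}-2",
                    report_year=ny,
                    drugs=entries,
                    reactions=reactions,
                    outcomes=outcomes,
                    sex=str(sex[i]),
                    age_years=age,
                    country=str(countries[i]) or None,
                )
            )
        gt_drugs[case_id] = tuple(drug_names[j] for j in present)
        gt_roles[case_id] = {drug_names[j]: ROLE_ORDER[role_idx[i, j]] for j in present}
        gt_pts[case_id] = reactions
        gt_sex[case_id] = str(sex[i])
        gt_band[case_id] = str(b)
        gt_country[case_id] = str(countries[i])
        gt_year[case_id] = final_year
        gt_outcome[case_id] = str(oc)

    truth = GroundTruth(
        enrichments=config.enrichments,
        drugs=gt_drugs,
        roles=gt_roles,
        pts=gt_pts,
        sex=gt_sex,
        age_band=gt_band,
        country=gt_country,
        year=gt_year,
        outcome=gt_outcome,
        duplicated_case_ids=frozenset(c for i, c in enumerate(gt_drugs) if dup_mask[i]),
    )
    return ReportSet(reports), truth


def write_fixture(reports: ReportSet, dialect: str, out_dir: Union[str, Path]) -> list[Path]:
    """Write the DEMO/DRUG/REAC/OUTC fixture files for a generated set."""
    return write_tables(reports, dialect, out_dir)


def expected_cell_probabilities(
    config: SimulationConfig, drug: str, pt: str
) -> tuple[float, float, float, float]:
    """Analytic (report-level) cell probabilities for one (drug, PT) pair.

    Enumerates every drug subset (with the empty set rejected), applies the
    enrichment factors the subset triggers, and conditions the per-PT
    presence probability on the at-least-one-PT rejection step:
    ``P(PT_j | accepted, S) = q_j / (1 - prod_k (1 - q_k))``.  Returns the
    probabilities of the a/b/c/d cells of the report-level 2x2 table, the
    oracle the empirical ROR of a generated database is checked against.
    """
    config.validate()
    drug = normalize_term(drug)
    pt = normalize_term(pt)
    drug_names = [normalize_term(d.name) for d in config.drugs]
    pt_names = [normalize_term(p.name) for p in config.pts]
    if drug not in drug_names or pt not in pt_names:
        raise ConfigError(f"unknown drug {drug!r} or PT {pt!r}")
    probs = np.array([d.marginal_p for d in config.drugs])
    base = np.array([p.background_p for p in config.pts])
    t = pt_names.index(pt)
    d_idx = drug_names.index(drug)
    p_nonempty = 1.0 - np.prod(1.0 - probs)
    p_a = p_c = 0.0
    p_has_drug = 0.0
    n_drugs = len(probs)
    for mask in range(1, 1 << n_drugs):
        members = [j for j in range(n_drugs) if mask >> j & 1]
        p_subset = np.prod([probs[j] if mask >> j & 1 else 1 - probs[j] for j in range(n_drugs)])
        if p_subset == 0.0:
            continue
        p_subset /= p_nonempty
        q = base.copy()
        for e in config.enrichments:
            if drug_names.index(normalize_term(e.drug)) in members:
                j = pt_names.index(normalize_term(e.pt))
                q[j] = min(max(q[j], base[j] * e.rate), 1.0)
        p_any_pt = 1.0 - np.prod(1.0 - q)
        p_pt = q[t] / p_any_pt
        if d_idx in members:
            p_a += p_subset * p_pt
            p_has_drug += p_subset
        else:
            p_c += p_subset * p_pt
    p_b = p_has_drug - p_a
    p_d = 1.0 - p_a - p_b - p_c
    return p_a, p_b, p_c, p_d
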