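"""Reading and writing FAERS-structured report tables.

Two on-disk dialects are supported, both plain text:

``faers_ascii``
    The layout of FAERS quarterly ASCII extracts: ``$``-delimited files
    DEMO / DRUG / REAC / OUTC with a header row, joined on ``primaryid``.
    Only the columns this pipeline consumes are required (see
    ``_FAERS_COLUMNS``); extra columns are ignored.

``simple_tsv``
    A tab-delimited dialect with the same logical content but the package's
    own column names; it round-trips every field of :class:`CaseReport`
    losslessly and is the format the synthetic generator writes by default.

Parsing joins the four tables into :class:`~faers_signal.model.CaseReport`
records.  Rows whose join key has no demographics match are dropped and
counted in the log, as are reports left without any drug or any reaction
after the join.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import IO, Iterable, Mapping, Union

import pandas as pd
import yaml

from .model import (
    CaseReport,
    DrugEntry,
    OUTCOME_CODES,
    ParseError,
    PtSocMap,
    ReportSet,
    ROLE_CODES,
    normalize_term,
    version_sort_key,
)

logger = logging.getLogger(__name__)

Source = Union[str, Path, IO[str]]

DIALECTS = ("faers_ascii", "simple_tsv")

_FAERS_COLUMNS = {
    "demo": ["primaryid", "caseid", "caseversion", "fda_dt", "sex", "age", "age_cod", "occr_country"],
    "drug": ["primaryid", "role_cod", "drugname"],
    "reac": ["primaryid", "pt"],
    "outc": ["primaryid", "outc_cod"],
}

_SIMPLE_COLUMNS = {
    "demo": ["case_id", "version_key", "sex", "age_years", "country", "report_year"],
    "drug": ["case_id", "drug_name", "role_code"],
    "reac": ["case_id", "pt"],
    "outc": ["case_id", "outcome"],
}

#: FAERS age-unit codes → factor converting to years.
_AGE_FACTORS = {"YR": 1.0, "DEC": 10.0, "MON": 1.0 / 12.0, "DY": 1.0 / 365.25}


def _read_table(source: Source, sep: str, required: list[str], name: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False, engine="python")
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ParseError(f"could not parse {name} table: {exc}") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{name} table is missing mandatory column(s): {', '.join(missing)}")
    return df


def _quarter_of_date(fda_dt: str) -> tuple[int, int]:
    s = str(fda_dt).strip()
    if len(s) < 6 or not s[:6].isdigit():
        raise ParseError(f"bad fda_dt value {fda_dt!r} (expected YYYYMMDD)")
    year, month = int(s[:4]), int(s[4:6])
    if not 1 <= month <= 12:
        raise ParseError(f"bad month in fda_dt value {fda_dt!r}")
    return year, (month - 1) // 3 + 1


def _parse_age_faers(age: str, age_cod: str) -> float | None:
    age = str(age).strip()
    if not age:
        return None
    try:
        value = float(age)
    except ValueError:
        return None
    factor = _AGE_FACTORS.get(str(age_cod).strip().upper() or "YR")
    if factor is None:
        return None
    return value * factor


def _parse_sex(raw: str, dialect: str) -> str:
    s = str(raw).strip().lower()
    if dialect == "faers_ascii":
        return {"f": "female", "m": "male"}.get(s, "unknown")
    if s in ("female", "male"):
        return s
    if s in ("", "unknown"):
        return "unknown"
    raise ParseError(f"bad sex value {raw!r} in simple_tsv demographics")


def parse_reports(
    demo_stream: Source,
    drug_stream: Source,
    reac_stream: Source,
    outc_stream: Source,
    dialect: str,
) -> ReportSet:
    """Join DEMO/DRUG/REAC/OUTC tables into a :class:`ReportSet`.

    The result holds one :class:`CaseReport` per demographics row that ends
    up with at least one drug and one reaction; it is *not* deduplicated —
    call :func:`deduplicate` next.  Drug/reaction/outcome rows whose join
    key matches no demographics row are dropped with a logged count.
    """
    if dialect not in DIALECTS:
        raise ParseError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    sep = "$" if dialect == "faers_ascii" else "\t"
    cols = _FAERS_COLUMNS if dialect == "faers_ascii" else _SIMPLE_COLUMNS
    key = "primaryid" if dialect == "faers_ascii" else "case_id"

    demo = _read_table(demo_stream, sep, cols["demo"], "demographics (DEMO)")
    drug = _read_table(drug_stream, sep, cols["drug"], "drug (DRUG)")
    reac = _read_table(reac_stream, sep, cols["reac"], "reaction (REAC)")
    outc = _read_table(outc_stream, sep, cols["outc"], "outcome (OUTC)")
    if demo.empty:
        raise ParseError("demographics (DEMO) table contains no rows")

    known = set(demo[key])
    orphans = 0
    grouped: dict[str, dict[str, list]] = {k: {"drugs": [], "reacs": [], "outcs": []} for k in known}
    name_col = "drugname" if dialect == "faers_ascii" else "drug_name"
    role_col = "role_cod" if dialect == "faers_ascii" else "role_code"
    for _, row in drug.iterrows():
        k = row[key]
        if k not in grouped:
            orphans += 1
            continue
        role = str(row[role_col]).strip().upper()
        name = normalize_term(row[name_col])
        if role not in ROLE_CODES or not name:
            logger.warning("dropping drug row with bad role/name for key %s", k)
            continue
        grouped[k]["drugs"].append(DrugEntry(name=name, role_code=role))
    pt_col = "pt"
    for _, row in reac.iterrows():
        k = row[key]
        if k not in grouped:
            orphans += 1
            continue
        pt = normalize_term(row[pt_col])
        if pt:
            grouped[k]["reacs"].append(pt)
    outc_col = "outc_cod" if dialect == "faers_ascii" else "outcome"
    for _, row in outc.iterrows():
        k = row[key]
        if k not in grouped:
            orphans += 1
            continue
        code = str(row[outc_col]).strip().upper()
        if code in OUTCOME_CODES:
            grouped[k]["outcs"].append(code)
        elif code:
            logger.warning("dropping unknown outcome code %r for key %s", code, k)
    if orphans:
        logger.warning("dropped %d row(s) with no matching demographics record", orphans)

    reports: list[CaseReport] = []
    incomplete = 0
    for _, row in demo.iterrows():
        k = row[key]
        parts = grouped[k]
        if not parts["drugs"] or not parts["reacs"]:
            incomplete += 1
            continue
        if dialect == "faers_ascii":
            year, q = _quarter_of_date(row["fda_dt"])
            seq_raw = str(row["caseversion"]).strip()
            seq = int(seq_raw) if seq_raw.isdigit() else 1
            case_id = str(row["caseid"]).strip()
            version_key = f"{year}Q{q}-{seq}"
            report_year = year
            age = _parse_age_faers(row["age"], row["age_cod"])
            country = str(row["occr_country"]).strip() or None
        else:
            case_id = str(row["case_id"]).strip()
            version_key = str(row["version_key"]).strip()
            year_raw = str(row["report_year"]).strip()
            if not year_raw.isdigit():
                raise ParseError(f"bad report_year value {year_raw!r} for case {case_id!r}")
            report_year = int(year_raw)
            age_raw = str(row["age_years"]).strip()
            age = float(age_raw) if age_raw else None
            if age is not None and (math.isnan(age) or age < 0):
                raise ParseError(f"bad age_years value {age_raw!r} for case {case_id!r}")
            country = str(row["country"]).strip() or None
        if not case_id:
            raise ParseError("demographics row with empty case identifier")
        drugs = tuple(sorted(set(parts["drugs"]), key=lambda d: (d.name, d.role_code)))
        reactions = tuple(sorted(set(parts["reacs"])))
        outcomes = frozenset(parts["outcs"])
        reports.append(
            CaseReport(
                case_id=case_id,
                version_key=version_key,
                report_year=report_year,
                drugs=drugs,
                reactions=reactions,
                outcomes=outcomes,
                sex=_parse_sex(row["sex"], dialect),
                age_years=age,
                country=country,
            )
        )
    if incomplete:
        logger.warning("dropped %d report(s) lacking any drug or reaction row", incomplete)
    reports.sort(key=lambda r: (r.case_id, version_sort_key(r.version_key)))
    return ReportSet(reports)


def deduplicate(reports: ReportSet) -> ReportSet:
    """Keep one report per case_id: the highest version key.

    FAERS publishes follow-up versions of the same case; analysis is
    defined on the latest version.  Ties on the version key keep the record
    that appears last in input order.  The operation is idempotent.
    """
    best: dict[str, tuple[tuple, int, CaseReport]] = {}
    for idx, report in enumerate(reports):
        key = (version_sort_key(report.version_key), idx)
        current = best.get(report.case_id)
        if current is None or key >= current[:2]:
            best[report.case_id] = (key[0], idx, report)
    survivors = [entry[2] for entry in best.values()]
    survivors.sort(key=lambda r: (r.case_id, version_sort_key(r.version_key)))
    return ReportSet(survivors)


def load_pt_soc_map(stream: Source) -> PtSocMap:
    """Load a two-column PT→SOC table (TSV with header columns pt, soc)."""
    df = _read_table(stream, "\t", ["pt", "soc"], "PT→SOC mapping")
    return PtSocMap(zip(df["pt"], df["soc"]))


def load_drug_synonyms(source: Source) -> dict[str, list[str]]:
    """Load a drug-synonym table from YAML (``drug: [synonym, ...]``).

    The drug's own name is always included among its synonyms.
    """
    if hasattr(source, "read"):
        data = yaml.safe_load(source.read())
    else:
        with open(source, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ParseError("drug synonym file must be a mapping drug -> list of synonyms")
    out: dict[str, list[str]] = {}
    for drug, syns in data.items():
        name = normalize_term(drug)
        entries = [name]
        for s in syns or []:
            ns = normalize_term(s)
            if ns and ns not in entries:
                entries.append(ns)
        out[name] = entries
    return out


def match_drug(report: CaseReport, synonyms: Iterable[str]) -> bool:
    """Exact normalized-name drug matching (see :meth:`CaseReport.matches_drug`)."""
    synonyms = list(synonyms)
    if not synonyms:
        raise ValueError("synonym list must be non-empty")
    return report.matches_drug(synonyms)


# ---------------------------------------------------------------------------
# Writers (the synthetic generator's write_fixture delegates here)

def _version_parts(report: CaseReport) -> tuple[int, int, int]:
    year, q = (int(report.quarter[:4]), int(report.quarter[5]))
    seq = int(report.version_key.rsplit("-", 1)[1]) if "-" in report.version_key else 1
    return year, q, seq


def _fmt_age(age: float | None) -> str:
    if age is None:
        return ""
    return f"{age:g}"


def write_tables(reports: ReportSet, dialect: str, out_dir: Union[str, Path]) -> list[Path]:
    """Write DEMO/DRUG/REAC/OUTC tables in the chosen dialect.

    Returns the paths written.  The output parses back to an equal
    ReportSet (for ``faers_ascii`` the version key must follow the
    ``YYYYQn-seq`` convention, since receipt dates are reconstructed as
    mid-quarter dates).
    """
    if dialect not in DIALECTS:
        raise ParseError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sep = "$" if dialect == "faers_ascii" else "\t"
    demo_rows, drug_rows, reac_rows, outc_rows = [], [], [], []
    sex_out = {"female": "F", "male": "M", "unknown": ""}
    for report in reports:
        if dialect == "faers_ascii":
            year, q, seq = _version_parts(report)
            fda_dt = f"{year:04d}{3 * (q - 1) + 2:02d}15"  # mid-quarter date
            key = f"{report.case_id}.{seq}"
            demo_rows.append(
                {
                    "primaryid": key,
                    "caseid": report.case_id,
                    "caseversion": seq,
                    "fda_dt": fda_dt,
                    "sex": sex_out[report.sex],
                    "age": _fmt_age(report.age_years),
                    "age_cod": "YR" if report.age_years is not None else "",
                    "occr_country": report.country or "",
                }
            )
            for d in report.drugs:
                drug_rows.append({"primaryid": key, "role_cod": d.role_code, "drugname": d.name})
            for pt in report.reactions:
                reac_rows.append({"primaryid": key, "pt": pt})
            for code in sorted(report.outcomes):
                outc_rows.append({"primaryid": key, "outc_cod": code})
        else:
            key = report.case_id
            demo_rows.append(
                {
                    "case_id": key,
                    "version_key": report.version_key,
                    "sex": report.sex,
                    "age_years": _fmt_age(report.age_years),
                    "country": report.country or "",
                    "report_year": report.report_year,
                }
            )
            for d in report.drugs:
                drug_rows.append({"case_id": key, "drug_name": d.name, "role_code": d.role_code})
            for pt in report.reactions:
                reac_rows.append({"case_id": key, "pt": pt})
            for code in sorted(report.outcomes):
                outc_rows.append({"case_id": key, "outcome": code})

    names = (
        {"demo": "DEMO.txt", "drug": "DRUG.txt", "reac": "REAC.txt", "outc": "OUTC.txt"}
        if dialect == "faers_ascii"
        else {"demo": "demo.tsv", "drug": "drug.tsv", "reac": "reac.tsv", "outc": "outc.tsv"}
    )
    cols = _FAERS_COLUMNS if dialect == "faers_ascii" else _SIMPLE_COLUMNS
    paths = []
    for role, rows in (("demo", demo_rows), ("drug", drug_rows), ("reac", reac_rows), ("outc", outc_rows)):
        path = out / names[role]
        pd.DataFrame(rows, columns=cols[role]).to_csv(path, sep=sep, index=False)
        paths.append(path)
    return paths


def read_tables(in_dir: Union[str, Path], dialect: str) -> ReportSet:
    """Parse a directory written by :func:`write_tables`."""
    in_dir = Path(in_dir)
    names = (
        {"demo": "DEMO.txt", "drug": "DRUG.txt", "reac": "REAC.txt", "outc": "OUTC.txt"}
        if dialect == "faers_ascii"
        else {"demo": "demo.tsv", "drug": "drug.tsv", "reac": "reac.tsv", "outc": "outc.tsv"}
    )
    return parse_reports(
        in_dir / names["demo"], in_dir / names["drug"], in_dir / names["reac"], in_dir / names["outc"], dialect
    )
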