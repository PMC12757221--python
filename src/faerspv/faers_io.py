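"""Readers and case assembly for FAERS-style quarterly ASCII tables.

FAERS quarters are distributed as "$"-delimited text files, one per table
(DEMO, DRUG, REAC, THER, OUTC, INDI), joined on the PRIMARYID identifier.
This module parses those tables into :class:`RawRow` records, assembles one
:class:`CaseReport` per PRIMARYID, removes duplicate case versions (keeping
the latest FDA receipt date per CASEID), flags target-event cases and maps
verbatim drug names onto ATC-normalised names.

Column dialects changed across FAERS history; the reader takes an explicit
schema per table and ships the modern (post-2014) column set as its default
rather than sniffing headers.
"""

from __future__ import annotations

import datetime as _dt
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigurationError, SchemaError

__all__ = [
    "TABLE_SCHEMAS",
    "RawRow",
    "ParseLog",
    "DrugEntry",
    "CaseReport",
    "DedupLog",
    "NormalizeLog",
    "read_ascii_table",
    "assemble_reports",
    "deduplicate",
    "extract_cases",
    "load_atc_table",
    "normalize_drugs",
    "parse_faers_date",
    "classify_date",
]

#: Default (post-2014) column sets per table. The reader requires every
#: declared column to be present; extra columns are carried through untouched.
TABLE_SCHEMAS: dict[str, list[str]] = {
    "DEMO": [
        "primaryid", "caseid", "caseversion", "i_f_code", "event_dt",
        "mfr_dt", "init_fda_dt", "fda_dt", "rept_cod", "auth_num", "mfr_num",
        "mfr_sndr", "lit_ref", "age", "age_cod", "age_grp", "sex", "e_sub",
        "wt", "wt_cod", "rept_dt", "to_mfr", "occp_cod", "reporter_country",
        "occr_country",
    ],
    "DRUG": [
        "primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai",
    ],
    "REAC": ["primaryid", "caseid", "pt", "drug_rec_act"],
    "THER": [
        "primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt", "dur",
        "dur_cod",
    ],
    "OUTC": ["primaryid", "caseid", "outc_cod"],
    "INDI": ["primaryid", "caseid", "indi_drug_seq", "indi_pt"],
}

#: Multipliers from FAERS age unit codes to years. Empty code defaults to YR.
_AGE_TO_YEARS = {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12, "WK": 1 / 52, "DY": 1 / 365.25}
_WT_TO_KG = {"KG": 1.0, "LBS": 1 / 2.20462, "GMS": 1 / 1000}
_MAX_PLAUSIBLE_AGE = 120.0


def parse_faers_date(raw: str | None) -> _dt.date | None:
    """Parse an 8-digit FAERS date, returning ``None`` for anything else.

    Partial (4- or 6-digit) and syntactically invalid dates map to ``None``;
    use :func:`classify_date` when the reason matters.
    """
    if raw is None:
        return None
    raw = raw.strip()
    if len(raw) != 8 or not raw.isdigit():
        return None
    try:
        return _dt.date(int(raw[:4]), int(raw[4:6]), int(raw[6:8]))
    except ValueError:
        return None


def classify_date(raw: str | None) -> str:
    """Classify a raw date string as 'ok', 'missing', 'partial' or 'invalid'."""
    if raw is None or raw.strip() == "":
        return "missing"
    raw = raw.strip()
    if raw.isdigit() and len(raw) in (4, 6):
        return "partial"
    if parse_faers_date(raw) is None:
        return "invalid"
    return "ok"


@dataclass
class RawRow:
    """One data line of a FAERS table, split on '$'; empty fields are absent."""

    table_id: str
    primaryid: str
    caseid: str
    payload: dict[str, str]


@dataclass
class ParseLog:
    """Accounting for one table read: rows kept, rows skipped and why."""

    table_id: str
    path: str
    n_rows: int = 0
    n_skipped: int = 0
    skipped_lines: list[int] = field(default_factory=list)


def read_ascii_table(
    path: str | Path,
    table_id: str,
    schema: Mapping[str, list[str]] | None = None,
    encoding: str = "latin-1",
) -> tuple[list[RawRow], ParseLog]:
    """Read one "$"-delimited FAERS table.

    Parameters
    ----------
    path
        File whose first line is a "$"-delimited header.
    table_id
        One of ``DEMO, DRUG, REAC, THER, OUTC, INDI``.
    schema
        Mapping table_id -> required columns; defaults to :data:`TABLE_SCHEMAS`.
    encoding
        Text encoding, ``latin-1`` by default as in FAERS releases.

    Returns
    -------
    (rows, log)
        Parsed rows (empty fields omitted from the payload) and a parse log.
        Lines whose field count does not match the header are skipped and
        counted in the log, never silently dropped.
    """
    schema = dict(schema) if schema is not None else TABLE_SCHEMAS
    if table_id not in schema:
        raise ConfigurationError(f"unknown table_id {table_id!r}")
    required = schema[table_id]
    path = Path(path)
    log = ParseLog(table_id=table_id, path=str(path))
    rows: list[RawRow] = []
    with open(path, encoding=encoding) as fh:
        header_line = fh.readline().rstrip("\n").rstrip("\r")
        columns = [c.strip().lower() for c in header_line.split("$")]
        missing = [c for c in required if c not in columns]
        if missing:
            raise SchemaError(table_id, missing)
        ncol = len(columns)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("$")
            if len(fields) != ncol:
                log.n_skipped += 1
                log.skipped_lines.append(lineno)
                continue
            payload = {
                col: val.strip()
                for col, val in zip(columns, fields)
                if val.strip() != ""
            }
            rows.append(
                RawRow(
                    table_id=table_id,
                    primaryid=payload.get("primaryid", ""),
                    caseid=payload.get("caseid", ""),
                    payload=payload,
                )
            )
            log.n_rows += 1
    return rows, log


def load_corpus(
    directory: str | Path,
    schema: Mapping[str, list[str]] | None = None,
    encoding: str = "latin-1",
) -> tuple[dict[str, list[RawRow]], dict[str, list[ParseLog]]]:
    """Read every quarterly table file in a directory.

    Files are matched as ``<TABLE>*.txt`` (e.g. ``DEMO21Q3.txt``), read in
    sorted filename order and concatenated per table. Returns the table-id ->
    rows mapping accepted by :func:`assemble_reports` plus per-file parse
    logs. A corpus without any DEMO file is an error.
    """
    directory = Path(directory)
    tables: dict[str, list[RawRow]] = {}
    logs: dict[str, list[ParseLog]] = {}
    for table_id in TABLE_SCHEMAS:
        for path in sorted(directory.glob(f"{table_id}*.txt")):
            rows, log = read_ascii_table(path, table_id, schema=schema, encoding=encoding)
            tables.setdefault(table_id, []).extend(rows)
            logs.setdefault(table_id, []).append(log)
    if "DEMO" not in tables:
        raise ConfigurationError(f"no DEMO table found under {directory}")
    return tables, logs


@dataclass
class DrugEntry:
    """One drug record on a report; ``role`` is the FAERS role code."""

    drugname_raw: str
    role: str
    drug_seq: str = "1"
    drugname_norm: str | None = None
    atc_code: str | None = None
    start_dt: _dt.date | None = None
    start_dt_raw: str | None = None


@dataclass
class CaseReport:
    """One safety report after table joining.

    ``version_date`` is the raw 8-digit FDA receipt date (FDA_DT) used as the
    recency key for de-duplication. Raw date strings are retained alongside
    their parsed forms so that downstream exclusion accounting can distinguish
    missing, partial and invalid entries. ``age_years`` and ``weight_kg`` are
    left absent (``None``) rather than sentinel-coded when missing.
    """

    primaryid: str
    caseid: str
    version_date: str | None = None
    event_dt: _dt.date | None = None
    event_dt_raw: str | None = None
    age_years: float | None = None
    sex: str | None = None
    weight_kg: float | None = None
    country: str | None = None
    outcomes: set[str] = field(default_factory=set)
    drugs: list[DrugEntry] = field(default_factory=list)
    reaction_pts: set[str] = field(default_factory=set)

    def ps_drugs(self) -> list[DrugEntry]:
        """Drug entries with the Primary Suspect role."""
        return [d for d in self.drugs if d.role == "PS"]

    def has_pt(self, target_pt: str) -> bool:
        """Case-insensitive exact match of ``target_pt`` against this report's PTs."""
        t = target_pt.strip().casefold()
        return any(pt.strip().casefold() == t for pt in self.reaction_pts)


def _convert_age(raw_age: str | None, raw_cod: str | None) -> float | None:
    if raw_age is None:
        return None
    try:
        value = float(raw_age)
    except ValueError:
        return None
    factor = _AGE_TO_YEARS.get((raw_cod or "YR").upper())
    if factor is None:
        return None
    years = value * factor
    if years < 0 or years > _MAX_PLAUSIBLE_AGE:
        return None
    return years


def _convert_weight(raw_wt: str | None, raw_cod: str | None) -> float | None:
    if raw_wt is None:
        return None
    try:
        value = float(raw_wt)
    except ValueError:
        return None
    factor = _WT_TO_KG.get((raw_cod or "KG").upper())
    if factor is None:
        return None
    kg = value * factor
    return kg if kg > 0 else None


def assemble_reports(tables: Mapping[str, list[RawRow]]) -> list[CaseReport]:
    """Join per-table rows on PRIMARYID into :class:`CaseReport` objects.

    ``tables`` maps table ids to row lists as returned by
    :func:`read_ascii_table`; DEMO is required, the others optional. THER rows
    are attached to drug entries via their drug sequence number. Age and
    weight are harmonised to years/kg from their FAERS unit codes; ages above
    120 years are treated as implausible and set absent. Country is the
    upper-cased reporter country.
    """
    if "DEMO" not in tables:
        raise ConfigurationError("assemble_reports requires a DEMO table")

    reports: dict[str, CaseReport] = {}
    order: list[str] = []
    for row in tables["DEMO"]:
        p = row.payload
        event_raw = p.get("event_dt")
        rep = CaseReport(
            primaryid=row.primaryid,
            caseid=row.caseid,
            version_date=p.get("fda_dt"),
            event_dt=parse_faers_date(event_raw),
            event_dt_raw=event_raw,
            age_years=_convert_age(p.get("age"), p.get("age_cod")),
            sex=p.get("sex"),
            weight_kg=_convert_weight(p.get("wt"), p.get("wt_cod")),
            country=(p.get("reporter_country") or None),
        )
        if rep.country is not None:
            rep.country = rep.country.upper()
        reports[rep.primaryid] = rep
        order.append(rep.primaryid)

    ther_by_key: dict[tuple[str, str], RawRow] = {}
    for row in tables.get("THER", []):
        seq = row.payload.get("dsg_drug_seq", "1")
        ther_by_key.setdefault((row.primaryid, seq), row)

    for row in tables.get("DRUG", []):
        rep = reports.get(row.primaryid)
        if rep is None:
            continue
        seq = row.payload.get("drug_seq", "1")
        entry = DrugEntry(
            drugname_raw=row.payload.get("drugname", ""),
            role=row.payload.get("role_cod", ""),
            drug_seq=seq,
        )
        ther = ther_by_key.get((row.primaryid, seq))
        if ther is not None:
            entry.start_dt_raw = ther.payload.get("start_dt")
            entry.start_dt = parse_faers_date(entry.start_dt_raw)
        rep.drugs.append(entry)

    for row in tables.get("REAC", []):
        rep = reports.get(row.primaryid)
        if rep is not None and "pt" in row.payload:
            rep.reaction_pts.add(row.payload["pt"])

    for row in tables.get("OUTC", []):
        rep = reports.get(row.primaryid)
        if rep is not None and "outc_cod" in row.payload:
            rep.outcomes.add(row.payload["outc_cod"])

    return [reports[pid] for pid in order]


@dataclass
class DedupLog:
    n_in: int
    n_out: int
    n_removed: int


def _recency_key(report: CaseReport) -> tuple[str, str]:
    # FDA receipt date first, primaryid (zero-padded numeric) as tie-break.
    return (report.version_date or "00000000", report.primaryid.zfill(20))


def deduplicate(reports: Iterable[CaseReport]) -> tuple[list[CaseReport], DedupLog]:
    """Keep a single version per CASEID — the latest FDA receipt date.

    Ties on the receipt date are broken by the larger PRIMARYID (lexicographic
    on the zero-padded numeric string). Input order of the retained reports is
    preserved. Idempotent by construction.
    """
    best: dict[str, CaseReport] = {}
    order: list[str] = []
    n_in = 0
    for rep in reports:
        n_in += 1
        prev = best.get(rep.caseid)
        if prev is None:
            best[rep.caseid] = rep
            order.append(rep.caseid)
        elif _recency_key(rep) > _recency_key(prev):
            best[rep.caseid] = rep
    out = [best[cid] for cid in order]
    return out, DedupLog(n_in=n_in, n_out=len(out), n_removed=n_in - len(out))


def extract_cases(reports: Iterable[CaseReport], target_pt: str) -> list[bool]:
    """Flag reports that are cases of ``target_pt``.

    A report is a case iff the target Preferred Term appears among its
    reaction PTs (case-insensitive exact match) AND at least one of its drugs
    has the Primary Suspect role — suspect-role attribution is PS-only.
    """
    if not target_pt or not target_pt.strip():
        raise ValueError("target_pt must be a non-empty PT string")
    return [bool(r.ps_drugs()) and r.has_pt(target_pt) for r in reports]


def _fold_name(name: str) -> str:
    """Canonical key for drug-name matching: trimmed, case-folded, outer punctuation stripped."""
    return name.strip().strip(".,;:").strip().casefold()


def load_atc_table(source: str | Path | pd.DataFrame) -> dict[str, tuple[str, str]]:
    """Load a drug-name normalization table.

    The table (CSV or DataFrame) must have columns ``drugname``, ``norm_name``
    and ``atc_code``. Keys are case-folded and whitespace/punctuation trimmed;
    duplicate keys with conflicting values raise :class:`ConfigurationError`.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, dtype=str)
    required = {"drugname", "norm_name", "atc_code"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"ATC table missing columns {sorted(missing)}")
    mapping: dict[str, tuple[str, str]] = {}
    for rec in df.itertuples(index=False):
        key = _fold_name(str(rec.drugname))
        value = (str(rec.norm_name), str(rec.atc_code))
        if key in mapping and mapping[key] != value:
            raise ConfigurationError(
                f"conflicting ATC table entries for {key!r}: {mapping[key]} vs {value}"
            )
        mapping[key] = value
    return mapping


@dataclass
class NormalizeLog:
    n_mapped: int = 0
    n_unmapped: int = 0
    unmapped_names: Counter = field(default_factory=Counter)


def normalize_drugs(
    reports: Iterable[CaseReport], atc_table: dict[str, tuple[str, str]]
) -> NormalizeLog:
    """Fill ``drugname_norm`` / ``atc_code`` on every drug entry in place.

    Matching is case-insensitive on trimmed raw names (outer punctuation such
    as a trailing period is ignored). Unmapped names are left absent and
    tallied in the returned log.
    """
    log = NormalizeLog()
    for rep in reports:
        for entry in rep.drugs:
            hit = atc_table.get(_fold_name(entry.drugname_raw))
            if hit is None:
                log.n_unmapped += 1
                log.unmapped_names[entry.drugname_raw] += 1
            else:
                entry.drugname_norm, entry.atc_code = hit
                log.n_mapped += 1
    return log
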