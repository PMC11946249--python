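"""Reading and writing FAERS-style quarterly ASCII tables.

FAERS quarterly extracts are "$"-delimited text files, one per table
(DEMO, DRUG, REAC, OUTC, INDI, THER), linked by the PRIMARYID report key
and the CASEID case key.  The schema changed at 2014Q3 (e.g. ISR/CASE
became PRIMARYID/CASEID); readers here accept either dialect through a
column-alias map and ignore unknown columns, so a single reader covers
the 2011Q1-2023Q4 window.

The module also assembles the per-table rows into joined ``CaseReport``
objects (the analysis unit for everything downstream) and writes the
pipeline's result tables.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from datetime import date
from pathlib import Path
from typing import Mapping, Optional, Sequence

__all__ = [
    "DemoRecord", "DrugRecord", "ReacRecord", "OutcRecord", "IndiRecord",
    "TherRecord", "CaseReport", "ParseResult", "AssemblyResult",
    "read_ascii_table", "assemble_cases", "frames_to_records",
    "write_signal_table", "round2", "fmt2", "percentage", "age_to_years",
    "FormatError", "TABLE_KINDS",
]

TABLE_KINDS = ("DEMO", "DRUG", "REAC", "OUTC", "INDI", "THER")

#: Old-dialect (pre-2014Q3) and cosmetic header variants -> canonical name.
COLUMN_ALIASES = {
    "isr": "primaryid",
    "case": "caseid",
    "case_id": "caseid",
    "gndr_cod": "sex",
    "drug_name": "drugname",
    "country": "reporter_country",
}

#: Divisors converting FAERS age-unit codes to years.
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,        # decades: multiply
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

SEX_CODES = {"F", "M"}
ROLE_CODES = {"PS", "SS", "C", "I"}
OUTCOME_CODES = {"DE", "HO", "LT", "DS", "CA", "RI", "OT"}


class FormatError(ValueError):
    """Raised when a table file's header cannot be interpreted."""


# ---------------------------------------------------------------------------
# typed records, one dataclass per FAERS table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DemoRecord:
    primaryid: str
    caseid: str
    fda_dt: Optional[date]
    event_dt: Optional[date] = None
    age: Optional[float] = None
    age_cod: Optional[str] = None
    sex: Optional[str] = None
    reporter_country: Optional[str] = None
    occp_cod: Optional[str] = None


@dataclass(frozen=True)
class DrugRecord:
    primaryid: str
    drugname: str
    role_cod: str


@dataclass(frozen=True)
class ReacRecord:
    primaryid: str
    pt: str


@dataclass(frozen=True)
class OutcRecord:
    primaryid: str
    outc_cod: str


@dataclass(frozen=True)
class IndiRecord:
    primaryid: str
    indi_pt: str


@dataclass(frozen=True)
class TherRecord:
    primaryid: str
    start_dt: Optional[date] = None
    end_dt: Optional[date] = None


@dataclass
class CaseReport:
    """One joined safety report: the unit of all downstream counting."""

    primaryid: str
    caseid: str
    fda_dt: Optional[date]
    age_years: Optional[float] = None
    sex: Optional[str] = None
    country: Optional[str] = None
    reporter: Optional[str] = None
    drugs: list[tuple[str, str]] = field(default_factory=list)  # (name, role)
    pts: set[str] = field(default_factory=set)
    outcomes: set[str] = field(default_factory=set)
    therapy_start: Optional[date] = None
    event_date: Optional[date] = None


@dataclass
class ParseResult:
    records: list
    rejects: int  # rows skipped for wrong field count


@dataclass
class AssemblyResult:
    cases: list[CaseReport]
    dropped_no_reac: int
    orphans: int  # child rows whose primaryid has no DEMO row


# ---------------------------------------------------------------------------
# field parsing helpers
# ---------------------------------------------------------------------------

def _parse_date(text: str) -> Optional[date]:
    """Parse YYYYMMDD; partial FAERS dates (YYYY, YYYYMM) become missing."""
    text = text.strip()
    if len(text) != 8 or not text.isdigit():
        return None
    try:
        return date(int(text[:4]), int(text[4:6]), int(text[6:8]))
    except ValueError:
        return None


def _parse_float(text: str) -> Optional[float]:
    text = text.strip()
    if not text:
        return None
    try:
        return float(text)
    except ValueError:
        return None


def _clean(text: str) -> Optional[str]:
    text = text.strip()
    return text or None


def age_to_years(age: Optional[float], age_cod: Optional[str]) -> Optional[float]:
    """Normalize an (age, unit-code) pair to years; unknown unit -> missing."""
    if age is None:
        return None
    code = (age_cod or "YR").upper()
    factor = AGE_UNIT_TO_YEARS.get(code)
    if factor is None:
        return None
    return age * factor


# ---------------------------------------------------------------------------
# row -> record constructors (shared by the file reader and the in-memory path)
# ---------------------------------------------------------------------------

def _row_demo(get) -> Optional[DemoRecord]:
    pid = _clean(get("primaryid"))
    if pid is None:
        return None
    sex = _clean(get("sex"))
    if sex is not None:
        sex = sex.upper()
        if sex not in SEX_CODES:
            sex = None
    occp = _clean(get("occp_cod"))
    return DemoRecord(
        primaryid=pid,
        caseid=_clean(get("caseid")) or pid,
        fda_dt=_parse_date(get("fda_dt")),
        event_dt=_parse_date(get("event_dt")),
        age=_parse_float(get("age")),
        age_cod=_clean(get("age_cod")),
        sex=sex,
        reporter_country=_clean(get("reporter_country")),
        occp_cod=occp.upper() if occp else None,
    )


def _row_drug(get) -> Optional[DrugRecord]:
    pid = _clean(get("primaryid"))
    name = _clean(get("drugname"))
    role = (_clean(get("role_cod")) or "").upper()
    if pid is None or name is None or role not in ROLE_CODES:
        return None
    return DrugRecord(pid, name, role)


def _row_reac(get) -> Optional[ReacRecord]:
    pid = _clean(get("primaryid"))
    pt = _clean(get("pt"))
    if pid is None or pt is None:
        return None
    return ReacRecord(pid, pt)


def _row_outc(get) -> Optional[OutcRecord]:
    pid = _clean(get("primaryid"))
    code = (_clean(get("outc_cod")) or "").upper()
    if pid is None or code not in OUTCOME_CODES:
        return None
    return OutcRecord(pid, code)


def _row_indi(get) -> Optional[IndiRecord]:
    pid = _clean(get("primaryid"))
    indi = _clean(get("indi_pt"))
    if pid is None or indi is None:
        return None
    return IndiRecord(pid, indi)


def _row_ther(get) -> Optional[TherRecord]:
    pid = _clean(get("primaryid"))
    if pid is None:
        return None
    return TherRecord(pid, _parse_date(get("start_dt")), _parse_date(get("end_dt")))


_ROW_BUILDERS = {
    "DEMO": _row_demo,
    "DRUG": _row_drug,
    "REAC": _row_reac,
    "OUTC": _row_outc,
    "INDI": _row_indi,
    "THER": _row_ther,
}

#: Columns that must be resolvable from the header for the file to parse.
_REQUIRED_COLUMNS = {
    "DEMO": ("primaryid",),
    "DRUG": ("primaryid", "drugname", "role_cod"),
    "REAC": ("primaryid", "pt"),
    "OUTC": ("primaryid", "outc_cod"),
    "INDI": ("primaryid", "indi_pt"),
    "THER": ("primaryid",),
}


def read_ascii_table(path, table_kind: str) -> ParseResult:
    """Read one "$"-delimited FAERS table into typed records.

    Rows whose field count disagrees with the header, or that fail a
    record's own validity requirements (empty key, unknown role code),
    are skipped and counted in ``rejects``.  Unknown columns are ignored.
    """
    table_kind = table_kind.upper()
    if table_kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind {table_kind!r}")
    path = Path(path)
    build = _ROW_BUILDERS[table_kind]
    records: list = []
    rejects = 0
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file, no header")
        header = [
            COLUMN_ALIASES.get(h.strip().lower(), h.strip().lower())
            for h in header_line.rstrip("\n").rstrip("\r").split("$")
        ]
        index = {name: i for i, name in enumerate(header)}
        for col in _REQUIRED_COLUMNS[table_kind]:
            if col not in index:
                raise FormatError(
                    f"{path}: header lacks required column {col!r} "
                    f"for table kind {table_kind}"
                )
        ncol = len(header)
        for line in fh:
            fields = line.rstrip("\n").rstrip("\r").split("$")
            if len(fields) != ncol:
                rejects += 1
                continue
            get = lambda name: fields[index[name]] if name in index else ""
            rec = build(get)
            if rec is None:
                rejects += 1
            else:
                records.append(rec)
    return ParseResult(records, rejects)


def frames_to_records(frames: Mapping) -> dict[str, list]:
    """Convert generator DataFrames (all-string columns) to typed records.

    Applies exactly the row constructors the file reader uses, so the
    in-memory path and the write-then-read path produce equal records.
    """
    out: dict[str, list] = {}
    for kind in TABLE_KINDS:
        df = frames[kind]
        build = _ROW_BUILDERS[kind]
        cols = list(df.columns)
        records = []
        for row in df.itertuples(index=False, name=None):
            values = dict(zip(cols, row))
            rec = build(lambda name: values.get(name, ""))
            if rec is not None:
                records.append(rec)
        out[kind] = records
    return out


# ---------------------------------------------------------------------------
# case assembly
# ---------------------------------------------------------------------------

def assemble_cases(tables: Mapping[str, Sequence]) -> AssemblyResult:
    """Join the six record lists into one ``CaseReport`` per DEMO row.

    Reports without any reaction row are dropped (the analysis unit is a
    report-event pair); child rows without a DEMO parent are tallied as
    orphans.  Ages are normalized to years here.
    """
    demo: Sequence[DemoRecord] = tables.get("DEMO", [])
    by_pid: dict[str, CaseReport] = {}
    for d in demo:
        by_pid[d.primaryid] = CaseReport(
            primaryid=d.primaryid,
            caseid=d.caseid,
            fda_dt=d.fda_dt,
            age_years=age_to_years(d.age, d.age_cod),
            sex=d.sex,
            country=d.reporter_country,
            reporter=d.occp_cod,
            event_date=d.event_dt,
        )
    orphans = 0
    for r in tables.get("DRUG", []):
        case = by_pid.get(r.primaryid)
        if case is None:
            orphans += 1
        else:
            case.drugs.append((r.drugname, r.role_cod))
    for r in tables.get("REAC", []):
        case = by_pid.get(r.primaryid)
        if case is None:
            orphans += 1
        else:
            case.pts.add(r.pt)
    for r in tables.get("OUTC", []):
        case = by_pid.get(r.primaryid)
        if case is None:
            orphans += 1
        else:
            case.outcomes.add(r.outc_cod)
    for r in tables.get("THER", []):
        case = by_pid.get(r.primaryid)
        if case is None:
            orphans += 1
        elif r.start_dt is not None:
            if case.therapy_start is None or r.start_dt < case.therapy_start:
                case.therapy_start = r.start_dt
    for r in tables.get("INDI", []):
        if r.primaryid not in by_pid:
            orphans += 1
    cases = [c for c in by_pid.values() if c.pts]
    dropped = len(by_pid) - len(cases)
    return AssemblyResult(cases, dropped, orphans)


# ---------------------------------------------------------------------------
# rounding and result output
# ---------------------------------------------------------------------------

def round2(x: float) -> float:
    """Round to 2 decimals, ties away from zero (the convention used for
    every reported statistic).

    Works on the shortest decimal repr of the float, so 11.005 -> 11.01
    as a reader of the printed value expects, rather than on the binary
    representation (11.00499999...).
    """
    if x is None or not math.isfinite(x):
        return x
    q = Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    return float(q)


def fmt2(x) -> str:
    if x is None or (isinstance(x, float) and not math.isfinite(x)):
        return ""
    return f"{round2(float(x)):.2f}"


def percentage(count: float, total: float) -> float:
    """count/total as a percentage, rounded half away from zero to 2 dp."""
    if total == 0:
        raise ZeroDivisionError("percentage of an empty total")
    return round2(100.0 * count / total)


def write_signal_table(results: Sequence, path) -> None:
    """Write disproportionality results as CSV, 2-dp half-away rounding.

    ``results`` are ``signal_stats.SignalResult`` objects (duck-typed to
    avoid a circular import).
    """
    if not results:
        raise ValueError("no results to write")
    path = Path(path)
    header = [
        "drug", "event", "level", "N",
        "ROR", "ROR_CI_low", "ROR_CI_high", "PRR", "chi2",
        "IC", "IC025", "EBGM", "EBGM05",
        "ror_flag", "prr_flag", "bcpnn_flag", "mgps_flag", "combined",
    ]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for r in results:
            writer.writerow([
                r.drug, r.event, r.level, int(r.a),
                fmt2(r.ror.ror if r.ror.defined else None),
                fmt2(r.ror.ci_low if r.ror.defined else None),
                fmt2(r.ror.ci_high if r.ror.defined else None),
                fmt2(r.prr.prr if r.prr.defined else None),
                fmt2(r.prr.chi2 if r.prr.defined else None),
                fmt2(r.ic.ic), fmt2(r.ic.ic025),
                fmt2(r.mgps.ebgm), fmt2(r.mgps.ebgm05),
                int(r.flags.ror_flag), int(r.flags.prr_flag),
                int(r.flags.bcpnn_flag), int(r.flags.mgps_flag),
                int(r.flags.combined),
            ])
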