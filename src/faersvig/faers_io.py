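"""Reading FAERS quarterly ASCII extracts and FDA-style deduplication.

FAERS publishes quarterly dollar-sign-delimited ASCII tables (DEMO, DRUG,
REAC, THER).  This module parses them into typed records, normalises ages to
years, and applies the FDA deduplication guidance: among reports sharing a
CASE_ID keep the one with the most recent FDA_DT; among reports sharing a
PRIMARY_ID keep the higher PRIMARY_ID.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

# Unit codes -> factor converting the stated value to years.  A week is
# 1/52.143 of a year and an hour 1/8766 (365.25 * 24), the conventions used
# when normalising FAERS AGE_COD.
_AGE_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MO": 1.0 / 12.0,
    "WK": 1.0 / 52.143,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

_HCP_CODES = {"MD", "PH", "HP", "RN", "OT"}
_NON_HCP_CODES = {"CN", "LW"}

HCP = "HCP"
NON_HCP = "non-HCP"


def normalize_age(age_value: float | None, age_unit: str | None) -> float | None:
    """Convert a FAERS (AGE, AGE_COD) pair to age in years.

    A present value with an absent unit is treated as years (logged).  A
    negative value is treated as absent with a warning.  Returns ``None``
    when the age cannot be determined.
    """
    if age_value is None:
        return None
    if age_value < 0:
        logger.warning("negative age value %r treated as absent", age_value)
        return None
    if age_unit is None:
        logger.debug("age value %r without unit treated as years", age_value)
        return float(age_value)
    factor = _AGE_FACTORS.get(age_unit.upper())
    if factor is None:
        logger.warning("unknown age unit %r treated as absent", age_unit)
        return None
    return float(age_value) * factor


def parse_faers_date(raw: str | None) -> tuple[int | None, _dt.date | None]:
    """Parse a FAERS date string into (year, day-resolved date).

    FAERS dates come as YYYYMMDD but may be truncated to YYYYMM or YYYY.
    Partial dates keep their year (for report-year tabulation) and yield no
    day-resolved date, so day arithmetic never fabricates a day of month.
    """
    if not raw:
        return None, None
    raw = raw.strip()
    if not raw.isdigit():
        return None, None
    if len(raw) == 8:
        try:
            return int(raw[:4]), _dt.date(int(raw[:4]), int(raw[4:6]), int(raw[6:8]))
        except ValueError:
            return int(raw[:4]), None
    if len(raw) in (4, 6):
        return int(raw[:4]), None
    return None, None


@dataclass(frozen=True)
class ReportRecord:
    """One DEMO row: report identity, dates, and demographics."""

    primary_id: str
    case_id: str
    fda_dt: str | None = None
    event_dt: str | None = None
    age_value: float | None = None
    age_unit: str | None = None
    sex: str | None = None
    country: str | None = None
    reporter: str | None = None  # HCP / non-HCP / None

    @property
    def age_years(self) -> float | None:
        return normalize_age(self.age_value, self.age_unit)

    @property
    def report_year(self) -> int | None:
        return parse_faers_date(self.fda_dt)[0]

    @property
    def fda_date(self) -> _dt.date | None:
        return parse_faers_date(self.fda_dt)[1]

    @property
    def event_date(self) -> _dt.date | None:
        return parse_faers_date(self.event_dt)[1]


@dataclass(frozen=True)
class DrugRecord:
    """One DRUG row: free-text drug name and its FAERS role code."""

    primary_id: str
    drug_name: str
    role_code: str  # PS | SS | C | I
    therapy_start_dt: str | None = None

    @property
    def therapy_start_date(self) -> _dt.date | None:
        return parse_faers_date(self.therapy_start_dt)[1]


@dataclass(frozen=True)
class ReactionRecord:
    """One REAC row: a MedDRA-style preferred term for a report."""

    primary_id: str
    pt: str


@dataclass(frozen=True)
class TherapyRecord:
    """One THER row: a therapy start date for a report."""

    primary_id: str
    start_dt: str | None

    @property
    def start_date(self) -> _dt.date | None:
        return parse_faers_date(self.start_dt)[1]


_ROLE_CODES = {"PS", "SS", "C", "I"}

# Required header columns per table (matched case-insensitively; unknown
# columns are ignored, optional ones fall back to absent).
_REQUIRED = {
    "DEMO": ("PRIMARYID", "CASEID"),
    "DRUG": ("PRIMARYID", "DRUGNAME", "ROLE_COD"),
    "REAC": ("PRIMARYID", "PT"),
    "THER": ("PRIMARYID", "START_DT"),
}


def _clean(value: str | None) -> str | None:
    if value is None:
        return None
    value = value.strip()
    return value or None


def _reporter_from_code(code: str | None) -> str | None:
    if code is None:
        return None
    code = code.upper()
    if code in _HCP_CODES:
        return HCP
    if code in _NON_HCP_CODES:
        return NON_HCP
    return None


def _demo_record(row: dict[str, str | None]) -> ReportRecord:
    age_raw = _clean(row.get("AGE"))
    try:
        age_value = float(age_raw) if age_raw is not None else None
    except ValueError:
        age_value = None
    return ReportRecord(
        primary_id=row["PRIMARYID"],  # type: ignore[arg-type]
        case_id=row["CASEID"],  # type: ignore[arg-type]
        fda_dt=_clean(row.get("FDA_DT")),
        event_dt=_clean(row.get("EVENT_DT")),
        age_value=age_value,
        age_unit=_clean(row.get("AGE_COD")),
        sex=(_clean(row.get("SEX")) or _clean(row.get("GNDR_COD")) or None),
        country=(_clean(row.get("OCCR_COUNTRY")) or _clean(row.get("REPORTER_COUNTRY"))),
        reporter=_reporter_from_code(_clean(row.get("OCCP_COD"))),
    )


def _drug_record(row: dict[str, str | None]) -> DrugRecord | None:
    role = (_clean(row.get("ROLE_COD")) or "").upper()
    if role not in _ROLE_CODES:
        return None
    name = _clean(row.get("DRUGNAME"))
    if name is None:
        return None
    return DrugRecord(
        primary_id=row["PRIMARYID"],  # type: ignore[arg-type]
        drug_name=name,
        role_code=role,
    )


def _reac_record(row: dict[str, str | None]) -> ReactionRecord | None:
    pt = _clean(row.get("PT"))
    if pt is None:
        return None
    return ReactionRecord(primary_id=row["PRIMARYID"], pt=" ".join(pt.split()))  # type: ignore[arg-type]


def _ther_record(row: dict[str, str | None]) -> TherapyRecord:
    return TherapyRecord(primary_id=row["PRIMARYID"], start_dt=_clean(row.get("START_DT")))  # type: ignore[arg-type]


def read_table(path: str | Path, schema: str):
    """Parse one FAERS ASCII table.

    Parameters
    ----------
    path
        File whose first line is a ``$``-separated header.  The dialect has
        no quoting or escaping; files are decoded as UTF-8 with replacement
        because legacy extracts contain stray bytes.
    schema
        One of ``DEMO``, ``DRUG``, ``REAC``, ``THER``.

    Returns
    -------
    list of :class:`ReportRecord`, :class:`DrugRecord`,
    :class:`ReactionRecord` or :class:`TherapyRecord`.

    Ragged data lines (wrong field count) are skipped with a logged warning;
    a malformed header raises :class:`ValueError` naming the file.
    """
    schema = schema.upper()
    if schema not in _REQUIRED:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(_REQUIRED)}")
    path = Path(path)
    with open(path, encoding="utf-8", errors="replace") as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise ValueError(f"{path}: empty or missing header line")
        header = [c.strip().upper() for c in header_line.rstrip("\n").rstrip("\r").split("$")]
        missing = [c for c in _REQUIRED[schema] if c not in header]
        if missing:
            raise ValueError(f"{path}: header missing required column(s) {missing} for {schema}")
        ncols = len(header)
        builder = {
            "DEMO": _demo_record,
            "DRUG": _drug_record,
            "REAC": _reac_record,
            "THER": _ther_record,
        }[schema]
        records = []
        skipped = 0
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("$")
            if len(fields) != ncols:
                skipped += 1
                logger.warning("%s:%d: ragged line (%d fields, expected %d) skipped",
                               path, lineno, len(fields), ncols)
                continue
            row = dict(zip(header, fields))
            pid = _clean(row.get("PRIMARYID"))
            if pid is None:
                skipped += 1
                logger.warning("%s:%d: missing PRIMARYID, line skipped", path, lineno)
                continue
            row["PRIMARYID"] = pid
            if schema == "DEMO":
                cid = _clean(row.get("CASEID"))
                if cid is None:
                    skipped += 1
                    logger.warning("%s:%d: missing CASEID, line skipped", path, lineno)
                    continue
                row["CASEID"] = cid
            rec = builder(row)
            if rec is not None:
                records.append(rec)
    if skipped:
        logger.warning("%s: %d malformed line(s) skipped", path, skipped)
    return records


def _pid_sort_key(pid: str):
    # Numeric comparison when the id parses as an integer, else lexicographic;
    # all-numeric ids sort before non-numeric ones for determinism.
    if pid.isdigit():
        return (0, int(pid), pid)
    return (1, 0, pid)


def _recency_key(record: ReportRecord):
    # Raw FAERS dates are zero-padded digit strings, so string order is
    # chronological; absent dates sort earliest.  Ties fall back to the
    # higher primary id, then to the full record content, making the
    # retention rule total and order-invariant even for malformed inputs
    # that reuse a primary id with conflicting fields.
    return (record.fda_dt or "", _pid_sort_key(record.primary_id), repr(record))


def deduplicate(reports: Iterable[ReportRecord]) -> list[ReportRecord]:
    """Apply the FDA deduplication rules to DEMO records.

    Keeps one record per PRIMARY_ID (the higher id wins when ids collide,
    i.e. exact-id collisions keep the most recent FDA_DT), then one record
    per CASE_ID (most recent FDA_DT wins; FDA_DT ties resolved by the higher
    PRIMARY_ID).  The result is sorted by primary id, so the operation is
    idempotent and invariant under permutation of its input.
    """
    by_pid: dict[str, ReportRecord] = {}
    for rec in reports:
        cur = by_pid.get(rec.primary_id)
        if cur is None or _recency_key(rec) > _recency_key(cur):
            by_pid[rec.primary_id] = rec
    by_case: dict[str, ReportRecord] = {}
    for rec in by_pid.values():
        cur = by_case.get(rec.case_id)
        if cur is None or _recency_key(rec) > _recency_key(cur):
            by_case[rec.case_id] = rec
    return sorted(by_case.values(), key=lambda r: _pid_sort_key(r.primary_id))
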