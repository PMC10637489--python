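"""Reading FAERS-style quarterly ASCII tables and assembling reports.

FAERS quarterly extracts are dollar-delimited text tables with a header
row.  The raw stream contains multiple versions of the same case (the
database is republished quarterly), so before any counting the standard
deduplication rule is applied: keep, per CASEID, the version with the
latest FDA_DT, breaking ties by the higher PRIMARYID.
"""

from __future__ import annotations

import datetime
import logging
from pathlib import Path

import pandas as pd

from .records import DrugEntry, ReportRecord, TherapyEntry

log = logging.getLogger(__name__)


class FaersFormatError(ValueError):
    """Raised for missing mandatory files or excess malformed rows."""


#: Mandatory table -> expected columns (FAERS naming).
TABLE_COLUMNS: dict[str, list[str]] = {
    "DEMO": [
        "PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT", "SEX", "AGE",
        "AGE_COD", "WT", "WT_COD", "OCCP_COD", "REPORTER_COUNTRY",
    ],
    "DRUG": ["PRIMARYID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME", "PROD_AI"],
    "REAC": ["PRIMARYID", "PT"],
    "THER": ["PRIMARYID", "DSG_DRUG_SEQ", "START_DT", "END_DT"],
    "INDI": ["PRIMARYID", "INDI_PT"],
    "OUTC": ["PRIMARYID", "OUTC_COD"],
}

DELIM = "$"


# ---------------------------------------------------------------------------
# date classification

def parse_date(text: str | None) -> tuple[str, str | None]:
    """Classify a FAERS date string.

    Returns ``(kind, value)`` where kind is one of:

    - ``"full"``    -- 8 digits forming a valid calendar date
    - ``"partial"`` -- 6 digits (valid year+month) or 4 digits (year only),
      the FAERS dialect for partially known dates
    - ``"missing"`` -- empty / None
    - ``"invalid"`` -- anything else (non-digits, impossible month/day, ...)

    Classification never raises; cleaning stages decide what to exclude.
    """
    if text is None:
        return "missing", None
    s = str(text).strip()
    if not s:
        return "missing", None
    if not s.isdigit():
        return "invalid", s
    if len(s) == 8:
        try:
            datetime.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
        except ValueError:
            return "invalid", s
        return "full", s
    if len(s) == 6:
        month = int(s[4:6])
        if 1 <= month <= 12:
            return "partial", s
        return "invalid", s
    if len(s) == 4:
        if 1900 <= int(s) <= 2100:
            return "partial", s
        return "invalid", s
    return "invalid", s


def date_to_ordinal(yyyymmdd: str) -> int:
    """Proleptic ordinal of a full-precision FAERS date string."""
    return datetime.date(
        int(yyyymmdd[:4]), int(yyyymmdd[4:6]), int(yyyymmdd[6:8])
    ).toordinal()


# ---------------------------------------------------------------------------
# raw table reading

def _read_table(path: Path, columns: list[str], tolerance: float) -> pd.DataFrame:
    rows: list[list[str]] = []
    malformed = 0
    with open(path, encoding="utf-8", newline="") as fh:
        header_line = fh.readline()
        header = [h.strip() for h in header_line.rstrip("\r\n").split(DELIM)]
        if header != columns:
            raise FaersFormatError(
                f"{path.name}: header {header!r} does not match expected {columns!r}"
            )
        total = 0
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            total += 1
            fields = line.split(DELIM)
            if len(fields) != len(columns):
                malformed += 1
                continue
            rows.append(fields)
    if malformed:
        log.warning("%s: %d malformed rows skipped", path.name, malformed)
    if total and malformed / total > tolerance:
        raise FaersFormatError(
            f"{path.name}: {malformed}/{total} malformed rows exceeds "
            f"tolerance {tolerance:.0%}"
        )
    df = pd.DataFrame(rows, columns=columns, dtype=str)
    df.attrs["n_malformed"] = malformed
    return df


def read_quarter(directory: str | Path, malformed_tolerance: float = 0.05) -> dict[str, pd.DataFrame]:
    """Parse one quarter directory (DEMO.txt, DRUG.txt, ...).

    All columns are preserved as text; empty strings denote missing values.
    Rows with the wrong number of delimiters are counted, logged and skipped;
    more than ``malformed_tolerance`` of them in a table is an error.
    """
    directory = Path(directory)
    tables: dict[str, pd.DataFrame] = {}
    for name, columns in TABLE_COLUMNS.items():
        path = directory / f"{name}.txt"
        if not path.exists():
            raise FaersFormatError(f"mandatory file missing: {path}")
        tables[name] = _read_table(path, columns, malformed_tolerance)
    return tables


# ---------------------------------------------------------------------------
# deduplication

def _primaryid_key(series: pd.Series) -> pd.Series:
    """Numeric sort key for PRIMARYID; non-numeric ids fall back to -1 and
    are then ordered by their string form in a secondary sort column."""
    return pd.to_numeric(series, errors="coerce").fillna(-1.0)


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """One row per CASEID: survivor maximizes (FDA_DT, PRIMARYID).

    Implements the two-step rule -- latest FDA_DT first, higher PRIMARYID on
    ties -- as a single lexicographic maximization.  Idempotent.
    """
    if demo.empty:
        return demo.copy()
    work = demo.assign(
        _fda=pd.to_numeric(demo["FDA_DT"], errors="coerce").fillna(-1.0),
        _pid=_primaryid_key(demo["PRIMARYID"]),
    )
    work = work.sort_values(
        ["CASEID", "_fda", "_pid", "PRIMARYID"], kind="mergesort"
    )
    out = work.drop_duplicates("CASEID", keep="last")
    return out.drop(columns=["_fda", "_pid"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# assembly

def _opt_float(s: str) -> float | None:
    s = s.strip()
    if not s:
        return None
    try:
        return float(s)
    except ValueError:
        return None


def _opt_str(s: str) -> str | None:
    return s if s != "" else None


def assemble_reports(tables: dict[str, pd.DataFrame]) -> tuple[list[ReportRecord], dict[str, int]]:
    """Join child tables onto (deduplicated) DEMO rows by PRIMARYID.

    Child rows referencing a PRIMARYID absent from DEMO (dropped report
    versions, or stray ids) are discarded; a tally of discards per table is
    returned alongside the records.
    """
    demo = tables["DEMO"]
    keep = set(demo["PRIMARYID"])
    discarded: dict[str, int] = {}
    children: dict[str, dict[str, list]] = {}
    for name in ("DRUG", "REAC", "THER", "INDI", "OUTC"):
        df = tables[name]
        mask = df["PRIMARYID"].isin(keep)
        discarded[name] = int((~mask).sum())
        grouped: dict[str, list] = {}
        for row in df[mask].itertuples(index=False):
            grouped.setdefault(row.PRIMARYID, []).append(row)
        children[name] = grouped
    for name, n in discarded.items():
        if n:
            log.info("%s: %d child rows referenced dropped report versions", name, n)

    records: list[ReportRecord] = []
    for row in demo.itertuples(index=False):
        pid = row.PRIMARYID
        sex = row.SEX if row.SEX in ("F", "M") else "unknown"
        rec = ReportRecord(
            primaryid=int(pid),
            caseid=int(row.CASEID),
            fda_dt=row.FDA_DT,
            event_dt=_opt_str(row.EVENT_DT),
            sex=sex,
            age_value=_opt_float(row.AGE),
            age_unit=_opt_str(row.AGE_COD),
            weight_value=_opt_float(row.WT),
            weight_unit=_opt_str(row.WT_COD),
            country=row.REPORTER_COUNTRY,
            reporter=row.OCCP_COD,
            outcomes=[r.OUTC_COD for r in children["OUTC"].get(pid, [])],
            drugs=[
                DrugEntry(
                    seq=int(r.DRUG_SEQ), role=r.ROLE_COD,
                    drugname=r.DRUGNAME, prod_ai=r.PROD_AI,
                )
                for r in children["DRUG"].get(pid, [])
            ],
            reactions=[r.PT for r in children["REAC"].get(pid, [])],
            therapies=[
                TherapyEntry(
                    drug_seq=int(r.DSG_DRUG_SEQ),
                    start_dt=_opt_str(r.START_DT),
                    end_dt=_opt_str(r.END_DT),
                )
                for r in children["THER"].get(pid, [])
            ],
            indications=[r.INDI_PT for r in children["INDI"].get(pid, [])],
        )
        records.append(rec)
    return records, discarded


def read_reports(directory: str | Path, malformed_tolerance: float = 0.05) -> tuple[list[ReportRecord], dict[str, int]]:
    """Convenience: read a quarter, deduplicate DEMO, assemble records.

    Returns the records plus a tally dict including the number of duplicate
    report versions removed.
    """
    tables = read_quarter(directory, malformed_tolerance)
    n_raw = len(tables["DEMO"])
    tables = dict(tables)
    tables["DEMO"] = deduplicate(tables["DEMO"])
    records, discarded = assemble_reports(tables)
    tallies = {"demo_rows_raw": n_raw, "duplicates_removed": n_raw - len(records)}
    tallies.update({f"discarded_{k.lower()}": v for k, v in discarded.items()})
    return records, tallies
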