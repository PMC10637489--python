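"""Target-drug cohort construction and descriptive tables.

The analysis unit downstream is the distinct (report, PT) record.  This
module finds reports naming the target drug (by free-text DRUGNAME or
active-ingredient PROD_AI, restricted to chosen role codes, primary
suspect by default), extracts case pairs, removes the drug's own
indications from the event list, annotates PTs with their System Organ
Class, and produces the demographic and annual-count summaries.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .records import ReportRecord

log = logging.getLogger(__name__)


def normalize_name(name: str) -> str:
    """Case/whitespace-insensitive drug-name key.

    Trailing formulation qualifiers after a period ("ETOPOSIDE. INJECTION")
    are stripped, a common FAERS free-text pattern.
    """
    return name.split(".", 1)[0].strip().casefold()


@dataclass(frozen=True)
class DrugQuery:
    """Which drug rows count as the target drug."""

    names: frozenset[str]
    fields: tuple[str, ...] = ("DRUGNAME", "PROD_AI")
    roles: frozenset[str] = frozenset({"PS"})

    @classmethod
    def from_names(cls, names, fields=("DRUGNAME", "PROD_AI"), roles=("PS",)) -> "DrugQuery":
        normalized = frozenset(normalize_name(n) for n in names)
        if not normalized:
            raise ValueError("name list must be non-empty")
        return cls(names=normalized, fields=tuple(fields), roles=frozenset(roles))

    def _row_matches(self, drug) -> bool:
        candidates = []
        if "DRUGNAME" in self.fields:
            candidates.append(drug.drugname)
        if "PROD_AI" in self.fields:
            candidates.append(drug.prod_ai)
        return any(normalize_name(c) in self.names for c in candidates)

    def matches(self, report: ReportRecord) -> bool:
        return any(
            d.role in self.roles and self._row_matches(d) for d in report.drugs
        )

    def matched_seqs(self, report: ReportRecord) -> set[int]:
        """DRUG_SEQ values of target rows (for linking therapy episodes)."""
        return {
            d.seq for d in report.drugs
            if d.role in self.roles and self._row_matches(d)
        }


def identify_drug_reports(reports: list[ReportRecord], query: DrugQuery) -> list[ReportRecord]:
    """Reports with >=1 drug row matching the query name and role."""
    out = [r for r in reports if query.matches(r)]
    if not out:
        log.warning("drug query matched no reports")
    return out


# ---------------------------------------------------------------------------
# case pairs


def extract_case_pairs(reports: list[ReportRecord]) -> pd.DataFrame:
    """Distinct (report, PT) pairs; duplicate PT mentions collapse."""
    rows = [
        (r.primaryid, pt)
        for r in reports
        for pt in r.distinct_reactions()
    ]
    return pd.DataFrame(rows, columns=["primaryid", "pt"])


def build_pair_database(
    reports: list[ReportRecord], query: DrugQuery
) -> pd.DataFrame:
    """All distinct (report, PT) pairs with a boolean target-drug flag.

    This is the case/non-case database the disproportionality stage
    consumes: `target` pairs come from reports where the query matches.
    """
    rows = []
    for r in reports:
        is_target = query.matches(r)
        for pt in r.distinct_reactions():
            rows.append((r.primaryid, pt, is_target))
    return pd.DataFrame(rows, columns=["primaryid", "pt", "target"])


def derive_indication_set(reports: list[ReportRecord], min_count: int = 1) -> set[str]:
    """Indication PTs observed in the target reports' INDI rows."""
    counts: dict[str, int] = {}
    for r in reports:
        for ind in set(i.strip().casefold() for i in r.indications):
            counts[ind] = counts.get(ind, 0) + 1
    return {ind for ind, n in counts.items() if n >= min_count}


def exclude_indications(
    pairs: pd.DataFrame, indication_pts: set[str]
) -> tuple[pd.DataFrame, int]:
    """Drop pairs whose PT is in the exclusion set (case-insensitive)."""
    if not indication_pts:
        return pairs, 0
    normalized = {p.strip().casefold() for p in indication_pts}
    mask = pairs["pt"].str.strip().str.casefold().isin(normalized)
    n_removed = int(mask.sum())
    if n_removed:
        log.info("indication exclusion removed %d pairs", n_removed)
    return pairs[~mask].reset_index(drop=True), n_removed


# ---------------------------------------------------------------------------
# PT -> SOC map


class PtSocMap:
    """Total map from PT to one SOC; unknown PTs map to ``"Unmapped"``."""

    UNMAPPED = "Unmapped"

    def __init__(self, mapping: dict[str, str]):
        self._map = {normalize_key(pt): soc for pt, soc in mapping.items()}

    @classmethod
    def from_csv(cls, path: str | Path) -> "PtSocMap":
        mapping: dict[str, str] = {}
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            if [h.strip().upper() for h in header[:2]] != ["PT", "SOC"]:
                raise ValueError(f"{path}: expected 'PT,SOC' header, got {header!r}")
            for row in reader:
                if len(row) >= 2:
                    mapping[row[0]] = row[1]
        return cls(mapping)

    def get(self, pt: str) -> str:
        return self._map.get(normalize_key(pt), self.UNMAPPED)

    def annotate(self, pairs: pd.DataFrame) -> pd.DataFrame:
        """Add a ``soc`` column; count of unmapped pairs is logged."""
        soc = pairs["pt"].map(self.get)
        n_unmapped = int((soc == self.UNMAPPED).sum())
        if n_unmapped:
            log.info("%d pairs have PTs absent from the SOC map", n_unmapped)
        return pairs.assign(soc=soc)


def normalize_key(pt: str) -> str:
    return pt.strip().casefold()


# ---------------------------------------------------------------------------
# demographics normalization


def age_in_years(value: float | None, unit: str | None) -> float | None:
    """Normalize AGE/AGE_COD to years."""
    if value is None:
        return None
    factor = {
        "DEC": 10.0, "YR": 1.0, "MON": 1 / 12, "WK": 1 / 52,
        "DY": 1 / 365.25, "HR": 1 / 8766,
    }.get(unit or "YR")
    if factor is None:
        return None
    return value * factor


def weight_in_kg(value: float | None, unit: str | None) -> float | None:
    if value is None:
        return None
    factor = {"KG": 1.0, "LBS": 0.4536, "GMS": 1 / 1000}.get(unit or "KG")
    if factor is None:
        return None
    return value * factor


def age_bin(years: float | None) -> str:
    """<18 (child/adolescent), 18-64 (adult), >64 (elder); both boundary
    ages 18 and 64 fall in the middle bin."""
    if years is None:
        return "unknown"
    if years < 18:
        return "<18"
    if years <= 64:
        return "18-64"
    return ">64"


def weight_bin(kg: float | None) -> str:
    """<80 / 80-100 / >100 kg; 80 and 100 fall in the middle bin."""
    if kg is None:
        return "unknown"
    if kg < 80:
        return "<80"
    if kg <= 100:
        return "80-100"
    return ">100"


def reporter_category(occp_cod: str) -> str:
    """FAERS occupation codes grouped as consumer vs health professional."""
    code = occp_cod.strip().upper()
    if code == "CN":
        return "consumer"
    if code in ("MD", "PH", "OT", "RN", "HP", "LW"):
        return "health professional"
    return "unknown"


# ---------------------------------------------------------------------------
# descriptive tables


def _pct(count: int, total: int) -> float:
    if total == 0:
        return 0.0
    return round(100.0 * count / total, 1)


def demographics_summary(reports: list[ReportRecord], top_k: int = 5) -> pd.DataFrame:
    """Counts and percentages per characteristic, 1 decimal.

    For sex, weight, age and reporter the categories (including 'unknown')
    partition the reports and percentages are of the total report count;
    countries and indications list the top-k only.  Outcome rows count
    reports carrying each code, and because a report can carry several
    serious-outcome codes their percentages are of the total number of
    outcome entries (so the outcome block itself sums to 100%).
    """
    total = len(reports)
    rows: list[tuple[str, str, int, float]] = []

    def tally(characteristic: str, values, order=None) -> None:
        counts: dict[str, int] = {}
        for v in values:
            counts[v] = counts.get(v, 0) + 1
        keys = order if order is not None else sorted(counts)
        for k in keys:
            rows.append((characteristic, k, counts.get(k, 0), _pct(counts.get(k, 0), total)))

    tally("sex", (r.sex if r.sex in ("F", "M") else "unknown" for r in reports),
          order=["F", "M", "unknown"])
    tally("weight_kg", (weight_bin(weight_in_kg(r.weight_value, r.weight_unit)) for r in reports),
          order=["<80", "80-100", ">100", "unknown"])
    tally("age_years", (age_bin(age_in_years(r.age_value, r.age_unit)) for r in reports),
          order=["<18", "18-64", ">64", "unknown"])
    tally("reporter", (reporter_category(r.reporter) for r in reports),
          order=["health professional", "consumer", "unknown"])

    country_counts: dict[str, int] = {}
    for r in reports:
        country_counts[r.country] = country_counts.get(r.country, 0) + 1
    for k, n in sorted(country_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]:
        rows.append(("country", k, n, _pct(n, total)))

    outcome_counts: dict[str, int] = {}
    for r in reports:
        for oc in set(r.outcomes):
            outcome_counts[oc] = outcome_counts.get(oc, 0) + 1
    outcome_total = sum(outcome_counts.values())
    for k, n in sorted(outcome_counts.items(), key=lambda kv: (-kv[1], kv[0])):
        rows.append(("outcome", k, n, _pct(n, outcome_total)))

    indi_counts: dict[str, int] = {}
    for r in reports:
        for ind in set(r.indications):
            indi_counts[ind] = indi_counts.get(ind, 0) + 1
    for k, n in sorted(indi_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]:
        rows.append(("indication", k, n, _pct(n, total)))

    return pd.DataFrame(rows, columns=["characteristic", "level", "count", "pct"])


def annual_counts(
    reports: list[ReportRecord], start_year: int = 2004, end_year: int = 2022
) -> pd.Series:
    """Report counts keyed by calendar year of FDA_DT; zero years included."""
    counts = {y: 0 for y in range(start_year, end_year + 1)}
    for r in reports:
        year = int(r.fda_dt[:4])
        if year in counts:
            counts[year] += 1
    return pd.Series(counts, name="reports").rename_axis("year")
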