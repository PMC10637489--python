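"""Core record model for spontaneous safety reports.

A *case* is a real-world event narrative; FAERS assigns it a CASEID and
publishes one or more versions of it, each with its own PRIMARYID.  After
deduplication exactly one version per case remains.  ``ReportRecord`` holds
one report version together with its nested drug / reaction / therapy /
indication / outcome entries, mirroring the joined content of the DEMO,
DRUG, REAC, THER, INDI and OUTC quarterly tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: FAERS drug role codes: primary suspect, secondary suspect, concomitant,
#: interacting.
VALID_ROLES = ("PS", "SS", "C", "I")

#: FAERS serious-outcome codes (death, life-threatening, hospitalization,
#: disability, congenital anomaly, required intervention, other).
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

AGE_UNITS = ("DEC", "YR", "MON", "WK", "DY", "HR")
WEIGHT_UNITS = ("KG", "LBS", "GMS")


@dataclass
class DrugEntry:
    """One DRUG-table row: a drug named on the report."""

    seq: int
    role: str
    drugname: str
    prod_ai: str


@dataclass
class TherapyEntry:
    """One THER-table row: a therapy episode for the drug with ``drug_seq``.

    Dates are kept as raw FAERS strings (``YYYYMMDD``, possibly truncated to
    ``YYYYMM``/``YYYY`` for partial dates, or ``None`` when absent) so that
    downstream cleaning can classify them explicitly.
    """

    drug_seq: int
    start_dt: str | None = None
    end_dt: str | None = None


@dataclass
class ReportRecord:
    """One safety-report version with all child entries joined in."""

    primaryid: int
    caseid: int
    fda_dt: str
    event_dt: str | None = None
    sex: str = "unknown"  # 'F', 'M' or 'unknown'
    age_value: float | None = None
    age_unit: str | None = None
    weight_value: float | None = None
    weight_unit: str | None = None
    country: str = ""
    reporter: str = ""  # OCCP_COD, e.g. MD/PH/RN/OT/CN
    outcomes: list[str] = field(default_factory=list)
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)
    therapies: list[TherapyEntry] = field(default_factory=list)
    indications: list[str] = field(default_factory=list)

    def distinct_reactions(self) -> list[str]:
        """Reaction PTs with within-report duplicates collapsed, order kept."""
        seen: set[str] = set()
        out: list[str] = []
        for pt in self.reactions:
            key = pt.strip().casefold()
            if key not in seen:
                seen.add(key)
                out.append(pt)
        return out
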