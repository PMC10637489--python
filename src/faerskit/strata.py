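"""Subgroup disproportionality and within-drug sex-difference analysis.

Subgroup screening re-runs the full four-algorithm case/non-case analysis
inside each stratum's own database slice (both the target drug and the
comparator restricted to the stratum).  Records whose stratification value
is unknown are excluded from that stratification.

The sex-difference analysis conditions on target-drug reports only: for
each PT a 2x2 of (event vs all other events) x (female vs male) is formed
over distinct (report, PT) records, giving a female-over-male reporting
odds ratio with a Table-style log-normal CI, a two-sided Fisher exact
p-value, and Benjamini-Hochberg adjustment across all tested PTs.  Volcano
coordinates are x = log2(ROR_fm), y = -log10(p_adj).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from . import disprop
from .cohort import (
    DrugQuery,
    age_bin,
    age_in_years,
    build_pair_database,
    reporter_category,
    weight_bin,
    weight_in_kg,
)
from .records import ReportRecord

log = logging.getLogger(__name__)

STRATUM_LEVELS: dict[str, tuple[str, ...]] = {
    "age": ("<18", "18-64", ">64"),
    "weight": ("<80", "80-100", ">100"),
    "sex": ("F", "M"),
    "reporter": ("consumer", "health professional"),
}


@dataclass(frozen=True)
class StratumSpec:
    """A stratification variable with its ordered levels."""

    variable: str

    def __post_init__(self):
        if self.variable not in STRATUM_LEVELS:
            raise ValueError(f"unknown stratification variable {self.variable!r}")

    @property
    def levels(self) -> tuple[str, ...]:
        return STRATUM_LEVELS[self.variable]

    def level_of(self, report: ReportRecord) -> str | None:
        """The report's level, or None when unknown (excluded)."""
        if self.variable == "age":
            lvl = age_bin(age_in_years(report.age_value, report.age_unit))
        elif self.variable == "weight":
            lvl = weight_bin(weight_in_kg(report.weight_value, report.weight_unit))
        elif self.variable == "sex":
            lvl = report.sex
        else:
            lvl = reporter_category(report.reporter)
        return lvl if lvl in self.levels else None


def subgroup_signals(
    reports: list[ReportRecord],
    query: DrugQuery,
    spec: StratumSpec,
    min_cases: int = 3,
    top_n: int = 10,
) -> dict[str, dict[str, pd.DataFrame]]:
    """Per-level four-algorithm screening within each stratum slice.

    Returns, per level, the screened significant table (``significant``)
    and its top-``top_n`` rows by case count (``top``).  Levels with no
    target-drug records yield empty tables with a warning.
    """
    out: dict[str, dict[str, pd.DataFrame]] = {}
    by_level: dict[str, list[ReportRecord]] = {lvl: [] for lvl in spec.levels}
    for r in reports:
        lvl = spec.level_of(r)
        if lvl is not None:
            by_level[lvl].append(r)
    for lvl, slice_reports in by_level.items():
        pairs = build_pair_database(slice_reports, query)
        if pairs.empty or not pairs["target"].any():
            log.warning("stratum %s=%s has no target-drug records", spec.variable, lvl)
            empty = pd.DataFrame(
                columns=["pt", "a", "b", "c", "d", *disprop.STAT_COLUMNS, *disprop.FLAG_COLUMNS]
            )
            out[lvl] = {"significant": empty, "top": empty}
            continue
        table = disprop.pt_signal_table(pairs, min_cases=min_cases)
        sig = disprop.screen_signals(table)
        top = sig.sort_values(["a", "pt"], ascending=[False, True]).head(top_n)
        out[lvl] = {"significant": sig, "top": top.reset_index(drop=True)}
    return out


# ---------------------------------------------------------------------------
# sex differences within the target drug


def gender_disproportionality(
    target_reports: list[ReportRecord], min_cases: int = 3
) -> pd.DataFrame:
    """Female-vs-male reporting odds ratio per PT within the target drug.

    PTs with fewer than ``min_cases`` target-drug records overall are not
    tested.  Zero cells leave the ROR and its CI as NaN sentinels; the
    Fisher exact p is still computed.
    """
    rows = [
        (r.primaryid, r.sex, pt)
        for r in target_reports
        if r.sex in ("F", "M")
        for pt in r.distinct_reactions()
    ]
    pairs = pd.DataFrame(rows, columns=["primaryid", "sex", "pt"])
    if pairs.empty:
        return pd.DataFrame(
            columns=["pt", "a_f", "b_f", "a_m", "b_m", "ror_fm", "ror_lo",
                     "ror_hi", "p_value", "p_adj", "log2_ror", "neg_log10_p_adj"]
        )
    total_f = int((pairs["sex"] == "F").sum())
    total_m = int((pairs["sex"] == "M").sum())
    counts = pairs.groupby(["pt", "sex"]).size().unstack(fill_value=0)
    a_f = counts.get("F", pd.Series(0, index=counts.index)).astype(int)
    a_m = counts.get("M", pd.Series(0, index=counts.index)).astype(int)
    keep = (a_f + a_m) >= min_cases
    pts = counts.index[keep]
    af = a_f[keep].to_numpy(dtype=float)
    am = a_m[keep].to_numpy(dtype=float)
    bf = total_f - af
    bm = total_m - am

    with np.errstate(divide="ignore", invalid="ignore"):
        any_zero = (af == 0) | (bf == 0) | (am == 0) | (bm == 0)
        ror = np.where(any_zero, np.nan, (af * bm) / (bf * am))
        se = np.sqrt(1 / af + 1 / bf + 1 / am + 1 / bm)
        lo = np.exp(np.log(ror) - disprop.Z95 * se)
        hi = np.exp(np.log(ror) + disprop.Z95 * se)

    p = np.array([
        fisher_exact([[int(a1), int(b1)], [int(a2), int(b2)]], alternative="two-sided")[1]
        for a1, b1, a2, b2 in zip(af, bf, am, bm)
    ])
    p_adj = bh_adjust(p) if len(p) else p

    with np.errstate(divide="ignore", invalid="ignore"):
        df = pd.DataFrame({
            "pt": pts,
            "a_f": af.astype(int), "b_f": bf.astype(int),
            "a_m": am.astype(int), "b_m": bm.astype(int),
            "ror_fm": ror, "ror_lo": lo, "ror_hi": hi,
            "p_value": p, "p_adj": p_adj,
            "log2_ror": np.log2(ror),
            "neg_log10_p_adj": -np.log10(p_adj),
        })
    return df.sort_values("pt").reset_index(drop=True)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def volcano_coordinates(signals: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """(x, y) volcano coordinates with significance and direction labels.

    x = log2(ROR_fm), y = -log10(p_adj).  Rows with undefined ROR are
    omitted (logged).  ``direction`` is 'female' for x > 0, 'male' for
    x < 0, 'none' at exactly 0.
    """
    defined = signals["ror_fm"].notna()
    n_omitted = int((~defined).sum())
    if n_omitted:
        log.info("volcano: %d PTs omitted for undefined ROR", n_omitted)
    df = signals[defined].copy()
    df["x"] = np.log2(df["ror_fm"])
    df["y"] = -np.log10(df["p_adj"])
    df["significant"] = df["p_adj"] < alpha
    df["direction"] = np.select(
        [df["x"] > 0, df["x"] < 0], ["female", "male"], default="none"
    )
    return df[["pt", "x", "y", "significant", "direction"]].reset_index(drop=True)
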