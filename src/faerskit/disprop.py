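"""Case/non-case disproportionality statistics.

For each (drug, event) pair a 2x2 table over distinct (report, PT) records
is formed:

=========  ===================  =====================
            target event         other events
=========  ===================  =====================
target drug        a                    b
other drugs        c                    d
=========  ===================  =====================

Four estimators are computed, each with its conventional signal criterion:

- ROR   = ad/(bc);          positive when the lower 95% CI bound > 1
- PRR   = a(c+d)/(c(a+b)) with chi-squared (uncorrected);
  positive when PRR >= 2, chi2 >= 4
- IC    = log2[aN/((a+c)(a+b))] (BCPNN information component);
  positive when IC025 > 0
- EBGM  = aN/((a+c)(a+b)) with a log-normal interval;
  positive when EBGM05 > 2

A minimum case count (3 by default) applies on top of the ROR and PRR
criteria, and a screened signal must satisfy all four simultaneously.

Note on the Bayesian labels: IC and EBGM here are the observed-to-expected
reporting ratio on log2 and natural scales -- no Dirichlet posterior and no
gamma-Poisson shrinkage is applied, so 2**IC == EBGM holds exactly.  The
IC025 spread is a delta-method standard error on the log2 scale,
sqrt(1/a+1/b+1/c+1/d)/ln 2 (configurable).  All interval bounds are
undefined (NaN) whenever a cell is zero; an optional Haldane +0.5
correction is available but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; floats are accepted so identity-based table
    constructions (fixing ROR and solving for d) stay exact."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0:
                raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


@dataclass
class SignalResult:
    """Estimators, interval bounds and criterion flags for one event."""

    pt: str
    a: float
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    soc: str | None = None
    ror_pos: bool = False
    prr_pos: bool = False
    bcpnn_pos: bool = False
    mgps_pos: bool = False
    all_four: bool = False
    unexpected: bool | None = None


STAT_COLUMNS = ["ror", "ror_lo", "ror_hi", "prr", "chi2", "ic", "ic025", "ebgm", "ebgm05"]
FLAG_COLUMNS = ["ror_pos", "prr_pos", "bcpnn_pos", "mgps_pos", "all_four"]


def _stats_arrays(a, b, c, d, haldane: float = 0.0) -> dict[str, np.ndarray]:
    """Vectorized estimator computation; zero cells yield NaN."""
    a = np.asarray(a, dtype=float) + haldane
    b = np.asarray(b, dtype=float) + haldane
    c = np.asarray(c, dtype=float) + haldane
    d = np.asarray(d, dtype=float) + haldane
    n = a + b + c + d
    out: dict[str, np.ndarray] = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        any_zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
        se_log = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)

        ror = np.where(any_zero, np.nan, (a * d) / (b * c))
        out["ror"] = ror
        out["ror_lo"] = np.exp(np.log(ror) - Z95 * se_log)
        out["ror_hi"] = np.exp(np.log(ror) + Z95 * se_log)

        prr = np.where((c == 0) | (a + b == 0), np.nan, a * (c + d) / (c * (a + b)))
        out["prr"] = prr
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        out["chi2"] = np.where(
            denom == 0, np.nan, (a * d - b * c) ** 2 * n / denom
        )

        rrr = np.where(
            (a == 0) | (a + c == 0) | (a + b == 0),
            np.nan,
            a * n / ((a + c) * (a + b)),
        )
        out["ic"] = np.log2(rrr)
        out["ic025"] = out["ic"] - 2.0 * np.where(any_zero, np.nan, se_log) / math.log(2)
        out["ebgm"] = rrr
        out["ebgm05"] = np.exp(
            np.log(rrr) - Z95 * np.where(any_zero, np.nan, se_log)
        )
    return out


def compute_signal_stats(
    table: ContingencyTable, pt: str = "", haldane: float = 0.0
) -> SignalResult:
    """Point estimates and 95% interval bounds for one 2x2 table.

    Criterion flags are left False; apply :func:`apply_criteria` after.
    """
    stats = _stats_arrays(
        np.array([table.a]), np.array([table.b]),
        np.array([table.c]), np.array([table.d]), haldane=haldane,
    )
    return SignalResult(
        pt=pt, a=table.a, **{k: float(stats[k][0]) for k in STAT_COLUMNS}
    )


def apply_criteria(result: SignalResult, min_cases: int = 3) -> SignalResult:
    """Set the per-algorithm positivity flags and their conjunction.

    NaN estimators fail their criterion (comparison with NaN is False).
    """
    ror_pos = bool(result.ror_lo > 1.0) and result.a >= min_cases
    prr_pos = (
        bool(result.prr >= 2.0) and bool(result.chi2 >= 4.0) and result.a >= min_cases
    )
    bcpnn_pos = bool(result.ic025 > 0.0)
    mgps_pos = bool(result.ebgm05 > 2.0)
    return replace(
        result,
        ror_pos=ror_pos,
        prr_pos=prr_pos,
        bcpnn_pos=bcpnn_pos,
        mgps_pos=mgps_pos,
        all_four=ror_pos and prr_pos and bcpnn_pos and mgps_pos,
    )


# ---------------------------------------------------------------------------
# pair-database screening


def build_contingency(pairs: pd.DataFrame, event: str) -> ContingencyTable:
    """2x2 table for one event from a pair database.

    ``pairs`` must hold one row per distinct (report, PT) record with
    columns ``pt`` and boolean ``target``.  An event absent everywhere
    yields a valid table with a = c = 0.
    """
    is_event = pairs["pt"] == event
    is_target = pairs["target"].astype(bool)
    a = int((is_event & is_target).sum())
    b = int((~is_event & is_target).sum())
    c = int((is_event & ~is_target).sum())
    d = int((~is_event & ~is_target).sum())
    return ContingencyTable(a, b, c, d)


def _flag_frame(df: pd.DataFrame, min_cases: int) -> pd.DataFrame:
    df = df.copy()
    df["ror_pos"] = (df["ror_lo"] > 1.0) & (df["a"] >= min_cases)
    df["prr_pos"] = (df["prr"] >= 2.0) & (df["chi2"] >= 4.0) & (df["a"] >= min_cases)
    df["bcpnn_pos"] = df["ic025"] > 0.0
    df["mgps_pos"] = df["ebgm05"] > 2.0
    df["all_four"] = df[["ror_pos", "prr_pos", "bcpnn_pos", "mgps_pos"]].all(axis=1)
    return df


def pt_signal_table(
    pairs: pd.DataFrame,
    min_cases: int = 3,
    haldane: float = 0.0,
    level: str = "pt",
    include_zero_target: bool = False,
) -> pd.DataFrame:
    """All-events signal table from a pair database.

    One row per distinct value of ``level`` (``"pt"`` or ``"soc"``) with
    a >= 1 among target pairs (``include_zero_target`` adds a = 0 rows for
    events seen only among non-target pairs), carrying cells, estimators
    and flags.
    """
    target = pairs["target"].astype(bool)
    total_t = int(target.sum())
    total_nt = int((~target).sum())
    a_counts = pairs.loc[target, level].value_counts()
    c_counts = pairs.loc[~target, level].value_counts()
    events = a_counts.index
    if include_zero_target:
        events = events.union(c_counts.index, sort=False)
    a = a_counts.reindex(events).fillna(0).to_numpy(dtype=float)
    c = c_counts.reindex(events).fillna(0).to_numpy(dtype=float)
    b = total_t - a
    d = total_nt - c
    stats = _stats_arrays(a, b, c, d, haldane=haldane)
    df = pd.DataFrame({level: events, "a": a, "b": b, "c": c, "d": d, **stats})
    if level == "pt" and "soc" in pairs.columns:
        soc_of = pairs.drop_duplicates("pt").set_index("pt")["soc"]
        df.insert(1, "soc", df["pt"].map(soc_of))
    df = _flag_frame(df, min_cases)
    return df.reset_index(drop=True)


def soc_level_signals(
    pairs: pd.DataFrame, min_cases: int = 3, haldane: float = 0.0
) -> pd.DataFrame:
    """Same statistics with events aggregated at SOC level.

    a counts every target (report, PT) record whose PT belongs to the SOC.
    """
    if "soc" not in pairs.columns:
        raise ValueError("pairs must carry a 'soc' column; annotate first")
    return pt_signal_table(
        pairs, min_cases=min_cases, haldane=haldane, level="soc",
        include_zero_target=True,
    )


def screen_signals(signal_table: pd.DataFrame) -> pd.DataFrame:
    """Keep only rows satisfying all four criteria simultaneously."""
    return signal_table[signal_table["all_four"]].reset_index(drop=True)


def rank_and_filter(significant: pd.DataFrame, min_a: int = 30) -> pd.DataFrame:
    """Rows with a > min_a (strict), ranked by EBGM05 descending.

    Ties break by larger case count, then PT name.
    """
    key = "pt" if "pt" in significant.columns else "soc"
    df = significant[significant["a"] > min_a]
    return df.sort_values(
        ["ebgm05", "a", key], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# novelty flagging


def load_label_pts(path: str | Path) -> set[str]:
    """Read a product-label PT list, one PT per line."""
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


def flag_unexpected(significant: pd.DataFrame, label_pts: set[str]) -> pd.DataFrame:
    """Mark signals whose PT is absent from the label (case-insensitive)."""
    labeled = {p.strip().casefold() for p in label_pts}
    out = significant.copy()
    out["unexpected"] = ~out["pt"].str.strip().str.casefold().isin(labeled)
    return out
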