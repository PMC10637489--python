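"""Time-to-onset (TTO) analysis.

TTO is the delay in whole days between the start of the target drug's
therapy (earliest full-precision START_DT among the target drug rows) and
the adverse event onset date (EVENT_DT).  Records with missing or partial
dates, or with onset before therapy start, are excluded and tallied.
Same-day onsets (delay 0) are retained.

The retained delays are summarized (median, IQR, range), binned into
30-day months, and fitted with a two-parameter Weibull distribution whose
shape parameter beta classifies the hazard over time: early failure
(decreasing hazard, beta < 1), random (beta ~ 1) or wear-out (increasing,
beta > 1), judged on the 95% confidence interval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import DrugQuery
from .ingest import date_to_ordinal, parse_date
from .records import ReportRecord

log = logging.getLogger(__name__)


@dataclass
class TtoSample:
    """Retained onset delays plus exclusion tallies.

    ``values`` are non-negative whole days; the tallies plus ``len(values)``
    reconcile with the number of target reports examined.
    """

    values: np.ndarray
    n_excluded_missing: int = 0
    n_excluded_invalid: int = 0
    n_excluded_negative: int = 0

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class TtoSummary:
    n: int
    median: float
    q1: float
    q3: float
    min: float
    max: float


@dataclass
class WeibullFit:
    """MLE of a two-parameter Weibull with log-scale normal-approximation
    CIs from the observed information matrix."""

    alpha: float  # scale, days
    alpha_lo: float
    alpha_hi: float
    beta: float  # shape, dimensionless
    beta_lo: float
    beta_hi: float
    n: int
    small_sample: bool = False  # n < 30 warning annotation


# ---------------------------------------------------------------------------


def compute_tto(reports: list[ReportRecord], query: DrugQuery) -> TtoSample:
    """Per-report onset delay for the target drug.

    For each report the earliest full-precision START_DT among therapy rows
    linked to a target drug row is used.  Exclusion rules: missing event
    date or no therapy start at all -> missing; partial/invalid event or
    start dates (with none usable) -> invalid; onset before start ->
    negative.  Delay 0 is retained.
    """
    values: list[int] = []
    n_missing = n_invalid = n_negative = 0
    for r in reports:
        seqs = query.matched_seqs(r)
        ev_kind, ev = parse_date(r.event_dt)
        if ev_kind == "missing":
            n_missing += 1
            continue
        if ev_kind != "full":
            n_invalid += 1
            continue
        starts = [t.start_dt for t in r.therapies if t.drug_seq in seqs]
        if not any(s is not None for s in starts):
            n_missing += 1
            continue
        full_starts = [
            v for kind, v in (parse_date(s) for s in starts) if kind == "full"
        ]
        if not full_starts:
            n_invalid += 1
            continue
        start_ord = min(date_to_ordinal(s) for s in full_starts)
        delay = date_to_ordinal(ev) - start_ord
        if delay < 0:
            n_negative += 1
            continue
        values.append(delay)
    return TtoSample(
        values=np.asarray(values, dtype=float),
        n_excluded_missing=n_missing,
        n_excluded_invalid=n_invalid,
        n_excluded_negative=n_negative,
    )


def summarize_tto(sample: TtoSample) -> TtoSummary:
    """Median and quartiles (inclusive linear interpolation), min and max.

    An empty sample yields the explicit sentinel ``TtoSummary(n=0, NaN...)``.
    """
    v = sample.values
    if len(v) == 0:
        return TtoSummary(0, math.nan, math.nan, math.nan, math.nan, math.nan)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return TtoSummary(len(v), float(med), float(q1), float(q3), float(v.min()), float(v.max()))


def bin_tto(sample: TtoSample, bin_days: int = 30, n_bins: int = 12) -> pd.DataFrame:
    """Counts and percentages per 30-day bin plus a > 360-day tail.

    Bin k covers days [30(k-1), 30k); day 0 falls in bin 1.  Percentages
    are of the sample size, 1 decimal.
    """
    v = sample.values
    total = len(v)
    rows = []
    for k in range(1, n_bins + 1):
        lo, hi = bin_days * (k - 1), bin_days * k
        count = int(((v >= lo) & (v < hi)).sum())
        rows.append((f"{lo}-{hi - 1}", lo, hi, count))
    tail = int((v >= bin_days * n_bins).sum())
    rows.append((f">{bin_days * n_bins}", bin_days * n_bins, math.inf, tail))
    df = pd.DataFrame(rows, columns=["bin", "lo", "hi", "count"])
    df["pct"] = [round(100.0 * c / total, 1) if total else 0.0 for c in df["count"]]
    return df


# ---------------------------------------------------------------------------
# Weibull fit


class DegenerateSampleError(ValueError):
    """All observations equal: the Weibull MLE does not exist."""


def _weibull_nll(params: np.ndarray, x: np.ndarray) -> float:
    log_alpha, log_beta = params
    alpha, beta = math.exp(log_alpha), math.exp(log_beta)
    z = x / alpha
    return -float(
        np.sum(np.log(beta / alpha) + (beta - 1) * np.log(z) - z**beta)
    )


def _hessian(f, params: np.ndarray, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of f at params."""
    k = len(params)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            H[i, j] = H[j, i] = (
                f(params + ei + ej, x)
                - f(params + ei - ej, x)
                - f(params - ei + ej, x)
                + f(params - ei - ej, x)
            ) / (4 * h * h)
    return H


def fit_weibull(values: np.ndarray | TtoSample, zero_day: float = 0.5) -> WeibullFit:
    """Maximum-likelihood two-parameter Weibull fit with 95% CIs.

    Zero-day delays are mapped to ``zero_day`` (the likelihood needs
    positive support).  CIs come from the observed information matrix on
    (log alpha, log beta), exponentiated so bounds stay positive.  The fit
    is deterministic given the sample; n < 30 is annotated as a small
    sample, an all-equal sample raises :class:`DegenerateSampleError`.
    """
    if isinstance(values, TtoSample):
        values = values.values
    x = np.asarray(values, dtype=float).copy()
    if len(x) == 0:
        raise DegenerateSampleError("empty sample")
    x[x == 0] = zero_day
    if np.all(x == x[0]):
        raise DegenerateSampleError("all observations equal")
    small = len(x) < 30
    if small:
        log.warning("Weibull fit on n=%d < 30: estimates are unstable", len(x))

    beta_hat, _, alpha_hat = sps.weibull_min.fit(x, floc=0)
    params = np.array([math.log(alpha_hat), math.log(beta_hat)])
    H = _hessian(_weibull_nll, params, x)
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    z = 1.959963984540054
    return WeibullFit(
        alpha=alpha_hat,
        alpha_lo=math.exp(params[0] - z * se[0]),
        alpha_hi=math.exp(params[0] + z * se[0]),
        beta=beta_hat,
        beta_lo=math.exp(params[1] - z * se[1]),
        beta_hi=math.exp(params[1] + z * se[1]),
        n=len(x),
        small_sample=small,
    )


def classify_failure(fit: WeibullFit) -> str:
    """Hazard profile from the shape CI: 'early' if the upper bound of beta
    is below 1, 'wear-out' if the lower bound exceeds 1, else 'random'."""
    if fit.beta_hi < 1.0:
        return "early"
    if fit.beta_lo > 1.0:
        return "wear-out"
    return "random"
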