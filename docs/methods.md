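# Methods

## Data model and deduplication

A FAERS-style quarter is six dollar-delimited text tables (DEMO, DRUG,
REAC, THER, INDI, OUTC) keyed by PRIMARYID, the identifier of one
*version* of a case; CASEID identifies the case itself.  Because the
database is republished quarterly, several versions of a case coexist.
Deduplication keeps, per CASEID, the version maximizing the pair
(FDA_DT, PRIMARYID) lexicographically — i.e. the latest receipt date,
ties broken by the higher version id — in a single pass; the operation is
idempotent.  PRIMARYIDs are compared numerically when they are all-digit,
with a defensive string fallback.  Child rows referencing dropped versions
are discarded and tallied.

Dates are `YYYYMMDD` strings; 6- and 4-digit truncations are the partial-
date dialect and are *retained* in records but excluded by the onset
cleaning, since they are only unusable for day-resolution arithmetic.
Missing demographics map to explicit `unknown` categories rather than
being dropped, so every characteristic partitions the cohort.

## Cohort construction and counting unit

Target-drug reports are found by exact token match (case/whitespace
normalized, trailing formulation qualifiers after a period stripped) of a
name list against DRUGNAME and PROD_AI, restricted to chosen role codes —
primary suspect (PS) only by default, which trades sensitivity for
attribution accuracy.  Substring matching is deliberately not used.

All disproportionality counting uses distinct (report, PT) records:
duplicate PT mentions within a report collapse to one, `a + b` is the
target drug's total record count, and `N` is the total record count of the
deduplicated database.  `N` is always explicit in the implementation;
published per-estimator columns for a given cohort need not be mutually
consistent with any single `N`, and only N-free identities (such as the
PRR value implied by a case count and an ROR at fixed `a + b`) are used as
cross-checks against printed tables.

Indication PTs (the disease being treated) masquerade as reactions in
spontaneous data; by default the exclusion list is derived globally from
the INDI rows of the target reports and can be overridden with an explicit
list.  PT→SOC annotation is a total map loaded from a two-column CSV;
unknown PTs are annotated `Unmapped` and counted, never dropped silently.

## Estimators and criteria

The four statistics and their signal criteria are listed in the README.
Numerical choices:

- **Zero cells.**  Any zero cell leaves the affected estimators and all
  interval bounds as NaN sentinels, and NaN fails every criterion.  There
  is no silent continuity correction; an optional Haldane +0.5 is
  available (`haldane=0.5`) but off by default so that identity-based
  checks remain exact.
- **χ²** is the uncorrected Pearson statistic (no Yates correction).
- **IC interval.**  The IC025 spread is a delta-method standard error on
  the log₂ scale, √(1/a+1/b+1/c+1/d)/ln 2, subtracted twice from IC.  It
  uses only table cells and is deterministic; a Dirichlet-posterior BCPNN
  variant could be swapped in behind the same field.
- **EBGM here is the raw observed-to-expected reporting ratio** with a
  log-normal interval, not a gamma-Poisson shrinkage estimator; the
  shrinkage version is an explicit non-goal.  Consequently 2^IC = EBGM
  holds exactly, which the tests assert.
- **Ranking** of screened signals uses EBGM05 descending (the most
  stringent bound) among PTs with case count strictly above the threshold
  (default a > 30; the worked example lowers it for a small cohort), with
  ties broken by case count then PT name for full determinism.
- Novelty (`unexpected`) is a case-insensitive exact-match lookup of the
  PT against a product-label PT list, one term per line.

No multiplicity correction is applied at the screening stage; the
four-way conjunction plus the three-case minimum is the (conventional)
false-positive control there.  The sex-difference analysis, which runs
hundreds of explicit hypothesis tests, *is* BH-adjusted.

## Time-to-onset

Onset delay is EVENT_DT − START_DT in whole days, with START_DT the
earliest full-precision therapy start among the target drug's rows
(earliest exposure is the conservative choice when several episodes
exist).  Exclusions — missing dates, partial/invalid dates, negative
delays — are tallied separately and reconcile with the input count.
Day-0 delays are genuine same-day onsets and are retained; for the Weibull
likelihood, which needs positive support, they are mapped to 0.5 day and
the replacement is part of the documented fitting contract.

Binning uses 30-day months (bin k = days [30(k−1), 30k), day 0 in month
1, a > 360-day tail), reproducing count/percentage arithmetic without
calendar logic.

The Weibull fit is maximum likelihood for the two-parameter distribution;
95% CIs come from the observed information matrix on (log α, log β),
exponentiated so bounds are always positive.  The fit is deterministic
given the sample, refuses degenerate (all-equal or empty) samples and
annotates n < 30 as unstable.  Failure-type classification is interval
based: `early` when the upper CI bound of β is below 1, `wear-out` when
the lower bound exceeds 1, otherwise `random`.  Note that with β well
below 1 the distribution is heavily right-skewed, so the sample median
can sit far below the fitted scale α; the summary statistics and the fit
are reported independently and no reconciliation is attempted.

## Subgroups and sex differences

Subgroup screening re-runs the complete four-algorithm analysis inside
each stratum's own slice (target and comparator both restricted), because
stratified disproportionality is otherwise ill-defined.  Strata: age <18 /
18–64 / >64 years (18 and 64 in the middle bin; AGE_COD converted via
DEC×10, MON÷12, WK÷52, DY÷365.25, HR÷8766), weight <80 / 80–100 / >100 kg
(80 and 100 in the middle bin; LBS×0.4536, GMS÷1000), sex F/M, reporter
consumer vs health professional.  Unknown values drop a report from that
stratification only.

The sex-difference analysis conditions on the target drug's reports: per
PT with ≥ 3 cases, a 2×2 of (event vs other events) × (F vs M) gives a
female-over-male ROR with the same log-normal CI, a two-sided Fisher exact
p (used uniformly regardless of cell size — exact, and no cell-size
branch), and BH adjustment across all tested PTs.  Volcano coordinates are
x = log₂ ROR, y = −log₁₀ p_adj, labelled significant at p_adj < 0.05;
swapping the sex labels inverts the ROR and negates x exactly, which is
property-tested.

## Synthetic data generator

The generator emulates the study conditions the package is designed for:

- **Catalogs.**  10 drugs with inclusion probabilities 0.05–0.25 and ~40
  PTs over 8 SOCs whose baseline probabilities sum to ≈ 3, matching the
  ~3 reaction records per report seen in large spontaneous databases.
  Every report names at least one drug; exactly one included drug is the
  primary suspect (uniform among those included, with a
  probability-weighted pick when none was sampled).
- **Planted associations** multiply an event's baseline probability by a
  relative reporting ratio λ in reports containing the drug (capped at 1
  with a warning).  Defaults plant a cytotoxic-agent-like profile on the
  target drug (λ 6–50 on haematological, metabolic and reproductive
  terms).  A planted signal may be restricted to one stratum level and/or
  scaled in females, enabling subgroup- and sex-recovery tests.
- **Onset lags** are Weibull(scale 38.56 days, shape 0.55) — an
  early-failure profile typical of cytotoxic therapy — drawn per
  (report, drug) because therapy start dates attach to drugs; the report's
  event date is the primary-suspect start plus its lag, floored to whole
  days, so the true lag is recoverable exactly.
- **Demographics** follow an oncology reporting mix (sex F/M/unknown
  .343/.496/.161; age and weight bins with heavy weight missingness;
  country and reporter-occupation mixes; one serious-outcome code per
  report).
- **Dirty-data injection**: 55% missing event dates (large spontaneous
  cohorts yield usable onsets for well under a tenth of records), 5%
  partial dates (truncation to `YYYYMM`/`YYYY`), 10% duplicate case
  versions, 3% indication leakage into reaction lists.  Duplicates are
  injected *after* generation, each copying a case with a new PRIMARYID
  and an FDA_DT ≥ the original's, in flavours that exercise both halves of
  the dedup rule; the intended survivor is recorded as exact ground truth.

Everything is reproducible from the config seed.  What the generator does
**not** emulate: real drug-name misspellings beyond case/whitespace/
formulation variants, correlated event co-occurrence (PTs are
conditionally independent given the drug list), reporting trends over
calendar time, multi-outcome reports, and the pre-2004 legacy schema.
Passing tests therefore demonstrate correctness of the machinery and
calibration under clean independence assumptions, not robustness to every
real-world artefact.

## Verification strategy and problem sizes

The suite uses independent oracles throughout: hand/direct arithmetic for
the estimator formulas, brute-force recounts for contingency cells and
pair extraction, a sort-based quantile oracle, a hypergeometric
enumeration oracle for Fisher p-values, a hand-computed BH example, and
generator ground truth for deduplication, cohort identification and onset
lags.  Calibration checks run on 20 000-case generated databases: with
λ = 1 everywhere the ROR criterion fires on ≤ 10% and the four-way
intersection on ≤ 5% of (drug, PT) pairs; a planted λ = 10 on a rare
(3%) drug is recovered by EBGM within a factor of two (the
observed-to-expected ratio is structurally diluted by the drug's own share
of the database, which the fixture keeps small).  Weibull recovery is
checked over 20 seeded replicates at n = 2 000 (median relative error
< 10% for both parameters) and at the reference size n = 2 138.  These
sizes keep the default suite under a minute while leaving narrow
stochastic margins; all stochastic tests are seeded.

## Known limitations

- Disproportionality measures reporting, not risk: no causal or
  incidence interpretation, and no exposure denominator exists.
- The raw observed/expected "EBGM" lacks shrinkage, so small-count cells
  have wide, poorly calibrated intervals (mitigated by the 3-case minimum
  and the EBGM05 ranking).
- Onset analysis ignores right-censoring by design: reports without an
  event date are excluded, not censored.
- The IC interval is a normal approximation, not the BCPNN posterior.
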