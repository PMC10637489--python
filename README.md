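# faerskit

Signal detection for spontaneous adverse-event report data in the FAERS
quarterly-extract format.

Spontaneous reporting systems such as the FDA Adverse Event Reporting
System (FAERS) collect safety reports for marketed drugs.  Because there is
no denominator of exposed patients, post-marketing surveillance relies on
*disproportionality*: comparing how often an event is reported with a drug
against how often it is reported with all other drugs.  `faerskit`
implements that workflow end to end for pharmacoepidemiologists and
pharmacovigilance analysts: parsing and deduplicating the raw quarterly
tables, building a target-drug cohort (primary-suspect role by default),
screening every preferred term (PT) with four estimators, analysing
time-to-onset with a Weibull model, and running subgroup and sex-difference
analyses.  A synthetic-data generator with planted ground truth makes every
stage testable without downloading the real database.

## The statistics

For a drug–event pair, distinct (report, PT) records form a 2×2 table:
`a` (drug ∧ event), `b` (drug ∧ other events), `c` (other drugs ∧ event),
`d` (neither), with `N = a+b+c+d`.  The four screening statistics are

- **ROR** = ad/(bc), 95% CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d));
  positive signal when the lower bound exceeds 1
- **PRR** = a(c+d)/[c(a+b)] with uncorrected
  χ² = (ad−bc)²·N/[(a+b)(c+d)(a+c)(b+d)]; positive when PRR ≥ 2 and χ² ≥ 4
- **IC** = log₂[aN/((a+c)(a+b))]; positive when IC025 > 0
- **EBGM** = aN/[(a+c)(a+b)] with a log-normal interval; positive when
  EBGM05 > 2

A screened signal needs at least 3 cases and all four criteria
simultaneously.  Onset delays (EVENT_DT − START_DT, whole days) are fitted
with a two-parameter Weibull; a shape β < 1 (by its 95% CI) marks an
*early-failure* hazard that decreases with time on drug.  Sex differences
are tested within the target drug's reports by a female-over-male ROR per
PT with two-sided Fisher exact p-values and Benjamini–Hochberg adjustment.
See `docs/methods.md` for modelling details and caveats.

## Worked example

Generate a synthetic quarter (5 000 cases, planted etoposide-like signals,
10% duplicate case versions) and run the whole pipeline:

```sh
faerskit synth --out-dir demo/data --n-reports 5000 --seed 7
# wrote 5512 report versions (5000 cases, 512 duplicates) to demo/data

cat > demo/config.yaml <<EOF
data_dir: demo/data
out_dir: demo/out
pt_soc_map: demo/data/pt_soc_map.csv
label_pts: demo/data/label_pts.txt
rank_min_a: 10
EOF
faerskit all --config demo/config.yaml
```

`demo/out/signals_pt_significant_rendered.csv` then holds the PTs that
pass all four criteria:

```
                   pt    a   ror  ror_lo  ror_hi   prr   chi2  ebgm  ebgm05  unexpected
  Febrile neutropenia 44.0 10.48    7.08   15.52  9.74 208.48  6.21    4.20       False
     Thrombocytopenia 26.0  5.32    3.37    8.40  5.13  64.41  4.04    2.56       False
Tumour lysis syndrome 16.0  8.75    4.69   16.33  8.53  67.11  5.73    3.07        True
      Ovarian failure 15.0 15.81    7.59   32.93 15.42  97.99  7.96    3.82        True
```

All four are planted associations; the generator's strong haematological
and metabolic signals survive screening while background PTs are rejected.
`unexpected=True` marks terms absent from the bundled synthetic label list
(novel signals).  `demo/out/tto_summary.json` reports the onset profile —
median 23 days (IQR 5–85), Weibull α = 47.0, β = 0.64 (CI 0.56–0.74),
classified `early` failure — consistent with the generator's
Weibull(38.56, 0.55) onset-lag model at this sample size.  A
`manifest.json` records input hashes, configuration and every exclusion
tally (deduplication, indication exclusion, date cleaning), so the report
flow reconciles from the manifest alone.

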