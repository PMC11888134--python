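# pvsignal

Case/non-case disproportionality analysis for spontaneous-report
(pharmacovigilance) databases, built around the motivating example of
hypertension reporting with serotonin reuptake inhibitors (SRIs), together
with a synthetic Individual Case Safety Report (ICSR) generator so the whole
pipeline can be exercised and calibrated without access to a proprietary
database.

## Who this is for

Pharmacoepidemiologists and signal-detection analysts who work with
ICSR-style data (a reports table, a drugs table, a reactions table) and want
a tested, reproducible implementation of the classic case/non-case design:
reports mentioning the event of interest are *cases*, all other reports are
*non-cases*, and drug–event disproportionality is quantified by the
reporting odds ratio.

## The statistics

For each drug–event pair the 2×2 table of exposed/unexposed × case/non-case
counts (a, b, c, d) yields the **reporting odds ratio**

    ROR = (a·d) / (b·c)

with the log-normal (Woolf) 95% confidence interval
`exp(ln ROR ± 1.959964·√(1/a + 1/b + 1/c + 1/d))`. A **safety signal** is
declared when ROR > 1 *and* the lower CI bound > 1 (both strict). A zero
cell triggers the Haldane–Anscombe +0.5 correction; a drug with no exposed
case has an undefined ROR (rendered `NA`). The **adjusted ROR (aROR)** is
the exponentiated exposure coefficient of a multivariable logistic model of
case status on exposure, age band, sex, concurrent antihypertensive
(ATC C02) reporting, and co-reported drugs with known pressor potential,
fitted by an internally implemented iteratively-reweighted-least-squares
Newton scoring. Dose–effect is explored by splitting each drug's exposed
reports at the median recorded daily dose (ties low) and testing the dose
trend with an OLS slope test; descriptives cover the cohort table,
time-to-onset medians/IQRs and positive dechallenge/rechallenge counts.

Sensitivity analyses: exposure restricted to *suspect* drug entries, and the
whole analysis restricted to the antidepressant-treated population
(ATC N06A).

## Worked example

```python
import pvsignal as pv

cfg = pv.make_paper_like_config(scale=0.02, seed=7)   # 20,000 reports
study = pv.CaseNonCaseStudy.from_synthetic(cfg)
print(study.fit(adjusted=True).summary())
```

```
Case/non-case disproportionality analysis
records: 19,577   role policy: any_role   population: whole_database

drug               cases  non-cases     ROR          95% CI    aROR          95% CI  signal
alaproclate            0          0      NA              NA      NA              NA      NA
citalopram            52      2,492    1.13     (0.84-1.51)    1.05     (0.78-1.41)      no
escitalopram          57      2,352    1.34     (1.01-1.78)    1.27     (0.95-1.69)     yes
etoperidone            0          0      NA              NA      NA              NA      NA
fluoxetine            60      2,628    1.25     (0.95-1.66)    1.21     (0.91-1.61)      no
fluvoxamine            5        306    0.87     (0.36-2.11)    0.80     (0.33-1.95)      no
paroxetine            56      2,137    1.46     (1.10-1.95)    1.41     (1.06-1.88)     yes
sertraline            82      3,585    1.28     (1.00-1.64)    1.22     (0.95-1.56)      no
zimeldine              0         20      NA              NA      NA              NA      NA
SRI class            231     10,197    1.56     (1.26-1.94)    1.46     (1.18-1.82)     yes
```

Each row is one drug's 2×2 table against all other reports: `cases`/`non-cases`
are the exposed cells (a, b), `ROR` the crude reporting odds ratio with its
Woolf interval, `aROR` the covariate-adjusted estimate, and `signal` the
strict ROR>1-and-CI-low>1 rule. Drugs with no exposed case (the two obsolete
compounds at this database size) are `NA` by design. The pooled `SRI class`
row counts reports exposed to *any* target drug once. At this small scale the
per-drug estimates are noisy; at the default `scale=0.1` they concentrate
around the planted values.

The same analysis runs from the shell against any three-table CSV database:

```bash
pvsignal simulate --out db --seed 7
pvsignal analyze --reports db/reports.csv --drugs db/drugs.csv \
    --reactions db/reactions.csv --out results
pvsignal validate --replicates 20 --seed 1
```

`analyze` writes one CSV per output table (signal table, sensitivity
analyses, dose table, cohort summary, time-to-onset, dechallenge/rechallenge)
plus a `manifest.yaml` with input checksums and row counts; every rendered
table has a full-precision `*_raw.csv` companion.

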