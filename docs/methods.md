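# Methods

## Design

`pvsignal` implements the case/non-case design for spontaneous-report
databases. Within one database of Individual Case Safety Reports (ICSRs),
*cases* are adult reports carrying at least one reaction term from a flat
event-term list (a stand-in for a licensed "Hypertension (broad)"
standardized MedDRA query; matching is exact on stripped, case-folded
strings — no terminology-hierarchy traversal). *Non-cases* are all other
adult reports. Exposure to each target drug is classified from ATC codes on
the report; vocabulary code entries act as prefixes, so the class entry
`C02` matches any antihypertensive substance code. By default a drug counts
in any role (suspect, concomitant, interacting); the suspect-only
restriction is a sensitivity analysis, as is restricting the whole analysis
set to reports carrying any ATC N06A antidepressant.

Reports with unknown age are excluded from every analysis: the design is
restricted to the adult demographic, which requires a known adult age, and a
raw `age_years` column is binned at load time into 18–44, 45–64, 65–74, 75+
(under-18s map to `unknown` and are therefore excluded too). Unknown sex is
retained as its own covariate level so the crude and adjusted analyses run
on the identical record set.

## Estimators

**Crude ROR.** For the 2×2 table (a = exposed cases, b = exposed non-cases,
c, d unexposed), ROR = (a·d)/(b·c) with the Woolf log-normal 95% CI using
z = 1.959964 — the standard disproportionality interval in this field. If
any cell is zero while the drug has at least one exposed report, the
Haldane–Anscombe correction adds 0.5 to all four cells first; a drug with no
exposed case (a = 0) has an undefined ROR, rendered `NA`. A **signal** is
ROR > 1 and lower CI bound > 1, both strict — a one-sided rule at the 97.5%
quantile, so under the null it fires at ≈2.5%.

**Adjusted ROR.** A multivariable logistic model of case status on the
exposure indicator, age-band dummies (reference 18–44), sex dummies
(reference female, `unknown` kept as a level), a concurrent-antihypertensive
flag and a pressor-comedication flag; main effects only, no interactions.
The fit is an in-package iteratively reweighted least squares (Newton
scoring): convergence when the largest absolute coefficient change drops
below 1e-8, cap of 50 iterations; standard errors from the inverse observed
information; aROR = exp(exposure coefficient) with a Wald interval.
Complete/quasi-complete separation (a fitted probability within 1e-10 of
0/1 with a diverged coefficient) is flagged and rendered `NA` rather than
reported. Constant covariate columns are dropped, so a degenerate dataset
collapses to the exposure-only model, whose exponentiated slope equals the
crude ROR exactly (the saturated-2×2 identity; the test-suite verifies it
against a statsmodels GLM oracle at 1e-6). The covariate flags never count
the target drug's own codes; if a code set overlapped the drug's codes the
flag is recomputed excluding them.

**Dose–effect.** Per drug, the median of recorded daily doses over exposed
reports (cases and non-cases; even counts average the two central values)
splits exposed reports into a low stratum (dose ≤ median — ties low) and a
high stratum (dose > median). Exposed reports without a recorded dose join
neither stratum, so low-a + high-a + missing-dose exposed cases partition
the main-analysis a cell. Both strata share the main analysis' unexposed
comparator cells, since stratification applies only to exposed reports. A
stratum pair is evaluated only when both strata contain at least five
exposed cases; otherwise every stratified field is `NA`. The dose trend is
an OLS regression of case status on the high-stratum indicator over exposed
dose-recorded reports (two-sided slope p). A linear-probability slope test
was chosen over a logistic slope on log-dose because the output contract
calls for a linear regression model; the logistic alternative is available
by fitting the strata's adjusted models directly. Doses are assumed to be
mg/day as recorded — no defined-daily-dose normalization.

**Descriptives.** Cohort percentages are rounded half-up to one decimal and
always recompute exactly as 100·count/denominator. Denominators follow the
conventional cohort-table structure: seriousness over reports with known
seriousness, seriousness criteria over serious reports (criteria are
multi-select), everything else over all cases. Time-to-onset is (earliest
matching-reaction onset date) − (earliest matching drug start date) in
whole days, kept only when non-negative — negative latencies indicate data
errors and are excluded, not clamped. Quartiles use midpoint interpolation
(the common statistical-package default; published IQRs cannot adjudicate
the convention). Dechallenge/rechallenge counts a report once per drug when
any matching entry records the positive outcome.

## Synthetic database generator

The generator emulates the structure of a large pharmacovigilance extract
with known ground truth. Per report it draws covariates (age band, sex,
antihypertensive comedication, pressor comedication), per-drug exposure with
probability tilted on the logit scale by the covariate event score times
`exposure_confounding_log_or` (creating genuine confounding when positive),
and case status from a logistic model: baseline log-odds + planted per-drug
log-ORs + covariate effects. Case reports get one event term and an onset
date at drug start + ⌊Exponential(mean 30 d)⌋ — only medians/IQRs are ever
summarized, so any positively skewed one-parameter distribution serves.
Exposed entries get log-normal daily doses around the drug's typical median
(dispersion 0.4 on the log scale) with a configurable missingness
probability (default 0.8, reflecting how sparse dose capture is in
spontaneous reports), roles (suspect with probability 0.6), start/stop
dates, and Bernoulli dechallenge/rechallenge outcomes for case reports.
Random streams are split per component and per drug, so adding a drug never
perturbs the other draws; the generator is a pure function of its config
including the seed (byte-identical files on re-run).

The study-scale default (`make_paper_like_config`) plants nine target drugs
with exposure prevalences sized so that, at the full scale of 10⁶ reports,
expected exposed-report counts are on the order of a large real-world SRI
extract (two obsolete compounds are effectively unexposed and exercise the
`NA` paths). Planted conditional effects sit in the 1.16–1.40 OR range
typical of adjusted estimates for this drug class, with one null drug and
one inverse association; positive confounding (0.25 on the logit scale,
with age/sex/comedication effects of 0.35–1.1 log-odds) makes crude RORs
exceed the planted conditional ORs, as in real adjusted analyses. The
baseline event log-odds (−4.64 at reference covariates) was solved once by
simulation so the case rate among exposed reports is ≈2.2%, the event
prevalence this kind of hypertension extract exhibits. The default desk
scale is 0.1 (100,000 reports); `scale` changes only the database size,
never rates or effects.

What the generator does *not* model: reporting-country structure, duplicate
reports, secular reporting trends, notoriety bias, within-report term
correlation beyond the planted stroke/MI co-terms, or realistic free-text
drug names. Passing calibration tests therefore demonstrates that the
estimators recover what they claim from data satisfying the logistic
reporting model — not that real-database biases are absent.

## Numerical and calibration choices

Problem sizes for the stochastic validation batteries were chosen to make
Monte-Carlo noise small relative to the quantities checked: 400 replicate
null databases of 50,000 reports for the signal-rate check (accept 1–4.5%
around the theoretical ≈2.5%), 100 replicates of 200,000 reports for CI
coverage (accept ≥90/100 around 95%), 20 confounded replicates of 100,000
reports for the crude-vs-adjusted comparison, and 200 replicates for the
dose-trend type-I rate (accept 2–9% around 5%). Replicate seeds are derived
from one root seed via `numpy.random.SeedSequence`.

Degenerate inputs: an empty database is legal (empty outputs, not an
error); an empty comparator population under the N06A filter warns rather
than fails; drugs with no recorded doses skip the dose analysis; zero-variance
trend indicators return an undefined p. Output tables render ratios to two
decimals and percentages/day-summaries to one decimal, with a full-precision
`*_raw.csv` companion for machines.

## Known limitations

- Exact string matching of reaction terms; misspelled or hierarchical
  MedDRA variants will not match unless added to the term list.
- The shipped vocabulary is an editable synthetic fixture: the event-term
  list, the pressor-drug prefix list and the ATC codes of the obsolete
  compounds are illustrative placeholders, not licensed terminology.
- The adjusted model conditions on four reported covariates only;
  unmeasured confounding (e.g. indication severity) is untouched, exactly
  as in real disproportionality analyses.
- No de-duplication of suspected duplicate reports and no causality
  scoring; the ROR is a reporting measure, not an incidence measure.
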