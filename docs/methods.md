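# Methods

## The case/non-case design

Spontaneous-report databases have no denominators: they contain only
reports, each naming one or more drugs (with role codes: primary suspect
PS, secondary suspect SS, concomitant C, interacting I) and one or more
MedDRA-coded reactions (preferred terms, PTs, rolling up to system organ
classes, SOCs). Disproportionality analysis therefore compares *reporting*
odds, not incidence: reports carrying at least one target-SOC PT are
"cases", all other reports "non-cases", and exposure is naming the target
drug as primary suspect. A 2×2 table of report counts (a, b, c, d as in
the README) is built against the entire deduplicated database as
comparator, at SOC level and per PT.

Key labeling rules, each of which changes counts materially:

* only PS records create exposure — SS/C/I records never do, to limit
  confounding by co-medication;
* a report is a case once, however many target-SOC PTs it carries; per-PT
  counts also count each report at most once per PT;
* drug names resolve by normalized *exact* match (trim, case-fold, strip
  trailing dose/form tokens) against a name→ATC dictionary. No fuzzy
  matching: a false exposure distorts the 2×2 more than a missed one;
* PTs missing from the PT→SOC map never create cases; they are tallied in
  a QC counter so a truncated map is visible rather than silent.

## Deduplication

One case may appear as several report versions. Per `caseid` the survivor
maximizes `(fda_dt, primaryid)` lexicographically — the latest receipt
date, then the highest report-version id. The operation is idempotent and
order-free, and the survivor count equals the number of distinct cases.
Partial receipt dates (4- or 6-digit) are padded with month/day 01 for
ordering only; deduplication runs before the quarter-window filter, so the
window always sees one version per case.

## Estimators

**ROR.** Point `ad/bc`; Woolf interval
`exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`. Any zero cell yields an
undefined-estimate marker rather than an exception (signals require
a ≥ 10 anyway); an optional Haldane +0.5 correction is available for
exploratory output only.

**IC.** Point estimate in bits, the observed/expected form
`log₂(a·n/((a+b)(a+c)))`. The interval is `IC ± 2·√V(IC)`. The default
V(IC) is the closed-form variance of the posterior IC in the Bayesian
confidence propagation neural network parameterization with all
Beta/Dirichlet hyperparameters equal to 1; a delta-method alternative
`(1/ln 2)²·(1/a − 1/(a+b) − 1/(a+c) + 1/n)` is selectable per run and the
choice is recorded in the run metadata. Two numerical details: the
interval is centred on the reported point estimate, so `IC₀₂₅ ≤ IC ≤ IC₉₇₅`
holds whenever a ≥ 1; and when the delta expression is non-positive (it is
the derivative of IC in a, negative once a dominates its margins — outside
the sparse case/non-case regime) the closed form is used in its place.
When a = 0 the observed/expected form is undefined and the shrinkage
posterior mean is reported with an explicit flag.

**Dual criterion.** Signal ⇔ (ROR CI low > 1 ∧ a ≥ 10) ∧ (IC₀₂₅ > 0).
The conjunction is conservative: simulated at the null with expected
a ≈ 20 it fires in well under 5% of datasets. No multiple-testing
correction is applied across PT-level tests (matching field practice for
hypothesis-generating screens); the number of tests performed is emitted
so users can post-correct.

## Subgroups and cross-stratification

Two contrasts share the ROR code path. *Subgroup* analysis restricts the
whole universe to a stratum (sex, or half-open age band [18, 75) / [75, ∞))
and rebuilds the exposure-vs-rest table there, with stratum-matched
non-cases as the comparator. *Cross-stratification* restricts to the
drug's PS-exposed reports and contrasts two disjoint demographic strata as
table rows (events as columns); swapping stratum and reference inverts the
ROR exactly in rational arithmetic. Reports with unknown sex or missing
age are excluded only from strata conditioning on that field. Stratified
and pooled RORs need not agree (odds ratios are non-collapsible); the test
suite pins this with a constructed two-stratum example whose stratum RORs
are exactly 1 while the pooled ROR is not.

## Time to onset

For each PS-exposed case report with a day-resolved event date and at
least one day-resolved therapy start for the drug, onset is
`event − earliest start` in whole days. Partial dates and negative
differences are excluded (never imputed) and counted in QC tallies.
Summaries are median and IQR with linearly interpolated quantiles
(type 7), the convention under which integer day counts produce
fractional summaries; the convention is a parameter for users who prefer
another.

## The synthetic generator

`faerspv.synthetic` emulates the FAERS relational schema with planted
truth. Per base report it draws sex (56.5/43.5 F/M among known, 8.6%
missing), age (mixture: ~1% children, truncated normal adults centred at
64, truncated normal elderly centred at 79; 15% missing — median ≈ 66 and
roughly a fifth of known ages ≥ 75, the demographic shape of statin
safety reporting), country, receipt date in the 2014Q1–2023Q1 window,
per-drug exposure (2% per statin by default), and case status from a
logistic model: `odds(case) = baseline_odds × θ_drug^exposed × stratum
multiplier`, with baseline odds 0.09 (≈8.3% background respiratory share)
and default θ of 2.0/1.9. Because θ multiplies the *odds*, it is exactly
the estimand of the ROR, so parameter recovery needs no bias correction.
Reports carry 1–3 PTs (truncated geometric; secondary PTs of cases are
sometimes respiratory too, exercising the once-per-report rule), drug-name
variants (generic/salt/brand/dose-suffixed), background co-medication,
duplicate case versions (20% of cases, geometric extra-version count,
40% of extras tying on receipt date so both deduplication tie-break
branches occur), partial dates, and log-normal onset times (default
medians 7 and 14.5 days). The generator returns the five typed tables
plus a `GroundTruth` (planted θ, per-case flags, and the survivor map
implied by the deduplication rule).

What it does *not* emulate: content drift between duplicate versions,
free-text drug-name noise beyond dose suffixes, correlated
co-prescription, reporting-rate secular trends, or multi-axial MedDRA.
Green tests therefore certify the pipeline's arithmetic and rules on
schema-faithful data, not robustness to every real-world coding pathology.

`fixture_small()` is the deterministic ~200-report dataset used in golden
tests; four crafted reports guarantee coverage of the exclusion rules
(unknown sex, month-resolution event date, negative onset, target drug in
a concomitant role). Its expected 2×2 cells and onset summaries were
frozen from an independent brute-force enumeration
(`tests/data/fixture_small_expected.json`).

## Validation problem sizes

Simulation-based checks use sizes chosen to make their tolerances
meaningful: parameter recovery runs θ ∈ {1, 2, 4} with 200 replicates per
θ at 200,000 reports in `scripts/acceptance.py` (50,000 in the test suite)
— the median must land within 5% of θ; interval coverage is assessed
pooled over the 600 replicates against a 93–97% band, since per-θ
coverage at 200 replicates has binomial noise of ±1.5 percentage points
and would fail such a band one run in five even at exact nominal
coverage (per-θ coverages are still reported). The null false-signal rate
uses 1,000 datasets sized so the expected co-report count is ≈20; onset
recovery demands the median within 10% of exp(μ) at ≥5,000 records.
Replicate simulations strip features irrelevant to the quantity under
study (duplicate versions, outcome rows, extra reaction rows) so that
large replicate counts stay cheap; each such stripped feature has its own
dedicated test at full fidelity.

## Known limitations

* Disproportionality measures reporting, not risk; no confounder
  adjustment is attempted (none is possible within the design).
* The bundled PT→SOC map is a synthetic stand-in for licensed MedDRA with
  invented PT codes (the respiratory SOC code is the published one); real
  analyses must supply a licensed export.
* Single primary SOC per PT; multi-axial linkage is out of scope.
* The quarter-window filter uses the receipt date (`fda_dt`), matching how
  FAERS organizes quarterly files, not the event date.
* Whether per-PT tables count reports or reaction rows is a convention;
  this package counts each report once per PT.
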