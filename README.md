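# faerspv

Case/non-case disproportionality analysis for FAERS-style spontaneous
adverse-event reports, built as a reusable pharmacovigilance pipeline with a
synthetic-data simulator for validation.

Post-marketing drug-safety surveillance asks whether an adverse event is
reported *disproportionately often* with a given drug, relative to the rest
of a spontaneous-reporting database such as the FDA Adverse Event Reporting
System (FAERS). This package implements that workflow end to end for
studies of the form "is drug X associated with events in MedDRA system
organ class Y?" — the motivating use case being statins (atorvastatin,
rosuvastatin as primary-suspect drugs, WHO ATC codes C10AA05/C10AA07) and
respiratory, thoracic and mediastinal disorders (MedDRA SOC 10038738). It
is aimed at pharmacoepidemiologists and biostatisticians who want the whole
chain — raw quarterly ASCII tables to signal tables — scripted, testable
and reproducible.

## What it computes

Reports are deduplicated by the FDA-recommended rule (per `CASEID`, keep
the most recent `FDA_DT`, ties broken by the highest `PRIMARYID`), then
cross-classified per drug–event pair:

|                | target event | other events |
|----------------|--------------|--------------|
| target drug    | a            | b            |
| other drugs    | c            | d            |

with two disproportionality statistics:

* **Reporting odds ratio** — `ROR = ad/bc`, 95% CI
  `exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d))`;
* **Information component** (Bayesian confidence propagation neural
  network) — `IC = log₂(a·n / ((a+b)(a+c)))` with `n = a+b+c+d`, and the
  credibility interval `IC ± 2·√V(IC)` using the closed-form BCPNN
  posterior variance (delta-method variance selectable).

A drug–event pair is a **signal** only when both methods fire: ROR CI lower
bound > 1 with `a ≥ 10`, and `IC₀₂₅ > 0`. Around this core the package
provides primary-suspect cohort building, per-PT analyses against the whole
database, sex/age subgroup and cross-stratified RORs, time-to-onset
medians/IQRs (type-7 quantiles), demographic summary tables, and a
synthetic FAERS generator that plants known reporting-odds multipliers so
every stage can be verified against ground truth.

## Worked example

```python
import tempfile
from pathlib import Path
from faerspv import RunConfig, run_pipeline, fixture_small

workdir = Path(tempfile.mkdtemp())
paths = fixture_small().write(workdir / "data")   # 5 FAERS-style ASCII tables
result = run_pipeline(RunConfig(inputs={k: str(p) for k, p in paths.items()}))

print(result.counts)
soc = result.signals.frame[result.signals.frame["event"].str.startswith("SOC:")]
print(soc[["drug", "a", "ror", "ror_ci_low", "ror_ci_high",
           "ic", "ic025", "signal"]].round(2).to_string(index=False))
tto = result.tto_summaries["atorvastatin"]
print(f"atorvastatin onset: n={tto.n} median={tto.median_days} days "
      f"IQR ({tto.iqr_low}, {tto.iqr_high})")
```

prints

```
{'raw_demo_rows': 267, 'deduplicated_reports': 204, 'in_window_reports': 204,
 'exposed_atorvastatin': 29, 'exposed_rosuvastatin': 31, 'cases': 21}
        drug  a  ror  ror_ci_low  ror_ci_high   ic  ic025  signal
atorvastatin 10 7.85        2.95        20.89 1.74   0.61    True
rosuvastatin  5 1.89        0.64         5.59 0.65  -0.73   False
atorvastatin onset: n=6 median=3.0 days IQR (1.25, 27.25)
```

Reading this: of 267 raw report versions, 204 distinct cases survive
deduplication; 29 name atorvastatin as primary suspect, of which `a = 10`
are respiratory cases. The bundled fixture plants a reporting-odds
multiplier of 4 for atorvastatin, and the dual criterion flags it
(ROR 7.85 with CI above 1 and ≥10 cases, IC₀₂₅ > 0) while rosuvastatin's
weaker planted multiplier does not clear the interval criteria at this
sample size. Onset medians and IQRs use linearly interpolated quantiles,
hence the fractional days.

The same pipeline runs from a shell:

```bash
faerspv generate -o data --seed 7           # synthetic FAERS tables
faerspv run -c config.yaml -o out           # full analysis, TSV outputs
```

## Layout

| module | contents |
|---|---|
| `faerspv.faers_model` | FAERS table schemas, "$"-delimited readers/writers, deduplication |
| `faerspv.cohort` | drug dictionary, PT→SOC map, exposure/case labeling |
| `faerspv.disproportionality` | 2×2 tables, ROR, IC, dual criterion, `DisproportionalityModel` |
| `faerspv.stratified` | sex/age subgroup and cross-stratified RORs |
| `faerspv.onset` | time-to-onset records and summaries |
| `faerspv.synthetic` | ground-truthed synthetic FAERS generator |
| `faerspv.reporting` | pipeline orchestration, table surfaces, run metadata |
| `faerspv.cli` | `faerspv` command-line interface |

The bundled PT→SOC table (`data/synthetic_meddra_map.tsv`) is a synthetic
stand-in for the licensed MedDRA dictionary; swap in a licensed export via
the `meddra_map` config key for real analyses. See `docs/methods.md` for
the statistical details, generator design and known limitations.
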