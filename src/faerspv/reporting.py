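"""End-to-end pipeline orchestration and publication-style table surfaces.

``run_pipeline`` executes read → deduplicate → window filter → label →
disproportionality (SOC and per-PT) → subgroup and cross-stratified
analyses → time to onset, logging row counts at every stage so the flow
raw → deduplicated → in-window → exposed → cases can be reconstructed from
the run metadata.  All outputs are deterministic given the config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import faers_model as fm
from ._format import pct, round_half_up
from .cohort import Cohort, DrugDictionary, MeddraMap, build_cohort, pt_event_counts
from .disproportionality import (DisproportionalityModel,
                                 DisproportionalityResults)
from .onset import OnsetSummary, compute_tto, summarize_tto
from .stratified import StratumSpec, cross_stratified_ror, subgroup_estimate

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "PipelineResult", "RunConfig",
           "demographics_table", "run_pipeline", "top_pt_table"]

DEFAULT_TARGET_DRUGS = {"atorvastatin": "C10AA05", "rosuvastatin": "C10AA07"}
RESPIRATORY_SOC = 10038738

#: Subgroup strata for the sex/age analysis (half-open age bands [18,75), [75,∞)).
DEFAULT_STRATA = (
    StratumSpec("female", sex="F"),
    StratumSpec("male", sex="M"),
    StratumSpec("18-74", age_low=18.0, age_high=75.0),
    StratumSpec(">=75", age_low=75.0),
)

_MAE_F = StratumSpec("middle-aged and elderly female", "F", 18.0, 75.0)
_ELD_F = StratumSpec("elderly female", "F", 75.0)
_MAE_M = StratumSpec("middle-aged and elderly men", "M", 18.0, 75.0)
_ELD_M = StratumSpec("elderly men", "M", 75.0)

#: (stratum, reference) pairs for the within-drug cross-stratification.
DEFAULT_CROSS_PAIRS = (
    (_MAE_F, _MAE_M), (_ELD_F, _MAE_M), (_MAE_F, _ELD_M), (_ELD_F, _ELD_M),
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def quarter_bounds(quarter: str) -> tuple[int, int]:
    """(first, last) yyyymmdd of a quarter written like ``2014Q1``."""
    year, q = quarter.upper().split("Q")
    year, q = int(year), int(q)
    if not 1 <= q <= 4:
        raise ValueError(f"bad quarter: {quarter!r}")
    first_month = 3 * (q - 1) + 1
    last_day = {1: 331, 2: 630, 3: 930, 4: 1231}[q]
    return year * 10000 + first_month * 100 + 1, year * 10000 + last_day


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    inputs: dict                      # table kind -> file path (DEMO..OUTC)
    drug_dictionary: Optional[str] = None   # None -> bundled
    meddra_map: Optional[str] = None        # None -> bundled (synthetic stand-in)
    target_drugs: dict = field(default_factory=lambda: dict(DEFAULT_TARGET_DRUGS))
    target_soc: int = RESPIRATORY_SOC
    window: Optional[tuple[str, str]] = ("2014Q1", "2023Q1")
    strata: Sequence[StratumSpec] = DEFAULT_STRATA
    cross_pairs: Sequence[tuple[StratumSpec, StratumSpec]] = DEFAULT_CROSS_PAIRS
    ic_variance: str = "bcpnn"
    zero_cell: str = "none"
    pt_level: bool = True
    top_k_pts: int = 5
    output_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.target_drugs:
            raise ValueError("target_drugs must be non-empty")
        if self.window is not None:
            lo, _ = quarter_bounds(self.window[0])
            _, hi = quarter_bounds(self.window[1])
            if lo > hi:
                raise ValueError("window start must be <= end")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        strata = [StratumSpec(s.get("label", ""), s.get("sex", "ANY"),
                              float(s.get("age_low", 0.0)),
                              float(s.get("age_high", np.inf)))
                  for s in raw.get("strata", [])] or DEFAULT_STRATA
        window = raw.get("window")
        if isinstance(window, dict):
            window = (window["start"], window["end"])
        return cls(
            inputs=raw["inputs"],
            drug_dictionary=raw.get("drug_dictionary"),
            meddra_map=raw.get("meddra_map"),
            target_drugs=raw.get("target_drugs", dict(DEFAULT_TARGET_DRUGS)),
            target_soc=int(raw.get("target_soc", RESPIRATORY_SOC)),
            window=tuple(window) if window else None,
            strata=strata,
            ic_variance=raw.get("ic_variance", "bcpnn"),
            zero_cell=raw.get("zero_cell", "none"),
            pt_level=bool(raw.get("pt_level", True)),
            top_k_pts=int(raw.get("top_k_pts", 5)),
            output_dir=raw.get("output_dir"),
            seed=int(raw.get("seed", 0)),
        )


@dataclass
class PipelineResult:
    cohort: Cohort
    signals: DisproportionalityResults
    demographics: pd.DataFrame
    top_pts: dict                  # drug -> DataFrame
    subgroups: pd.DataFrame
    cross_strata: pd.DataFrame
    tto_summaries: dict            # drug -> OnsetSummary | None
    tto_qc: dict
    counts: dict                   # stage -> row counts

    def write(self, outdir: str | Path, config: RunConfig) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.signals.to_tsv(outdir / "signals.tsv")
        self.demographics.to_csv(outdir / "demographics.tsv", sep="\t",
                                 index=False, lineterminator="\n")
        tops = pd.concat([df.assign(drug=d) for d, df in self.top_pts.items()],
                         ignore_index=True) if self.top_pts else pd.DataFrame()
        tops.to_csv(outdir / "top_pts.tsv", sep="\t", index=False,
                    lineterminator="\n")
        self.subgroups.to_csv(outdir / "subgroups.tsv", sep="\t", index=False,
                              lineterminator="\n")
        self.cross_strata.to_csv(outdir / "cross_strata.tsv", sep="\t",
                                 index=False, lineterminator="\n")
        tto_rows = [{"drug": d, "n": s.n, "median_days": s.median_days,
                     "iqr_low": s.iqr_low, "iqr_high": s.iqr_high,
                     **self.tto_qc.get(d, {})}
                    for d, s in self.tto_summaries.items() if s is not None]
        pd.DataFrame(tto_rows).to_csv(outdir / "tto.tsv", sep="\t", index=False,
                                      lineterminator="\n")
        meta = {"version": __version__, "ic_variance": config.ic_variance,
                "zero_cell": config.zero_cell, "seed": config.seed,
                "n_tests": self.signals.n_tests, "counts": self.counts,
                "qc": {**self.cohort.qc, "tto": self.tto_qc}}
        (outdir / "metadata.json").write_text(json.dumps(meta, indent=1,
                                                         default=float) + "\n")


# ---------------------------------------------------------------------------
# Table surfaces
# ---------------------------------------------------------------------------

def _age_bin(age: float) -> str:
    if np.isnan(age):
        return "unknown"
    if age < 18:
        return "<18"
    if age < 75:
        return "18-74"
    return ">=75"


def demographics_table(demo: pd.DataFrame, cohort: Cohort,
                       drugs: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-drug demographic summary of exposed case reports.

    One row per (section, category) with ``<drug>_n`` / ``<drug>_pct`` and
    ``total_n`` / ``total_pct`` columns.  Percentages use the per-drug case
    total as denominator (the combined total for the total column), rounded
    half-up at 2 decimals; exhaustive disjoint sections therefore sum to
    100% up to rounding.
    """
    drugs = list(drugs) if drugs is not None else list(cohort.drugs)
    demo = fm.add_age_years(fm.normalize_sex(demo))
    demo = demo.set_index("primaryid")

    groups = {}
    for d in drugs:
        ids = cohort.flags.index[cohort.flags[d] & cohort.flags["case"]]
        groups[d] = demo.loc[demo.index.intersection(ids)]
    all_ids = cohort.flags.index[cohort.flags["case"]
                                 & cohort.flags[drugs].any(axis=1)]
    groups["total"] = demo.loc[demo.index.intersection(all_ids)]
    denoms = {k: len(v) for k, v in groups.items()}

    rows: list[dict] = []

    def add(section: str, category: str, counts: dict) -> None:
        row = {"section": section, "category": category}
        for k in drugs + ["total"]:
            row[f"{k}_n"] = counts.get(k, 0)
            row[f"{k}_pct"] = pct(counts.get(k, 0), denoms[k])
        rows.append(row)

    add("total", "cases", {k: denoms[k] for k in groups})
    # the total column's share is taken of the combined total, like the
    # printed per-drug shares of the overall case count
    rows[-1]["total_pct"] = 100.0
    for d in drugs:
        rows[-1][f"{d}_pct"] = pct(denoms[d], denoms["total"])

    for sex_label, name in [("F", "female"), ("M", "male"),
                            ("UNKNOWN", "unknown")]:
        add("sex", name, {k: int((g["sex"] == sex_label).sum())
                          for k, g in groups.items()})
    for bin_label in ["<18", "18-74", ">=75", "unknown"]:
        add("age", bin_label,
            {k: int((g["age_years"].map(_age_bin) == bin_label).sum())
             for k, g in groups.items()})

    med_row = {"section": "age", "category": "median (IQR)"}
    for k, g in groups.items():
        age = g["age_years"].dropna().to_numpy()
        if age.size:
            q1, med, q3 = np.quantile(age, [0.25, 0.5, 0.75])
            med_row[f"{k}_n"] = round_half_up(med, 1)
            med_row[f"{k}_pct"] = np.nan
            med_row[f"{k}_iqr"] = f"{round_half_up(q1, 1)}-{round_half_up(q3, 1)}"
    rows.append(med_row)

    top_countries = (groups["total"]["occr_country"].value_counts()
                     .head(3).index.tolist())
    for ctry in top_countries:
        add("country", ctry, {k: int((g["occr_country"] == ctry).sum())
                              for k, g in groups.items()})

    years = sorted({s[:4] for g in groups.values()
                    for s in g["fda_dt"].astype(str) if len(s) >= 4})
    for y in years:
        add("year", y, {k: int(g["fda_dt"].astype(str).str.startswith(y).sum())
                        for k, g in groups.items()})

    return pd.DataFrame(rows)


def outcomes_table(outc: pd.DataFrame, cohort: Cohort,
                   drugs: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Outcome-code frequencies among exposed case reports, per drug."""
    drugs = list(drugs) if drugs is not None else list(cohort.drugs)
    rows = []
    for code, outcome in fm.OUTCOME_CODES.items():
        row = {"section": "outcome", "category": outcome.value}
        for d in drugs:
            ids = cohort.flags.index[cohort.flags[d] & cohort.flags["case"]]
            sub = outc[outc["primaryid"].isin(ids)
                       & outc["outc_cod"].str.upper().eq(code)]
            n = sub["primaryid"].nunique()
            row[f"{d}_n"] = int(n)
            row[f"{d}_pct"] = pct(n, len(ids))
        rows.append(row)
    return pd.DataFrame(rows)


def top_pt_table(counts: pd.Series, k: int, denominator: int) -> pd.DataFrame:
    """Top-``k`` preferred terms by report count.

    Ties break alphabetically by PT name; percentages are shares of the
    per-drug SOC-level case total.  If ``k`` exceeds the number of distinct
    PTs, all are returned.
    """
    df = (counts.rename_axis("pt").reset_index(name="count")
          .sort_values(["count", "pt"], ascending=[False, True],
                       kind="mergesort")
          .head(k).reset_index(drop=True))
    df["pct"] = [pct(c, denominator) for c in df["count"]]
    return df


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis; see the module docstring for the stages."""
    counts: dict = {}

    @_stage("read")
    def read_all():
        frames = {}
        for kind in ["DEMO", "DRUG", "REAC", "THER", "OUTC"]:
            path = config.inputs.get(kind) or config.inputs.get(kind.lower())
            if path is None:
                raise FileNotFoundError(f"no input path configured for {kind}")
            frames[kind] = fm.read_table(path, kind)
        return frames

    frames = read_all()
    counts["raw_demo_rows"] = len(frames["DEMO"])
    logger.info("read %d DEMO rows", counts["raw_demo_rows"])

    @_stage("deduplicate")
    def dedup():
        return fm.deduplicate(frames["DEMO"])

    demo = dedup()
    counts["deduplicated_reports"] = len(demo)

    @_stage("window_filter")
    def window():
        if config.window is None:
            return demo
        lo, _ = quarter_bounds(config.window[0])
        _, hi = quarter_bounds(config.window[1])
        key = fm._fda_sort_key(demo["fda_dt"])
        return demo[(key >= lo) & (key <= hi)].reset_index(drop=True)

    demo_w = window()
    counts["in_window_reports"] = len(demo_w)

    @_stage("filter_children")
    def children():
        ids = demo_w["primaryid"]
        return {k: fm.filter_children(frames[k], ids)
                for k in ["DRUG", "REAC", "THER", "OUTC"]}

    kids = children()

    @_stage("label")
    def label():
        dictionary = DrugDictionary.from_tsv(config.drug_dictionary)
        meddra = MeddraMap.from_tsv(config.meddra_map)
        return dictionary, meddra, build_cohort(
            demo_w, kids["DRUG"], kids["REAC"], dictionary, meddra,
            config.target_drugs, config.target_soc)

    dictionary, meddra, cohort = label()
    for d in config.target_drugs:
        counts[f"exposed_{d}"] = int(cohort.flags[d].sum())
    counts["cases"] = int(cohort.flags["case"].sum())
    logger.info("report flow: raw=%d dedup=%d in-window=%d cases=%d",
                counts["raw_demo_rows"], counts["deduplicated_reports"],
                counts["in_window_reports"], counts["cases"])

    @_stage("disproportionality")
    def signals():
        model = DisproportionalityModel.from_cohort(cohort,
                                                    pt_level=config.pt_level)
        return model.fit(ic_variance=config.ic_variance,
                         zero_cell=config.zero_cell)

    results = signals()

    @_stage("tables")
    def tables():
        demtab = demographics_table(demo_w, cohort)
        outtab = outcomes_table(kids["OUTC"], cohort)
        demtab = pd.concat([demtab, outtab], ignore_index=True)
        tops = {}
        for d in config.target_drugs:
            pt_counts = pt_event_counts(kids["REAC"], cohort, d)
            denom = int((cohort.flags[d] & cohort.flags["case"]).sum())
            tops[d] = top_pt_table(pt_counts, config.top_k_pts, denom)
        return demtab, tops

    demtab, tops = tables()

    @_stage("subgroups")
    def subgroups():
        rows = []
        for d in config.target_drugs:
            for stratum in config.strata:
                table, est = subgroup_estimate(
                    cohort, d, stratum, ic_variance=config.ic_variance,
                    zero_cell=config.zero_cell)
                rows.append({"drug": d, "stratum": stratum.label,
                             "a": table.a, "b": table.b, "c": table.c,
                             "d": table.d, "ror": est.ror,
                             "ror_ci_low": est.ror_ci_low,
                             "ror_ci_high": est.ror_ci_high,
                             "ic": est.ic, "ic025": est.ic025})
        return pd.DataFrame(rows)

    @_stage("cross_stratification")
    def cross():
        rows = []
        for d in config.target_drugs:
            for stratum, reference in config.cross_pairs:
                r = cross_stratified_ror(cohort, d, stratum, reference)
                rows.append({"drug": d, "stratum": stratum.label,
                             "reference": reference.label,
                             "a": r.table.a, "b": r.table.b,
                             "c": r.table.c, "d": r.table.d,
                             "ror": r.ror, "ci_low": r.ci_low,
                             "ci_high": r.ci_high})
        return pd.DataFrame(rows)

    @_stage("time_to_onset")
    def tto():
        summaries, qcs = {}, {}
        for d, atc in config.target_drugs.items():
            ids = cohort.flags.index[cohort.flags[d] & cohort.flags["case"]]
            records, qc = compute_tto(demo_w, kids["THER"], kids["DRUG"],
                                      ids, atc, dictionary, drug_label=d)
            summaries[d] = summarize_tto(records, drug=d)
            qcs[d] = {**qc, "n_tto": len(records)}
        return summaries, qcs

    sub = subgroups()
    crs = cross()
    tto_summaries, tto_qc = tto()

    result = PipelineResult(cohort=cohort, signals=results,
                            demographics=demtab, top_pts=tops,
                            subgroups=sub, cross_strata=crs,
                            tto_summaries=tto_summaries, tto_qc=tto_qc,
                            counts=counts)
    if config.output_dir:
        result.write(config.output_dir, config)
    return result
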