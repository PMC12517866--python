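"""Pipeline orchestration, table surfaces, rounding rules, and the CLI."""

from __future__ import annotations

import filecmp
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from faerspv._format import fmt_pct, pct, round_half_up
from faerspv.reporting import (RunConfig, demographics_table, quarter_bounds,
                               run_pipeline, top_pt_table, PipelineError)


class TestRounding:
    @pytest.mark.parametrize("num,den,expected", [
        (8211, 15676, 52.38), (7465, 15676, 47.62),   # per-drug case shares
        (4540, 8211, 55.29), (1741, 8211, 21.20),     # sex / top-PT shares
        (1231, 7465, 16.49), (768, 7465, 10.29),
    ])
    def test_published_style_percentages(self, num, den, expected):
        assert pct(num, den) == expected

    def test_half_up_not_bankers(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(2.675, 2) == 2.68

    def test_fmt_pct_fixed_decimals(self):
        assert fmt_pct(1741, 8211) == "21.20%"
        assert fmt_pct(1, 3) == "33.33%"
        assert fmt_pct(1, 0) == "nan"


class TestQuarterWindow:
    def test_quarter_bounds(self):
        assert quarter_bounds("2014Q1") == (20140101, 20140331)
        assert quarter_bounds("2023Q1") == (20230101, 20230331)
        assert quarter_bounds("2020Q4") == (20201001, 20201231)

    def test_bad_quarter_rejected(self):
        with pytest.raises(ValueError):
            quarter_bounds("2020Q5")

    def test_out_of_window_reports_dropped(self, fixture_dir, tmp_path):
        cfg = RunConfig(inputs={k: str(v) for k, v in fixture_dir.items()},
                        window=("2022Q1", "2023Q1"))
        res = run_pipeline(cfg)
        assert res.counts["in_window_reports"] < res.counts["deduplicated_reports"]


class TestDemographicsTable:
    def test_single_report_is_all_of_every_category(self, fixture_cohort):
        demo, kids, cohort = fixture_cohort
        one = cohort.flags[cohort.flags["atorvastatin"]
                           & cohort.flags["case"]].index[:1]
        sub = cohort.flags.loc[one]
        trimmed = cohort
        trimmed = type(cohort)(flags=cohort.flags.loc[one],
                               reactions=cohort.reactions, meddra=cohort.meddra,
                               target_soc=cohort.target_soc,
                               drugs=("atorvastatin",))
        table = demographics_table(demo[demo["primaryid"].isin(one)], trimmed,
                                   drugs=["atorvastatin"])
        totals = table[table["section"] == "total"]
        assert totals["atorvastatin_pct"].iloc[0] == 100.0

    def test_sections_sum_to_100(self, fixture_cohort):
        demo, kids, cohort = fixture_cohort
        table = demographics_table(demo, cohort)
        for section in ["sex", "age"]:
            rows = table[(table["section"] == section)
                         & table["category"].ne("median (IQR)")]
            for col in ["atorvastatin_pct", "rosuvastatin_pct", "total_pct"]:
                assert rows[col].sum() == pytest.approx(100.0, abs=0.02)

    def test_counts_are_exposed_case_reports(self, fixture_cohort):
        demo, kids, cohort = fixture_cohort
        table = demographics_table(demo, cohort)
        total = table[table["section"] == "total"].iloc[0]
        for d in cohort.drugs:
            assert total[f"{d}_n"] == int((cohort.flags[d]
                                           & cohort.flags["case"]).sum())


class TestTopPtTable:
    def test_ties_break_alphabetically(self):
        counts = pd.Series({"Wheezing": 5, "Asthma": 5, "Cough": 9})
        out = top_pt_table(counts, k=3, denominator=20)
        assert out["pt"].tolist() == ["Cough", "Asthma", "Wheezing"]
        assert out["pct"].tolist() == [45.0, 25.0, 25.0]

    def test_k_larger_than_distinct_returns_all(self):
        counts = pd.Series({"Cough": 2})
        assert len(top_pt_table(counts, k=5, denominator=2)) == 1

    def test_share_of_soc_case_total(self):
        out = top_pt_table(pd.Series({"Dyspnoea": 1741}), k=1, denominator=8211)
        assert out["pct"].iloc[0] == 21.20


class TestPipeline:
    def test_deterministic_outputs(self, fixture_dir, tmp_path):
        inputs = {k: str(v) for k, v in fixture_dir.items()}
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        run_pipeline(RunConfig(inputs=inputs, output_dir=str(out1)))
        run_pipeline(RunConfig(inputs=inputs, output_dir=str(out2)))
        for name in ["signals.tsv", "demographics.tsv", "subgroups.tsv",
                     "cross_strata.tsv", "top_pts.tsv", "tto.tsv"]:
            assert filecmp.cmp(out1 / name, out2 / name, shallow=False), name

    def test_empty_reactions_is_clean_degenerate_run(self, fixture_dir,
                                                     tmp_path):
        inputs = {k: str(v) for k, v in fixture_dir.items()}
        empty = tmp_path / "reac_empty.txt"
        empty.write_text("primaryid$caseid$pt_code$pt\n")
        inputs["REAC"] = str(empty)
        res = run_pipeline(RunConfig(inputs=inputs))
        assert res.counts["cases"] == 0
        assert not res.signals.frame["signal"].any()
        assert all(s is None for s in res.tto_summaries.values())

    def test_missing_input_names_stage(self, fixture_dir):
        inputs = {k: str(v) for k, v in fixture_dir.items()}
        inputs["DRUG"] = "/nonexistent/drug.txt"
        with pytest.raises(PipelineError, match="read"):
            run_pipeline(RunConfig(inputs=inputs))

    def test_count_flow_reconstructable(self, fixture_dir):
        res = run_pipeline(RunConfig(
            inputs={k: str(v) for k, v in fixture_dir.items()}))
        c = res.counts
        assert (c["raw_demo_rows"] >= c["deduplicated_reports"]
                >= c["in_window_reports"] >= c["cases"])

    def test_metadata_records_variance_choice_and_seed(self, fixture_dir,
                                                       tmp_path):
        out = tmp_path / "meta"
        run_pipeline(RunConfig(inputs={k: str(v) for k, v in fixture_dir.items()},
                               ic_variance="delta", seed=9,
                               output_dir=str(out)))
        meta = json.loads((out / "metadata.json").read_text())
        assert meta["ic_variance"] == "delta" and meta["seed"] == 9
        assert "counts" in meta and "qc" in meta


class TestGoldenFixture:
    def test_matches_committed_expectations(self, fixture_dir):
        """SOC-level 2x2 cells, case counts and onset summaries on the
        committed fixture equal values frozen from a brute-force enumeration."""
        expected = json.loads(
            (Path(__file__).parent / "data"
             / "fixture_small_expected.json").read_text())
        res = run_pipeline(RunConfig(
            inputs={k: str(v) for k, v in fixture_dir.items()}))
        soc = res.signals.frame[res.signals.frame["event"].str.startswith("SOC:")]
        for drug, cells in expected["soc_tables"].items():
            row = soc[soc["drug"] == drug].iloc[0]
            assert [int(row[c]) for c in "abcd"] == cells
        assert res.counts["deduplicated_reports"] == expected["n_reports"]
        assert res.counts["cases"] == expected["n_cases"]
        for drug, summ in expected["tto"].items():
            s = res.tto_summaries[drug]
            assert [s.n, s.median_days, s.iqr_low, s.iqr_high] == summ


class TestCli:
    def test_generate_and_run_subcommands(self, tmp_path):
        from click.testing import CliRunner
        import yaml

        from faerspv.cli import main

        runner = CliRunner()
        gen_cfg = tmp_path / "gen.yaml"
        gen_cfg.write_text(yaml.safe_dump({"n_reports": 300, "seed": 5}))
        data_dir = tmp_path / "data"
        r = runner.invoke(main, ["generate", "-c", str(gen_cfg),
                                 "-o", str(data_dir)])
        assert r.exit_code == 0, r.output
        run_cfg = tmp_path / "run.yaml"
        run_cfg.write_text(yaml.safe_dump({
            "inputs": {k: str(data_dir / f"{k.lower()}.txt")
                       for k in ["DEMO", "DRUG", "REAC", "THER", "OUTC"]},
            "output_dir": str(tmp_path / "out")}))
        r = runner.invoke(main, ["run", "-c", str(run_cfg)])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "out" / "signals.tsv").exists()
        r = runner.invoke(main, ["tto", "-c", str(run_cfg)])
        assert r.exit_code == 0, r.output
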