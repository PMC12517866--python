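from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests._oracles imports

from faerspv import faers_model as fm
from faerspv.cohort import DrugDictionary, MeddraMap, build_cohort
from faerspv.reporting import DEFAULT_TARGET_DRUGS, RESPIRATORY_SOC
from faerspv.synthetic import SyntheticConfig, fixture_small


def lean_config(**overrides) -> SyntheticConfig:
    """Generator config stripped of features irrelevant to the calling test
    (no duplicate versions, outcomes or extra PTs) so simulations stay fast."""
    base = dict(
        p_duplicate_version=0.0,
        outcome_probs={},
        mean_background_drugs=0.0,
        p_nonps_target=0.0,
        p_missing_event_date=1.0,
        p_partial_date=0.0,
        pts_geometric_p=1.0,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def dictionary() -> DrugDictionary:
    return DrugDictionary.from_tsv()


@pytest.fixture(scope="session")
def meddra() -> MeddraMap:
    return MeddraMap.from_tsv()


@pytest.fixture(scope="session")
def fixture_ds():
    return fixture_small()


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, fixture_ds) -> dict:
    """The small fixture written as ASCII tables; returns kind -> path."""
    outdir = tmp_path_factory.mktemp("fixture_small")
    return fixture_ds.write(outdir)


@pytest.fixture(scope="session")
def fixture_cohort(fixture_ds, dictionary, meddra):
    demo = fm.deduplicate(fixture_ds.demo)
    kids = {k: fm.filter_children(getattr(fixture_ds, k.lower()),
                                  demo["primaryid"])
            for k in ["DRUG", "REAC", "THER", "OUTC"]}
    cohort = build_cohort(demo, kids["DRUG"], kids["REAC"], dictionary, meddra,
                          DEFAULT_TARGET_DRUGS, RESPIRATORY_SOC)
    return demo, kids, cohort
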