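"""Exposure and outcome labeling for the case/non-case design.

*Exposure*: a report is exposed to a study drug only when at least one of
its DRUG rows resolves to that drug's ATC code **and** carries the primary
suspect (PS) role — secondary suspect, concomitant and interacting records
never create exposure, which keeps confounding by co-medication out of the
numerator.

*Outcome*: a report is a *case* when at least one of its reaction preferred
terms (PTs) maps to the target system organ class (SOC); it counts once no
matter how many target-SOC PTs it carries.  Every other report is a
non-case.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Cohort",
    "DrugDictionary",
    "MeddraMap",
    "build_cohort",
    "label_cases",
    "label_exposure",
    "normalize_drug_name",
    "pt_event_counts",
    "resolve_drug",
]

#: Trailing tokens stripped from free-text drug names before lookup:
#: numeric doses ("20MG", "10 MG", "0.5G", bare strengths) and dose forms.
_DOSE_TOKEN = re.compile(
    r"^(?:\d+(?:\.\d+)?\s*(?:MG|MCG|G|ML|IU|UG)?|MG|TABLETS?|TABS?|CAPSULES?|"
    r"CAPS?|INJECTION|SOLUTION|ORAL|FILM|COATED)$")


def normalize_drug_name(name: str) -> str:
    """Trim, case-fold and strip trailing dose tokens from a drug name.

    Applied identically when the dictionary is built and at lookup, so
    "  atorvastatin Calcium 20MG " and "ATORVASTATIN CALCIUM" collide.
    """
    tokens = str(name).upper().split()
    while tokens and _DOSE_TOKEN.match(tokens[-1]):
        tokens.pop()
    return " ".join(tokens)


def _bundled(fname: str) -> Path:
    return Path(str(resources.files("faerspv").joinpath("data", fname)))


@dataclass
class DrugDictionary:
    """Normalized drug-name → WHO ATC code lookup (exact match only).

    No fuzzy matching: in disproportionality a false exposure distorts the
    2×2 more than a missed one, so unknown spellings simply do not resolve.
    """

    entries: dict[str, str]

    @classmethod
    def from_tsv(cls, path: str | Path | None = None) -> "DrugDictionary":
        """Load a (name, atc_code) TSV; defaults to the bundled dictionary."""
        path = _bundled("drug_dictionary.tsv") if path is None else Path(path)
        df = pd.read_csv(path, sep="\t", dtype=str)
        entries = {normalize_drug_name(n): c.strip()
                   for n, c in zip(df["name"], df["atc_code"])}
        return cls(entries)

    def lookup(self, drug_name: str) -> Optional[str]:
        return self.entries.get(normalize_drug_name(drug_name))


def resolve_drug(drug_name: str, dictionary: DrugDictionary) -> Optional[str]:
    """ATC code for a free-text drug name, or ``None`` when not in the dictionary."""
    return dictionary.lookup(drug_name)


@dataclass
class MeddraMap:
    """PT → primary SOC mapping (one SOC per PT; multi-axiality out of scope).

    The bundled map is a synthetic stand-in for the licensed MedDRA
    dictionary: PT and SOC names are real MedDRA vocabulary and the
    respiratory SOC carries its published code, but PT codes are invented.
    Point :meth:`from_tsv` at a licensed export for production use.
    """

    pt_to_soc: dict[int, int]
    pt_names: dict[int, str]
    soc_names: dict[int, str]

    @classmethod
    def from_tsv(cls, path: str | Path | None = None) -> "MeddraMap":
        """Load a (pt_code, pt_name, soc_code, soc_name) TSV."""
        path = _bundled("synthetic_meddra_map.tsv") if path is None else Path(path)
        df = pd.read_csv(path, sep="\t", dtype={"pt_code": int, "soc_code": int})
        return cls(
            pt_to_soc=dict(zip(df["pt_code"], df["soc_code"])),
            pt_names=dict(zip(df["pt_code"], df["pt_name"])),
            soc_names=dict(zip(df["soc_code"], df["soc_name"])),
        )

    def pts_in_soc(self, soc_code: int) -> list[int]:
        return [pt for pt, soc in self.pt_to_soc.items() if soc == soc_code]


# ---------------------------------------------------------------------------
# Labeling
# ---------------------------------------------------------------------------

def label_exposure(drug: pd.DataFrame,
                   target_atc: Mapping[str, str],
                   dictionary: DrugDictionary) -> pd.DataFrame:
    """Per-report primary-suspect exposure flags for each target drug.

    Parameters
    ----------
    drug
        DRUG child table (already filtered to surviving reports).
    target_atc
        Mapping of analysis label → ATC code, e.g.
        ``{"atorvastatin": "C10AA05", "rosuvastatin": "C10AA07"}``.  A report
        naming both drugs as PS is exposed to both and enters each drug's
        analysis.

    Returns
    -------
    DataFrame indexed by ``primaryid`` with one boolean column per label.
    """
    from .faers_model import map_levels

    atc = map_levels(drug["drugname"],
                     lambda nm: dictionary.entries.get(normalize_drug_name(nm)))
    ps = map_levels(drug["role_cod"],
                    lambda r: str(r).strip().upper() == "PS").astype(bool)
    out = pd.DataFrame(index=pd.Index(drug["primaryid"].unique(), name="primaryid"))
    for label, code in target_atc.items():
        hits = drug.loc[ps & (atc == code), "primaryid"].unique()
        out[label] = out.index.isin(hits)
    return out


def label_cases(reac: pd.DataFrame, meddra: MeddraMap,
                target_soc: int) -> tuple[pd.Series, int]:
    """Case flag per report plus the count of unmapped PT codes seen.

    A report is a case once regardless of how many target-SOC PTs it
    carries; PT codes absent from the map never make a case and are tallied
    for QC.
    """
    from .faers_model import map_levels

    soc = pd.Series(map_levels(reac["pt_code"],
                               lambda c: meddra.pt_to_soc.get(c) if pd.notna(c)
                               else None),
                    index=reac.index)
    unmapped = int((soc.isna() & reac["pt_code"].notna()).sum())
    hits = reac.loc[soc.eq(target_soc).fillna(False), "primaryid"].unique()
    case = pd.Series(False, index=pd.Index(reac["primaryid"].unique(),
                                           name="primaryid"))
    case[case.index.isin(hits)] = True
    return case, unmapped


def pt_event_counts(reac: pd.DataFrame, cohort: "Cohort",
                    drug: str) -> pd.Series:
    """Reports per target-SOC PT among a drug's exposed case reports.

    Each report contributes at most once per PT (duplicate REAC rows are
    collapsed), so every per-PT count is bounded by the drug's SOC-level
    case count.
    """
    exposed_cases = cohort.flags.index[
        cohort.flags[drug] & cohort.flags["case"]]
    soc = reac["pt_code"].map(cohort.meddra.pt_to_soc)
    sub = reac[soc.eq(cohort.target_soc).fillna(False)
               & reac["primaryid"].isin(exposed_cases)]
    pairs = sub.drop_duplicates(["primaryid", "pt_code"])
    counts = pairs.groupby("pt_code").size()
    counts.index = counts.index.map(lambda c: cohort.meddra.pt_names.get(int(c), str(c)))
    return counts.sort_values(ascending=False)


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Labeled deduplicated report universe for disproportionality.

    ``flags`` is indexed by ``primaryid`` and carries one boolean column per
    target drug, a ``case`` column, and the demographics needed for
    stratification (``sex``, ``age_years``).
    """

    flags: pd.DataFrame
    reactions: pd.DataFrame
    meddra: MeddraMap
    target_soc: int
    drugs: tuple[str, ...]
    qc: dict = field(default_factory=dict)

    @property
    def n_reports(self) -> int:
        return len(self.flags)

    def case_flags_for_pt(self, pt_code: int) -> pd.Series:
        """Boolean case flag per report for a single-PT event definition."""
        hits = self.reactions.loc[
            self.reactions["pt_code"].eq(pt_code), "primaryid"].unique()
        return pd.Series(self.flags.index.isin(hits), index=self.flags.index)


def build_cohort(demo: pd.DataFrame, drug: pd.DataFrame, reac: pd.DataFrame,
                 dictionary: DrugDictionary, meddra: MeddraMap,
                 target_atc: Mapping[str, str], target_soc: int) -> Cohort:
    """Label a deduplicated report universe and assemble a :class:`Cohort`.

    ``demo`` must already be deduplicated (one row per case) and the child
    tables filtered to its survivors; demographics are normalized here
    (sex → {F, M, UNKNOWN}, age → years).
    """
    from . import faers_model as fm

    demo = fm.add_age_years(fm.normalize_sex(demo))
    flags = pd.DataFrame(index=pd.Index(demo["primaryid"].astype("int64"),
                                        name="primaryid"))
    flags["sex"] = demo["sex"].to_numpy()
    flags["age_years"] = demo["age_years"].to_numpy()

    exposure = label_exposure(drug, target_atc, dictionary)
    for label in target_atc:
        flags[label] = flags.index.isin(exposure.index[exposure[label]])

    case, unmapped = label_cases(reac, meddra, target_soc)
    flags["case"] = flags.index.isin(case.index[case])

    return Cohort(
        flags=flags,
        reactions=reac[["primaryid", "pt_code", "pt"]].copy(),
        meddra=meddra,
        target_soc=target_soc,
        drugs=tuple(target_atc),
        qc={"unmapped_pt_rows": unmapped,
            "n_reports": len(flags),
            "n_cases": int(flags["case"].sum())},
    )
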