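"""Subgroup and cross-stratified disproportionality by sex and age.

Two distinct contrasts share the ROR/CI code path:

* **Subgroup analysis** — drug-vs-rest *within* a demographic stratum: the
  report universe is restricted to the stratum and the usual exposure × event
  2×2 is built there.  This probes whether the drug–event association is
  specific to, say, women or the elderly.
* **Cross-stratification** — stratum-vs-reference *within* a drug: among the
  reports naming the drug as primary suspect, the 2×2 rows are the two
  demographic strata and the columns are event vs non-event.  Swapping
  stratum and reference inverts the ROR exactly (in rational arithmetic).

Reports with unknown sex are excluded from any stratum that conditions on
sex, and reports with missing age from any stratum that conditions on age;
strata that do not condition on the missing field are unaffected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import Cohort
from .disproportionality import (ContingencyTable, IcVariance, SignalEstimate,
                                 ZeroCell, estimate)

__all__ = ["CrossStratResult", "StratumSpec", "cross_stratified_ror",
           "reciprocity_product", "subgroup_estimate"]

INF = math.inf


@dataclass(frozen=True)
class StratumSpec:
    """A demographic stratum: a sex restriction and a half-open age band.

    ``age_low`` is inclusive, ``age_high`` exclusive (years); ``sex="ANY"``
    or the default (0, inf) age band leaves that dimension unrestricted.
    The study strata are e.g. ``StratumSpec("elderly female", "F", 75)`` or
    ``StratumSpec("middle-aged and elderly men", "M", 18, 75)``.
    """

    label: str
    sex: str = "ANY"
    age_low: float = 0.0
    age_high: float = INF

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M", "ANY"):
            raise ValueError(f"sex must be F, M or ANY, got {self.sex!r}")
        if not self.age_low < self.age_high:
            raise ValueError("age_low must be < age_high")

    @property
    def conditions_on_age(self) -> bool:
        return (self.age_low, self.age_high) != (0.0, INF)

    def mask(self, flags: pd.DataFrame) -> np.ndarray:
        """Membership over a cohort flags frame (sex, age_years columns).

        Unknown sex / missing age are excluded only when the stratum
        conditions on that field.
        """
        m = np.ones(len(flags), dtype=bool)
        if self.sex != "ANY":
            m &= flags["sex"].to_numpy() == self.sex
        if self.conditions_on_age:
            age = flags["age_years"].to_numpy(dtype=float)
            m &= ~np.isnan(age) & (age >= self.age_low) & (age < self.age_high)
        return m

    def overlaps(self, other: "StratumSpec") -> bool:
        sex_overlap = (self.sex == other.sex
                       or self.sex == "ANY" or other.sex == "ANY")
        age_overlap = (self.age_low < other.age_high
                       and other.age_low < self.age_high)
        return sex_overlap and age_overlap


@dataclass
class CrossStratResult:
    """Stratum-vs-reference ROR within one drug's primary-suspect reports."""

    drug: str
    stratum: StratumSpec
    reference: StratumSpec
    table: ContingencyTable
    ror: float
    ci_low: float
    ci_high: float
    defined: bool

    def ror_exact(self) -> Optional[Fraction]:
        """The ROR as an exact rational (None when a cell is zero)."""
        t = self.table
        if t.b * t.c == 0:
            return None
        return Fraction(t.a * t.d, t.b * t.c)


def subgroup_estimate(cohort: Cohort, drug: str, stratum: StratumSpec,
                      event: int | None = None,
                      ic_variance: IcVariance = "bcpnn",
                      zero_cell: ZeroCell = "none"
                      ) -> tuple[ContingencyTable, SignalEstimate]:
    """Exposure-vs-rest 2×2 restricted to one demographic stratum.

    The all-inclusive stratum reproduces the unstratified analysis; an empty
    margin yields undefined-estimate markers, never an exception.
    """
    m = stratum.mask(cohort.flags)
    exposed = cohort.flags[drug].to_numpy(dtype=bool) & m
    if event is None:
        case = cohort.flags["case"].to_numpy(dtype=bool)
    else:
        case = cohort.case_flags_for_pt(int(event)).to_numpy(dtype=bool)
    case = case & m
    a = int(np.sum(exposed & case))
    b = int(np.sum(exposed & ~case & m))
    c = int(np.sum(~exposed & case & m))
    d = int(np.sum(~exposed & ~case & m))
    table = ContingencyTable(a, b, c, d)
    return table, estimate(table, ic_variance, zero_cell)


def cross_stratified_ror(cohort: Cohort, drug: str, stratum: StratumSpec,
                         reference: StratumSpec,
                         event: int | None = None) -> CrossStratResult:
    """Stratum-vs-reference event odds among the drug's PS-exposed reports.

    Raises
    ------
    ValueError
        If the two strata overlap — the 2×2 rows must partition reports.
    """
    if stratum.overlaps(reference):
        raise ValueError(
            f"strata {stratum.label!r} and {reference.label!r} overlap; "
            "cross-stratification requires disjoint strata")
    exposed = cohort.flags[drug].to_numpy(dtype=bool)
    if event is None:
        case = cohort.flags["case"].to_numpy(dtype=bool)
    else:
        case = cohort.case_flags_for_pt(int(event)).to_numpy(dtype=bool)
    in_s = stratum.mask(cohort.flags) & exposed
    in_r = reference.mask(cohort.flags) & exposed
    a = int(np.sum(in_s & case))
    b = int(np.sum(in_s & ~case))
    c = int(np.sum(in_r & case))
    d = int(np.sum(in_r & ~case))
    table = ContingencyTable(a, b, c, d)
    from .disproportionality import ror as _ror
    point, lo, hi, defined = _ror(table)
    return CrossStratResult(drug=drug, stratum=stratum, reference=reference,
                            table=table, ror=point, ci_low=lo, ci_high=hi,
                            defined=defined)


def reciprocity_product(forward: CrossStratResult,
                        backward: CrossStratResult) -> Optional[Fraction]:
    """Exact product ROR(A vs B) × ROR(B vs A); equals 1 when both defined."""
    f, b = forward.ror_exact(), backward.ror_exact()
    if f is None or b is None:
        return None
    return f * b
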