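"""Case/non-case disproportionality statistics: ROR and the BCPNN IC.

For one drug–event pair the deduplicated report universe is cross-classified
into the 2×2 table

    ============  ============  ============
                  target event  other events
    target drug        a             b
    other drugs        c             d
    ============  ============  ============

and two measures of disproportionate reporting are computed.

**Reporting odds ratio.**  ``ROR = ad/bc`` with the Woolf log-scale interval
``exp(ln ROR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d))``.

**Information component.**  The observed/expected form of the BCPNN IC,

    IC = log2( a·n / ((a+b)(a+c)) ),    n = a+b+c+d,

with the ±2·sqrt(V(IC)) credibility interval.  The default V(IC) is the
closed-form variance of the posterior IC from the Bayesian confidence
propagation neural network (Bate *et al.* 1998) with all Beta/Dirichlet
hyperparameters equal to 1; a delta-method variance is selectable.

**Signal rule.**  A pair is a signal only when *both* methods fire: the ROR
interval's lower limit exceeds 1 with at least 10 co-reports, and IC025 > 0.
The conjunction is deliberately conservative.

The module exposes both plain functions (:func:`ror`,
:func:`information_component`, :func:`decide_signal`) and a statsmodels-like
:class:`DisproportionalityModel` whose :meth:`~DisproportionalityModel.fit`
returns a :class:`DisproportionalityResults` with a summary table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = [
    "ContingencyTable",
    "DisproportionalityModel",
    "DisproportionalityResults",
    "SignalDecision",
    "SignalEstimate",
    "build_table",
    "decide_signal",
    "information_component",
    "ror",
]

Z95 = 1.96  # two-sided 95% normal quantile, as printed in the ROR formula
LN2 = math.log(2.0)

IcVariance = Literal["bcpnn", "delta"]
ZeroCell = Literal["none", "haldane"]


@dataclass(frozen=True)
class ContingencyTable:
    """Report counts for one drug–event pair (see module docstring)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def drug_margin(self) -> int:
        """All reports exposed to the drug (a + b)."""
        return self.a + self.b

    @property
    def event_margin(self) -> int:
        """All case reports (a + c)."""
        return self.a + self.c

    def with_haldane(self) -> tuple[float, float, float, float]:
        """Cells with the +0.5 continuity correction applied."""
        return self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5


@dataclass
class SignalEstimate:
    """Point estimates and 95% intervals for one drug–event pair."""

    ror: float
    ror_ci_low: float
    ror_ci_high: float
    ic: float
    ic025: float
    ic975: float
    n_cases: int
    ror_defined: bool = True
    ic_shrunk: bool = False
    ic_variance: str = "bcpnn"


@dataclass
class SignalDecision:
    """Outcome of the dual ROR ∧ IC signal criterion."""

    ror_positive: bool
    ic_positive: bool
    signal: bool
    reason: str = ""


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def ror(table: ContingencyTable,
        zero_cell: ZeroCell = "none") -> tuple[float, float, float, bool]:
    """Reporting odds ratio with its Woolf 95% confidence interval.

    Returns ``(ror, ci_low, ci_high, defined)``.  With ``zero_cell="none"``
    (the default) any zero cell yields NaNs and ``defined=False`` rather
    than an exception — the ≥10-case signal rule makes corrected estimates
    unnecessary for decisions, so the Haldane +0.5 correction is offered
    only for exploratory output.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if zero_cell == "haldane":
        a, b, c, d = table.with_haldane()
    elif min(a, b, c, d) == 0:
        return math.nan, math.nan, math.nan, False
    point = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    log_ror = math.log(point)
    return (point,
            math.exp(log_ror - Z95 * se),
            math.exp(log_ror + Z95 * se),
            True)


def _bcpnn_variance(a: int, margin_x: int, margin_y: int, n: int) -> float:
    """Closed-form posterior IC variance (Bate et al. 1998, hyperparams 1).

    ``margin_x = a+b`` (drug), ``margin_y = a+c`` (event).  Prior constants:
    alpha1 = beta1 = gamma11 = 1, alpha = beta = 2, and gamma chosen so the
    prior IC is centred at zero.
    """
    alpha1 = beta1 = gamma11 = 1.0
    alpha = beta = 2.0
    gamma = gamma11 * (n + alpha) * (n + beta) / ((margin_x + alpha1) * (margin_y + beta1))
    term_xy = (n - a + gamma - gamma11) / ((a + gamma11) * (1 + n + gamma))
    term_x = (n - margin_x + alpha - alpha1) / ((margin_x + alpha1) * (1 + n + alpha))
    term_y = (n - margin_y + beta - beta1) / ((margin_y + beta1) * (1 + n + beta))
    return (term_xy + term_x + term_y) / LN2 ** 2


def _bcpnn_expectation(a: int, margin_x: int, margin_y: int, n: int) -> float:
    """Posterior mean IC under the same Bate et al. parameterization."""
    alpha1 = beta1 = gamma11 = 1.0
    alpha = beta = 2.0
    gamma = gamma11 * (n + alpha) * (n + beta) / ((margin_x + alpha1) * (margin_y + beta1))
    return math.log2((a + gamma11) * (n + alpha) * (n + beta)
                     / ((n + gamma) * (margin_x + alpha1) * (margin_y + beta1)))


def information_component(
        table: ContingencyTable,
        variance: IcVariance = "bcpnn") -> tuple[float, float, float, bool]:
    """IC point estimate and ±2√V(IC) credibility interval, in bits.

    Returns ``(ic, ic025, ic975, shrunk)``.  The point estimate is the
    observed/expected form ``log2(a·n / ((a+b)(a+c)))``; when ``a = 0`` that
    form is undefined and the shrinkage posterior mean is substituted with
    ``shrunk=True``.  The interval is centred on the reported point so that
    ``ic025 ≤ ic ≤ ic975`` always holds.

    ``variance="delta"`` selects the delta-method approximation
    ``(1/ln2)²·(1/a − 1/(a+b) − 1/(a+c) + 1/n)`` instead of the BCPNN
    closed form.
    """
    a, n = table.a, table.n
    mx, my = table.drug_margin, table.event_margin
    if n == 0 or mx == 0 or my == 0:
        return math.nan, math.nan, math.nan, False
    shrunk = False
    if a == 0:
        point = _bcpnn_expectation(a, mx, my, n)
        shrunk = True
    else:
        point = math.log2(a * n / (mx * my))
    if variance == "delta":
        var = (1.0 / a - 1.0 / mx - 1.0 / my + 1.0 / n) / LN2 ** 2 if a else 0.0
        if var <= 0.0:
            # the first-order approximation degenerates (large a relative to
            # its margins); fall back to the closed-form posterior variance
            var = _bcpnn_variance(a, mx, my, n)
    elif variance == "bcpnn":
        var = _bcpnn_variance(a, mx, my, n)
    else:
        raise ValueError(f"unknown IC variance estimator: {variance!r}")
    half = 2.0 * math.sqrt(var)
    return point, point - half, point + half, shrunk


#: Minimum co-report count for the ROR arm of the signal rule.
MIN_CASES = 10


def decide_signal(est: SignalEstimate) -> SignalDecision:
    """Apply the dual criterion: ROR CI low > 1 with ≥10 cases, and IC025 > 0."""
    if not est.ror_defined or math.isnan(est.ic025):
        return SignalDecision(False, False, False, reason="undefined estimate")
    ror_positive = est.ror_ci_low > 1.0 and est.n_cases >= MIN_CASES
    ic_positive = est.ic025 > 0.0
    signal = ror_positive and ic_positive
    reason = "" if signal else "; ".join(
        msg for ok, msg in [
            (est.n_cases >= MIN_CASES, f"fewer than {MIN_CASES} cases"),
            (est.ror_ci_low > 1.0, "ROR CI lower bound not above 1"),
            (ic_positive, "IC025 not above 0"),
        ] if not ok)
    return SignalDecision(ror_positive, ic_positive, signal, reason)


def estimate(table: ContingencyTable,
             ic_variance: IcVariance = "bcpnn",
             zero_cell: ZeroCell = "none") -> SignalEstimate:
    """Convenience: both estimators on one table."""
    r, lo, hi, defined = ror(table, zero_cell)
    ic, ic025, ic975, shrunk = information_component(table, ic_variance)
    return SignalEstimate(ror=r, ror_ci_low=lo, ror_ci_high=hi,
                          ic=ic, ic025=ic025, ic975=ic975,
                          n_cases=table.a, ror_defined=defined,
                          ic_shrunk=shrunk, ic_variance=ic_variance)


# ---------------------------------------------------------------------------
# Table construction
# ---------------------------------------------------------------------------

def build_table(cohort: Cohort, drug: str,
                event: int | None = None) -> ContingencyTable:
    """2×2 table for one drug against the whole report universe.

    ``event=None`` uses the SOC-level case flag; an integer PT code
    restricts the event to that single preferred term, still with the entire
    deduplicated universe as the comparator.
    """
    exposed = cohort.flags[drug].to_numpy(dtype=bool)
    if event is None:
        case = cohort.flags["case"].to_numpy(dtype=bool)
    else:
        case = cohort.case_flags_for_pt(int(event)).to_numpy(dtype=bool)
    a = int(np.sum(exposed & case))
    b = int(np.sum(exposed & ~case))
    c = int(np.sum(~exposed & case))
    d = int(np.sum(~exposed & ~case))
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class DisproportionalityModel:
    """Case/non-case disproportionality model over one or more 2×2 tables.

    Build it from explicit counts (:meth:`from_counts`) or from a labeled
    :class:`~faerspv.cohort.Cohort` (:meth:`from_cohort`, one table per
    drug × event definition); :meth:`fit` evaluates ROR and IC on every
    table and returns a :class:`DisproportionalityResults`.

    Examples
    --------
    >>> m = DisproportionalityModel.from_counts(10, 90, 100, 9900)
    >>> res = m.fit()
    >>> round(res.frame.loc[0, "ror"], 2)
    11.0
    """

    def __init__(self, tables: Sequence[tuple[str, str, ContingencyTable]]):
        self.tables = list(tables)

    @classmethod
    def from_counts(cls, a: int, b: int, c: int, d: int,
                    drug: str = "drug", event: str = "event"
                    ) -> "DisproportionalityModel":
        return cls([(drug, event, ContingencyTable(a, b, c, d))])

    @classmethod
    def from_cohort(cls, cohort: Cohort,
                    drugs: Optional[Sequence[str]] = None,
                    pt_level: bool = False) -> "DisproportionalityModel":
        """One SOC-level table per drug; ``pt_level=True`` adds one table per
        target-SOC PT observed among that drug's exposed case reports."""
        drugs = list(drugs) if drugs is not None else list(cohort.drugs)
        soc_name = cohort.meddra.soc_names.get(cohort.target_soc,
                                               str(cohort.target_soc))
        tables: list[tuple[str, str, ContingencyTable]] = []
        for drug in drugs:
            tables.append((drug, f"SOC:{soc_name}", build_table(cohort, drug)))
            if pt_level:
                seen = cohort.reactions.loc[
                    cohort.reactions["primaryid"].isin(
                        cohort.flags.index[cohort.flags[drug]
                                           & cohort.flags["case"]]),
                    "pt_code"].dropna().unique()
                for pt in sorted(int(p) for p in seen
                                 if cohort.meddra.pt_to_soc.get(int(p))
                                 == cohort.target_soc):
                    name = cohort.meddra.pt_names.get(pt, str(pt))
                    tables.append((drug, f"PT:{name}",
                                   build_table(cohort, drug, event=pt)))
        return cls(tables)

    def fit(self, ic_variance: IcVariance = "bcpnn",
            zero_cell: ZeroCell = "none") -> "DisproportionalityResults":
        rows = []
        for drug, event, table in self.tables:
            est = estimate(table, ic_variance, zero_cell)
            dec = decide_signal(est)
            rows.append({
                "drug": drug, "event": event,
                "a": table.a, "b": table.b, "c": table.c, "d": table.d,
                "ror": est.ror, "ror_ci_low": est.ror_ci_low,
                "ror_ci_high": est.ror_ci_high,
                "ic": est.ic, "ic025": est.ic025, "ic975": est.ic975,
                "n_cases": est.n_cases,
                "ror_positive": dec.ror_positive,
                "ic_positive": dec.ic_positive,
                "signal": dec.signal,
                "reason": dec.reason,
            })
        frame = pd.DataFrame(rows)
        if not frame.empty:
            frame = frame.sort_values(
                ["ror", "drug", "event"], ascending=[False, True, True],
                na_position="last", kind="mergesort").reset_index(drop=True)
        return DisproportionalityResults(frame, ic_variance=ic_variance,
                                         zero_cell=zero_cell,
                                         n_tests=len(self.tables))


class DisproportionalityResults:
    """Fitted estimates for every drug–event table, with a summary view.

    Attributes
    ----------
    frame
        One row per (drug, event): counts, ROR with CI, IC with credibility
        interval, and the dual-criterion flags, sorted by descending ROR.
    n_tests
        Number of (drug, event) tests performed — no multiplicity
        correction is applied, so downstream users may post-correct.
    """

    #: Column order for the exported TSV.
    TSV_COLUMNS = ["drug", "event", "a", "b", "c", "d", "ror", "ror_ci_low",
                   "ror_ci_high", "ic", "ic025", "ic975", "n_cases", "signal"]

    def __init__(self, frame: pd.DataFrame, ic_variance: str,
                 zero_cell: str, n_tests: int):
        self.frame = frame
        self.ic_variance = ic_variance
        self.zero_cell = zero_cell
        self.n_tests = n_tests

    @property
    def signals(self) -> pd.DataFrame:
        """Rows meeting the dual criterion."""
        return self.frame[self.frame["signal"]]

    def summary(self, decimals: int = 2) -> str:
        """Human-readable table (rounding is presentation-only; the signal
        decisions were made on unrounded values)."""
        from ._format import round_half_up

        if self.frame.empty:
            return "DisproportionalityResults: no tables"
        lines = [
            "Case/non-case disproportionality"
            f"  (IC variance: {self.ic_variance}; {self.n_tests} tests,"
            " no multiplicity correction)",
            f"{'drug':<14}{'event':<34}{'a':>7}{'ROR':>8}"
            f"{'95% CI':>17}{'IC':>7}{'IC025':>8}  signal",
        ]
        for _, r in self.frame.iterrows():
            ci = (f"({round_half_up(r.ror_ci_low, decimals)}-"
                  f"{round_half_up(r.ror_ci_high, decimals)})"
                  if np.isfinite(r.ror_ci_low) else "(undef)")
            lines.append(
                f"{r.drug:<14}{r.event[:32]:<34}{r.a:>7}"
                f"{round_half_up(r.ror, decimals) if np.isfinite(r.ror) else 'NA':>8}"
                f"{ci:>17}"
                f"{round_half_up(r.ic, decimals):>7}"
                f"{round_half_up(r.ic025, decimals):>8}"
                f"  {'yes' if r.signal else 'no'}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame[self.TSV_COLUMNS].to_csv(path, sep="\t", index=False,
                                            lineterminator="\n")

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<DisproportionalityResults: {self.n_tests} tables, "
                f"{int(self.frame['signal'].sum())} signals>")
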