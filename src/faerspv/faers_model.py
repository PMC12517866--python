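"""Relational data model for FAERS-style quarterly extracts.

The FDA Adverse Event Reporting System distributes each quarter as a set of
"$"-delimited ASCII tables sharing the ``primaryid`` report-version key:
DEMO (demographics and administrative fields), DRUG (one row per reported
drug with its role code), REAC (MedDRA-coded reactions), THER (therapy start
and end dates), OUTC (outcome codes), plus RPSR and INDI which this package
reads but does not analyse.

One *case* (``caseid``) may appear as several report versions
(``primaryid``); :func:`deduplicate` keeps a single version per case using
the FDA-recommended rule: the most recent ``fda_dt`` wins, and ties are
broken by the highest ``primaryid``.

Tables are held as :class:`pandas.DataFrame` objects with typed columns;
dataclass views (:class:`SafetyReport` and friends) are provided for
record-level work.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AgeUnit",
    "DrugRecord",
    "DrugRole",
    "Outcome",
    "PartialDate",
    "ReactionRecord",
    "SafetyReport",
    "SchemaError",
    "Sex",
    "TherapyRecord",
    "add_age_years",
    "deduplicate",
    "filter_children",
    "normalize_age",
    "read_table",
    "safety_reports",
    "write_table",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class Sex(str, enum.Enum):
    F = "F"
    M = "M"
    UNKNOWN = "UNKNOWN"


class AgeUnit(str, enum.Enum):
    YEAR = "YEAR"
    DECADE = "DECADE"
    MONTH = "MONTH"
    WEEK = "WEEK"
    DAY = "DAY"
    UNKNOWN = "UNKNOWN"


class DrugRole(str, enum.Enum):
    PS = "PS"  # primary suspect
    SS = "SS"  # secondary suspect
    C = "C"    # concomitant
    I = "I"    # interacting


class Outcome(str, enum.Enum):
    DEATH = "DEATH"
    LIFE_THREATENING = "LIFE_THREATENING"
    HOSPITALIZATION = "HOSPITALIZATION"
    DISABILITY = "DISABILITY"
    CONGENITAL_ANOMALY = "CONGENITAL_ANOMALY"
    OTHER_SERIOUS = "OTHER_SERIOUS"


#: FAERS OUTC_COD values mapped to outcome categories.
OUTCOME_CODES = {
    "DE": Outcome.DEATH,
    "LT": Outcome.LIFE_THREATENING,
    "HO": Outcome.HOSPITALIZATION,
    "DS": Outcome.DISABILITY,
    "CA": Outcome.CONGENITAL_ANOMALY,
    "OT": Outcome.OTHER_SERIOUS,
}

#: FAERS AGE_COD values mapped to age units.
AGE_UNIT_CODES = {
    "YR": AgeUnit.YEAR,
    "YEAR": AgeUnit.YEAR,
    "DEC": AgeUnit.DECADE,
    "DECADE": AgeUnit.DECADE,
    "MON": AgeUnit.MONTH,
    "MONTH": AgeUnit.MONTH,
    "WK": AgeUnit.WEEK,
    "WEEK": AgeUnit.WEEK,
    "DY": AgeUnit.DAY,
    "DAY": AgeUnit.DAY,
}

#: Years-per-unit conversion factors; results outside [0, 130] are dropped.
AGE_UNIT_FACTORS = {
    AgeUnit.YEAR: 1.0,
    AgeUnit.DECADE: 10.0,
    AgeUnit.MONTH: 1.0 / 12.0,
    AgeUnit.WEEK: 1.0 / 52.1775,
    AgeUnit.DAY: 1.0 / 365.25,
}

AGE_MIN_YEARS = 0.0
AGE_MAX_YEARS = 130.0


# ---------------------------------------------------------------------------
# Partial dates
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=False)
class PartialDate:
    """A FAERS date of year, month or day resolution.

    FAERS date fields are numeric strings of 4 (``YYYY``), 6 (``YYYYMM``) or
    8 (``YYYYMMDD``) digits.  For ordering, absent month/day are padded with
    01, which is only used inside deduplication where ``fda_dt`` is in
    practice always day-resolved.
    """

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise ValueError("day requires month")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None and not 1 <= self.day <= 31:
            raise ValueError(f"day out of range: {self.day}")

    @property
    def resolution(self) -> str:
        if self.day is not None:
            return "DAY"
        if self.month is not None:
            return "MONTH"
        return "YEAR"

    @classmethod
    def parse(cls, raw: object) -> Optional["PartialDate"]:
        """Parse a 4-, 6- or 8-digit numeric string; ``None`` if unparseable."""
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            return None
        s = str(raw).strip()
        if s.endswith(".0"):  # numeric column read as float
            s = s[:-2]
        if not s.isdigit():
            return None
        try:
            if len(s) == 4:
                return cls(int(s))
            if len(s) == 6:
                return cls(int(s[:4]), int(s[4:6]))
            if len(s) == 8:
                return cls(int(s[:4]), int(s[4:6]), int(s[6:8]))
        except ValueError:
            return None
        return None

    def __str__(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"

    def sort_key(self) -> int:
        """8-digit integer with absent month/day padded by 01."""
        return self.year * 10000 + (self.month or 1) * 100 + (self.day or 1)

    def to_date(self) -> Optional[date]:
        """Calendar date when day-resolved and valid, else ``None``."""
        if self.day is None:
            return None
        try:
            return date(self.year, self.month, self.day)
        except ValueError:
            return None


# ---------------------------------------------------------------------------
# Record views
# ---------------------------------------------------------------------------

@dataclass
class SafetyReport:
    """One (possibly not yet deduplicated) spontaneous report version."""

    primary_id: int
    case_id: int
    fda_date: Optional[PartialDate]
    sex: Sex = Sex.UNKNOWN
    age_value: Optional[float] = None
    age_unit: AgeUnit = AgeUnit.UNKNOWN
    country: Optional[str] = None
    event_date: Optional[PartialDate] = None
    outcomes: frozenset = frozenset()

    @property
    def age_years(self) -> Optional[float]:
        return normalize_age(self.age_value, self.age_unit)


@dataclass
class DrugRecord:
    primary_id: int
    drug_name: str
    role: DrugRole
    atc_code: Optional[str] = None
    start_date: Optional[PartialDate] = None


@dataclass
class ReactionRecord:
    primary_id: int
    pt_code: Optional[int]
    pt_name: str


@dataclass
class TherapyRecord:
    primary_id: int
    start_date: Optional[PartialDate] = None
    end_date: Optional[PartialDate] = None


# ---------------------------------------------------------------------------
# ASCII dialect
# ---------------------------------------------------------------------------

DELIMITER = "$"

#: Required columns per table kind.  RPSR and INDI are schema stubs: they are
#: readable for completeness but no analysis touches them.
TABLE_COLUMNS = {
    "DEMO": ["primaryid", "caseid", "fda_dt", "event_dt", "sex", "age",
             "age_cod", "occr_country"],
    "DRUG": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname"],
    "REAC": ["primaryid", "caseid", "pt_code", "pt"],
    "THER": ["primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"],
    "OUTC": ["primaryid", "caseid", "outc_cod"],
    "RPSR": ["primaryid", "caseid", "rpsr_cod"],
    "INDI": ["primaryid", "caseid", "indi_drug_seq", "indi_pt"],
}

_INT_COLUMNS = {"primaryid", "caseid", "drug_seq", "dsg_drug_seq", "pt_code"}
_FLOAT_COLUMNS = {"age"}


def _empty_frame(table_kind: str) -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in TABLE_COLUMNS[table_kind]})
    return _coerce(df, table_kind)


def _coerce(df: pd.DataFrame, table_kind: str) -> pd.DataFrame:
    """Coerce columns to their types; unparseable numerics become <NA>."""
    df = df.copy()
    for col in TABLE_COLUMNS[table_kind]:
        if col in _INT_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
        elif col in _FLOAT_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
        else:
            df[col] = df[col].fillna("").astype(str).str.strip()
    return df[TABLE_COLUMNS[table_kind]]


def read_table(path: str | Path, table_kind: str) -> pd.DataFrame:
    """Read one FAERS-style "$"-delimited ASCII table.

    The first line must be a header containing every required column for
    ``table_kind`` (extra columns are dropped; order does not matter).
    Unparseable numeric fields become missing, never raise.  An empty file
    yields an empty (typed) frame.

    Raises
    ------
    SchemaError
        If a required column is absent, naming the column.
    """
    if table_kind not in TABLE_COLUMNS:
        raise ValueError(f"unknown table kind: {table_kind!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=DELIMITER, dtype=str,
                         keep_default_na=False, na_values=[""])
    except pd.errors.EmptyDataError:
        return _empty_frame(table_kind)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in TABLE_COLUMNS[table_kind]:
        if col not in df.columns:
            raise SchemaError(
                f"{table_kind} table {path.name!r} is missing required "
                f"column {col!r}")
    return _coerce(df, table_kind)


def write_table(df: pd.DataFrame, path: str | Path, table_kind: str) -> None:
    """Write a typed frame back to the "$"-delimited ASCII dialect."""
    cols = TABLE_COLUMNS[table_kind]
    out = df[cols].copy()
    for col in cols:
        if col in _INT_COLUMNS:
            out[col] = out[col].astype("Int64").astype(str).replace("<NA>", "")
        elif col in _FLOAT_COLUMNS:
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else f"{v:g}")
    out.to_csv(path, sep=DELIMITER, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Age normalization
# ---------------------------------------------------------------------------

def normalize_age(age_value: Optional[float],
                  age_unit: AgeUnit | str | None) -> Optional[float]:
    """Convert an (age, unit) pair to years; implausible values become absent.

    Results outside [0, 130] years are dropped rather than clipped — in
    spontaneous-report data an age of 200 "years" is a coding error, not a
    patient.  Unknown units yield ``None`` with a logged warning.
    """
    if age_value is None or (isinstance(age_value, float) and np.isnan(age_value)):
        return None
    if age_value < 0:
        return None
    if isinstance(age_unit, str) and not isinstance(age_unit, AgeUnit):
        unit = AGE_UNIT_CODES.get(age_unit.strip().upper())
        if unit is None:
            logger.warning("unknown age unit %r; treating age as missing", age_unit)
            return None
    else:
        unit = age_unit
    factor = AGE_UNIT_FACTORS.get(unit)
    if factor is None:
        if unit is not AgeUnit.UNKNOWN:
            logger.warning("unknown age unit %r; treating age as missing", age_unit)
        return None
    years = age_value * factor
    if not AGE_MIN_YEARS <= years <= AGE_MAX_YEARS:
        return None
    return years


def map_levels(values: pd.Series | np.ndarray, fn) -> np.ndarray:
    """Apply ``fn`` per *distinct* value and broadcast back (fast for columns
    with few unique levels, e.g. sex codes, age units, drug names)."""
    codes, uniques = pd.factorize(np.asarray(values, dtype=object),
                                  use_na_sentinel=False)
    mapped = np.array([fn(u) for u in uniques], dtype=object)
    return mapped[codes]


def add_age_years(demo: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`normalize_age`: adds an ``age_years`` column."""
    demo = demo.copy()

    codes, uniques = pd.factorize(np.asarray(demo["age_cod"], dtype=object),
                                  use_na_sentinel=False)
    levels = [str(u).strip().upper() for u in uniques]
    units = [AGE_UNIT_CODES.get(lv) for lv in levels]
    factor = np.array([AGE_UNIT_FACTORS[u] if u is not None else np.nan
                       for u in units], dtype=float)[codes]
    bad_levels = np.array([lv != "" and u is None
                           for lv, u in zip(levels, units)])[codes]
    unknown = bad_levels & demo["age"].notna().to_numpy()
    if unknown.any():
        logger.warning("%d rows with unknown age unit; ages treated as missing",
                       int(unknown.sum()))
    years = demo["age"].astype(float).to_numpy() * factor
    years[(years < AGE_MIN_YEARS) | (years > AGE_MAX_YEARS)] = np.nan
    demo["age_years"] = years
    return demo


def normalize_sex(demo: pd.DataFrame) -> pd.DataFrame:
    """Map the raw sex column onto {F, M, UNKNOWN} in place of free text."""
    demo = demo.copy()

    def _norm(v):
        s = str(v).strip().upper()
        return s if s in ("F", "M") else Sex.UNKNOWN.value

    demo["sex"] = map_levels(demo["sex"], _norm)
    return demo


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

def _fda_sort_key(fda_dt: pd.Series) -> pd.Series:
    """8-digit ordering key; partial dates padded with month/day = 01."""
    # fast path: a clean all-8-digit column (the overwhelmingly common case)
    num = pd.to_numeric(fda_dt, errors="coerce")
    if num.notna().all() and ((num >= 10_000_000) & (num < 100_000_000)).all():
        return num.astype(np.int64)
    s = fda_dt.astype(str).str.strip().str.replace(r"\.0$", "", regex=True)
    digits = s.where(s.str.fullmatch(r"\d{4}|\d{6}|\d{8}"), "")
    padded = digits.str.pad(8, side="right", fillchar="0")
    # pad with 01, not 00: "2021" -> 20210101
    padded = padded.where(digits.str.len() != 4, digits + "0101")
    padded = padded.where(digits.str.len() != 6, digits + "01")
    key = pd.to_numeric(padded, errors="coerce")
    return key.fillna(0).astype(np.int64)


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """Keep one report version per case, by the FDA-recommended rule.

    Within each ``caseid`` group the survivor maximizes
    ``(fda_dt, primaryid)`` lexicographically: latest receipt date first,
    highest report-version id to break ties.  Rows with a missing ``caseid``
    cannot be grouped and are retained as singleton cases.  Output is sorted
    by ascending ``primaryid``.
    """
    if demo.empty:
        return demo.copy()
    key = _fda_sort_key(demo["fda_dt"])
    work = demo.assign(_fda_key=key)
    grouped = work[work["caseid"].notna()]
    loners = work[work["caseid"].isna()]
    survivors = (grouped
                 .sort_values(["caseid", "_fda_key", "primaryid"], kind="mergesort")
                 .groupby("caseid", sort=False)
                 .tail(1))
    out = pd.concat([survivors, loners])
    return (out.drop(columns="_fda_key")
               .sort_values("primaryid", kind="mergesort")
               .reset_index(drop=True))


def filter_children(child: pd.DataFrame,
                    surviving_primary_ids: Iterable[int] | pd.Series) -> pd.DataFrame:
    """Drop child rows whose ``primaryid`` is not among the survivors."""
    if isinstance(surviving_primary_ids, pd.Series):
        ids = surviving_primary_ids.dropna().to_numpy(dtype=np.int64)
    else:
        ids = np.asarray([int(i) for i in surviving_primary_ids], dtype=np.int64)
    pids = child["primaryid"].to_numpy(dtype="float64", na_value=np.nan)
    keep = np.isin(pids, ids)
    return child[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Record iteration
# ---------------------------------------------------------------------------

def safety_reports(demo: pd.DataFrame,
                   outc: Optional[pd.DataFrame] = None) -> Iterator[SafetyReport]:
    """Yield dataclass views of a DEMO frame (optionally joining outcomes)."""
    outcome_map: dict[int, set] = {}
    if outc is not None:
        for pid, code in zip(outc["primaryid"], outc["outc_cod"]):
            mapped = OUTCOME_CODES.get(str(code).strip().upper())
            if pd.notna(pid) and mapped is not None:
                outcome_map.setdefault(int(pid), set()).add(mapped)
    for row in demo.itertuples(index=False):
        sex_raw = str(row.sex).strip().upper()
        unit = AGE_UNIT_CODES.get(str(row.age_cod).strip().upper(), AgeUnit.UNKNOWN)
        pid = int(row.primaryid)
        yield SafetyReport(
            primary_id=pid,
            case_id=int(row.caseid) if pd.notna(row.caseid) else pid,
            fda_date=PartialDate.parse(row.fda_dt),
            sex=Sex(sex_raw) if sex_raw in ("F", "M") else Sex.UNKNOWN,
            age_value=None if pd.isna(row.age) else float(row.age),
            age_unit=unit,
            country=str(row.occr_country) or None,
            event_date=PartialDate.parse(row.event_dt),
            outcomes=frozenset(outcome_map.get(pid, ())),
        )
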