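"""Time to onset: days from therapy start to the adverse-event date.

For every exposed case report with a day-resolved event date (``event_dt``)
and at least one day-resolved therapy start (``start_dt``) for the study
drug, the time to onset is ``event − earliest start`` in whole days.
Records with partial dates or negative differences are excluded — never
imputed — and tallied in a QC counter, since a partial FAERS date cannot be
placed on a day and a negative difference means the event preceded the
recorded exposure.

Summaries are the median and interquartile range using linearly
interpolated quantiles (type 7), the convention under which integer day
counts yield fractional summaries such as 14.5 or 3.25.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .cohort import DrugDictionary, normalize_drug_name

__all__ = ["OnsetSummary", "compute_tto", "plot_tto_histogram", "summarize_tto"]


@dataclass
class OnsetSummary:
    drug: str
    n: int
    median_days: float
    iqr_low: float
    iqr_high: float


def _day_resolved(raw: pd.Series) -> pd.Series:
    """Parse 8-digit date strings to datetimes; partial/absent become NaT."""
    s = raw.astype(str).str.strip().str.replace(r"\.0$", "", regex=True)
    s = s.where(s.str.fullmatch(r"\d{8}"), other=pd.NA)
    return pd.to_datetime(s, format="%Y%m%d", errors="coerce")


def compute_tto(demo: pd.DataFrame, ther: pd.DataFrame, drug: pd.DataFrame,
                exposed_case_ids: Iterable[int], atc_code: str,
                dictionary: DrugDictionary,
                drug_label: str = "drug") -> tuple[pd.DataFrame, dict]:
    """Per-report time to onset for one study drug.

    Parameters
    ----------
    demo, ther, drug
        Deduplicated DEMO and filtered THER/DRUG child tables.
    exposed_case_ids
        ``primaryid`` values of reports that are both PS-exposed to the drug
        and cases.
    atc_code, dictionary
        Used to find which DRUG rows (hence which THER rows, via the drug
        sequence number) belong to the study drug.

    Returns
    -------
    (records, qc)
        ``records`` has columns ``primaryid, drug, tto_days``;  ``qc``
        counts ``excluded_partial`` (no day-resolved start or event date)
        and ``excluded_negative``.
    """
    ids = pd.Index(list(exposed_case_ids), name="primaryid")
    atc = drug["drugname"].map(normalize_drug_name).map(dictionary.entries)
    target_rows = drug[atc.eq(atc_code) & drug["primaryid"].isin(ids)]

    ther_key = ther.merge(
        target_rows[["primaryid", "drug_seq"]].drop_duplicates(),
        left_on=["primaryid", "dsg_drug_seq"], right_on=["primaryid", "drug_seq"])
    ther_key = ther_key.assign(start=_day_resolved(ther_key["start_dt"]))
    starts = (ther_key.dropna(subset=["start"])
              .groupby("primaryid", sort=False)["start"].min())

    events = demo.loc[demo["primaryid"].isin(ids),
                      ["primaryid", "event_dt"]].copy()
    events["event"] = _day_resolved(events["event_dt"])
    events = events.set_index("primaryid")["event"]

    joined = pd.DataFrame({"start": starts}).join(events.rename("event"),
                                                  how="outer")
    joined = joined.reindex(ids)
    complete = joined.dropna(subset=["start", "event"])
    excluded_partial = len(joined) - len(complete)

    tto = (complete["event"] - complete["start"]).dt.days.astype(float)
    negative = tto < 0
    records = pd.DataFrame({
        "primaryid": complete.index[~negative],
        "drug": drug_label,
        "tto_days": tto[~negative].to_numpy(),
    }).reset_index(drop=True)
    qc = {"excluded_partial": int(excluded_partial),
          "excluded_negative": int(negative.sum())}
    return records, qc


def summarize_tto(records: pd.DataFrame, drug: str = "drug",
                  method: str = "linear") -> Optional[OnsetSummary]:
    """Median and IQR of onset days; ``None`` for empty input.

    ``method`` is any :func:`numpy.quantile` interpolation; the default
    ("linear", i.e. type 7) matches the fractional-day convention.
    """
    values = np.asarray(records["tto_days"] if isinstance(records, pd.DataFrame)
                        else records, dtype=float)
    if values.size == 0:
        return None
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method=method)
    return OnsetSummary(drug=drug, n=int(values.size), median_days=float(med),
                        iqr_low=float(q1), iqr_high=float(q3))


def plot_tto_histogram(records: pd.DataFrame, path, drug: str = "drug",
                       bins: int = 40) -> None:
    """Write a simple onset-time histogram to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(records["tto_days"], bins=bins, color="#4878a8", edgecolor="white")
    ax.set_xlabel("time to onset (days)")
    ax.set_ylabel("reports")
    ax.set_title(f"Time to onset: {drug}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
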