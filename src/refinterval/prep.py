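"""Cleaning, stratification and distribution-shape summaries of raw tables.

Routine laboratory extracts contain repeat visits (repeat testing is itself
a disease signal, so only each subject's earliest record is kept) and mixed
sexes/ages.  This module deduplicates to first records, stratifies by sex
with an age floor, and computes the moment summaries (median, IQR,
skewness, kurtosis) used to judge how close raw and processed data are to
Gaussian.

Kurtosis here is the **non-excess** convention ``m4 / m2**2`` (3 for a
Gaussian); skewness is the population-moment estimator ``m3 / m2**1.5``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CleanDataset", "MomentSummary", "deduplicate_first", "stratify", "sample_moments"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject_id", "date", "analyte", "value")


@dataclass
class CleanDataset:
    """Deduplicated records plus the number of repeat measurements removed."""

    records: pd.DataFrame
    removed_duplicates: int


@dataclass(frozen=True)
class MomentSummary:
    n: int
    median: float
    q25: float
    q75: float
    skewness: float
    kurtosis: float  # non-excess: 3 for a Gaussian

    @property
    def iqr(self) -> float:
        return self.q75 - self.q25


def deduplicate_first(records: pd.DataFrame) -> CleanDataset:
    """Keep only the earliest-dated row per (subject_id, analyte).

    Ties on the earliest date are broken by input order, so re-runs are
    deterministic.  Unparseable dates raise an error naming the row.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"input table missing required columns: {missing}")
    dates = pd.to_datetime(records["date"], errors="coerce")
    if dates.isna().any():
        bad = records.index[dates.isna()][0]
        raise ValueError(f"unparseable date {records.loc[bad, 'date']!r} at row {bad}")
    df = records.assign(_date=dates)
    first = (df.sort_values("_date", kind="stable")
               .drop_duplicates(["subject_id", "analyte"], keep="first"))
    first = first.sort_index().drop(columns="_date")
    removed = len(records) - len(first)
    return CleanDataset(records=first.reset_index(drop=True), removed_duplicates=removed)


def stratify(dataset, min_age: float = 18) -> dict:
    """Split a clean dataset into per-sex subsets, excluding rows below ``min_age``.

    Rows with missing or unrecognized sex are dropped with a logged warning.
    Returns ``{"male": DataFrame, "female": DataFrame}`` (either may be empty).
    """
    df = dataset.records if isinstance(dataset, CleanDataset) else dataset
    if "sex" not in df.columns or "age" not in df.columns:
        raise ValueError("stratify requires 'sex' and 'age' columns")
    sex = df["sex"].astype("string").str.lower()
    known = sex.isin(["male", "female"])
    n_bad = int((~known).sum())
    if n_bad:
        logger.warning("dropping %d rows with missing or unrecognized sex", n_bad)
    eligible = known & (pd.to_numeric(df["age"], errors="coerce") >= min_age)
    return {s: df[eligible & (sex == s)].reset_index(drop=True) for s in ("male", "female")}


def sample_moments(values) -> MomentSummary:
    """Median, quartiles, skewness and (non-excess) kurtosis of a sample.

    Quartiles use linear interpolation at rank ``p(n-1)+1``.  Requires at
    least 4 non-constant observations (shape is undefined for constants).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < 4:
        raise ValueError(f"need at least 4 observations, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0:
        raise ValueError("constant input: skewness and kurtosis are undefined")
    q25, med, q75 = np.quantile(x, [0.25, 0.5, 0.75])
    return MomentSummary(
        n=int(x.size),
        median=float(med), q25=float(q25), q75=float(q75),
        skewness=float(stats.skew(x, bias=True)),
        kurtosis=float(stats.kurtosis(x, fisher=False, bias=True)),
    )
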