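"""Agreement of indirect reference intervals with a reference-standard RI.

Given an indirect interval (LL_e, UL_e) and a reference-standard interval
(LL_r, UL_r) — typically one established by the direct, screened-cohort
method — each limit is scored by

* the signed relative deviation  ``d% = 100 * (X_e - X_r) / X_r``,
* the signed **bias ratio**  ``BR = (X_e - X_r) / SD_RI``  where
  ``SD_RI = (UL_r - LL_r) / 3.92`` expresses the reference interval's width
  in Gaussian SD units (a central-95% interval spans 3.92 SD).

A limit qualifies when ``|BR| < 0.375``, the conventional allowable-bias
threshold.  Across a matrix of method combinations the module reports
qualification rates per limit, ascending-|BR| top-k rankings with full tie
expansion at the k-th place, and the intersection of the LL and UL top
sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Set, Tuple

import numpy as np
import pandas as pd

from .estimators import ReferenceInterval

__all__ = [
    "BiasAssessment",
    "RankingResult",
    "BR_THRESHOLD",
    "d_percent",
    "sd_ri",
    "bias_ratio",
    "assess",
    "qualification_rate",
    "rank_top_k",
    "top_set_intersection",
]

#: allowable-bias threshold on |BR|
BR_THRESHOLD = 0.375

#: central-95% Gaussian interval width in SD units
_SPAN_95 = 3.92


def _limits(ri) -> Tuple[float, float]:
    if isinstance(ri, ReferenceInterval):
        return ri.lower, ri.upper
    lo, hi = ri
    return float(lo), float(hi)


@dataclass(frozen=True)
class BiasAssessment:
    """Per-limit deviation of one indirect RI from the reference-standard RI."""

    d_pct_ll: float
    d_pct_ul: float
    sd_ri: float
    br_ll: float
    br_ul: float
    threshold: float = BR_THRESHOLD

    @property
    def qualified_ll(self) -> bool:
        return abs(self.br_ll) < self.threshold

    @property
    def qualified_ul(self) -> bool:
        return abs(self.br_ul) < self.threshold


def d_percent(ri_e, ri_r) -> Tuple[float, float]:
    """Signed relative deviations (%) of the indirect limits from the reference limits."""
    ll_e, ul_e = _limits(ri_e)
    ll_r, ul_r = _limits(ri_r)
    if ll_r == 0 or ul_r == 0:
        raise ValueError("reference limits must be nonzero for a relative deviation")
    return (100.0 * (ll_e - ll_r) / ll_r, 100.0 * (ul_e - ul_r) / ul_r)


def sd_ri(ri_r) -> float:
    """Reference-interval SD: width of the reference RI divided by 3.92."""
    ll_r, ul_r = _limits(ri_r)
    width = ul_r - ll_r
    if width <= 0:
        raise ValueError(f"reference interval has non-positive width ({ll_r}, {ul_r})")
    return width / _SPAN_95


def bias_ratio(ri_e, ri_r) -> Tuple[float, float]:
    """Signed bias ratios (limit difference over SD_RI) for LL and UL."""
    ll_e, ul_e = _limits(ri_e)
    ll_r, ul_r = _limits(ri_r)
    s = sd_ri(ri_r)
    return ((ll_e - ll_r) / s, (ul_e - ul_r) / s)


def assess(ri_e, ri_r, threshold: float = BR_THRESHOLD) -> BiasAssessment:
    """Full bias assessment of one indirect RI against the reference RI."""
    d_ll, d_ul = d_percent(ri_e, ri_r)
    br_ll, br_ul = bias_ratio(ri_e, ri_r)
    return BiasAssessment(d_pct_ll=d_ll, d_pct_ul=d_ul, sd_ri=sd_ri(ri_r),
                          br_ll=br_ll, br_ul=br_ul, threshold=threshold)


def qualification_rate(assessments, threshold: float = BR_THRESHOLD) -> Tuple[float, float]:
    """Percentage of combinations with |BR| below threshold, per limit.

    Accepts an iterable of :class:`BiasAssessment` or a matrix DataFrame with
    ``BR_LL``/``BR_UL`` columns; rows from failed estimator cells (NaN BR)
    are excluded from the denominator.
    """
    if isinstance(assessments, pd.DataFrame):
        br_ll = assessments["BR_LL"].to_numpy(dtype=float)
        br_ul = assessments["BR_UL"].to_numpy(dtype=float)
    else:
        items = list(assessments)
        br_ll = np.array([a.br_ll for a in items], dtype=float)
        br_ul = np.array([a.br_ul for a in items], dtype=float)
    ok_ll = np.isfinite(br_ll)
    ok_ul = np.isfinite(br_ul)
    if not ok_ll.any() or not ok_ul.any():
        raise ValueError("no valid assessments")
    rate_ll = 100.0 * (np.abs(br_ll[ok_ll]) < threshold).mean()
    rate_ul = 100.0 * (np.abs(br_ul[ok_ul]) < threshold).mean()
    return float(rate_ll), float(rate_ul)


@dataclass
class RankingResult:
    """Ascending-|BR| ranking of combinations for one limit.

    ``members`` holds every combination whose |BR| is no larger than the
    k-th smallest value (so ties at the k-th place expand the set);
    ``ordered`` lists (label, |BR|) ascending, ties broken by label for
    reproducible output only — membership never depends on input order.
    """

    limit: str
    k: int
    ordered: List[Tuple[str, float]]
    members: Set[str]


def rank_top_k(assessments: pd.DataFrame, k: int = 10, limit: str = "LL",
               label_columns: Iterable[str] = ("transform", "outlier_method", "estimator"),
               ) -> RankingResult:
    """Top-k combinations by ascending |BR| for one limit, with tie expansion.

    ``assessments`` is a matrix DataFrame (as from ``run_matrix`` with a
    reference) carrying ``BR_LL``/``BR_UL``.  If fewer than ``k`` valid rows
    exist, all are returned with a warning.
    """
    col = f"BR_{limit}"
    if col not in assessments.columns:
        raise ValueError(f"no column {col!r} in assessments")
    df = assessments.copy()
    df["_label"] = df[list(label_columns)].astype(str).agg("-".join, axis=1)
    df["_abs"] = df[col].abs()
    df = df[np.isfinite(df["_abs"])]
    if df.empty:
        raise ValueError("no valid assessments to rank")
    df = df.sort_values(["_abs", "_label"], kind="stable")
    if len(df) < k:
        import warnings

        warnings.warn(f"only {len(df)} valid combinations for top-{k} ranking; returning all",
                      stacklevel=2)
        cutoff = df["_abs"].iloc[-1]
    else:
        cutoff = df["_abs"].iloc[k - 1]
    member_rows = df[df["_abs"] <= cutoff]
    return RankingResult(
        limit=limit, k=k,
        ordered=list(zip(df["_label"], df["_abs"])),
        members=set(member_rows["_label"]),
    )


def top_set_intersection(rank_ll: RankingResult, rank_ul: RankingResult) -> Set[str]:
    """Combinations in both the LL and UL (tie-expanded) top sets."""
    return rank_ll.members & rank_ul.members
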