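"""Outlier elimination rules for indirect reference-interval estimation.

Three classical rules are implemented as pure flagging operations:

* **Tukey fences** — flag points beyond ``Q1 - k*IQR`` / ``Q3 + k*IQR``
  (single pass, ``k = 1.5`` by default).
* **Reed–Dixon** — iteratively drop an extreme value whose gap to the
  adjacent order statistic exceeds one third of the current sample range.
* **Iterative mean ± 3 SD** — repeatedly drop points more than ``n_sd``
  sample standard deviations from the mean of the currently retained points,
  until a pass removes nothing.

Each rule returns a positional boolean mask, so flags computed on one scale
(typically the normalized scale) can be applied to the data on any scale.
Quartiles use linear interpolation at rank ``p*(n-1) + 1`` (numpy's default),
the single quantile convention used across the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, OutlierMixin

__all__ = [
    "OutlierReport",
    "TukeyFences",
    "ReedDixon",
    "IterativeMeanSD",
    "tukey_flags",
    "reed_dixon_flags",
    "iterative_mean_3sd_flags",
    "elimination_rate",
    "make_outlier_rule",
]


@dataclass
class OutlierReport:
    """Outcome of one elimination rule on one sample.

    ``mask`` is True where the observation was eliminated.
    """

    method: str
    mask: np.ndarray = field(repr=False)
    iterations: int
    elimination_rate: float

    @property
    def n(self) -> int:
        return int(self.mask.size)

    @property
    def n_eliminated(self) -> int:
        return int(self.mask.sum())

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n": self.n,
            "iterations": self.iterations,
            "elimination_rate": self.elimination_rate,
            "eliminated_indices": np.flatnonzero(self.mask).tolist(),
        }


def _as_values(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise ValueError(f"expected a 1-d array, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    return x


class _BaseRule(OutlierMixin, BaseEstimator):
    """Shared fit/report plumbing; subclasses implement ``_flag``."""

    method: str = ""

    def fit(self, X, y=None):
        x = _as_values(X)
        mask, iterations = self._flag(x)
        if mask.all():
            raise ValueError(f"{self.method}: every observation flagged; degenerate input")
        self.outlier_mask_ = mask
        self.iterations_ = int(iterations)
        self.elimination_rate_ = float(mask.mean())
        self.n_ = int(x.size)
        return self

    def fit_predict(self, X, y=None):
        """sklearn outlier convention: -1 for eliminated points, +1 for retained."""
        self.fit(X)
        return np.where(self.outlier_mask_, -1, 1)

    def predict(self, X=None):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "outlier_mask_")
        return np.where(self.outlier_mask_, -1, 1)

    def report(self) -> OutlierReport:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "outlier_mask_")
        return OutlierReport(
            method=self.method,
            mask=self.outlier_mask_,
            iterations=self.iterations_,
            elimination_rate=self.elimination_rate_,
        )


class TukeyFences(_BaseRule):
    """Single-pass interquartile fences: flag x outside [Q1 - k*IQR, Q3 + k*IQR]."""

    method = "tukey"

    def __init__(self, k: float = 1.5):
        self.k = k

    def _flag(self, x: np.ndarray):
        if x.size < 4:
            raise ValueError(f"tukey: need at least 4 observations, got {x.size}")
        q1, q3 = np.quantile(x, [0.25, 0.75])
        iqr = q3 - q1
        lo, hi = q1 - self.k * iqr, q3 + self.k * iqr
        self.fences_ = (float(lo), float(hi))
        return (x < lo) | (x > hi), 1


class ReedDixon(_BaseRule):
    """Reed's one-third-range rule, iterated to a fixed point.

    At each pass the more extreme of the two endpoint gaps is examined; an
    endpoint is dropped when its gap to the adjacent order statistic exceeds
    one third of the current range.  The range is recomputed after every
    removal.  On continuous unimodal data at large n this rule removes
    nothing, which is exactly its known conservative behaviour.
    """

    method = "reed_dixon"

    def _flag(self, x: np.ndarray):
        if x.size < 3:
            raise ValueError(f"reed_dixon: need at least 3 observations, got {x.size}")
        order = np.argsort(x, kind="stable")
        sorted_vals = x[order]
        lo_i, hi_i = 0, x.size - 1  # window of retained order statistics
        iterations = 0
        while hi_i - lo_i >= 2:
            iterations += 1
            rng = sorted_vals[hi_i] - sorted_vals[lo_i]
            if rng <= 0:
                break
            gap_lo = sorted_vals[lo_i + 1] - sorted_vals[lo_i]
            gap_hi = sorted_vals[hi_i] - sorted_vals[hi_i - 1]
            third = rng / 3.0
            if gap_hi >= gap_lo:
                if gap_hi > third:
                    hi_i -= 1
                    continue
                if gap_lo > third:
                    lo_i += 1
                    continue
            else:
                if gap_lo > third:
                    lo_i += 1
                    continue
                if gap_hi > third:
                    hi_i -= 1
                    continue
            break
        mask = np.zeros(x.size, dtype=bool)
        mask[order[:lo_i]] = True
        mask[order[hi_i + 1:]] = True
        return mask, max(iterations, 1)


class IterativeMeanSD(_BaseRule):
    """Iterated mean ± ``n_sd``·SD truncation (SD with n−1 denominator).

    Strict inequality is used so constant samples are a fixed point.
    """

    method = "iter_mean_3sd"

    def __init__(self, n_sd: float = 3.0, max_iter: int = 100):
        self.n_sd = n_sd
        self.max_iter = max_iter

    def _flag(self, x: np.ndarray):
        if x.size < 3:
            raise ValueError(f"iter_mean_3sd: need at least 3 observations, got {x.size}")
        mask = np.zeros(x.size, dtype=bool)
        iterations = 0
        for _ in range(self.max_iter):
            iterations += 1
            retained = x[~mask]
            if retained.size <= 2:
                raise ValueError("iter_mean_3sd: fewer than 3 observations retained; degenerate input")
            mean = retained.mean()
            sd = retained.std(ddof=1)
            new = (~mask) & (np.abs(x - mean) > self.n_sd * sd)
            if not new.any():
                break
            mask |= new
        return mask, iterations


_RULES = {"tukey": TukeyFences, "reed_dixon": ReedDixon, "iter_mean_3sd": IterativeMeanSD}


def make_outlier_rule(method: str, **kwargs) -> _BaseRule:
    """Instantiate an elimination rule by name."""
    if method not in _RULES:
        raise ValueError(f"unknown outlier method {method!r}; expected one of {sorted(_RULES)}")
    return _RULES[method](**kwargs)


def tukey_flags(values, k: float = 1.5) -> OutlierReport:
    """Flag points beyond the Tukey fences; see :class:`TukeyFences`."""
    return TukeyFences(k=k).fit(values).report()


def reed_dixon_flags(values) -> OutlierReport:
    """Apply the Reed–Dixon one-third-range rule; see :class:`ReedDixon`."""
    return ReedDixon().fit(values).report()


def iterative_mean_3sd_flags(values, max_iter: int = 100) -> OutlierReport:
    """Iterated mean ± 3 SD truncation; see :class:`IterativeMeanSD`."""
    return IterativeMeanSD(max_iter=max_iter).fit(values).report()


def elimination_rate(report: OutlierReport) -> float:
    """Fraction of the input flagged, in [0, 1]."""
    return report.elimination_rate
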