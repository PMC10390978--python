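"""The five indirect reference-interval estimators and the 2x3x5 matrix runner.

An indirect method estimates the central 95% interval of the *healthy*
sub-population from a routine laboratory dataset that may contain diseased
individuals.  Five estimators are provided, each as a scikit-learn style
estimator with ``fit`` and fitted ``lower_`` / ``upper_`` attributes on the
original measurement scale:

* :class:`ParametricRI` — mean ± 1.96 SD on the normalized scale, limits
  back-transformed.
* :class:`NonparametricRI` — 2.5th/97.5th percentiles at ranks
  ``0.025(n+1)`` / ``0.975(n+1)`` (CLSI convention) of the raw values.
* :class:`HoffmannRI` — ordinary least squares through the central linear
  segment of the normal quantile (Q-Q) plot, extrapolated to z = ±1.96.
* :class:`BhattacharyaRI` — Gaussian-component decomposition from the
  linearity of successive log bin-count differences of the histogram.
* :class:`KosmicRI` — truncated power-normal fit minimizing the
  Kolmogorov-Smirnov distance between model and data on a truncation
  interval chosen by grid search; robust to one-sided pathological
  contamination.

:func:`run_combo` wires one (transform, outlier rule, estimator) cell the
way the comparative design prescribes: the transform is fitted on the full
stratum, outlier flags are computed on the *transformed* values, the
parametric/Hoffmann/Bhattacharya estimators then consume the retained
transformed values (back-transforming their limits), while the
nonparametric and kosmic estimators consume the retained original-scale
values.  :func:`run_matrix` evaluates all 2 transforms x 3 outlier rules x
5 estimators = 30 cells with per-cell error isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.special import ndtr, ndtri
from sklearn.base import BaseEstimator

from .outliers import make_outlier_rule
from .transforms import BoxCoxTransform, _golden_section_max, make_transform

__all__ = [
    "ReferenceInterval",
    "ComboResult",
    "ParametricRI",
    "NonparametricRI",
    "HoffmannRI",
    "BhattacharyaRI",
    "KosmicRI",
    "ri_parametric",
    "ri_nonparametric",
    "ri_hoffmann",
    "ri_bhattacharya",
    "ri_kosmic",
    "run_combo",
    "run_matrix",
    "TRANSFORM_KINDS",
    "OUTLIER_METHODS",
    "ESTIMATOR_NAMES",
]

TRANSFORM_KINDS = ("log", "boxcox")
OUTLIER_METHODS = ("reed_dixon", "tukey", "iter_mean_3sd")
ESTIMATOR_NAMES = ("parametric", "nonparametric", "hoffmann", "bhattacharya", "kosmic")

#: central-95% z multiplier used throughout (the conventional rounded value)
Z_95 = 1.96


@dataclass(frozen=True)
class ReferenceInterval:
    """A (lower, upper) reference-limit pair on the original measurement scale."""

    lower: float
    upper: float
    estimator: str = ""
    n_used: int = 0

    def __post_init__(self):
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError(f"non-finite reference limits ({self.lower}, {self.upper})")
        if not self.lower < self.upper:
            raise ValueError(f"lower limit {self.lower} must be below upper limit {self.upper}")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def as_tuple(self) -> tuple:
        return (self.lower, self.upper)


def _values_1d(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise ValueError(f"expected a 1-d array of values, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    return x


class _BaseRIEstimator(BaseEstimator):
    """Shared surface: fit -> lower_, upper_, n_used_; interval_ property."""

    name: str = ""

    @property
    def interval_(self) -> ReferenceInterval:
        return ReferenceInterval(self.lower_, self.upper_, estimator=self.name, n_used=self.n_used_)

    def _finish(self, lower: float, upper: float, n_used: int):
        self.lower_ = float(lower)
        self.upper_ = float(upper)
        self.n_used_ = int(n_used)
        if not self.lower_ < self.upper_:
            raise ValueError(f"{self.name}: degenerate interval ({self.lower_}, {self.upper_})")
        return self


def _back(transform, lo: float, hi: float) -> tuple:
    if transform is None:
        return float(lo), float(hi)
    out = transform.inverse_transform(np.array([lo, hi]))
    return float(out[0]), float(out[1])


class ParametricRI(_BaseRIEstimator):
    """Gaussian mean ± z·SD on the normalized scale, limits back-transformed.

    Parameters
    ----------
    transform : fitted transform or None
        Used only to map the limits back to the measurement scale;
        ``None`` means the data are already on the reporting scale.
    z : float
        Central-interval multiplier (1.96 for a 95% interval).
    min_n : int
        Minimum retained sample size.
    """

    name = "parametric"

    def __init__(self, transform=None, z: float = Z_95, min_n: int = 20):
        self.transform = transform
        self.z = z
        self.min_n = min_n

    def fit(self, X, y=None):
        x = _values_1d(X)
        if x.size < self.min_n:
            raise ValueError(f"parametric: need at least {self.min_n} observations, got {x.size}")
        sd = x.std(ddof=1)
        if sd <= 0:
            raise ValueError("parametric: zero standard deviation")
        m = x.mean()
        lo, hi = _back(self.transform, m - self.z * sd, m + self.z * sd)
        return self._finish(lo, hi, x.size)


class NonparametricRI(_BaseRIEstimator):
    """CLSI nonparametric percentile interval on the original scale.

    Limits are read at ranks ``0.025(n+1)`` and ``0.975(n+1)`` with linear
    interpolation between adjacent order statistics, clamped to the sample
    minimum/maximum.  The CLSI minimum of 120 observations for a 95%
    interval is enforced by default and is configurable.
    """

    name = "nonparametric"

    def __init__(self, min_n: int = 120, coverage: float = 0.95):
        self.min_n = min_n
        self.coverage = coverage

    def fit(self, X, y=None):
        x = _values_1d(X)
        if x.size < max(self.min_n, 2):
            raise ValueError(
                f"nonparametric: need at least {self.min_n} observations "
                f"(CLSI minimum for a 95% interval), got {x.size}"
            )
        s = np.sort(x)
        n = s.size
        alpha = (1.0 - self.coverage) / 2.0
        lo = self._at_rank(s, alpha * (n + 1))
        hi = self._at_rank(s, (1.0 - alpha) * (n + 1))
        return self._finish(lo, hi, n)

    @staticmethod
    def _at_rank(s: np.ndarray, r: float) -> float:
        # 1-based rank, linear interpolation, clamped to [x(1), x(n)]
        n = s.size
        r = min(max(r, 1.0), float(n))
        i = int(np.floor(r))
        frac = r - i
        if i >= n:
            return float(s[-1])
        return float(s[i - 1] + frac * (s[i] - s[i - 1]))


class HoffmannRI(_BaseRIEstimator):
    """Normal quantile (Q-Q) plot line fit extrapolated to z = ±1.96.

    Sorted values are plotted against standard-normal quantiles of the Hazen
    plotting positions ``(i - 0.5)/n``.  An OLS line is fitted through the
    points whose plotting position lies in ``window`` (the central 25th-75th
    percentile band by default, replacing the traditional visual segment
    selection) and evaluated at z = ±1.96; the limits are back-transformed.
    """

    name = "hoffmann"

    def __init__(self, transform=None, window: tuple = (0.25, 0.75), z: float = Z_95):
        self.transform = transform
        self.window = window
        self.z = z

    def fit(self, X, y=None):
        x = np.sort(_values_1d(X))
        n = x.size
        p = (np.arange(1, n + 1) - 0.5) / n
        w0, w1 = self.window
        sel = (p >= w0) & (p <= w1)
        if sel.sum() < 3:
            raise ValueError(
                f"hoffmann: window {self.window} holds {int(sel.sum())} points; need at least 3"
            )
        zq = ndtri(p[sel])
        slope, intercept = np.polyfit(zq, x[sel], 1)
        if slope <= 0:
            raise ValueError(f"hoffmann: non-positive fitted slope {slope:.4g}")
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.n_window_ = int(sel.sum())
        lo, hi = _back(self.transform, intercept - self.z * slope, intercept + self.z * slope)
        return self._finish(lo, hi, n)


def _round_1sig(x: float) -> float:
    if x <= 0:
        raise ValueError("bin width must be positive")
    exp = np.floor(np.log10(x))
    return float(round(x / 10 ** exp) * 10 ** exp)


def _ols(x: np.ndarray, y: np.ndarray, w: Optional[np.ndarray] = None):
    """Weighted OLS line fit returning (slope, intercept, r_squared)."""
    if w is None:
        w = np.ones_like(x)
    wsum = w.sum()
    xm = (w * x).sum() / wsum
    ym = (w * y).sum() / wsum
    sxx = (w * (x - xm) ** 2).sum()
    sxy = (w * (x - xm) * (y - ym)).sum()
    if sxx == 0:
        raise ValueError("degenerate abscissa in OLS")
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    sst = (w * (y - ym) ** 2).sum()
    r2 = 1.0 - (w * resid ** 2).sum() / sst if sst > 0 else 0.0
    return float(slope), float(intercept), float(r2)


class BhattacharyaRI(_BaseRIEstimator):
    """Gaussian decomposition from log differences of histogram bin counts.

    For a histogram of bin width ``h`` with counts ``f_i`` at midpoints
    ``m_i``, a pure Gaussian component makes ``y_i = ln f_{i+1} - ln f_i``
    exactly linear in ``m_i`` with slope ``b = -h/sigma**2``; the line's
    x-intercept ``x0`` satisfies ``mu = x0 + h/2``.  An OLS line through a
    selected segment of log-difference points therefore yields the dominant
    component's mean and SD, and the reference interval is
    ``mu ± 1.96 sigma`` back-transformed.

    Segment selection is automatic by default: among contiguous runs of
    valid log-difference points (both counts positive), the window of
    length >= 4 (>= 3 as a fallback) with negative slope maximizing
    ``R^2 * length`` is chosen.  A manual ``segment=(start_bin, end_bin)``
    mirrors the traditional by-eye workflow and takes precedence.
    """

    name = "bhattacharya"

    def __init__(self, transform=None, bin_width: Optional[float] = None,
                 segment: Optional[tuple] = None, weighted: bool = False,
                 z: float = Z_95, min_count: int = 1):
        self.transform = transform
        self.bin_width = bin_width
        self.segment = segment
        self.weighted = weighted
        self.z = z
        self.min_count = min_count

    def fit(self, X, y=None):
        x = _values_1d(X)
        if x.size < 30:
            raise ValueError(f"bhattacharya: need at least 30 observations, got {x.size}")
        h = self.bin_width
        if h is None:
            q1, q3 = np.quantile(x, [0.25, 0.75])
            fd = 2.0 * (q3 - q1) * x.size ** (-1.0 / 3.0)
            if fd <= 0:
                raise ValueError("bhattacharya: zero interquartile range")
            h = _round_1sig(fd)
        lo_edge = np.floor(x.min() / h) * h
        edges = np.arange(lo_edge, x.max() + h, h)
        if edges[-1] <= x.max():
            edges = np.append(edges, edges[-1] + h)
        counts, _ = np.histogram(x, bins=edges)
        mids = 0.5 * (edges[:-1] + edges[1:])
        mu, sigma, diag = bhattacharya_from_counts(
            mids, counts, h, segment=self.segment,
            weighted=self.weighted, min_count=self.min_count,
        )
        self.bin_width_ = float(h)
        self.bin_edges_ = edges
        self.counts_ = counts
        self.mu_, self.sigma_ = float(mu), float(sigma)
        self.slope_, self.intercept_ = diag["slope"], diag["intercept"]
        self.segment_ = diag["segment"]
        self.r_squared_ = diag["r_squared"]
        lo, hi = _back(self.transform, mu - self.z * sigma, mu + self.z * sigma)
        return self._finish(lo, hi, x.size)


def bhattacharya_from_counts(midpoints, counts, bin_width: float,
                             segment: Optional[tuple] = None,
                             weighted: bool = False, min_count: int = 1):
    """Core log-difference regression on histogram counts.

    Returns ``(mu, sigma, diagnostics)`` where diagnostics carries the OLS
    slope/intercept, the chosen ``(start_bin, end_bin)`` segment (inclusive
    bin indices) and the segment R^2.  ``segment`` indexes *bins*; the
    regression uses log-difference points ``y_i`` for bins ``start..end-1``.
    """
    m = np.asarray(midpoints, dtype=float)
    f = np.asarray(counts, dtype=float)
    h = float(bin_width)
    if m.size != f.size:
        raise ValueError("midpoints and counts must have equal length")
    if m.size < 4:
        raise ValueError("bhattacharya: need at least 4 bins")
    valid = (f[:-1] >= max(min_count, 1)) & (f[1:] >= max(min_count, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.log(f[1:]) - np.log(f[:-1])

    def fit_window(i0, i1):  # y indices i0..i1 inclusive
        idx = np.arange(i0, i1 + 1)
        w = 1.0 / (1.0 / f[idx] + 1.0 / f[idx + 1]) if weighted else None
        return _ols(m[idx], y[idx], w)

    if segment is not None:
        start, end = segment
        # bins start..end inclusive give log-difference points start..end-1
        if end - start < 3:
            raise ValueError("bhattacharya: segment must cover at least 3 points")
        if start < 0 or end >= m.size:
            raise ValueError(f"bhattacharya: segment {segment} outside bin range [0, {m.size - 1}]")
        if not valid[start:end].all():
            raise ValueError("bhattacharya: segment includes empty bins")
        slope, intercept, r2 = fit_window(start, end - 1)
        chosen = (int(start), int(end))
    else:
        slope = intercept = r2 = None
        chosen = None
        best = -np.inf
        for min_len in (4, 3):  # prefer windows of >= 4 log-difference points
            for i0, i1 in _windows(valid, min_len):
                s, a, rr = fit_window(i0, i1)
                if s >= 0:
                    continue
                score = rr * (i1 - i0 + 1)
                if score > best:
                    best, slope, intercept, r2 = score, s, a, rr
                    chosen = (int(i0), int(i1 + 1))
            if chosen is not None:
                break
        if chosen is None:
            raise ValueError("bhattacharya: no segment with negative slope found")
    if slope >= 0:
        raise ValueError(f"bhattacharya: non-negative slope {slope:.4g}; no Gaussian component resolved")
    sigma = float(np.sqrt(-h / slope))
    x0 = -intercept / slope
    mu = float(x0 + h / 2.0)
    return mu, sigma, {"slope": slope, "intercept": intercept,
                       "segment": chosen, "r_squared": r2}


def _windows(valid: np.ndarray, min_len: int):
    """All (i0, i1) index windows of >= min_len consecutive valid points."""
    n = valid.size
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and valid[j + 1]:
            j += 1
        run_len = j - i + 1
        if run_len >= min_len:
            for a in range(i, j - min_len + 2):
                for b in range(a + min_len - 1, j + 1):
                    yield a, b
        i = j + 1


class KosmicRI(_BaseRIEstimator):
    """Truncated power-normal fit by Kolmogorov-Smirnov distance minimization.

    The healthy component is modeled as Gaussian after a Box-Cox transform.
    A grid of truncation-quantile pairs (lower in ``lower_range``, upper in
    ``upper_range``, spacing ``step``) is searched; for each candidate
    interval a Gaussian is fitted to the transformed data inside it by
    truncated-normal maximum likelihood, and the candidate is scored by the
    KS distance between the truncated model CDF and the conditional
    empirical CDF on the interval, divided by the fraction of the data the
    interval holds (narrow intervals can always be fitted closely, so the
    raw distance alone would reward them; the normalization prefers the
    widest interval the model still explains).  The best fit's
    ``mu ± 1.96 sigma`` is back-transformed through the Box-Cox exponent,
    which is estimated once on the central 80% of the data and held fixed
    during the search.
    """

    name = "kosmic"

    def __init__(self, lower_range: tuple = (0.05, 0.30), upper_range: tuple = (0.70, 0.95),
                 step: float = 0.01, lmbda: Optional[float] = None, z: float = Z_95,
                 min_points: int = 50, min_n_warn: int = 1000):
        self.lower_range = lower_range
        self.upper_range = upper_range
        self.step = step
        self.lmbda = lmbda
        self.z = z
        self.min_points = min_points
        self.min_n_warn = min_n_warn

    def fit(self, X, y=None):
        x = _values_1d(X)
        if np.any(x <= 0):
            raise ValueError("kosmic: values must be strictly positive")
        if np.ptp(x) == 0:
            raise ValueError("kosmic: constant input")
        n = x.size
        if n < self.min_n_warn:
            warnings.warn(
                f"kosmic: n={n} below the recommended minimum of {self.min_n_warn}; "
                "truncation search may be unstable", stacklevel=2)
        if self.lmbda is not None:
            lam = float(self.lmbda)
        else:
            q10, q90 = np.quantile(x, [0.10, 0.90])
            central = x[(x >= q10) & (x <= q90)]
            from scipy.stats import boxcox_llf
            lam = _golden_section_max(lambda l: boxcox_llf(l, central), -3.0, 3.0, 1e-3)
        t = np.sort(special.boxcox(x, lam))
        csum = np.concatenate(([0.0], np.cumsum(t)))
        csum2 = np.concatenate(([0.0], np.cumsum(t * t)))

        lo_qs = np.arange(self.lower_range[0], self.lower_range[1] + 1e-9, self.step)
        hi_qs = np.arange(self.upper_range[0], self.upper_range[1] + 1e-9, self.step)
        lo_ts = np.quantile(t, lo_qs)
        hi_ts = np.quantile(t, hi_qs)

        best = None
        for t1 in lo_ts:
            i = int(np.searchsorted(t, t1, side="left"))
            for t2 in hi_ts:
                j = int(np.searchsorted(t, t2, side="right"))
                m = j - i
                if m < self.min_points:
                    continue
                mu, sigma = _truncnorm_mle(t1, t2, m, csum[j] - csum[i], csum2[j] - csum2[i])
                if not np.isfinite(sigma) or sigma <= 0:
                    continue
                d = _ks_distance(t[i:j], t1, t2, mu, sigma)
                score = d / (m / n)
                if best is None or score < best[0]:
                    best = (score, d, mu, sigma, t1, t2, m)
        if best is None:
            raise ValueError(
                f"kosmic: no truncation interval held at least {self.min_points} points")
        score, d, mu, sigma, t1, t2, m = best
        self.lambda_ = float(lam)
        self.mu_, self.sigma_ = float(mu), float(sigma)
        self.truncation_ = (float(t1), float(t2))
        self.ks_distance_ = float(d)
        self.n_truncated_ = int(m)
        inv = BoxCoxTransform(lmbda=lam)
        lo, hi = _back(inv, mu - self.z * sigma, mu + self.z * sigma)
        return self._finish(lo, hi, n)


def _truncnorm_mle(t1: float, t2: float, n: int, s1: float, s2: float):
    """Truncated-normal ML fit from sufficient statistics (n, sum, sum of squares).

    The truncated-normal log-likelihood depends on the data only through
    these statistics, so each candidate interval is fitted cheaply.
    """
    mean = s1 / n
    var = max(s2 / n - mean * mean, 1e-30)
    sd = np.sqrt(var)

    def nll(theta):
        mu, log_sd = theta
        sigma = np.exp(log_sd)
        mass = ndtr((t2 - mu) / sigma) - ndtr((t1 - mu) / sigma)
        if mass <= 1e-300:
            return 1e308
        return (n * np.log(sigma) + (s2 - 2 * mu * s1 + n * mu * mu) / (2 * sigma * sigma)
                + n * np.log(mass))

    # truncation deflates the raw moments; start slightly inflated
    res = optimize.minimize(nll, x0=np.array([mean, np.log(sd * 1.3)]),
                            method="Nelder-Mead",
                            options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 400})
    mu, log_sd = res.x
    return float(mu), float(np.exp(log_sd))


def _ks_distance(pts: np.ndarray, t1: float, t2: float, mu: float, sigma: float) -> float:
    """Sup distance between the truncated model CDF and the empirical CDF on [t1, t2]."""
    m = pts.size
    lo = ndtr((t1 - mu) / sigma)
    mass = ndtr((t2 - mu) / sigma) - lo
    if mass <= 0:
        return 1.0
    model = (ndtr((pts - mu) / sigma) - lo) / mass
    steps = np.arange(1, m + 1) / m
    return float(max(np.max(np.abs(model - steps)),
                     np.max(np.abs(model - (steps - 1.0 / m)))))


# ---------------------------------------------------------------------------
# thin functional wrappers


def ri_parametric(transformed_values, model=None, z: float = Z_95) -> ReferenceInterval:
    return ParametricRI(transform=model, z=z).fit(transformed_values).interval_


def ri_nonparametric(values, min_n: int = 120) -> ReferenceInterval:
    return NonparametricRI(min_n=min_n).fit(values).interval_


def ri_hoffmann(transformed_values, model=None, window: tuple = (0.25, 0.75)) -> ReferenceInterval:
    return HoffmannRI(transform=model, window=window).fit(transformed_values).interval_


def ri_bhattacharya(transformed_values, model=None, bin_width=None, segment=None) -> ReferenceInterval:
    return BhattacharyaRI(transform=model, bin_width=bin_width,
                          segment=segment).fit(transformed_values).interval_


def ri_kosmic(values, **settings) -> ReferenceInterval:
    return KosmicRI(**settings).fit(values).interval_


# ---------------------------------------------------------------------------
# combination runner

#: estimators that consume the retained transformed values and back-transform
_TRANSFORMED_SCALE = {"parametric", "hoffmann", "bhattacharya"}


@dataclass
class ComboResult:
    """One cell of the transform x outlier-rule x estimator matrix."""

    transform: str
    outlier_method: str
    estimator: str
    interval: Optional[ReferenceInterval]
    n_used: int
    elimination_rate: float
    status: str = "ok"
    error: str = ""

    @property
    def label(self) -> str:
        return f"{self.transform}-{self.outlier_method}-{self.estimator}"


def run_combo(values, transform: str, outlier_method: str, estimator: str,
              estimator_kwargs: Optional[dict] = None) -> ComboResult:
    """Run one (transform, outlier rule, estimator) combination.

    The transform is fitted on the full sample; outlier flags are computed
    on the transformed values; the estimator then consumes either the
    retained transformed values (parametric, Hoffmann, Bhattacharya, which
    back-transform their limits) or the retained original-scale values
    (nonparametric, kosmic).
    """
    x = _values_1d(values)
    if estimator not in ESTIMATOR_NAMES:
        raise ValueError(f"unknown estimator {estimator!r}; expected one of {ESTIMATOR_NAMES}")
    kwargs = dict(estimator_kwargs or {})
    try:
        tr = make_transform(transform).fit(x)
    except Exception as exc:
        raise ValueError(f"transform stage ({transform}): {exc}") from exc
    try:
        tx = tr.transform(x)
        rule = make_outlier_rule(outlier_method).fit(tx)
    except Exception as exc:
        raise ValueError(f"outlier stage ({outlier_method}): {exc}") from exc
    keep = ~rule.outlier_mask_
    try:
        if estimator == "parametric":
            est = ParametricRI(transform=tr, **kwargs).fit(tx[keep])
        elif estimator == "hoffmann":
            est = HoffmannRI(transform=tr, **kwargs).fit(tx[keep])
        elif estimator == "bhattacharya":
            est = BhattacharyaRI(transform=tr, **kwargs).fit(tx[keep])
        elif estimator == "nonparametric":
            est = NonparametricRI(**kwargs).fit(x[keep])
        else:
            est = KosmicRI(**kwargs).fit(x[keep])
    except Exception as exc:
        raise ValueError(f"estimator stage ({estimator}): {exc}") from exc
    return ComboResult(
        transform=transform, outlier_method=outlier_method, estimator=estimator,
        interval=est.interval_, n_used=int(keep.sum()),
        elimination_rate=rule.elimination_rate_,
    )


def run_matrix(values, analyte: str = "", sex: str = "",
               reference: Optional[ReferenceInterval] = None,
               transforms: Sequence[str] = TRANSFORM_KINDS,
               outlier_methods: Sequence[str] = OUTLIER_METHODS,
               estimators: Sequence[str] = ESTIMATOR_NAMES,
               estimator_kwargs: Optional[dict] = None) -> pd.DataFrame:
    """Evaluate every (transform, outlier rule, estimator) cell on one stratum.

    Returns a DataFrame with one row per combination (30 with the default
    grids).  Estimator failures are recorded per cell in ``status`` rather
    than aborting the matrix.  When ``reference`` is given, each successful
    cell is joined to its bias assessment (d%, bias ratios, qualification
    flags at the |BR| < 0.375 allowable-bias threshold).
    """
    from .evaluation import assess  # local import to avoid a cycle

    x = _values_1d(values)
    per_est_kwargs = estimator_kwargs or {}
    rows = []
    for tkind in transforms:
        for om in outlier_methods:
            for est in estimators:
                row = {"analyte": analyte, "sex": sex, "transform": tkind,
                       "outlier_method": om, "estimator": est}
                try:
                    combo = run_combo(x, tkind, om, est,
                                      estimator_kwargs=per_est_kwargs.get(est))
                    row.update(LL=combo.interval.lower, UL=combo.interval.upper,
                               n_used=combo.n_used,
                               elimination_rate=combo.elimination_rate, status="ok")
                    if reference is not None:
                        a = assess(combo.interval, reference)
                        row.update(d_pct_LL=a.d_pct_ll, d_pct_UL=a.d_pct_ul,
                                   SD_RI=a.sd_ri, BR_LL=a.br_ll, BR_UL=a.br_ul,
                                   qualified_LL=a.qualified_ll, qualified_UL=a.qualified_ul)
                except (ValueError, RuntimeError) as exc:
                    row.update(LL=np.nan, UL=np.nan, n_used=0,
                               elimination_rate=np.nan, status=f"failed: {exc}")
                rows.append(row)
    return pd.DataFrame(rows)
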