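"""Normalization transforms for skewed laboratory data.

Indirect reference-interval estimators that assume Gaussian data (parametric,
Hoffmann, Bhattacharya) operate on a normalized scale; reference limits
computed there must be mapped back exactly to the measurement scale.  This
module provides the two normalizations used throughout the package — the
natural logarithm and the one-parameter Box-Cox power transform — as
scikit-learn style transformers with exact inverses, plus an identity
transform for raw-scale analyses.

The Box-Cox transform is ``(x**lmbda - 1) / lmbda`` for ``lmbda != 0`` and
``ln(x)`` at ``lmbda = 0`` (the continuous limit).  When ``lmbda`` is not
supplied it is fitted by maximizing the profile log-likelihood over
``[-3, 3]`` with a golden-section search.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy import special
from scipy.stats import boxcox_llf
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "LogTransform",
    "BoxCoxTransform",
    "IdentityTransform",
    "fit_boxcox",
    "apply_transform",
    "inverse_transform",
    "make_transform",
    "transform_from_dict",
]

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def _as_1d(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise ValueError(f"expected a 1-d array of measurements, got shape {x.shape}")
    return x


def _check_positive(x: np.ndarray) -> np.ndarray:
    if x.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(x)):
        bad = int(np.flatnonzero(~np.isfinite(x))[0])
        raise ValueError(f"non-finite value at row {bad}")
    if np.any(x <= 0):
        bad = int(np.flatnonzero(x <= 0)[0])
        raise ValueError(
            f"non-positive value {x[bad]!r} at row {bad}: transforms require strictly positive data"
        )
    return x


def _golden_section_max(f, lo: float, hi: float, tol: float = 1e-4) -> float:
    """Maximize a unimodal scalar function on [lo, hi] by golden-section search."""
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


class _ScaleTransform(TransformerMixin, BaseEstimator):
    """Common plumbing: 1-d validation, serialization, order preservation."""

    kind: str = ""

    def fit(self, X, y=None):
        _check_positive(_as_1d(X))
        return self

    def to_dict(self) -> dict:
        return {"kind": self.kind}

    # sklearn tag: we transform 1-d value arrays, not feature matrices
    def _more_tags(self):  # pragma: no cover - sklearn internals
        return {"X_types": ["1darray"]}


class LogTransform(_ScaleTransform):
    """Natural-log normalization; inverse is ``exp``."""

    kind = "log"

    def transform(self, X):
        return np.log(_check_positive(_as_1d(X)))

    def inverse_transform(self, Y):
        return np.exp(np.asarray(Y, dtype=float))


class IdentityTransform(_ScaleTransform):
    """No-op transform (raw measurement scale)."""

    kind = "identity"

    def fit(self, X, y=None):
        _as_1d(X)
        return self

    def transform(self, X):
        return np.array(_as_1d(X), copy=True)

    def inverse_transform(self, Y):
        return np.asarray(Y, dtype=float)


class BoxCoxTransform(_ScaleTransform):
    """One-parameter Box-Cox power transform.

    Parameters
    ----------
    lmbda : float or None
        Exponent λ.  ``None`` (default) fits λ by maximum profile likelihood
        over ``search_range`` when :meth:`fit` is called.
    search_range : tuple of float
        Bounds of the golden-section λ search.
    tol : float
        Absolute tolerance of the λ search.

    Attributes
    ----------
    lambda_ : float
        The exponent in use after :meth:`fit`.
    loglik_ : float or None
        Profile log-likelihood at ``lambda_`` (None when λ was user-supplied).
    """

    kind = "boxcox"

    def __init__(self, lmbda: Optional[float] = None,
                 search_range: tuple = (-3.0, 3.0), tol: float = 1e-4):
        self.lmbda = lmbda
        self.search_range = search_range
        self.tol = tol

    def fit(self, X, y=None):
        x = _check_positive(_as_1d(X))
        if self.lmbda is not None:
            self.lambda_ = float(self.lmbda)
            self.loglik_ = None
            return self
        if x.size < 20:
            raise ValueError(f"need at least 20 observations to fit lambda, got {x.size}")
        if np.ptp(x) == 0:
            raise ValueError("constant input: lambda is not identifiable")
        lo, hi = self.search_range
        lam = _golden_section_max(lambda l: boxcox_llf(l, x), lo, hi, self.tol)
        self.lambda_ = float(lam)
        self.loglik_ = float(boxcox_llf(lam, x))
        return self

    def _lam(self) -> float:
        if not hasattr(self, "lambda_"):
            if self.lmbda is None:
                raise ValueError("BoxCoxTransform is not fitted; call fit() first")
            self.lambda_ = float(self.lmbda)
            self.loglik_ = None
        return self.lambda_

    def transform(self, X):
        x = _check_positive(_as_1d(X))
        return special.boxcox(x, self._lam())

    def inverse_transform(self, Y):
        y = np.asarray(Y, dtype=float)
        lam = self._lam()
        # range of the forward map: lam*y + 1 > 0
        if lam > 0 and np.any(y <= -1.0 / lam):
            raise ValueError(f"inverse Box-Cox undefined: y must exceed {-1.0 / lam:.6g} for lambda={lam:.4g}")
        if lam < 0 and np.any(y >= -1.0 / lam):
            raise ValueError(f"inverse Box-Cox undefined: y must be below {-1.0 / lam:.6g} for lambda={lam:.4g}")
        return special.inv_boxcox(y, lam)

    def to_dict(self) -> dict:
        return {"kind": "boxcox", "lambda": self._lam()}


def make_transform(kind: str, **kwargs) -> _ScaleTransform:
    """Instantiate a transform by name (``log``, ``boxcox`` or ``identity``)."""
    table = {"log": LogTransform, "boxcox": BoxCoxTransform, "identity": IdentityTransform}
    if kind not in table:
        raise ValueError(f"unknown transform kind {kind!r}; expected one of {sorted(table)}")
    return table[kind](**kwargs)


def transform_from_dict(d: dict) -> _ScaleTransform:
    """Rebuild a fitted transform from its :meth:`to_dict` serialization."""
    kind = d.get("kind")
    if kind == "boxcox":
        t = BoxCoxTransform(lmbda=d["lambda"])
        t.lambda_ = float(d["lambda"])
        t.loglik_ = None
        return t
    return make_transform(kind)


def fit_boxcox(values) -> BoxCoxTransform:
    """Fit a Box-Cox transform (λ by profile maximum likelihood) to positive data."""
    return BoxCoxTransform().fit(values)


def apply_transform(model: _ScaleTransform, values) -> np.ndarray:
    """Apply a (fitted) transform's forward map."""
    return model.transform(values)


def inverse_transform(model: _ScaleTransform, y) -> np.ndarray:
    """Map transformed-scale values (e.g. reference limits) back to the measurement scale."""
    return model.inverse_transform(y)
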