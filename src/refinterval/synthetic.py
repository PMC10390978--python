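"""Synthetic laboratory datasets with known healthy-population quantiles.

Real hospital CBC databases mix a dominant healthy sub-population with
smaller pathological fractions and repeat visits.  This module generates
datasets with exactly that structure and, crucially, analytic ground-truth
reference limits, so estimator accuracy can be measured directly:

* the healthy component is **power-normal**: a Gaussian ``N(mu_h, sigma_h)``
  on the Box-Cox(lambda_h) scale, back-transformed to the measurement scale
  (``lambda_h = 0`` gives a lognormal) — the same family the kosmic
  estimator assumes, which makes every estimator's target quantile
  closed-form;
* pathological components are Gaussians on the original scale, displaced
  from the healthy centre by a stated number of healthy original-scale SDs
  (cleanly separable contamination);
* duplicate visits are fresh draws for the same subject with a later date,
  exercising first-record deduplication.

Presets for the eight CBC analytes (WBC, RBC, HGB, HCT, MCV, MCH, MCHC,
PLT) by sex are calibrated by moment-matching the median and IQR of typical
adult physical-examination populations on the transformed scale.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml
from scipy import special

from .estimators import ReferenceInterval, Z_95

__all__ = [
    "HealthyComponent",
    "PathologicalComponent",
    "SyntheticSpec",
    "make_preset",
    "simulate_dataset",
    "true_reference_limits",
    "ANALYTES",
    "SEXES",
]

ANALYTES = ("WBC", "RBC", "HGB", "HCT", "MCV", "MCH", "MCHC", "PLT")
SEXES = ("male", "female")

_NORM_Q3 = 0.6744897501960817  # standard-normal 75th percentile


@dataclass(frozen=True)
class HealthyComponent:
    """Power-normal healthy population: N(mu_h, sigma_h) on the Box-Cox(lambda_h) scale."""

    lambda_h: float
    mu_h: float
    sigma_h: float

    def __post_init__(self):
        if self.sigma_h <= 0:
            raise ValueError(f"sigma_h must be positive, got {self.sigma_h}")
        # back-transformed 2.5th/97.5th quantiles must exist
        for z in (-Z_95, Z_95):
            y = self.mu_h + z * self.sigma_h
            if self.lambda_h > 0 and y <= -1.0 / self.lambda_h:
                raise ValueError("healthy component's lower quantile falls outside the "
                                 "inverse Box-Cox domain; reduce sigma_h or lambda_h")
            if self.lambda_h < 0 and y >= -1.0 / self.lambda_h:
                raise ValueError("healthy component's upper quantile falls outside the "
                                 "inverse Box-Cox domain")

    @classmethod
    def from_median_iqr(cls, median: float, q25: float, q75: float,
                        lambda_h: float) -> "HealthyComponent":
        """Moment-match a power-normal to a target median and quartiles."""
        g = lambda v: float(special.boxcox(v, lambda_h))
        mu = g(median)
        sigma = (g(q75) - g(q25)) / (2.0 * _NORM_Q3)
        return cls(lambda_h=lambda_h, mu_h=mu, sigma_h=sigma)

    def quantile(self, p) -> np.ndarray:
        """Closed-form quantile(s) of the healthy distribution on the original scale."""
        from scipy.special import ndtri

        y = self.mu_h + ndtri(np.asarray(p, dtype=float)) * self.sigma_h
        return special.inv_boxcox(y, self.lambda_h)

    @property
    def original_scale_sd(self) -> float:
        """Half the central 68% width on the original scale — the separation unit
        used to place pathological components."""
        lo, hi = self.quantile([0.158655, 0.841345])
        return float(hi - lo) / 2.0


@dataclass(frozen=True)
class PathologicalComponent:
    """Gaussian contamination on the original scale.

    ``shift_sd`` places the component's mean ``shift_sd`` healthy
    original-scale SDs beyond the healthy centre, on ``side`` (``upper``,
    ``lower`` or ``both``, the latter split evenly).  ``scale_sd`` is the
    component SD in the same units.
    """

    fraction: float
    shift_sd: float = 4.0
    scale_sd: float = 1.0
    side: str = "upper"

    def __post_init__(self):
        if not 0.0 <= self.fraction < 0.5:
            raise ValueError(f"pathological fraction must be in [0, 0.5), got {self.fraction}")
        if self.side not in ("upper", "lower", "both"):
            raise ValueError(f"side must be upper|lower|both, got {self.side!r}")
        if self.shift_sd < 3.0:
            raise ValueError("pathological components must be shifted by >= 3 healthy SDs "
                             f"for clean separation, got {self.shift_sd}")


@dataclass
class SyntheticSpec:
    """Full recipe for one (analyte, sex) dataset; (n, seed) make it deterministic."""

    analyte: str
    sex: str
    healthy: HealthyComponent
    pathological: List[PathologicalComponent] = field(default_factory=list)
    duplicate_fraction: float = 0.0
    n: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}; expected one of {SEXES}")
        if not 0.0 <= self.duplicate_fraction <= 0.2:
            raise ValueError(f"duplicate_fraction must be in [0, 0.2], got {self.duplicate_fraction}")
        if self.n < 1:
            raise ValueError(f"n must be at least 1, got {self.n}")
        total = sum(p.fraction for p in self.pathological)
        if total >= 0.5:
            raise ValueError(f"total pathological fraction must be < 0.5, got {total}")

    def to_yaml(self) -> str:
        d = asdict(self)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SyntheticSpec":
        d = yaml.safe_load(io.StringIO(text))
        d["healthy"] = HealthyComponent(**d["healthy"])
        d["pathological"] = [PathologicalComponent(**p) for p in d.get("pathological", [])]
        return cls(**d)


# (median, q25, q75) per analyte and sex: typical adult sex-stratified CBC
# values from a large physical-examination population.  The Box-Cox exponent
# per analyte is a modelling choice: near 0 for the right-skewed counts
# (WBC, PLT), near 1 for the roughly symmetric RBC/HCT, above 1 for the
# mildly left-skewed indices (HGB, MCV, MCH, MCHC).
_PRESET_STATS = {
    ("WBC", "male"): (6.64, 5.68, 7.75),
    ("WBC", "female"): (6.09, 5.19, 7.11),
    ("RBC", "male"): (4.98, 4.75, 5.21),
    ("RBC", "female"): (4.39, 4.19, 4.58),
    ("HGB", "male"): (152.0, 146.0, 159.0),
    ("HGB", "female"): (130.0, 124.0, 136.0),
    ("HCT", "male"): (0.45, 0.43, 0.46),
    ("HCT", "female"): (0.39, 0.38, 0.41),
    ("MCV", "male"): (90.0, 87.0, 92.0),
    ("MCV", "female"): (89.0, 87.0, 92.0),
    ("MCH", "male"): (30.6, 29.8, 31.5),
    ("MCH", "female"): (29.8, 28.9, 30.7),
    ("MCHC", "male"): (341.0, 335.0, 347.0),
    ("MCHC", "female"): (332.0, 327.0, 338.0),
    ("PLT", "male"): (208.0, 180.0, 239.0),
    ("PLT", "female"): (230.0, 199.0, 266.0),
}

_PRESET_LAMBDA = {
    "WBC": 0.0, "PLT": 0.2, "RBC": 1.0, "HCT": 1.0,
    "HGB": 1.3, "MCV": 1.8, "MCH": 1.6, "MCHC": 1.4,
}


def make_preset(analyte: str, sex: str, n: int = 10_000, seed: int = 0,
                contamination: float = 0.0, side: str = "upper",
                duplicate_fraction: float = 0.0) -> SyntheticSpec:
    """Build a calibrated spec for one of the 8 CBC analytes by sex.

    The default spec has no contamination and no duplicate visits; its
    large-n simulated median approximates the calibration median.
    """
    if analyte not in ANALYTES:
        raise ValueError(f"unknown analyte {analyte!r}; expected one of {ANALYTES}")
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}; expected one of {SEXES}")
    median, q25, q75 = _PRESET_STATS[(analyte, sex)]
    healthy = HealthyComponent.from_median_iqr(median, q25, q75, _PRESET_LAMBDA[analyte])
    pathological = []
    if contamination > 0:
        pathological.append(PathologicalComponent(fraction=contamination, side=side))
    return SyntheticSpec(analyte=analyte, sex=sex, healthy=healthy,
                         pathological=pathological,
                         duplicate_fraction=duplicate_fraction, n=n, seed=seed)


def _draw_healthy(rng: np.random.Generator, comp: HealthyComponent, size: int) -> np.ndarray:
    lam = comp.lambda_h
    z = rng.normal(comp.mu_h, comp.sigma_h, size)
    if lam != 0.0:
        # keep draws inside the inverse-Box-Cox domain (negligible mass outside)
        bad = lam * z + 1.0 <= 0
        while bad.any():
            z[bad] = rng.normal(comp.mu_h, comp.sigma_h, int(bad.sum()))
            bad = lam * z + 1.0 <= 0
    return special.inv_boxcox(z, lam)


def _draw_pathological(rng: np.random.Generator, healthy: HealthyComponent,
                       comp: PathologicalComponent, size: int) -> np.ndarray:
    centre = float(healthy.quantile(0.5))
    unit = healthy.original_scale_sd
    scale = comp.scale_sd * unit
    if comp.side == "both":
        signs = np.where(rng.random(size) < 0.5, -1.0, 1.0)
    else:
        signs = np.full(size, 1.0 if comp.side == "upper" else -1.0)
    loc = centre + signs * comp.shift_sd * unit
    x = rng.normal(loc, scale)
    bad = x <= 0
    while bad.any():
        x[bad] = rng.normal(loc[bad], scale)
        bad = x <= 0
    return x


def simulate_dataset(spec: SyntheticSpec) -> pd.DataFrame:
    """Generate the long-format measurement table a spec describes.

    Returns exactly ``n + round(duplicate_fraction * n)`` rows with columns
    ``subject_id, date, sex, age, analyte, value`` (ISO dates); identical
    specs yield identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    fractions = np.array([p.fraction for p in spec.pathological])
    probs = np.concatenate(([1.0 - fractions.sum()], fractions))
    component = rng.choice(len(probs), size=n, p=probs)

    values = np.empty(n)
    idx_h = component == 0
    values[idx_h] = _draw_healthy(rng, spec.healthy, int(idx_h.sum()))
    for k, comp in enumerate(spec.pathological, start=1):
        idx = component == k
        if idx.any():
            values[idx] = _draw_pathological(rng, spec.healthy, comp, int(idx.sum()))

    base = pd.Timestamp("2010-01-01")
    dates = base + pd.to_timedelta(rng.integers(0, 730, n), unit="D")
    ages = rng.integers(18, 80, n)
    ids = np.array([f"S{i:06d}" for i in range(n)])

    frames = [pd.DataFrame({
        "subject_id": ids, "date": dates, "sex": spec.sex, "age": ages,
        "analyte": spec.analyte, "value": values,
    })]

    n_dup = int(round(spec.duplicate_fraction * n))
    if n_dup > 0:
        which = rng.choice(n, size=n_dup, replace=False)
        dup_vals = np.empty(n_dup)
        comp_dup = component[which]
        h = comp_dup == 0
        dup_vals[h] = _draw_healthy(rng, spec.healthy, int(h.sum()))
        for k, comp in enumerate(spec.pathological, start=1):
            idx = comp_dup == k
            if idx.any():
                dup_vals[idx] = _draw_pathological(rng, spec.healthy, comp, int(idx.sum()))
        frames.append(pd.DataFrame({
            "subject_id": ids[which],
            "date": dates[which] + pd.to_timedelta(rng.integers(1, 181, n_dup), unit="D"),
            "sex": spec.sex, "age": ages[which],
            "analyte": spec.analyte, "value": dup_vals,
        }))

    out = pd.concat(frames, ignore_index=True)
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    return out


def true_reference_limits(spec: SyntheticSpec) -> ReferenceInterval:
    """Ground-truth central-95% limits of the healthy component (contamination-free).

    Computed as the inverse Box-Cox of ``mu_h ± 1.96 sigma_h``, the same
    rounded multiplier every estimator in the package uses.
    """
    h = spec.healthy
    lo = special.inv_boxcox(h.mu_h - Z_95 * h.sigma_h, h.lambda_h)
    hi = special.inv_boxcox(h.mu_h + Z_95 * h.sigma_h, h.lambda_h)
    return ReferenceInterval(float(lo), float(hi), estimator="true", n_used=0)
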