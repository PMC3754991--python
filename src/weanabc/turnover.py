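"""Age-dependent bone mineral and collagen turnover in subadults.

Bone collagen is laid down by modeling (net addition of tissue during
skeletal growth) and replaced by remodeling (coupled resorption and
formation that leaves bone mass unchanged).  The *turnover rate* over a
one-year interval is the proportion of newly synthesized tissue relative
to the total at the end of the interval, aggregating both processes; in
early infancy it exceeds 1/yr, meaning the tissue present at age one is
essentially all post-natal.

The mineral phase records collagen-cohort formation with a delay: newly
deposited osteoid mineralizes to >70% of capacity within days (primary
mineralization) and acquires the remainder over years (secondary
mineralization).  Mineral-phase turnover is therefore a
mineralization-law-weighted sum over the collagen cohorts formed in the
current and earlier years, and collagen turnover is recovered by
deconvolving that delay year by year, starting from the 0-1 interval.

The 20 discrete collagen rates are finally smoothed into a quartic
polynomial (QP) in age, which is also the extrapolation used for ages
below one year, and whose closed-form integral gives the cumulative
fraction of collagen replaced between two ages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "TurnoverTable",
    "QPModel",
    "MineralizationLaw",
    "load_constants",
    "mineral_mass",
    "remodeling_rate",
    "mineral_turnover_table",
    "collagen_turnover_table",
    "fit_qp",
    "integrated_turnover",
    "default_turnover_table",
    "default_qp",
]

#: Ages below the QP's positive range are clamped to this rate (per year).
RATE_FLOOR = 1e-6

MAX_AGE = 20  # years covered by the discrete table


def load_constants(path: str | None = None) -> dict:
    """Load the physiology constants (growth curve, remodeling rate,
    mineralization law) from YAML.  Defaults to the packaged file."""
    if path is None:
        text = resources.files("weanabc").joinpath("_constants.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


@lru_cache(maxsize=1)
def _default_constants() -> dict:
    return load_constants()


def mineral_mass(age, constants: Mapping | None = None):
    """Skeletal mineral mass M(x) in grams at ``age`` years (sum of
    logistic growth components)."""
    constants = constants or _default_constants()
    age = np.asarray(age, dtype=float)
    total = np.zeros_like(age)
    for comp in constants["mineral_mass"]["components"]:
        total = total + comp["amplitude"] / (
            1.0 + np.exp(-comp["rate"] * (age - comp["midpoint"]))
        )
    return total


def remodeling_rate(age, constants: Mapping | None = None):
    """Trabecular remodeling rate R(x), fraction of existing bone
    replaced per year at ``age`` years."""
    constants = constants or _default_constants()
    age = np.asarray(age, dtype=float)
    q = constants["remodeling"]["log_coefficients"]
    return np.exp(sum(qi * age**i for i, qi in enumerate(q)))


@dataclass(frozen=True)
class TurnoverTable:
    """Per-year turnover rates for ages 0-20.

    ``mineral[i]`` (and ``collagen[i]`` once filled) is the fraction of
    the phase replaced during the year from ``interval_start[i]`` to
    ``interval_end[i]``.
    """

    interval_start: np.ndarray
    interval_end: np.ndarray
    mineral: np.ndarray
    collagen: np.ndarray | None = None

    def __post_init__(self):
        if not np.array_equal(self.interval_end, self.interval_start + 1):
            raise ValueError("intervals must be consecutive whole years")

    def __len__(self) -> int:
        return len(self.interval_start)


@dataclass(frozen=True)
class MineralizationLaw:
    """Cumulative mineralization m(lag) of a collagen cohort ``lag``
    whole years after matrix formation.

    ``m(0) = primary_fraction`` (primary mineralization completes within
    the formation year); the secondary remainder decays away with two
    exponential components, so m(lag) -> 1 as lag grows.
    """

    primary_fraction: float
    secondary_split: float
    secondary_retention_fast: float
    secondary_retention_slow: float

    @classmethod
    def from_constants(cls, constants: Mapping | None = None) -> "MineralizationLaw":
        constants = constants or _default_constants()
        law = constants["mineralization_law"]
        return cls(
            primary_fraction=law["primary_fraction"],
            secondary_split=law["secondary_split"],
            secondary_retention_fast=law["secondary_retention_fast"],
            secondary_retention_slow=law["secondary_retention_slow"],
        )

    @classmethod
    def identity(cls) -> "MineralizationLaw":
        """Law with no delay: everything mineralizes in the formation year."""
        return cls(1.0, 0.5, 0.5, 0.5)

    def fraction(self, lag) -> np.ndarray:
        """Cumulative mineralized fraction at integer ``lag`` years."""
        lag = np.asarray(lag)
        if np.any(lag < 0):
            raise ValueError("lag must be non-negative")
        residual = 1.0 - self.primary_fraction
        return 1.0 - residual * (
            self.secondary_split * self.secondary_retention_fast**lag
            + (1.0 - self.secondary_split) * self.secondary_retention_slow**lag
        )

    def increments(self, n: int) -> np.ndarray:
        """Mineral acquired per lag-year: dm[0] = m(0), dm[l] = m(l)-m(l-1)."""
        cum = self.fraction(np.arange(n))
        return np.diff(np.concatenate([[0.0], cum]))


def mineral_turnover_table(constants: Mapping | None = None) -> TurnoverTable:
    """Per-year mineral turnover for intervals 0-1 through 19-20.

    Each year's rate is the modeling (growth) contribution --- the
    fraction of end-of-year mineral mass added during the year --- plus
    the remodeling rate at mid-interval.
    """
    constants = constants or _default_constants()
    x = np.arange(MAX_AGE, dtype=float)
    m0 = mineral_mass(x, constants)
    m1 = mineral_mass(x + 1.0, constants)
    with np.errstate(divide="ignore", invalid="ignore"):
        growth = np.where(m1 > 0, 1.0 - m0 / np.where(m1 > 0, m1, 1.0), 0.0)
    rate = growth + remodeling_rate(x + 0.5, constants)
    return TurnoverTable(
        interval_start=np.arange(MAX_AGE),
        interval_end=np.arange(1, MAX_AGE + 1),
        mineral=rate,
    )


def mineralization_fraction(lag, constants: Mapping | None = None):
    """Cumulative mineralization fraction ``lag`` years after formation."""
    return MineralizationLaw.from_constants(constants).fraction(lag)


def collagen_turnover_table(
    mineral: TurnoverTable, law: MineralizationLaw | None = None
) -> TurnoverTable:
    """Recover collagen turnover by deconvolving the mineralization delay.

    The mineral turnover observed in year x is the law-weighted sum of
    collagen cohorts formed in years <= x::

        k_mineral(x) = sum_{l=0..x} dm(l) * k_collagen(x - l)

    which is solved sequentially from the youngest interval upward (the
    only causally well-posed order).
    """
    law = law or MineralizationLaw.from_constants()
    n = len(mineral)
    dm = law.increments(n)
    if dm[0] <= 0:
        raise ValueError("mineralization law has no primary fraction")
    kc = np.zeros(n)
    for i in range(n):
        delayed = float(np.dot(dm[1 : i + 1], kc[i - 1 :: -1][: i])) if i else 0.0
        kc[i] = (mineral.mineral[i] - delayed) / dm[0]
        if kc[i] <= 0:
            raise ValueError(
                f"deconvolution produced a non-positive collagen rate for "
                f"interval {mineral.interval_start[i]}-{mineral.interval_end[i]}"
            )
    return TurnoverTable(
        interval_start=mineral.interval_start,
        interval_end=mineral.interval_end,
        mineral=mineral.mineral,
        collagen=kc,
    )


@dataclass(frozen=True)
class QPModel:
    """Quartic polynomial turnover rate in age (years -> fraction/yr).

    ``coefficients`` are in descending degree order (numpy polynomial
    convention).  Evaluation clamps to a small positive floor so that
    extrapolated rates stay physically meaningful.
    """

    coefficients: np.ndarray
    _poly: np.poly1d = field(init=False, repr=False, compare=False)
    _antideriv: np.poly1d = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        coeffs = np.asarray(self.coefficients, dtype=float)
        if coeffs.shape != (5,):
            raise ValueError("QPModel needs exactly 5 coefficients")
        object.__setattr__(self, "coefficients", coeffs)
        object.__setattr__(self, "_poly", np.poly1d(coeffs))
        object.__setattr__(self, "_antideriv", np.polyint(np.poly1d(coeffs)))

    def rate(self, age):
        """Turnover rate (fraction/yr) at ``age``; floored at a small
        positive value."""
        return np.maximum(self._poly(np.asarray(age, dtype=float)), RATE_FLOOR)

    __call__ = rate

    def integral(self, from_age: float, to_age: float) -> float:
        """Closed-form integral of the (unfloored) quartic rate."""
        if from_age > to_age:
            raise ValueError("from_age must not exceed to_age")
        if from_age < 0:
            raise ValueError("ages must be non-negative")
        return float(self._antideriv(to_age) - self._antideriv(from_age))


def fit_qp(table: TurnoverTable) -> QPModel:
    """Least-squares quartic through the discrete collagen rates.

    Each interval's rate is attached to the interval *end* age (the rate
    over year [x, x+1] is recorded at x+1); this abscissa reproduces the
    published cumulative behaviour of the curve, including sub-year
    extrapolation toward age 0.
    """
    if table.collagen is None:
        raise ValueError("collagen column not filled; run collagen_turnover_table")
    x = table.interval_end.astype(float)
    try:
        coeffs = np.polyfit(x, table.collagen, 4)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate design
        raise ValueError("singular design in QP fit") from exc
    return QPModel(coeffs)


def integrated_turnover(qp: QPModel, from_age: float, to_age: float) -> float:
    """Cumulative fraction of collagen replaced between two ages."""
    return qp.integral(from_age, to_age)


@lru_cache(maxsize=1)
def default_turnover_table() -> TurnoverTable:
    """The full discrete table (mineral + collagen) under the packaged
    constants."""
    return collagen_turnover_table(mineral_turnover_table())


@lru_cache(maxsize=1)
def default_qp() -> QPModel:
    """The packaged quartic collagen-turnover model (the rate used by the
    forward simulation)."""
    return fit_qp(default_turnover_table())
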