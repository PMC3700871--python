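"""Poisson collision sub-model: log-linear rate in activity and wind.

The nightly number of collisions N_it is Poisson with

    log(lambda_it) = alpha0 + alpha1*zA_it + alpha2*zW_it + alpha3*zW_it^2

where zA and zW are the z-standardized acoustic-activity and wind-speed
covariates.  The quadratic wind term makes the rate unimodal in wind when
alpha3 < 0; the stationary point, back-transformed to m/s, is the wind
speed of maximum collision rate at constant activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .data_io import NightRecord, ValidationError

__all__ = [
    "CollisionCoefficients",
    "StandardizationParams",
    "standardize",
    "expected_rate",
    "linear_predictor",
    "wind_at_max_rate",
    "round_half_up",
    "design_matrix",
]


@dataclass(frozen=True)
class CollisionCoefficients:
    """Regression coefficients on the standardized-covariate scale."""

    alpha0: float  # intercept: log rate at average activity and wind
    alpha1: float  # acoustic activity
    alpha2: float  # wind speed (linear)
    alpha3: float  # wind speed (quadratic)

    def __post_init__(self) -> None:
        if not all(map(math.isfinite,
                       (self.alpha0, self.alpha1, self.alpha2, self.alpha3))):
            raise ValidationError("coefficients must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha0, self.alpha1, self.alpha2, self.alpha3])

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "CollisionCoefficients":
        a0, a1, a2, a3 = (float(x) for x in arr)
        return cls(a0, a1, a2, a3)


@dataclass(frozen=True)
class StandardizationParams:
    """Mean/SD pairs of the training covariates.

    Stored so that new data (e.g. a held-out turbine) is standardized with
    the *training* moments, keeping coefficients comparable.
    """

    activity_mean: float
    activity_sd: float
    wind_mean: float
    wind_sd: float

    def __post_init__(self) -> None:
        if self.activity_sd <= 0 or self.wind_sd <= 0:
            raise ValidationError("standard deviations must be positive")

    @classmethod
    def from_nights(cls, nights: Iterable[NightRecord]) -> "StandardizationParams":
        nights = list(nights)
        act = np.array([r.activity for r in nights], dtype=float)
        wind = np.array([r.wind for r in nights], dtype=float)
        _, (am, asd) = standardize(act)
        _, (wm, wsd) = standardize(wind)
        return cls(am, asd, wm, wsd)

    def apply(self, activity, wind) -> tuple[np.ndarray, np.ndarray]:
        """Standardize raw covariates with the stored moments."""
        zA = (np.asarray(activity, dtype=float) - self.activity_mean) / self.activity_sd
        zW = (np.asarray(wind, dtype=float) - self.wind_mean) / self.wind_sd
        return zA, zW


def standardize(values) -> tuple[np.ndarray, tuple[float, float]]:
    """z-transform to mean 0, sample SD 1 (n-1 denominator).

    Returns the z-scores and the ``(mean, sd)`` pair for back-transforming
    or for standardizing new data with the same moments.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValidationError("need at least 2 values to standardize")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        raise ValidationError("cannot standardize a constant sequence")
    return (arr - mean) / sd, (mean, sd)


def design_matrix(zA, zW) -> np.ndarray:
    """Columns (1, zA, zW, zW^2) matching the coefficient order."""
    zA = np.asarray(zA, dtype=float)
    zW = np.asarray(zW, dtype=float)
    return np.column_stack([np.ones_like(zA), zA, zW, zW * zW])


def linear_predictor(coef: CollisionCoefficients, zA, zW) -> np.ndarray:
    zA = np.asarray(zA, dtype=float)
    zW = np.asarray(zW, dtype=float)
    return coef.alpha0 + coef.alpha1 * zA + coef.alpha2 * zW + coef.alpha3 * zW * zW


def expected_rate(coef: CollisionCoefficients, zA, zW):
    """Expected nightly collision count lambda = exp(linear predictor)."""
    eta = linear_predictor(coef, zA, zW)
    with np.errstate(over="raise"):
        try:
            lam = np.exp(eta)
        except FloatingPointError:
            raise OverflowError(f"rate overflow at linear predictor {np.max(eta)}")
    return lam


def wind_at_max_rate(
    coef: CollisionCoefficients, sp: StandardizationParams
) -> float:
    """Wind speed (m/s) maximizing the collision rate at constant activity.

    The quadratic must be concave (alpha3 < 0); the stationary point
    z* = -alpha2 / (2 alpha3) is back-transformed with the stored wind
    moments.
    """
    if coef.alpha3 >= 0:
        raise ValidationError(
            f"no interior maximum: alpha3={coef.alpha3} is not negative")
    z_star = -coef.alpha2 / (2.0 * coef.alpha3)
    return sp.wind_mean + sp.wind_sd * z_star


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero (0.25 -> 0.3 at 1 d.p.)."""
    factor = 10.0 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)
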