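"""Informative Beta priors for detection parameters by moment matching.

Field studies report detection-process parameters (composite detection
probability ``p``, daily persistence ``s``, searcher efficiency ``f``) as
a point estimate with a 95% confidence interval.  The hierarchical model
consumes them as Beta priors whose mean and variance equal the reported
point estimate and squared standard error:

    alpha = m * (m * (1 - m) / v - 1)
    beta  = (1 - m) * (m * (1 - m) / v - 1),   v = se^2

The CI is converted to a standard error with the normal approximation
``se = width / (2 z)``; asymmetric CIs are symmetrized (only the width is
used), which also absorbs published CIs that are inconsistent with their
point estimate.  A vanishing se yields a point mass instead of a
degenerate, numerically hostile Beta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import stats

from .data_io import TurbineDetection, ValidationError

__all__ = [
    "BetaSpec",
    "PointMass",
    "DetectionPriors",
    "InfeasibleVarianceError",
    "beta_from_moments",
    "se_from_ci",
    "detection_priors",
    "POINT_MASS_SE",
]

#: Below this standard error the parameter is treated as known exactly.
POINT_MASS_SE = 1e-6


class InfeasibleVarianceError(ValueError):
    """Requested variance is not attainable by any Beta distribution."""


@dataclass(frozen=True)
class BetaSpec:
    """Shape pair of a Beta distribution used as an informative prior."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValidationError(
                f"Beta shapes must be positive, got ({self.alpha}, {self.beta})")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def variance(self) -> float:
        n = self.alpha + self.beta
        return self.alpha * self.beta / (n * n * (n + 1.0))

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        return rng.beta(self.alpha, self.beta, size=size)


@dataclass(frozen=True)
class PointMass:
    """A parameter known without error (fall-in, or a CI of zero width)."""

    value: float

    @property
    def mean(self) -> float:
        return self.value

    @property
    def variance(self) -> float:
        return 0.0

    @property
    def sd(self) -> float:
        return 0.0

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        return np.full(size, self.value) if size is not None else np.float64(self.value)


PriorSpec = Union[BetaSpec, PointMass]


def beta_from_moments(mean: float, se: float) -> PriorSpec:
    """Beta prior with the given mean and standard deviation.

    Returns a :class:`PointMass` when ``se`` is (numerically) zero.
    Raises :class:`InfeasibleVarianceError` when ``se**2 >= mean*(1-mean)``,
    the variance ceiling of the Beta family at that mean.
    """
    if not 0.0 < mean < 1.0:
        raise ValidationError(f"mean must lie strictly in (0, 1), got {mean}")
    if se < 0:
        raise ValidationError(f"se must be non-negative, got {se}")
    if se < POINT_MASS_SE:
        return PointMass(mean)
    v = se * se
    ceiling = mean * (1.0 - mean)
    if v >= ceiling:
        raise InfeasibleVarianceError(
            f"se^2={v:.6g} >= mean(1-mean)={ceiling:.6g}: no Beta "
            f"distribution has mean {mean} with that variance")
    nu = ceiling / v - 1.0
    return BetaSpec(alpha=mean * nu, beta=(1.0 - mean) * nu)


def se_from_ci(lower: float, upper: float, level: float = 0.95) -> float:
    """Normal-approximation standard error from a symmetric CI width."""
    if lower > upper:
        raise ValidationError(f"CI lower {lower} > upper {upper}")
    if not 0.0 < level < 1.0:
        raise ValidationError(f"level must be in (0, 1), got {level}")
    z = stats.norm.ppf(0.5 * (1.0 + level))
    return (upper - lower) / (2.0 * z)


@dataclass(frozen=True)
class DetectionPriors:
    """Priors for one turbine's detection parameters.

    ``p`` feeds the one-level observation model; ``s`` and ``f`` feed the
    three-level model, in which the fall-in proportion ``a`` enters as a
    known constant.
    """

    turbine_id: str
    p: PriorSpec
    s: PriorSpec
    f: PriorSpec
    fall_in: float


def detection_priors(t: TurbineDetection, level: float = 0.95) -> DetectionPriors:
    """Moment-matched priors for p, s, f of one turbine; a passes through."""
    out = {}
    for name, mean, ci in [
        ("p", t.detection_mean, t.detection_ci),
        ("s", t.persistence_mean, t.persistence_ci),
        ("f", t.efficiency_mean, t.efficiency_ci),
    ]:
        try:
            out[name] = beta_from_moments(mean, se_from_ci(*ci, level=level))
        except InfeasibleVarianceError as exc:
            raise InfeasibleVarianceError(
                f"turbine {t.turbine_id}, parameter {name}: {exc}") from None
    return DetectionPriors(
        turbine_id=t.turbine_id, p=out["p"], s=out["s"], f=out["f"],
        fall_in=t.fall_in)
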