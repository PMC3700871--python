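"""The conventional "corrected count" mortality estimator.

Given a total of C carcasses found and a carcass detection probability p,
Bayes' theorem with a flat prior on the number of kills N gives

    N - C | C, p  ~  NegBinomial(size = C + 1, prob = p),

whose mean is (C + 1)/p - 1.  Uncertainty in p (a Beta distribution,
typically moment-matched from a reported CI) is propagated by Monte
Carlo: mix the negative-binomial posterior over Beta draws of p.

This estimator uses no covariates; it is the comparator against which
the covariate-based hierarchical model is judged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Union

import numpy as np
from scipy import stats

from .data_io import TurbineDetection, ValidationError
from .priors import PointMass, PriorSpec, beta_from_moments, se_from_ci

__all__ = [
    "CorrectedCountResult",
    "posterior_given_p",
    "estimate_corrected",
    "estimate_corrected_per_turbine",
    "pooled_detection_prior",
]


@dataclass
class CorrectedCountResult:
    """Summary of the corrected-count posterior for one unit (or a pool)."""

    mean: float
    credible_lower: float
    credible_upper: float
    mode: int
    observed: int
    draws: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.credible_lower > self.credible_upper:
            raise ValidationError("credible interval lower > upper")
        if self.mode < self.observed:
            raise ValidationError("posterior mode below the observed count")


def posterior_given_p(C: int, p: float):
    """Posterior of the kill total N given detection probability p.

    Returns a frozen scipy distribution over N >= C (a shifted negative
    binomial); ``.mean()`` equals (C + 1)/p - 1.
    """
    if C < 0:
        raise ValidationError(f"carcass count must be >= 0, got {C}")
    if not 0.0 < p <= 1.0:
        raise ValidationError(
            f"detection probability must be in (0, 1], got {p} "
            "(the posterior is improper at p = 0)")
    return stats.nbinom(C + 1, p, loc=C)


def estimate_corrected(
    C: int,
    p_prior: PriorSpec,
    n_draws: int = 100_000,
    rng: Union[np.random.Generator, int, None] = None,
) -> CorrectedCountResult:
    """Corrected count with Monte-Carlo propagation of p's uncertainty.

    The reported mean is Rao-Blackwellized (the analytic conditional mean
    averaged over p draws); quantiles and mode come from the sampled
    mixture.  Beta draws numerically equal to 0 are redrawn.
    """
    if n_draws < 1000:
        raise ValidationError(f"n_draws must be >= 1000, got {n_draws}")
    rng = np.random.default_rng(rng)
    if isinstance(p_prior, PointMass):
        p_draws = np.full(n_draws, p_prior.value)
    else:
        p_draws = p_prior.sample(rng, size=n_draws)
        bad = p_draws <= 0.0
        while np.any(bad):
            p_draws[bad] = p_prior.sample(rng, size=int(bad.sum()))
            bad = p_draws <= 0.0
    cond_mean = (C + 1.0) / p_draws - 1.0
    n_draws_sample = C + rng.negative_binomial(C + 1, p_draws)
    lower, upper = np.percentile(n_draws_sample, [2.5, 97.5])
    values, freq = np.unique(n_draws_sample, return_counts=True)
    return CorrectedCountResult(
        mean=float(cond_mean.mean()),
        credible_lower=float(lower),
        credible_upper=float(upper),
        mode=int(values[np.argmax(freq)]),
        observed=C,
        draws=n_draws_sample,
    )


def pooled_detection_prior(detections: Iterable[TurbineDetection]) -> PriorSpec:
    """Effort-weighted Beta prior on detection probability for a pool.

    Weights each turbine's point estimate and CI width by its number of
    searches T_i, then moment-matches a single Beta.
    """
    detections = list(detections)
    if not detections:
        raise ValidationError("empty detection collection")
    T = np.array([d.n_searches for d in detections], dtype=float)
    p = np.array([d.detection_mean for d in detections])
    widths = np.array([d.detection_ci[1] - d.detection_ci[0] for d in detections])
    w = T / T.sum()
    mean = float(np.sum(w * p))
    se = se_from_ci(0.0, float(np.sum(w * widths)))
    return beta_from_moments(mean, se)


def estimate_corrected_per_turbine(
    detections: Iterable[TurbineDetection],
    mode: Literal["pooled", "per_turbine"] = "pooled",
    n_draws: int = 100_000,
    rng: Union[np.random.Generator, int, None] = None,
) -> Union[CorrectedCountResult, dict[str, CorrectedCountResult]]:
    """Corrected counts for a turbine collection.

    ``pooled`` sums carcasses and uses the effort-weighted prior (the
    study-total estimate); ``per_turbine`` returns one result per turbine
    whose draws can be summed draw-wise.
    """
    detections = list(detections)
    if not detections:
        raise ValidationError("empty detection collection")
    rng = np.random.default_rng(rng)
    if mode == "pooled":
        C = sum(d.total_found for d in detections)
        return estimate_corrected(C, pooled_detection_prior(detections),
                                  n_draws=n_draws, rng=rng)
    if mode == "per_turbine":
        out = {}
        for d in detections:
            prior = beta_from_moments(
                d.detection_mean, se_from_ci(*d.detection_ci))
            out[d.turbine_id] = estimate_corrected(
                d.total_found, prior, n_draws=n_draws, rng=rng)
        return out
    raise ValidationError(f"unknown mode {mode!r}")
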