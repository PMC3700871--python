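"""Bias metrics and posterior predictive model checking.

Bias is the ratio of estimated to true (simulated) collision totals per
turbine; an unbiased estimator has a median ratio near one.  Turbines
with a true total of zero have an undefined ratio and are excluded from
the summary (and counted separately) rather than reported as infinities.

The posterior predictive check simulates complete carcass-count data
sets from retained posterior draws through the fitted model's own
observation chain and compares the frequency table of counts per search
(how many searches found 0, 1, 2, ... carcasses) with the observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .collision_model import CollisionCoefficients, expected_rate
from .data_io import Dataset, ValidationError
from .inference import MortalityEstimate, PosteriorSamples
from .observation_models import simulate_three_level_path

__all__ = ["BiasRatio", "PpcTable", "bias_ratios", "posterior_predictive_check"]


@dataclass(frozen=True)
class BiasRatio:
    """Estimated / true collision total for one turbine."""

    turbine_id: str
    estimated: float
    true_value: int
    ratio: float  # inf when true_value == 0

    @classmethod
    def of(cls, turbine_id: str, estimated: float, true_value: int) -> "BiasRatio":
        ratio = estimated / true_value if true_value > 0 else math.inf
        return cls(turbine_id, estimated, true_value, ratio)


def bias_ratios(
    estimates: Mapping[str, Union[MortalityEstimate, float]],
    truth: Mapping[str, int],
) -> tuple[list[BiasRatio], dict[str, float]]:
    """Per-turbine bias ratios plus a median/quartile summary.

    ``estimates`` values may be :class:`MortalityEstimate` (the posterior
    mean is used) or plain numbers.  Turbine ids must match exactly.
    """
    if set(estimates) != set(truth):
        raise ValidationError(
            f"turbine id mismatch: estimates {sorted(estimates)} vs "
            f"truth {sorted(truth)}")
    ratios = []
    for tid in estimates:
        est = estimates[tid]
        value = est.mean if isinstance(est, MortalityEstimate) else float(est)
        ratios.append(BiasRatio.of(tid, value, int(truth[tid])))
    finite = [r.ratio for r in ratios if math.isfinite(r.ratio)]
    summary = {
        "n": len(ratios),
        "n_true_zero": sum(1 for r in ratios if not math.isfinite(r.ratio)),
        "median": float(np.median(finite)) if finite else math.nan,
        "q25": float(np.percentile(finite, 25)) if finite else math.nan,
        "q75": float(np.percentile(finite, 75)) if finite else math.nan,
    }
    return ratios, summary


@dataclass
class PpcTable:
    """Observed vs posterior-predicted frequencies of carcasses per search."""

    counts: np.ndarray            # the k values (0, 1, 2, ...)
    observed: np.ndarray          # observed frequency of searches with c = k
    predicted_median: np.ndarray
    predicted_lower: np.ndarray   # 2.5% prediction quantile
    predicted_upper: np.ndarray   # 97.5% prediction quantile
    n_searches: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "carcasses": self.counts,
            "observed": self.observed,
            "predicted_median": self.predicted_median,
            "predicted_lwr": self.predicted_lower,
            "predicted_upr": self.predicted_upper,
        })

    def observed_in_interval(self, k: int) -> bool:
        i = int(np.searchsorted(self.counts, k))
        return bool(self.predicted_lower[i] <= self.observed[i]
                    <= self.predicted_upper[i])


def posterior_predictive_check(
    samples: PosteriorSamples,
    data: Dataset,
    model: Literal["one_level", "three_level"],
    n_sims: Optional[int] = None,
    rng: Union[np.random.Generator, int, None] = None,
    thin: int = 10,
) -> PpcTable:
    """Frequency-table posterior predictive check.

    Every ``thin``-th retained draw (or ``n_sims`` evenly spaced draws)
    simulates a full data set of counts through the fitted observation
    chain; per count value k the 2.5/50/97.5% quantiles of the simulated
    frequencies frame the observed frequency.
    """
    if model != samples.model:
        raise ValidationError(
            f"samples were fitted with {samples.model!r}, not {model!r}")
    rng = np.random.default_rng(rng)
    if n_sims is not None:
        idx = np.unique(np.linspace(0, samples.n_draws - 1, n_sims).astype(int))
    else:
        idx = np.arange(0, samples.n_draws, thin)

    nights = sorted(data.nights, key=lambda r: (r.turbine_id, r.night_index))
    tids = samples.turbine_ids
    sp = samples.standardization
    per_turbine = {
        tid: [r for r in nights if r.turbine_id == tid] for tid in tids}
    n_searches = sum(r.searched for r in nights)

    sim_counts = []   # one flat array of per-search counts per draw
    for i in idx:
        coef = CollisionCoefficients.from_array(samples.coefficients[i])
        draw_counts = []
        for j, tid in enumerate(tids):
            recs = per_turbine[tid]
            zA, zW = sp.apply([r.activity for r in recs],
                              [r.wind for r in recs])
            lam = expected_rate(coef, zA, zW)
            N = rng.poisson(lam)
            searched = [r.searched for r in recs]
            if model == "one_level":
                p = samples.detection["p"][i, j]
                c = rng.binomial(N, p)
                draw_counts.append(c[np.asarray(searched)])
            else:
                det = data.detections[tid]
                state = simulate_three_level_path(
                    N, det.fall_in,
                    samples.detection["s"][i, j],
                    samples.detection["f"][i, j],
                    rng, searched=searched)
                draw_counts.append(
                    state.found[np.asarray(searched)])
        sim_counts.append(np.concatenate(draw_counts))

    obs = np.array([r.carcass_count for r in nights if r.searched])
    kmax = int(max(obs.max(initial=0),
                   max(int(s.max(initial=0)) for s in sim_counts)))
    ks = np.arange(kmax + 1)
    obs_freq = np.bincount(obs, minlength=kmax + 1)
    freq_matrix = np.stack(
        [np.bincount(s, minlength=kmax + 1) for s in sim_counts])
    lower, median, upper = np.percentile(freq_matrix, [2.5, 50, 97.5], axis=0)
    return PpcTable(
        counts=ks, observed=obs_freq,
        predicted_median=median, predicted_lower=lower,
        predicted_upper=upper, n_searches=int(n_searches))
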