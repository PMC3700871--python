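"""Shared fixtures, including the (expensive) parameter-recovery study."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pytest

from windmort.data_io import (
    Dataset,
    NightRecord,
    TurbineDetection,
    load_example_detection_table,
)
from windmort.inference import (
    McmcConfig,
    fit_three_level,
    mortality_summary,
    predict_new,
)
from windmort.simulation import SimConfig, simulate_replicate, train_test_split

TRUE_COEFFICIENTS = np.array([-4.1, 0.5, -2.9, -1.3])


@pytest.fixture(scope="session")
def example_detections() -> list[TurbineDetection]:
    return load_example_detection_table()


def make_detection(tid="t1", year=2008, C=0, T=10, a=0.9, s=0.8, f=0.7,
                   p=0.5, s_ci=None, f_ci=None, p_ci=None) -> TurbineDetection:
    def ci(mean, half):
        return (max(0.0, mean - half), min(1.0, mean + half))

    return TurbineDetection(
        turbine_id=tid, year=year, total_found=C, n_searches=T, fall_in=a,
        persistence_mean=s, persistence_ci=s_ci or ci(s, 0.1),
        efficiency_mean=f, efficiency_ci=f_ci or ci(f, 0.05),
        detection_mean=p, detection_ci=p_ci or ci(p, 0.1),
    )


@pytest.fixture()
def toy_dataset() -> Dataset:
    """2 turbines x 3 nights with a handful of carcasses."""
    nights = []
    counts = {"t1": [1, 0, 0], "t2": [0, 2, 0]}
    rng = np.random.default_rng(0)
    for tid, cs in counts.items():
        for t, c in enumerate(cs, start=1):
            nights.append(NightRecord(
                turbine_id=tid, night_index=t, carcass_count=c,
                activity=int(rng.integers(0, 30)),
                wind=float(rng.uniform(1, 9))))
    dets = {tid: make_detection(tid=tid, C=sum(cs), T=len(cs))
            for tid, cs in counts.items()}
    return Dataset(nights=nights, detections=dets)


@dataclass
class RecoveryResults:
    """Outcome of the seeded replicate recovery study (shared across tests)."""

    coverage: np.ndarray          # (n_replicates, 4) bool
    turbine_ratios: list[float]   # estimated/true per training turbine
    turbine_pairs: list[tuple[float, int]]   # (estimated, true) totals
    predicted_ratios: list[float]  # held-out turbine, one per replicate
    n_replicates: int


@pytest.fixture(scope="session")
def recovery_results() -> RecoveryResults:
    """Fit the three-level model to 20 simulated studies (18 turbines with
    the bundled 2008 detection parameters, 100 nightly-searched nights,
    collision coefficients -4.1/0.5/-2.9/-1.3) with one turbine held out
    per study, and collect coefficient coverage, per-turbine mortality
    ratios and held-out prediction ratios."""
    n_reps = 20
    cfg = SimConfig(n_turbines=18, nights_per_turbine=100)
    coverage = np.zeros((n_reps, 4), dtype=bool)
    turbine_ratios: list[float] = []
    turbine_pairs: list[tuple[float, int]] = []
    predicted_ratios: list[float] = []
    root = np.random.SeedSequence(20130703)   # fixed study seed
    for i, child in enumerate(root.spawn(n_reps)):
        rep = simulate_replicate(cfg, np.random.default_rng(child))
        split = train_test_split(rep, rng=i)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            samples = fit_three_level(
                split.train,
                cfg=McmcConfig.test_profile(seed=i, model="three_level"))
        ci = np.percentile(samples.coefficients, [2.5, 97.5], axis=0)
        coverage[i] = (ci[0] <= TRUE_COEFFICIENTS) & (TRUE_COEFFICIENTS <= ci[1])
        truth = rep.true_totals()
        for tid, est in mortality_summary(samples, by="turbine").items():
            turbine_pairs.append((est.mean, truth[tid]))
            if truth[tid] > 0:
                turbine_ratios.append(est.mean / truth[tid])
        pred = predict_new(samples, split.test.nights, rng=i)
        if truth[split.held_out] > 0:
            predicted_ratios.append(pred.mean / truth[split.held_out])
    return RecoveryResults(coverage=coverage, turbine_ratios=turbine_ratios,
                           turbine_pairs=turbine_pairs,
                           predicted_ratios=predicted_ratios,
                           n_replicates=n_reps)
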