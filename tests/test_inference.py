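import warnings

import numpy as np
import pytest

from windmort.collision_model import (
    CollisionCoefficients,
    StandardizationParams,
    design_matrix,
)
from windmort.data_io import Dataset, NightRecord, ValidationError
from windmort.inference import (
    McmcConfig,
    MortalityEstimate,
    PosteriorSamples,
    fit_one_level,
    fit_three_level,
    gelman_rubin,
    mortality_summary,
    predict_new,
)
from windmort.priors import PointMass
from windmort.simulation import SimConfig, simulate_replicate

from conftest import make_detection


def _quiet(fn, *args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fn(*args, **kwargs)


def _samples_from_chains(chain_a, chain_b) -> PosteriorSamples:
    """Minimal PosteriorSamples wrapping two scalar chains as alpha0."""
    n = len(chain_a)
    coefs = np.zeros((2 * n, 4))
    coefs[:, 0] = np.concatenate([chain_a, chain_b])
    return PosteriorSamples(
        model="one_level", turbine_ids=[], coefficients=coefs,
        chain=np.repeat([0, 1], n), detection={},
        latent_totals=np.zeros((2 * n, 0)),
        standardization=StandardizationParams(0, 1, 0, 1),
        config=McmcConfig(n_iterations=2, burn_in=0, seed=0),
    )


class TestGelmanRubin:
    def test_identical_chains_give_unity(self):
        chain = np.random.default_rng(0).normal(size=500)
        rhat = gelman_rubin(_samples_from_chains(chain, chain))
        assert rhat["alpha0"] == pytest.approx(1.0, abs=1e-6)

    def test_independent_stationary_chains_converge(self):
        rng = np.random.default_rng(1)
        rhat = gelman_rubin(_samples_from_chains(
            rng.normal(size=10_000), rng.normal(size=10_000)))
        assert rhat["alpha0"] < 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(2)
        rhat = gelman_rubin(_samples_from_chains(
            rng.normal(0, 1, 5_000), rng.normal(10, 1, 5_000)))
        assert rhat["alpha0"] > 2

    def test_single_chain_rejected(self):
        s = _samples_from_chains(np.zeros(50), np.zeros(50))
        s.chain = np.zeros(100, dtype=int)
        with pytest.raises(ValidationError):
            gelman_rubin(s)


class TestMortalitySummary:
    def test_degenerate_draws(self):
        s = _samples_from_chains(np.zeros(20), np.zeros(20))
        s.latent_totals = np.full((40, 2), 20.0)
        est = mortality_summary(s, by="total")
        assert est == MortalityEstimate(40.0, 40.0, 40.0, 40.0)

    def test_total_is_drawwise_sum_of_turbines(self):
        rng = np.random.default_rng(3)
        s = _samples_from_chains(np.zeros(30), np.zeros(30))
        s.turbine_ids = ["a", "b"]
        s.latent_totals = rng.poisson(5.0, size=(60, 2)).astype(float)
        assert np.array_equal(s.total_draws, s.latent_totals.sum(axis=1))
        per = mortality_summary(s, by="turbine")
        total = mortality_summary(s, by="total")
        assert total.mean == pytest.approx(sum(e.mean for e in per.values()))


class TestPredictNew:
    def test_empty_covariates_predict_zero(self):
        s = _samples_from_chains(np.zeros(20), np.zeros(20))
        assert predict_new(s, [], rng=0) == MortalityEstimate(0, 0, 0, 0)

    def test_point_mass_posterior_matches_poisson_expectation(self):
        coef = CollisionCoefficients(-1.0, 0.3, -0.4, -0.2)
        s = _samples_from_chains(np.zeros(2_000), np.zeros(2_000))
        s.coefficients = np.tile(coef.as_array(), (4_000, 1))
        sp = StandardizationParams(10, 4, 5.5, 1.8)
        nights = [NightRecord("new", t + 1, 0, activity=5 * t, wind=3.0 + t)
                  for t in range(4)]
        zA, zW = sp.apply([r.activity for r in nights],
                          [r.wind for r in nights])
        lam_total = np.exp(design_matrix(zA, zW) @ coef.as_array()).sum()
        est = predict_new(s, nights, sp=sp, rng=1)
        mc_se = np.sqrt(lam_total / 4_000)
        assert est.mean == pytest.approx(lam_total, abs=4 * mc_se)


def _one_level_data(n_turbines=4, nights=40, p=0.6, seed=0,
                    coef=CollisionCoefficients(-2.0, 0.4, -0.5, -0.3)):
    """Data generated directly from the one-level model."""
    rng = np.random.default_rng(seed)
    rec, dets = [], {}
    sp = StandardizationParams(10, 5, 5.5, 1.8)
    for i in range(n_turbines):
        tid = f"t{i}"
        act = rng.integers(0, 25, nights)
        wind = rng.uniform(0.5, 10.0, nights)
        zA, zW = sp.apply(act, wind)
        N = rng.poisson(np.exp(design_matrix(zA, zW) @ coef.as_array()))
        c = rng.binomial(N, p)
        rec += [NightRecord(tid, t + 1, int(c[t]), int(act[t]),
                            float(wind[t])) for t in range(nights)]
        dets[tid] = make_detection(tid=tid, C=int(c.sum()), T=nights, p=p)
    return Dataset(nights=rec, detections=dets), sp


class TestFits:
    def test_posterior_totals_never_below_observed(self):
        data, sp = _one_level_data(seed=1)
        observed = np.array([
            sum(r.carcass_count for r in data.nights_for(t))
            for t in data.turbine_ids()])
        cfg = McmcConfig(n_iterations=600, burn_in=300, seed=0)
        for fit in (fit_one_level, fit_three_level):
            s = _quiet(fit, data, cfg=cfg)
            assert np.all(s.latent_totals >= observed[None, :])

    def test_seeded_runs_are_bit_reproducible(self):
        data, _ = _one_level_data(seed=2)
        cfg = McmcConfig(n_iterations=400, burn_in=200, seed=7)
        a = _quiet(fit_one_level, data, cfg=cfg)
        b = _quiet(fit_one_level, data, cfg=cfg)
        assert np.array_equal(a.coefficients, b.coefficients)
        assert np.array_equal(a.latent_totals, b.latent_totals)
        c = _quiet(fit_three_level, data, cfg=cfg)
        d = _quiet(fit_three_level, data, cfg=cfg)
        assert np.array_equal(c.coefficients, d.coefficients)

    def test_missing_prior_for_turbine_rejected(self):
        data, _ = _one_level_data(n_turbines=2, nights=5, seed=3)
        with pytest.raises(ValidationError, match="prior"):
            fit_one_level(data, priors={"t0": PointMass(0.5)},
                          cfg=McmcConfig(n_iterations=20, burn_in=10, seed=0))

    def test_perfect_detection_pins_totals_to_observed_counts(self):
        """With p = 1 (one-level) or a = s = f = 1 (three-level) the
        observation chain is lossless and the posterior totals must equal
        the observed totals in every draw."""
        data, _ = _one_level_data(p=1.0, seed=4)
        observed = np.array([
            sum(r.carcass_count for r in data.nights_for(t))
            for t in data.turbine_ids()])
        cfg = McmcConfig(n_iterations=400, burn_in=200, seed=1)
        ids = data.turbine_ids()
        s1 = _quiet(fit_one_level, data,
                    priors={t: PointMass(1.0) for t in ids}, cfg=cfg)
        assert np.all(s1.latent_totals == observed[None, :])
        s3 = _quiet(fit_three_level, data,
                    s_priors={t: PointMass(1.0) for t in ids},
                    f_priors={t: PointMass(1.0) for t in ids},
                    fall_in={t: 1.0 for t in ids}, cfg=cfg)
        assert np.all(s3.latent_totals == observed[None, :])

    def test_implied_rate_matches_mean_count_when_p_is_one(self):
        """With no detection loss the fitted mean collision rate must
        reproduce the mean nightly carcass count."""
        data, sp = _one_level_data(n_turbines=6, nights=80, p=1.0, seed=5)
        ids = data.turbine_ids()
        s = _quiet(fit_one_level, data,
                   priors={t: PointMass(1.0) for t in ids},
                   cfg=McmcConfig(n_iterations=3_000, burn_in=1_500, seed=2))
        nights = sorted(data.nights, key=lambda r: (r.turbine_id,
                                                    r.night_index))
        zA, zW = s.standardization.apply([r.activity for r in nights],
                                         [r.wind for r in nights])
        X = design_matrix(zA, zW)
        rate = np.exp(s.coefficients @ X.T).mean(axis=1)
        cbar = np.mean([r.carcass_count for r in nights])
        assert abs(rate.mean() - cbar) < 3 * rate.std()

    def test_one_and_three_level_totals_agree_on_daily_search_data(self):
        """Fitted to the same nightly-searched simulated data, the two
        observation models give closely agreeing grand totals (the
        published fits differ by at most one collision)."""
        rep = simulate_replicate(SimConfig(n_turbines=10,
                                           nights_per_turbine=100), 19)
        m1 = mortality_summary(_quiet(
            fit_one_level, rep.dataset,
            cfg=McmcConfig.test_profile(seed=2))).mean
        m3 = mortality_summary(_quiet(
            fit_three_level, rep.dataset,
            cfg=McmcConfig.test_profile(seed=2, model="three_level"))).mean
        assert abs(m1 - m3) / m3 < 0.10

    def test_convergence_failure_warns_not_silent(self):
        data, _ = _one_level_data(seed=6)
        with pytest.warns(UserWarning, match="R-hat"):
            # near-zero steps freeze each chain at its own jittered start
            fit_one_level(data, cfg=McmcConfig(
                n_iterations=60, burn_in=30, seed=0, proposal_scale=1e-6))


class TestRecoveryProperties:
    def test_per_turbine_estimates_track_true_totals(self, recovery_results):
        """Across the recovery study, estimated per-turbine totals are
        positively rank-correlated with the simulated truth."""
        from scipy import stats
        est, true = zip(*recovery_results.turbine_pairs)
        rho = stats.spearmanr(est, true).statistic
        assert rho > 0

    def test_held_out_turbine_predictions_are_unbiased(self, recovery_results):
        """Median predicted/true ratio for the held-out turbine across
        replicates stays within a factor of two of unity."""
        med = np.median(recovery_results.predicted_ratios)
        assert 0.5 <= med <= 2.0
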