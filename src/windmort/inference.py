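"""Bayesian inference for the collision N-mixture models.

Both model variants share the Poisson collision sub-model
``N_it ~ Poisson(lambda_it)`` with a log-linear rate in standardized
acoustic activity and wind (see :mod:`windmort.collision_model`) and a
Normal(0, 100) prior on each coefficient.  They differ in the
observation sub-model (see :mod:`windmort.observation_models`).

The sampler is Metropolis-within-Gibbs with exact conjugate updates
wherever they exist:

* one-level latent counts: ``N_it - c_it | rest ~ Poisson(lambda_it (1 - p_i))``
  on searched nights (``N_it ~ Poisson(lambda_it)`` where no search
  constrains them);
* three-level latent collisions given the fall-ins:
  ``N_it - Nfa_it | rest ~ Poisson(lambda_it (1 - a_i))``;
* detection probabilities: conjugate Beta updates from their binomial
  likelihood terms (point-mass priors are left untouched);
* three-level fall-ins: single-site +/-1 Metropolis with the collisions
  N integrated out (marginally fallen ~ Poisson(lambda a)), so moves are
  not throttled by the current N; remaining-carcass counts: single-site
  +/-1 Metropolis in a red-black night schedule.  Any proposal violating
  a carry-over invariant has density zero;
* coefficients: one-at-a-time Gaussian random-walk proposals with step
  sizes adapted toward ~30% acceptance, plus a joint proposal whose
  covariance is learned from the burn-in history (wind and wind^2 terms
  are strongly correlated).  Adaptation runs during burn-in only and is
  frozen afterwards, keeping the chain Markovian.

Runs are bit-reproducible for a fixed :class:`McmcConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .collision_model import (
    CollisionCoefficients,
    StandardizationParams,
    design_matrix,
)
from .data_io import Dataset, NightRecord, ValidationError
from .priors import (
    BetaSpec,
    DetectionPriors,
    PointMass,
    PriorSpec,
    detection_priors,
)

__all__ = [
    "McmcConfig",
    "PosteriorSamples",
    "MortalityEstimate",
    "ConvergenceWarning",
    "fit_one_level",
    "fit_three_level",
    "gelman_rubin",
    "mortality_summary",
    "predict_new",
    "priors_from_dataset",
]

COEF_NAMES = ("alpha0", "alpha1", "alpha2", "alpha3")
RHAT_THRESHOLD = 1.1


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when R-hat exceeds the threshold."""


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings.

    Defaults follow the published analysis: 2 chains, 20,000 iterations
    with 10,000 burn-in for the one-level model; 100,000 with 90,000
    burn-in for the slower-converging three-level model.  The
    ``test_profile`` (4,000 / 2,000) is for desk-scale runs.
    """

    n_chains: int = 2
    n_iterations: int = 20_000
    burn_in: int = 10_000
    thin: int = 1
    seed: int = 0
    proposal_scale: float = 0.1
    #: Optional: freeze the regression coefficients (oracle tests, PPC toys).
    fix_coefficients: Optional[CollisionCoefficients] = None

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValidationError("need at least one chain")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValidationError("require 0 <= burn_in < n_iterations")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")

    @classmethod
    def one_level_default(cls, seed: int = 0) -> "McmcConfig":
        return cls(n_iterations=20_000, burn_in=10_000, seed=seed)

    @classmethod
    def three_level_default(cls, seed: int = 0) -> "McmcConfig":
        return cls(n_iterations=100_000, burn_in=90_000, seed=seed)

    @classmethod
    def test_profile(cls, seed: int = 0,
                     model: str = "one_level") -> "McmcConfig":
        """Reduced desk-scale settings: 4,000/2,000 for the one-level
        model; doubled for the three-level model, whose latent chain and
        coefficients converge more slowly (the publication-scale settings
        scale it up five-fold for the same reason)."""
        if model == "three_level":
            return cls(n_iterations=8_000, burn_in=4_000, seed=seed)
        return cls(n_iterations=4_000, burn_in=2_000, seed=seed)


@dataclass(frozen=True)
class MortalityEstimate:
    """Posterior summary of a collision total (95% equal-tail interval)."""

    mean: float
    median: float
    credible_lower: float
    credible_upper: float

    def __post_init__(self) -> None:
        if not (self.credible_lower <= self.median <= self.credible_upper):
            raise ValidationError("require lower <= median <= upper")


@dataclass
class PosteriorSamples:
    """Pooled post-burn-in draws from all chains.

    ``detection`` maps parameter name ("p" for the one-level model, "s"
    and "f" for the three-level one) to a (draws x turbines) array;
    ``latent_totals`` holds the per-turbine collision totals N_i. per
    draw.
    """

    model: str
    turbine_ids: list[str]
    coefficients: np.ndarray
    chain: np.ndarray
    detection: dict[str, np.ndarray]
    latent_totals: np.ndarray
    standardization: StandardizationParams
    config: McmcConfig
    rhat: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.coefficients.shape[0]

    @property
    def total_draws(self) -> np.ndarray:
        """Grand-total collision draws (sum over turbines, draw-wise)."""
        return self.latent_totals.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"chain": self.chain}
        for k, name in enumerate(COEF_NAMES):
            cols[name] = self.coefficients[:, k]
        for pname, arr in self.detection.items():
            for j, tid in enumerate(self.turbine_ids):
                cols[f"{pname}_{tid}"] = arr[:, j]
        for j, tid in enumerate(self.turbine_ids):
            cols[f"N_total_{tid}"] = self.latent_totals[:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Flat data layout


@dataclass
class _FlatData:
    """Night table flattened to aligned arrays, blocks per turbine."""

    tids: list[str]
    tidx: np.ndarray      # turbine index per row
    c: np.ndarray         # observed count (0 on unsearched nights)
    searched: np.ndarray  # bool
    first: np.ndarray     # bool, night_index == 1
    last: np.ndarray      # bool, final night of its turbine
    parity: np.ndarray    # (night_index - 1) % 2, for red-black updates
    X: np.ndarray         # design matrix (1, zA, zW, zW^2)
    sp: StandardizationParams

    @property
    def n_rows(self) -> int:
        return len(self.c)

    @property
    def n_turbines(self) -> int:
        return len(self.tids)


def _flatten(data: Dataset, sp: Optional[StandardizationParams]) -> _FlatData:
    nights = sorted(data.nights, key=lambda r: (r.turbine_id, r.night_index))
    if not nights:
        raise ValidationError("dataset has no night records")
    tids = []
    for r in nights:
        if not tids or tids[-1] != r.turbine_id:
            tids.append(r.turbine_id)
    pos = {t: i for i, t in enumerate(tids)}
    tidx = np.array([pos[r.turbine_id] for r in nights])
    c = np.array([r.carcass_count for r in nights])
    searched = np.array([r.searched for r in nights])
    night = np.array([r.night_index for r in nights])
    first = night == 1
    last = np.append(first[1:], True)
    if sp is None:
        sp = StandardizationParams.from_nights(nights)
    zA, zW = sp.apply([r.activity for r in nights], [r.wind for r in nights])
    return _FlatData(tids=tids, tidx=tidx, c=c, searched=searched,
                     first=first, last=last, parity=(night - 1) % 2,
                     X=design_matrix(zA, zW), sp=sp)


def priors_from_dataset(data: Dataset) -> dict[str, DetectionPriors]:
    """Moment-matched detection priors for every turbine in the dataset."""
    return {tid: detection_priors(det)
            for tid, det in data.detections.items()}


def _as_prior(spec) -> PriorSpec:
    if isinstance(spec, (BetaSpec, PointMass)):
        return spec
    raise ValidationError(f"expected BetaSpec or PointMass, got {type(spec)}")


# ---------------------------------------------------------------------------
# Shared sampler pieces


def _init_coefficients(fd: _FlatData, det_eff: np.ndarray) -> np.ndarray:
    """Crude Poisson-IRLS fit of counts on covariates with a detection
    offset, used only to start the chains near the posterior bulk."""
    mask = fd.searched
    X, y = fd.X[mask], fd.c[mask].astype(float)
    offset = np.log(np.clip(det_eff[fd.tidx[mask]], 1e-3, 1.0))
    beta = np.zeros(4)
    beta[0] = np.log((y.sum() + 0.5) / np.exp(offset).sum())
    for _ in range(25):
        eta = np.clip(X @ beta + offset, -30.0, 5.0)
        mu = np.exp(eta)
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * mu
        try:
            new = np.linalg.solve(XtW @ X + 1e-6 * np.eye(4), XtW @ z)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(new)):
            break
        if np.max(np.abs(new - beta)) < 1e-8:
            beta = new
            break
        beta = new
    if not np.all(np.isfinite(beta)):
        beta = np.array([np.log((y.sum() + 0.5) / max(len(y), 1)), 0, 0, 0])
    return np.clip(beta, -10.0, 10.0)


class _CoefSampler:
    """Metropolis sampler for the 4 coefficients; keeps eta = X beta cached.

    Each sweep does four single-coordinate Gaussian random-walk updates
    (step sizes adapted toward ~30% acceptance during burn-in) plus one
    joint proposal from a multivariate normal whose covariance is learned
    from the burn-in history — the wind and wind^2 coefficients are
    strongly correlated and coordinate-wise walks alone mix them slowly.
    All adaptation freezes at the end of burn-in.
    """

    def __init__(self, X, init, scale, fixed, rng):
        self.X = X
        self.beta = init.astype(float).copy()
        self.scales = np.full(4, scale)
        self.fixed = fixed
        self.rng = rng
        self.eta = X @ self.beta
        self.lam = np.exp(np.clip(self.eta, -700, 700))
        self._acc = np.zeros(4)
        self._tries = np.zeros(4)
        self._history: list[np.ndarray] = []
        self._chol: Optional[np.ndarray] = None

    def _dll(self, N, eta_prop, lam_prop, prop):
        return (np.dot(N, eta_prop - self.eta)
                - (lam_prop.sum() - self.lam.sum())
                + float(self.beta @ self.beta - prop @ prop) / 200.0)

    def update(self, N: np.ndarray, adapt: bool) -> None:
        if self.fixed:
            return
        for k in range(4):
            step = self.scales[k] * self.rng.normal()
            prop = self.beta.copy()
            prop[k] += step
            eta_prop = self.eta + step * self.X[:, k]
            lam_prop = np.exp(np.clip(eta_prop, -700, 700))
            self._tries[k] += 1
            if np.log(self.rng.random()) < self._dll(N, eta_prop, lam_prop, prop):
                self.beta = prop
                self.eta = eta_prop
                self.lam = lam_prop
                self._acc[k] += 1
            if adapt and self._tries[k] >= 50:
                rate = self._acc[k] / self._tries[k]
                if rate > 0.35:
                    self.scales[k] *= 1.15
                elif rate < 0.2:
                    self.scales[k] *= 0.85
                self._acc[k] = 0.0
                self._tries[k] = 0.0
        if adapt:
            self._history.append(self.beta.copy())
            if len(self._history) >= 500 and len(self._history) % 250 == 0:
                cov = np.cov(np.array(self._history[-1500:]).T)
                try:
                    self._chol = np.linalg.cholesky(
                        cov + 1e-8 * np.eye(4)) * (2.38 / 2.0)
                except np.linalg.LinAlgError:
                    pass
        if self._chol is not None:
            prop = self.beta + self._chol @ self.rng.normal(size=4)
            eta_prop = self.X @ prop
            lam_prop = np.exp(np.clip(eta_prop, -700, 700))
            if np.log(self.rng.random()) < self._dll(N, eta_prop, lam_prop, prop):
                self.beta = prop
                self.eta = eta_prop
                self.lam = lam_prop


def _beta_update(prior: PriorSpec, successes: float, failures: float,
                 current: float, rng) -> float:
    if isinstance(prior, PointMass):
        return current
    return rng.beta(prior.alpha + successes, prior.beta + failures)


def _chain_rng(cfg: McmcConfig, chain: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(chain,)))


# ---------------------------------------------------------------------------
# One-level fit


def fit_one_level(
    data: Dataset,
    priors: Optional[Mapping[str, Union[PriorSpec, DetectionPriors]]] = None,
    cfg: Optional[McmcConfig] = None,
    standardization: Optional[StandardizationParams] = None,
) -> PosteriorSamples:
    """Posterior sampling for the one-level observation model.

    ``priors`` maps turbine id to the Beta prior on its detection
    probability p (a :class:`DetectionPriors` bundle is accepted and its
    ``p`` used); omitted, it is derived from ``data.detections``.
    """
    cfg = cfg or McmcConfig.one_level_default()
    fd = _flatten(data, standardization)
    if priors is None:
        priors = priors_from_dataset(data)
    p_priors = []
    for tid in fd.tids:
        if tid not in priors:
            raise ValidationError(f"no prior supplied for turbine {tid}")
        spec = priors[tid]
        p_priors.append(_as_prior(spec.p if isinstance(spec, DetectionPriors)
                                  else spec))

    succ = np.bincount(fd.tidx[fd.searched], weights=fd.c[fd.searched],
                       minlength=fd.n_turbines)
    det_eff = np.array([pr.mean for pr in p_priors])
    init = (cfg.fix_coefficients.as_array() if cfg.fix_coefficients
            else _init_coefficients(fd, det_eff))

    keep = (cfg.n_iterations - cfg.burn_in) // cfg.thin
    chains = []
    for chain in range(cfg.n_chains):
        rng = _chain_rng(cfg, chain)
        beta0 = init if cfg.fix_coefficients else init + 0.05 * rng.normal(size=4)
        coef = _CoefSampler(fd.X, beta0, cfg.proposal_scale,
                            cfg.fix_coefficients is not None, rng)
        p = det_eff.copy()
        rec = {"coef": np.empty((keep, 4)),
               "p": np.empty((keep, fd.n_turbines)),
               "totals": np.empty((keep, fd.n_turbines))}
        r = 0
        for it in range(cfg.n_iterations):
            # latent counts: exact conditional
            mean = np.where(fd.searched, coef.lam * (1.0 - p[fd.tidx]),
                            coef.lam)
            N = np.where(fd.searched, fd.c, 0) + rng.poisson(mean)
            # detection probabilities: conjugate Beta
            fail = np.bincount(fd.tidx[fd.searched],
                               weights=(N - fd.c)[fd.searched],
                               minlength=fd.n_turbines)
            for j, pr in enumerate(p_priors):
                p[j] = _beta_update(pr, succ[j], fail[j], p[j], rng)
            coef.update(N, adapt=it < cfg.burn_in)
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                rec["coef"][r] = coef.beta
                rec["p"][r] = p
                rec["totals"][r] = np.bincount(fd.tidx, weights=N,
                                               minlength=fd.n_turbines)
                r += 1
        chains.append(rec)

    return _assemble(fd, cfg, chains, model="one_level",
                     detection_names=("p",))


# ---------------------------------------------------------------------------
# Three-level fit


def fit_three_level(
    data: Dataset,
    s_priors: Optional[Mapping[str, PriorSpec]] = None,
    f_priors: Optional[Mapping[str, PriorSpec]] = None,
    fall_in: Optional[Mapping[str, float]] = None,
    cfg: Optional[McmcConfig] = None,
    standardization: Optional[StandardizationParams] = None,
) -> PosteriorSamples:
    """Posterior sampling for the three-level observation model.

    ``s_priors`` / ``f_priors`` map turbine id to the Beta priors on
    persistence and searcher efficiency; ``fall_in`` gives the known
    fall-in proportion a_i.  Any omitted argument is derived from
    ``data.detections``.
    """
    cfg = cfg or McmcConfig.three_level_default()
    fd = _flatten(data, standardization)
    derived = priors_from_dataset(data) if (
        s_priors is None or f_priors is None or fall_in is None) else None
    s_list, f_list, a_arr = [], [], np.empty(fd.n_turbines)
    for j, tid in enumerate(fd.tids):
        s_spec = s_priors[tid] if s_priors is not None else derived[tid].s
        f_spec = f_priors[tid] if f_priors is not None else derived[tid].f
        a_val = fall_in[tid] if fall_in is not None else derived[tid].fall_in
        s_list.append(_as_prior(s_spec))
        f_list.append(_as_prior(f_spec))
        if not 0.0 < a_val <= 1.0:
            raise ValidationError(
                f"turbine {tid}: fall-in must be in (0, 1], got {a_val}")
        a_arr[j] = a_val

    det_eff = a_arr * np.array([s.mean for s in s_list]) \
        * np.array([f.mean for f in f_list])
    init = (cfg.fix_coefficients.as_array() if cfg.fix_coefficients
            else _init_coefficients(fd, det_eff))

    M = fd.n_rows
    prev = np.maximum(np.arange(M) - 1, 0)
    nxt = np.minimum(np.arange(M) + 1, M - 1)
    cc = np.where(fd.searched, fd.c, 0)
    succ_f = np.bincount(fd.tidx[fd.searched], weights=fd.c[fd.searched],
                         minlength=fd.n_turbines)
    keep = (cfg.n_iterations - cfg.burn_in) // cfg.thin

    def carry_of(rem):
        cr = (rem - cc)[prev]
        cr[fd.first] = 0
        return cr

    chains = []
    for chain in range(cfg.n_chains):
        rng = _chain_rng(cfg, chain)
        beta0 = init if cfg.fix_coefficients else init + 0.05 * rng.normal(size=4)
        coef = _CoefSampler(fd.X, beta0, cfg.proposal_scale,
                            cfg.fix_coefficients is not None, rng)
        s = np.array([x.mean for x in s_list])
        f = np.array([x.mean for x in f_list])
        # start on the observed path: every found carcass fell and
        # persisted the night it was found; satisfies all invariants
        N = cc.copy()
        fallen = cc.copy()
        rem = cc.copy()
        a_row = a_arr[fd.tidx]
        rec = {"coef": np.empty((keep, 4)),
               "s": np.empty((keep, fd.n_turbines)),
               "f": np.empty((keep, fd.n_turbines)),
               "totals": np.empty((keep, fd.n_turbines))}
        r = 0
        for it in range(cfg.n_iterations):
            with np.errstate(divide="ignore"):
                ln_s, ln_1ms = np.log(s), np.log1p(-s)
                ln_1mf = np.log1p(-f)
            ln_1ms_row = ln_1ms[fd.tidx]
            # fall-ins: +/-1 Metropolis with the collisions N integrated
            # out (marginally fallen ~ Poisson(lambda a)), so moves are
            # not gated by the current N; the exact conditional draw of N
            # below keeps the joint state consistent
            avail = carry_of(rem) + fallen
            delta = rng.integers(0, 2, M) * 2 - 1
            prop = fallen + delta
            up = delta > 0
            feas = (prop >= 0) & (avail + delta >= rem)
            ln_lam_a = np.log(coef.lam) + np.log(a_row)
            with np.errstate(divide="ignore", invalid="ignore"):
                logr = (delta * ln_lam_a
                        - np.log(np.where(up, fallen + 1.0, fallen))
                        * delta
                        + np.log(np.where(up, avail + 1, avail - rem))
                        - np.log(np.where(up, avail + 1 - rem, avail))
                        + delta * ln_1ms_row)
            acc = feas & (np.log(rng.random(M)) < logr)
            fallen = np.where(acc, prop, fallen)
            # collisions: exact conditional given the fall-ins
            N = fallen + rng.poisson(coef.lam * (1.0 - a_row))
            # remaining: red-black +/-1 Metropolis (site t couples to t+1
            # through the carry-over, so alternate night parities)
            for par in (0, 1):
                avail = carry_of(rem) + fallen
                m = fd.parity == par
                delta = rng.integers(0, 2, M) * 2 - 1
                prop = rem + delta
                up = delta > 0
                av_next = avail[nxt]
                rem_next = rem[nxt]
                down_ok = fd.last | (av_next + delta >= rem_next)
                feas = m & (prop >= cc) & (prop <= avail) & down_ok
                with np.errstate(divide="ignore", invalid="ignore"):
                    persist = (np.log(np.where(up, avail - rem, rem))
                               - np.log(np.where(up, rem + 1,
                                                 avail - rem + 1))
                               + delta * (ln_s - ln_1ms)[fd.tidx])
                    search = (np.log(np.where(up, rem + 1, rem - cc))
                              - np.log(np.where(up, rem + 1 - cc, rem))
                              + delta * ln_1mf[fd.tidx])
                    down = (np.log(np.where(up, av_next + 1,
                                            av_next - rem_next))
                            - np.log(np.where(up, av_next + 1 - rem_next,
                                              av_next))
                            + delta * ln_1ms[fd.tidx[nxt]])
                    logr = (persist
                            + np.where(fd.searched, search, 0.0)
                            + np.where(fd.last, 0.0, down))
                acc = feas & (np.log(rng.random(M)) < logr)
                rem = np.where(acc, prop, rem)
            # persistence and efficiency: conjugate Beta
            avail = carry_of(rem) + fallen
            succ_s = np.bincount(fd.tidx, weights=rem, minlength=fd.n_turbines)
            fail_s = np.bincount(fd.tidx, weights=avail - rem,
                                 minlength=fd.n_turbines)
            fail_f = np.bincount(fd.tidx[fd.searched],
                                 weights=(rem - fd.c)[fd.searched],
                                 minlength=fd.n_turbines)
            for j in range(fd.n_turbines):
                s[j] = _beta_update(s_list[j], succ_s[j], fail_s[j], s[j], rng)
                f[j] = _beta_update(f_list[j], succ_f[j], fail_f[j], f[j], rng)
            coef.update(N, adapt=it < cfg.burn_in)
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                rec["coef"][r] = coef.beta
                rec["s"][r] = s
                rec["f"][r] = f
                rec["totals"][r] = np.bincount(fd.tidx, weights=N,
                                               minlength=fd.n_turbines)
                r += 1
        chains.append(rec)

    return _assemble(fd, cfg, chains, model="three_level",
                     detection_names=("s", "f"))


# ---------------------------------------------------------------------------
# Assembly, diagnostics, summaries


def _assemble(fd, cfg, chains, model, detection_names) -> PosteriorSamples:
    keep = chains[0]["coef"].shape[0]
    samples = PosteriorSamples(
        model=model,
        turbine_ids=list(fd.tids),
        coefficients=np.concatenate([ch["coef"] for ch in chains]),
        chain=np.repeat(np.arange(len(chains)), keep),
        detection={name: np.concatenate([ch[name] for ch in chains])
                   for name in detection_names},
        latent_totals=np.concatenate([ch["totals"] for ch in chains]),
        standardization=fd.sp,
        config=cfg,
    )
    if cfg.n_chains >= 2 and keep >= 10:
        samples.rhat = gelman_rubin(samples)
        bad = {k: v for k, v in samples.rhat.items() if v > RHAT_THRESHOLD}
        if bad:
            msg = ("convergence not reached (R-hat > "
                   f"{RHAT_THRESHOLD}): {bad}")
            samples.warnings.append(msg)
            warnings.warn(msg, ConvergenceWarning)
    return samples


def _psrf(series: np.ndarray, chain: np.ndarray) -> float:
    """Classic potential scale reduction factor over the recorded
    (post-burn-in) portion of each chain; floored at 1."""
    labels = np.unique(chain)
    groups = [series[chain == g] for g in labels]
    n = min(len(g) for g in groups)
    groups = [g[:n] for g in groups]
    W = float(np.mean([np.var(g, ddof=1) for g in groups]))
    means = np.array([np.mean(g) for g in groups])
    B_over_n = float(np.var(means, ddof=1))
    if W <= 0.0:
        return 1.0
    var_plus = (n - 1) / n * W + B_over_n
    return max(1.0, float(np.sqrt(var_plus / W)))


def gelman_rubin(samples: PosteriorSamples) -> dict[str, float]:
    """Brooks-Gelman-Rubin R-hat per parameter (coefficients, detection
    parameters, per-turbine and grand latent totals).

    Values above 1.1 indicate non-convergence.  Requires >= 2 chains and
    >= 10 recorded draws per chain.
    """
    n_chains = len(np.unique(samples.chain))
    if n_chains < 2:
        raise ValidationError("R-hat needs at least 2 chains")
    per_chain = samples.n_draws // n_chains
    if per_chain < 10:
        raise ValidationError("R-hat needs at least 10 draws per chain")
    out = {}
    fixed_coef = samples.config.fix_coefficients is not None
    for k, name in enumerate(COEF_NAMES):
        if not fixed_coef:
            out[name] = _psrf(samples.coefficients[:, k], samples.chain)
    for pname, arr in samples.detection.items():
        for j, tid in enumerate(samples.turbine_ids):
            if arr[:, j].std() > 0:
                out[f"{pname}_{tid}"] = _psrf(arr[:, j], samples.chain)
    out["N_total"] = _psrf(samples.total_draws, samples.chain)
    return out


def _summary(draws: np.ndarray) -> MortalityEstimate:
    lower, median, upper = np.percentile(draws, [2.5, 50.0, 97.5])
    return MortalityEstimate(mean=float(np.mean(draws)), median=float(median),
                             credible_lower=float(lower),
                             credible_upper=float(upper))


def mortality_summary(
    samples: PosteriorSamples,
    by: Literal["turbine", "total"] = "total",
) -> Union[MortalityEstimate, dict[str, MortalityEstimate]]:
    """Posterior mean/median and 95% equal-tail interval of collision
    totals, per turbine or summed over all turbines."""
    if samples.n_draws == 0:
        raise ValidationError("empty posterior sample")
    if by == "total":
        return _summary(samples.total_draws)
    if by == "turbine":
        return {tid: _summary(samples.latent_totals[:, j])
                for j, tid in enumerate(samples.turbine_ids)}
    raise ValidationError(f"unknown grouping {by!r}")


def predict_new(
    samples: PosteriorSamples,
    covariates: Sequence[NightRecord],
    sp: Optional[StandardizationParams] = None,
    rng: Union[np.random.Generator, int, None] = None,
) -> MortalityEstimate:
    """Posterior predictive collision total for new turbine-nights.

    Covariates are standardized with the *training* moments; for each
    posterior coefficient draw a Poisson total is simulated, giving a
    predictive distribution that carries both parameter and collision
    stochasticity.  No carcass-search data is needed.
    """
    covariates = list(covariates)
    if not covariates:
        return MortalityEstimate(0.0, 0.0, 0.0, 0.0)
    sp = sp or samples.standardization
    rng = np.random.default_rng(rng)
    zA, zW = sp.apply([r.activity for r in covariates],
                      [r.wind for r in covariates])
    X = design_matrix(zA, zW)
    eta = samples.coefficients @ X.T          # draws x nights
    lam = np.exp(np.clip(eta, -700, 700))
    totals = rng.poisson(lam).sum(axis=1)
    return _summary(totals)
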