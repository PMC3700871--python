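# Methods

`windmort` estimates the number of birds or bats killed by wind-turbine
rotor blades from morning carcass searches, acoustic activity recordings
and nightly wind speed, using a hierarchical N-mixture model: a latent
count process (collisions per turbine-night) observed through an
imperfect, explicitly modelled detection process.

## The model

### Collision process

For turbine *i* and night *t* the number of collisions is

    N_it ~ Poisson(λ_it),
    log λ_it = α0 + α1·zA_it + α2·zW_it + α3·zW_it²,

where `zA` is the z-standardized acoustic activity index (number of bat
echolocation recordings per night at the nacelle) and `zW` the
z-standardized nightly median wind speed. The quadratic wind term lets
the rate peak at intermediate wind: below ~2 m/s the rotor barely moves,
while at high wind bat activity collapses. Coefficients carry
Normal(0, 100) priors (effectively flat). Covariates are standardized
with the sample standard deviation (n−1 denominator) over the analysed
data set; the moments are stored so that held-out or future nights are
standardized with the *training* moments.

### Observation process

Two variants link collisions to carcasses found:

* **One-level:** `c_it ~ Binomial(N_it, p_i)` with `p_i` the composite
  carcass detection probability. It assumes every carcass found at
  search *t* was killed during interval *t* — no carry-over of
  overlooked carcasses.
* **Three-level:** an explicit chain with carry-over. Per night,
  `fallen ~ Binomial(N, a_i)` carcasses land inside the searched plot;
  the pool present before scavenging is

      available_t = remaining_{t−1} − found_{t−1} + fallen_t,

  with `available_1 = fallen_1` (clean plot at study start);
  `remaining ~ Binomial(available, s_i)` survive scavengers for the 24 h
  until the search; `found ~ Binomial(remaining, f_i)`; found carcasses
  are removed by the searcher. Nights without a search receive the
  persistence thinning but not the search thinning (found is 0 and the
  pool carries over); with daily searches this extension is inert.

Detection parameters come from independent field experiments and enter
as moment-matched Beta priors: a reported point estimate *m* with 95% CI
is converted to `se = width/(2·1.96)` and then to
`Beta(m·ν, (1−m)·ν)` with `ν = m(1−m)/se² − 1`. Asymmetric or
typesetting-inconsistent CIs are symmetrized — only the width is used.
A se below 1e-6 is treated as a known constant rather than an extreme
Beta (numerical stability). The fall-in proportion `a_i` is always
treated as known without error.

## Posterior sampling

Metropolis-within-Gibbs, two chains by default, with exact conjugate
updates wherever available (they double as test oracles):

* one-level latent counts: `N_it − c_it | rest ~ Poisson(λ_it(1−p_i))`,
  drawn directly;
* three-level collisions given fall-ins:
  `N_it − fallen_it | rest ~ Poisson(λ_it(1−a_i))`;
* detection probabilities: conjugate Beta updates from their binomial
  likelihood terms;
* three-level fall-ins: ±1 Metropolis proposals evaluated with `N`
  marginalized out (`fallen ~ Poisson(λ a)` marginally) followed by the
  exact conditional redraw of `N`. Conditioning the move on the current
  `N` instead would gate upward moves on an event of probability
  ≈ λ(1−a) per sweep and freeze the latent allocation;
* three-level remaining-carcass counts: ±1 Metropolis in a red–black
  (odd/even night) schedule, since night *t* couples to *t+1* through
  the carry-over; any proposal violating a chain invariant has density
  zero;
* coefficients: four single-coordinate Gaussian random walks (step
  sizes adapted toward ~30% acceptance) plus one joint multivariate
  proposal whose covariance is learned from the burn-in history — the
  wind and wind² coefficients are strongly correlated and coordinate
  walks alone mix them slowly. All adaptation freezes at the end of
  burn-in, keeping the post-burn-in chain Markovian.

Sampler correctness is verified in the test suite against brute-force
path enumeration on small problems (total-variation distance < 0.02)
and against the exact marginal Poisson regression that the one-level
model reduces to when `p` is known.

Defaults follow the motivating study: 20,000 iterations / 10,000
burn-in (one-level) and 100,000 / 90,000 (three-level, which converges
more slowly). The desk-scale test profile uses 4,000 / 2,000 and
8,000 / 4,000 respectively — the three-level profile is doubled for the
same slow-convergence reason the full-scale setting is quintupled.
Convergence is assessed with the classic Brooks–Gelman–Rubin potential
scale reduction factor computed on the post-burn-in portion of each
chain (floored at 1; threshold 1.1); non-convergence attaches a warning
to the result rather than failing silently. Seeded runs are
bit-reproducible; chain *k* of seed *s* uses the NumPy seed sequence
`(s, spawn_key=(k,))`.

Mortality estimates are posterior means/medians with 95% equal-tail
credible intervals of the latent totals `N_i· = Σ_t N_it` (per turbine)
and their draw-wise grand total. Reported intervals are always
equal-tail quantiles, and are labelled as such in all outputs.

## Corrected-count comparator

The conventional covariate-free estimator inverts the found total
through the detection probability with Bayes' theorem: under a flat
prior on the kill total N, `N − C | C, p ~ NegBinomial(C+1, p)` with
mean `(C+1)/p − 1`. Uncertainty in p is propagated by Monte Carlo,
mixing that posterior over Beta draws of p (zero draws are redrawn);
the reported mean is Rao-Blackwellized. Pooled study totals use an
effort-weighted prior: the mean and CI width of `p_i` weighted by the
number of searches `T_i`. The pooled reading reproduces the published
totals; summing per-turbine posteriors instead gives a visibly larger
2007 total because low-effort, low-p turbines are no longer
down-weighted.

## Synthetic data generator

The nightly field records behind the motivating study are not public,
so the simulator is the package's stand-in for them and defines the
conditions under which the estimators are validated:

* **Covariates.** Bootstrap mode resamples observed (activity, wind)
  *pairs* with replacement within turbine, preserving their negative
  correlation and the between-turbine variance. Parametric mode (the
  default when no source table exists) draws nightly wind from a
  truncated normal with mean 5.5 m/s, SD 1.8 (the published 2008
  moments), and activity from a negative binomial with
  `log μ = 3.9 − 0.25·wind` and dispersion 0.8 — calibrated to ~13
  recordings per night overall (≈16,000 recordings over 1,225
  turbine-nights) with the overdispersion and activity–wind sign
  typical of nacelle recordings. The parametric generator has no
  night-to-night weather autocorrelation and no seasonal phenology;
  passing tests therefore demonstrate recovery under realistic
  marginals and cross-correlation, not under serial dependence.
* **Collisions and carcasses.** Coefficients default to the published
  2008 three-level posterior means (−4.1, 0.5, −2.9, −1.3), giving a
  sparse ~0.05 collisions per turbine-night (≥96% of searches find
  nothing, matching the field data); a user-supplied coefficient draw
  table is accepted where a joint posterior is available. Collisions
  are pushed through the full three-level chain with each turbine's
  a/s/f point values from the bundled 30-turbine table; searches happen
  nightly.
* **Recovery experiment.** 20 replicates of 18 turbines × 100 nights,
  one random turbine held out, three-level fit at the desk profile.
  Checks: each coefficient's 95% CrI covers its generating value in
  ≥80% of replicates; the median estimated/true per-turbine mortality
  ratio lies in [0.7, 1.4]; the median held-out prediction ratio lies
  within a factor of two. Problem sizes keep the whole experiment at a
  few minutes on one CPU; at these sizes (~4–5 true kills per turbine)
  per-replicate posteriors are wide, which the thresholds reflect.

## Numerical and design choices

* Binomial log-pmfs are computed with `gammaln`/`xlogy` so that point
  masses at 0 or 1 (perfect detection limits) are handled exactly; in
  the lossless limit a = s = f = 1 the posterior collapses onto the
  observed counts in every draw, which tests assert.
* Posterior totals can never fall below observed totals — a structural
  invariant of the latent chain, asserted per draw.
* Enumeration-based tests truncate latent counts at `c + 30`; at the
  rates in play the truncated mass is < 1e-12. The sampler itself is
  untruncated.
* The wind of maximum collision rate is the closed form
  `wind_mean + wind_sd · (−α2/(2α3))`, defined only for α3 < 0;
  reported values are rounded half-up to one decimal, matching the
  published 4.3 / 5.7 / 3.5 m/s.
* Ratio-of-totals bias summaries exclude turbines with a true total of
  zero (the ratio is undefined; they are counted separately) instead of
  propagating infinities.
* Posterior predictive checks simulate a complete data set through the
  fitted model's own observation chain for every 10th retained draw and
  tabulate carcasses-found-per-search frequencies with 2.5/50/97.5%
  quantiles. Interval bounds are equal-tail quantiles of the simulated
  frequencies.
* Year-specific analyses standardize covariates within the analysed
  data set (the two study years were analysed separately).

## Known limitations

* Persistence is a single 24-h Bernoulli thinning per night; there is
  no continuous-time decay within the interval and no sub-daily timing
  of death.
* Detection parameters are time-constant per turbine by default
  (`a_it = a_i`); the observation API accepts per-night values but the
  fitting routines currently use per-turbine parameters.
* The one-level model inherits its same-night assumption; the package
  exposes both models and applies no correction for the bias this may
  induce.
* Coefficients are not identified separately from strongly collinear
  covariates (wind and activity correlate); predictions for realistic
  covariate pairs are unaffected, but individual coefficients should be
  interpreted with care.
* Prediction for new turbines assumes the covariate–collision
  relationship transfers; nothing in the model checks that assumption.
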