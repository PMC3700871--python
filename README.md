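# windmort

Estimating bird and bat collision mortality at wind-energy turbines
from carcass searches, acoustic activity and wind speed.

Carcass searches under turbines vastly undercount the animals actually
killed: carcasses fall outside the searched plot, are removed by
scavengers, or are overlooked. Dividing the found count by an estimated
detection probability ("corrected counts") fixes the level but says
nothing about *when* collisions happen, and is wildly unstable when few
carcasses are found. `windmort` implements a hierarchical N-mixture
model that combines the nightly search counts with covariates of the
collision rate — an acoustic bat-activity index and wind speed measured
at the nacelle — and with independently estimated detection parameters,
yielding mortality estimates per turbine and night, and predictions for
turbines or nights with no searches at all. It is aimed at ecological
consultants and researchers monitoring wind-energy impacts on bats and
birds.

## Model

Collisions per turbine *i* and night *t* follow

    N_it ~ Poisson(λ_it),     log λ_it = α0 + α1·zA_it + α2·zW_it + α3·zW_it²

with standardized activity `zA` and wind `zW`. Found carcasses arise
from a binomial observation model: either directly,
`c_it ~ Binom(N_it, p_i)` (one-level), or through an explicit chain of
falling into the searched plot (`a_i`), persisting against scavengers
(`s_i`) with carry-over of unfound carcasses between nights, and being
found by the searcher (`f_i`) (three-level). Detection parameters from
field trials enter as moment-matched Beta priors. Inference is MCMC
(Metropolis-within-Gibbs with exact conjugate updates where they
exist); the conventional corrected-count estimator
`N − C | C, p ~ NegBinom(C+1, p)` with Monte-Carlo propagation of the
uncertainty in `p` is included as the comparator, along with the full
data simulator and evaluation tools (bias ratios, posterior predictive
checks). See `docs/methods.md` for the complete account.

The detection table of the 30-turbine German study that motivated the
model ships with the package, as do the per-year aggregates and the
published coefficient means.

## Worked example

```python
import numpy as np
from windmort import (
    load_example_detection_table, summarize_dataset,
    estimate_corrected_per_turbine,
    SimConfig, simulate_replicate, McmcConfig,
    fit_three_level, mortality_summary,
)

dets = load_example_detection_table()
print(summarize_dataset(dets).to_string(index=False))

res = estimate_corrected_per_turbine(
    [d for d in dets if d.year == 2007], mode="pooled",
    n_draws=100_000, rng=1)
print(f"2007 corrected count: {res.mean:.1f} "
      f"(95% CrI {res.credible_lower:.0f}-{res.credible_upper:.0f})")

rep = simulate_replicate(SimConfig(n_turbines=18,
                                   nights_per_turbine=100, seed=7))
print("simulated true total:", sum(rep.true_totals().values()),
      "| carcasses found:", sum(r.carcass_count for r in rep.dataset.nights))

samples = fit_three_level(
    rep.dataset, cfg=McmcConfig.test_profile(seed=1, model="three_level"))
est = mortality_summary(samples, by="total")
print(f"estimated total mortality: {est.mean:.1f} "
      f"(95% CrI {est.credible_lower:.0f}-{est.credible_upper:.0f})")
print("coefficient posterior means:", samples.coefficients.mean(0).round(2))
```

prints

```
 year  n_turbines  total_carcasses  turbine_nights  mean_detection
 2007          12               22             473        0.585833
 2008          18               35            1225        0.611667
2007 corrected count: 39.1 (95% CrI 27-59)
simulated true total: 88 | carcasses found: 57
estimated total mortality: 94.0 (95% CrI 78-113)
coefficient posterior means: [-3.75  0.48 -2.62 -1.22]
```

Reading it: the bundled study found 22 carcasses over 473 turbine-nights
in 2007; inverting them through the effort-weighted detection
probability gives ≈39 kills (CrI 27–59). The simulated study generated
88 true collisions of which searches recovered 57; the three-level
model, fitted at the reduced desk profile and seeing only the 57 counts
plus covariates, estimates 94 (CrI 78–113), covering the truth, and
recovers coefficient values near the generating (−4.1, 0.5, −2.9, −1.3).

A command-line interface wraps the same functionality:

```sh
windmort simulate sim.yaml --seed 1 --out-dir sims/
windmort fit sims/replicate_001/nights.csv sims/replicate_001/detection.csv \
         --model three_level --out-dir fit/
windmort corrected src/windmort/data/table2_detection.csv --year 2007
windmort predict fit/draws.csv new_nights.csv
windmort ppc fit/draws.csv nights.csv detection.csv
```

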