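"""Stochastic observation process linking collisions to found carcasses.

Two variants:

* **one-level** — the count found at search t is a single binomial
  thinning of that night's collisions, c_it ~ Binom(N_it, p_i), with p
  the composite carcass detection probability.  This assumes every
  carcass found at search t was killed during interval t.
* **three-level** — an explicit chain with carcass carry-over.  Per
  night: fallen ~ Binom(N, a) carcasses land in the searched plot; the
  pool available before scavenging is last night's survivors minus what
  the searcher removed plus the fresh falls,

      available_t = remaining_{t-1} - found_{t-1} + fallen_t,

  (available_1 = fallen_1: the plot starts clean); remaining ~
  Binom(available, s) survive scavengers for the 24 h until the search;
  and found ~ Binom(remaining, f).  Found carcasses are removed from the
  field by the searcher.

On a night without a search the persistence thinning still applies but
no search thinning does: found is 0 and the whole remaining pool carries
over.  With daily searches (the usual design) that extension is inert.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln, xlog1py, xlogy

from .data_io import NightRecord, ValidationError

__all__ = [
    "LatentState",
    "simulate_one_level",
    "loglik_one_level",
    "step_three_level",
    "simulate_three_level_path",
    "loglik_three_level_path",
    "binom_logpmf",
]


def binom_logpmf(k, n, p):
    """Vectorized log Binomial(k | n, p), -inf outside support.

    Handles p in {0, 1} exactly (xlogy/xlog1py conventions), which the
    samplers rely on for point-mass detection parameters.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)
               + xlogy(k, p) + xlog1py(n - k, -p))
    return np.where((k < 0) | (k > n), -np.inf, out)


@dataclass
class LatentState:
    """Latent counts of the three-level chain for one turbine.

    Arrays are aligned by night.  ``found`` equals the observed carcass
    counts once the state is conditioned on data; ``total`` is the latent
    number of collisions N_i. that mortality estimation targets.
    """

    collisions: np.ndarray   # N_it
    fallen: np.ndarray       # into the searched plot
    available: np.ndarray    # present before the night's scavenging
    remaining: np.ndarray    # still present at search time
    found: np.ndarray

    @property
    def total(self) -> int:
        return int(self.collisions.sum())

    def validate(self) -> None:
        c, fa, av, re, fo = (self.collisions, self.fallen, self.available,
                             self.remaining, self.found)
        if not (len(c) == len(fa) == len(av) == len(re) == len(fo)):
            raise ValidationError("latent arrays must have equal length")
        if np.any(fa > c) or np.any(re > av) or np.any(fo > re):
            raise ValidationError("latent chain ordering violated")
        if np.any((c < 0) | (fa < 0) | (av < 0) | (re < 0) | (fo < 0)):
            raise ValidationError("latent counts must be non-negative")
        carry = np.concatenate([[0], re[:-1] - fo[:-1]])
        if np.any(av != carry + fa):
            raise ValidationError("carry-over recursion violated")


def simulate_one_level(N: int, p: float, rng: np.random.Generator) -> int:
    """Carcasses found under the one-level model: Binom(N, p)."""
    return int(rng.binomial(N, p))


def loglik_one_level(c: int, N: int, p: float) -> float:
    """Exact log binomial pmf of finding c of N carcasses."""
    if c > N:
        raise ValidationError(f"found {c} carcasses from only {N} collisions")
    if c < 0:
        raise ValidationError("negative count")
    return float(binom_logpmf(c, N, p))


def step_three_level(
    prev_remaining: int,
    prev_found: int,
    N_new: int,
    a: float,
    s: float,
    f: float,
    rng: np.random.Generator,
    searched: bool = True,
) -> tuple[int, int, int, int]:
    """One night of the three-level chain; returns
    (fallen, available, remaining, found).

    For the first night pass ``prev_remaining = prev_found = 0``.  On an
    unsearched night ``found`` is forced to 0 (pass ``prev_found=0`` for
    the following night, which the caller gets for free by reusing the
    returned found).
    """
    if prev_found > prev_remaining:
        raise ValidationError(
            f"state corruption: prev_found {prev_found} > prev_remaining "
            f"{prev_remaining}")
    fallen = int(rng.binomial(N_new, a))
    available = prev_remaining - prev_found + fallen
    remaining = int(rng.binomial(available, s))
    found = int(rng.binomial(remaining, f)) if searched else 0
    return fallen, available, remaining, found


def simulate_three_level_path(
    N_seq: Sequence[int],
    a: float,
    s: float,
    f: float,
    rng: np.random.Generator,
    searched: Optional[Sequence[bool]] = None,
) -> LatentState:
    """Run the chain over a whole turbine's nights given collisions N_seq."""
    T = len(N_seq)
    if searched is None:
        searched = [True] * T
    state = LatentState(
        collisions=np.asarray(N_seq, dtype=int),
        fallen=np.zeros(T, dtype=int),
        available=np.zeros(T, dtype=int),
        remaining=np.zeros(T, dtype=int),
        found=np.zeros(T, dtype=int),
    )
    prev_rem, prev_found = 0, 0
    for t in range(T):
        fa, av, re, fo = step_three_level(
            prev_rem, prev_found, int(N_seq[t]), a, s, f, rng,
            searched=bool(searched[t]))
        state.fallen[t] = fa
        state.available[t] = av
        state.remaining[t] = re
        state.found[t] = fo
        prev_rem, prev_found = re, fo
    return state


def loglik_three_level_path(
    state: LatentState,
    counts: Sequence[NightRecord],
    a: float,
    s: float,
    f: float,
) -> float:
    """Joint log-likelihood of one turbine's observation chain.

    Sums the three binomial contributions per night, with the search term
    only on searched nights; -inf for paths violating the recursion or
    disagreeing with the observed counts.
    """
    T = len(state.collisions)
    if len(counts) != T:
        raise ValidationError(
            f"state has {T} nights but counts has {len(counts)}")
    searched = np.array([r.searched for r in counts])
    c = np.array([r.carcass_count for r in counts])
    if np.any(state.found != np.where(searched, c, 0)):
        return -np.inf
    carry = np.concatenate([[0], state.remaining[:-1] - state.found[:-1]])
    if np.any(state.available != carry + state.fallen):
        return -np.inf
    ll = (binom_logpmf(state.fallen, state.collisions, a)
          + binom_logpmf(state.remaining, state.available, s)
          + np.where(searched,
                     binom_logpmf(state.found, state.remaining, f), 0.0))
    return float(ll.sum())
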