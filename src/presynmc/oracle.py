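"""Exact references for validating the sampling engines.

For a single particle the chain law is exact: the state distribution after T
steps under a frozen environment is ``p0 @ P**T``.  Since particles evolve
independently, the occupancy counts of n identically started particles are
multinomial around that marginal, which gives goodness-of-fit oracles for
both stochastic engines without simulating anything.  Predicted PRNG-draw
counts per engine provide the complexity contract.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .engines import StateCounts, check_row_stochastic
from .errors import ConfigurationError, ContractError
from .kinetics import KineticScheme

__all__ = [
    "cme_propagate",
    "expected_counts",
    "predicted_prng_counts",
    "exact_one_step_count_distribution",
]


def cme_propagate(P: np.ndarray, p0: np.ndarray, steps: int) -> np.ndarray:
    """Exact single-particle distribution after ``steps`` applications of P."""
    P = check_row_stochastic(P)
    p = np.asarray(p0, dtype=float)
    if p.ndim != 1 or p.size != P.shape[0]:
        raise ContractError("p0 shape does not match P")
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ContractError("p0 must be a probability vector")
    if steps < 0:
        raise ConfigurationError("steps must be >= 0")
    out = p @ np.linalg.matrix_power(P, steps)
    s = out.sum()
    if abs(s - 1.0) > 1e-10:
        raise ContractError(f"propagated distribution lost normalization: {s!r}")
    return out


def expected_counts(P: np.ndarray, counts0: StateCounts, steps: int) -> np.ndarray:
    """Deterministic mean occupancy after ``steps`` — the Euler recursion."""
    P = check_row_stochastic(P)
    x = counts0.counts.astype(float)
    for _ in range(steps):
        x = x @ P
    return x


def predicted_prng_counts(engine: str, scheme: KineticScheme, n: int, steps: int) -> int:
    """Predicted draw count (standard/gaussian/ode, exact) or bound (multinomial).

    standard: one uniform per particle per step -> n*steps exactly.
    multinomial: worst case one component draw per branch of every state per
    step -> b*s*steps (the audited count is sharper: at most sum_i b_i per
    step, and only occupied states cost anything).
    gaussian: s normal draws per step.  ode: none.
    """
    if n < 0 or steps < 0:
        raise ConfigurationError("n and steps must be >= 0")
    if engine == "standard":
        return n * steps
    if engine == "multinomial":
        return scheme.max_branch * scheme.s * steps
    if engine == "gaussian":
        return scheme.s * steps
    if engine == "ode":
        return 0
    raise ConfigurationError(f"unknown engine {engine!r}")


def exact_one_step_count_distribution(counts0: StateCounts, P: np.ndarray) -> dict:
    """Exact joint pmf of the occupancy vector after one step, by enumeration.

    Feasible only for tiny systems (n <= ~6, s <= ~3): enumerates every
    per-state multinomial split and convolves.  Returns a mapping from
    occupancy tuples to probabilities summing to 1.
    """
    P = check_row_stochastic(P)
    s = P.shape[0]
    if counts0.total > 8 or s > 4:
        raise ConfigurationError("exact enumeration is limited to tiny systems")

    def splits(n, k):
        if k == 1:
            yield (n,)
            return
        for first in range(n + 1):
            for rest in splits(n - first, k - 1):
                yield (first,) + rest

    def multinomial_pmf(ns, probs):
        n = sum(ns)
        logp = math.lgamma(n + 1)
        for ni, pi in zip(ns, probs):
            if ni:
                if pi == 0:
                    return 0.0
                logp += ni * math.log(pi) - math.lgamma(ni + 1)
            else:
                logp -= math.lgamma(ni + 1)
        return math.exp(logp)

    dist = {tuple(np.zeros(s, dtype=int)): 1.0}
    for i in range(s):
        ni = int(counts0.counts[i])
        if ni == 0:
            continue
        new: dict = {}
        for split in splits(ni, s):
            p_split = multinomial_pmf(split, P[i])
            if p_split == 0.0:
                continue
            for occ, p_occ in dist.items():
                key = tuple(o + d for o, d in zip(occ, split))
                new[key] = new.get(key, 0.0) + p_occ * p_split
        dist = new
    return dist
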