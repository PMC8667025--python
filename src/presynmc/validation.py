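"""Self-check suite: engines against the exact chain law.

Each property compares a sampling engine with an analytic reference on a
frozen-environment scheme.  Used by the ``validate`` CLI subcommand and by
the test suite (at full replication there).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .engines import StateCounts, simulate, step_ode
from .kinetics import Environment, KineticScheme, KineticState, RateKind, RateLaw, \
    Transition, load_preset, transition_matrix
from .oracle import cme_propagate

__all__ = ["PropertyResult", "two_state_scheme", "chi_square_vs_cme",
           "run_validation"]


@dataclass
class PropertyResult:
    name: str
    passed: bool
    detail: str


def two_state_scheme(k01: float = 1000.0, k10: float = 1000.0) -> KineticScheme:
    states = [KineticState("A", 0), KineticState("B", 1)]
    transitions = [Transition(0, 1, RateLaw(RateKind.CONSTANT, k01)),
                   Transition(1, 0, RateLaw(RateKind.CONSTANT, k10))]
    return KineticScheme(states, transitions, name="two_state")


def chi_square_vs_cme(scheme: KineticScheme, engine: str, env: Environment,
                      replicates: int, steps: int, dt: float, seed,
                      start_state: int = 0) -> tuple[float, float]:
    """Chi-square statistic and p-value of empirical single-particle marginals.

    ``replicates`` identically started particles evolve independently, so the
    occupancy after ``steps`` is multinomial around the exact chain marginal
    p0 @ P^steps; one population run therefore provides the empirical
    distribution.  Bins with expected count < 5 are pooled.
    """
    P = transition_matrix(scheme, env, dt)
    p0 = np.zeros(scheme.s)
    p0[start_state] = 1.0
    expected_p = cme_propagate(P, p0, steps)
    initial = StateCounts.single_state(scheme.s, start_state, replicates)
    res = simulate(scheme, engine, env, initial, duration_s=steps * dt, dt_s=dt,
                   seed=seed, free_calcium_M=env.free_calcium)
    observed = res.states[-1].astype(float)
    expected = expected_p * replicates
    # merge bins with expected < 5 into the best-populated bin so the
    # chi-square approximation stays valid
    keep = expected >= 5
    if not keep.all():
        main = int(np.argmax(expected))
        observed[main] += observed[~keep].sum()
        expected[main] += expected[~keep].sum()
        observed, expected = observed[keep], expected[keep]
    stat, p = stats.chisquare(observed, expected * observed.sum() / expected.sum())
    return float(stat), float(p)


def run_validation(replicates: int = 2000, seed: int = 0,
                   alpha: float = 0.01) -> list[PropertyResult]:
    """Oracle-equivalence checks for both stochastic engines on 2/5/9-state
    schemes, plus mean-consistency of the deterministic update."""
    results = []
    rng_seed = np.random.SeedSequence(seed)
    seeds = iter(rng_seed.spawn(64))

    cases = [
        ("two_state", two_state_scheme(), Environment(0.0, 1e-6), 50),
        ("vdcc5", load_preset("vdcc5"), Environment(-20.0, 1e-7), 50),
        ("calbindin9", load_preset("calbindin9"), Environment(0.0, 1e-5), 50),
    ]
    for name, scheme, env, steps in cases:
        for engine in ("standard", "multinomial"):
            _, p = chi_square_vs_cme(scheme, engine, env, replicates, steps,
                                     1e-6, next(seeds))
            results.append(PropertyResult(
                f"cme_marginal:{name}:{engine}", p > alpha,
                f"chi-square p={p:.4f} (alpha={alpha})"))

    # deterministic update reproduces the exact mean recursion
    scheme = two_state_scheme(1000.0, 500.0)
    env = Environment(0.0, 1e-7)
    P = transition_matrix(scheme, env, 1e-6)
    from .engines import StateFractions
    f = StateFractions(np.array([1.0, 0.0]), 100)
    for _ in range(100):
        f = step_ode(f, P)
    exact = cme_propagate(P, np.array([1.0, 0.0]), 100)
    ok = bool(np.allclose(f.fractions, exact, atol=1e-10))
    results.append(PropertyResult("ode_equals_cme_mean", ok,
                                  f"max deviation {np.abs(f.fractions - exact).max():.2e}"))
    return results
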