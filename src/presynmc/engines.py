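"""Time-stepping engines for population Markov kinetics.

Four interchangeable strategies advance an occupancy vector under the same
one-step transition matrix:

``standard``
    Per-particle discrete inverse-transform sampling: one uniform draw per
    particle per step, mapped through the cumulative partition of its state's
    row.  Cost O(b*n*t) and exactly n PRNG draws per step.
``multinomial``
    Population sampling: one multinomial draw per *occupied* state per step
    distributes that state's particles over its destinations in a single
    shot.  A multinomial over m outcomes costs m-1 binomial component draws
    (the last bucket is fixed by conservation), so the per-step PRNG cost is
    at most the edge count and bounded by b*s independent of n.
``gaussian``
    Stochastic-ODE (AWGN) approximation: deterministic mean update
    x' = x P plus an additive zero-mean normal perturbation whose spread
    vanishes at the occupancy boundaries; s normal draws per step.  A
    central-limit approximation, accurate only for large n.
``ode``
    Deterministic forward-Euler update x' = x P; zero draws.

Both stochastic count engines conserve the particle total exactly at every
step and are identical in law (multinomial thinning of i.i.d. categorical
draws).  Every run carries an :class:`RNGAudit` whose counters are exact,
not sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractError
from .kinetics import Environment, KineticScheme, transition_matrix
from .stimulus import VoltageTrace

__all__ = [
    "ENGINES",
    "StateCounts",
    "StateFractions",
    "RNGAudit",
    "SimulationResult",
    "TrajectoryEnsemble",
    "check_row_stochastic",
    "sample_flow_matrix",
    "step_standard",
    "step_multinomial",
    "step_gaussian",
    "step_ode",
    "simulate",
    "run_ensemble",
    "ensemble_seeds",
]

ENGINES = ("standard", "multinomial", "gaussian", "ode")

_ROW_TOL = 1e-9


@dataclass
class StateCounts:
    """Integer occupancy per state; the total is conserved exactly."""

    counts: np.ndarray
    total: int = field(init=False)

    def __post_init__(self):
        c = np.asarray(self.counts)
        if not np.issubdtype(c.dtype, np.integer):
            rounded = np.rint(c).astype(np.int64)
            if not np.allclose(c, rounded):
                raise ConfigurationError("counts must be integers")
            c = rounded
        c = c.astype(np.int64)
        if (c < 0).any():
            raise ConfigurationError("counts must be >= 0")
        self.counts = c
        self.total = int(c.sum())

    @classmethod
    def single_state(cls, s: int, index: int, n: int) -> "StateCounts":
        c = np.zeros(s, dtype=np.int64)
        c[index] = n
        return cls(c)

    def fractions(self) -> "StateFractions":
        if self.total == 0:
            raise ConfigurationError("cannot normalize an empty population")
        return StateFractions(self.counts / self.total, self.total)


@dataclass
class StateFractions:
    """Real-valued occupancy fractions summing to 1, with the scaling total n."""

    fractions: np.ndarray
    total: float

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        if (f < -1e-9).any():
            raise ConfigurationError("fractions must be >= 0")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"fractions must sum to 1, got {f.sum()!r}")
        self.fractions = f

    def counts_scale(self) -> np.ndarray:
        return self.fractions * self.total


@dataclass
class RNGAudit:
    """Exact counters of pseudorandom draws, by category."""

    uniform_draws: int = 0
    multinomial_component_draws: int = 0
    normal_draws: int = 0
    poisson_draws: int = 0
    gaussian_clamp_events: int = 0

    @property
    def total_draws(self) -> int:
        return (self.uniform_draws + self.multinomial_component_draws
                + self.normal_draws + self.poisson_draws)

    def engine_draws(self, engine: str) -> int:
        return {"standard": self.uniform_draws,
                "multinomial": self.multinomial_component_draws,
                "gaussian": self.normal_draws,
                "ode": 0}[engine]

    def to_dict(self) -> dict:
        return {"uniform_draws": self.uniform_draws,
                "multinomial_component_draws": self.multinomial_component_draws,
                "normal_draws": self.normal_draws,
                "poisson_draws": self.poisson_draws,
                "gaussian_clamp_events": self.gaussian_clamp_events}

    def merge(self, other: "RNGAudit") -> None:
        self.uniform_draws += other.uniform_draws
        self.multinomial_component_draws += other.multinomial_component_draws
        self.normal_draws += other.normal_draws
        self.poisson_draws += other.poisson_draws
        self.gaussian_clamp_events += other.gaussian_clamp_events


def check_row_stochastic(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ContractError("transition matrix must be square")
    if (P < -_ROW_TOL).any() or (P > 1 + _ROW_TOL).any():
        raise ContractError("transition matrix entries must lie in [0, 1]")
    rows = P.sum(axis=1)
    if not np.allclose(rows, 1.0, rtol=0.0, atol=_ROW_TOL):
        bad = int(np.argmax(np.abs(rows - 1.0)))
        raise ContractError(f"row {bad} sums to {rows[bad]!r}, not 1")
    return P


# ---------------------------------------------------------------------------
# Single-step updates
# ---------------------------------------------------------------------------

def sample_flow_matrix(counts: StateCounts, P: np.ndarray, rng: np.random.Generator,
                       engine: str = "multinomial",
                       audit: RNGAudit | None = None) -> np.ndarray:
    """Integer flow matrix F[i, j] = particles moving i -> j this step.

    The column sums of F are the next occupancy vector.  Exposing the flows
    (not just the new counts) is what lets the calcium coupling move exactly
    one ion per binding/unbinding event.
    """
    P = check_row_stochastic(P)
    c = counts.counts
    s = P.shape[0]
    F = np.zeros((s, s), dtype=np.int64)
    if engine == "standard":
        for i in np.flatnonzero(c):
            u = rng.random(c[i])
            if audit is not None:
                audit.uniform_draws += int(c[i])
            cum = np.cumsum(P[i])
            dest = np.searchsorted(cum, u, side="left")
            np.minimum(dest, s - 1, out=dest)  # guard float round-off at cum[-1]
            F[i] = np.bincount(dest, minlength=s)
    elif engine == "multinomial":
        for i in np.flatnonzero(c):
            support = np.flatnonzero(P[i])
            if support.size == 1:
                F[i, support[0]] = c[i]
                continue
            p = P[i, support]
            draw = rng.multinomial(int(c[i]), p / p.sum())
            if audit is not None:
                audit.multinomial_component_draws += int(support.size) - 1
            F[i, support] = draw
    else:
        raise ConfigurationError(f"flow sampling requires a count engine, got {engine!r}")
    return F


def step_standard(counts: StateCounts, P: np.ndarray, rng: np.random.Generator,
                  audit: RNGAudit | None = None) -> StateCounts:
    """Advance every particle independently by inverse-transform sampling."""
    F = sample_flow_matrix(counts, P, rng, "standard", audit)
    return StateCounts(F.sum(axis=0))


def step_multinomial(counts: StateCounts, P: np.ndarray, rng: np.random.Generator,
                     audit: RNGAudit | None = None) -> StateCounts:
    """Advance each occupied state's population with one multinomial draw."""
    F = sample_flow_matrix(counts, P, rng, "multinomial", audit)
    return StateCounts(F.sum(axis=0))


def step_ode(fractions: StateFractions, P: np.ndarray) -> StateFractions:
    """Deterministic forward-Euler mean update through the one-step matrix."""
    P = check_row_stochastic(P)
    return StateFractions(fractions.fractions @ P, fractions.total)


def step_gaussian(state: Union[StateCounts, StateFractions], P: np.ndarray,
                  rng: np.random.Generator, audit: RNGAudit | None = None,
                  noise_scale: float = 1.0,
                  literal_variance: bool = False) -> StateFractions:
    """AWGN approximation: mean update plus state-dependent normal noise.

    The per-state spread is ``sqrt(x_i*(n-x_i))/n * noise_scale`` — zero at
    both occupancy boundaries, maximal at half occupancy.  With
    ``literal_variance=True`` the spread is taken as ``x_i*(n-x_i)`` itself
    (the variance-units reading, for comparison).  The result is clamped to
    [0, n] and renormalized so the total is conserved; clamp events are
    tallied in the audit because their frequency is the observable signature
    of the approximation breaking down at small n.
    """
    P = check_row_stochastic(P)
    if isinstance(state, StateCounts):
        n = float(state.total)
        x = state.counts.astype(float)
    else:
        n = float(state.total)
        x = state.counts_scale()
    if n <= 0:
        raise ConfigurationError("gaussian engine needs a positive total")
    mean = x @ P
    prod = np.clip(x * (n - x), 0.0, None)
    sd = prod if literal_variance else np.sqrt(prod) / n
    noise = rng.normal(0.0, 1.0, size=x.size) * sd * noise_scale
    if audit is not None:
        audit.normal_draws += int(x.size)
    y = mean + noise
    clamped = np.clip(y, 0.0, n)
    if audit is not None:
        audit.gaussian_clamp_events += int(np.sum(~np.isclose(y, clamped)))
    tot = clamped.sum()
    if tot == 0.0:
        clamped = np.full_like(clamped, n / clamped.size)
        tot = n
    return StateFractions(clamped / tot, n)


# ---------------------------------------------------------------------------
# Full simulations
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """One trajectory: times (s) and per-step occupancy (counts scale)."""

    times: np.ndarray
    states: np.ndarray  # (T+1, s); integer counts or counts-scale floats
    state_names: list
    engine: str
    dt: float
    audit: RNGAudit

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy frame: time_s, state, value."""
        T, s = self.states.shape
        return pd.DataFrame({
            "time_s": np.repeat(self.times, s),
            "state": np.tile(np.asarray(self.state_names, dtype=object), T),
            "value": self.states.ravel(),
        })


def _resolve_environment(stimulus, free_calcium_M: float):
    """Returns (voltage_array_or_None, fixed_env_or_None)."""
    if isinstance(stimulus, Environment):
        return None, stimulus
    if isinstance(stimulus, VoltageTrace):
        return stimulus, None
    raise ConfigurationError("stimulus must be a VoltageTrace or an Environment")


def simulate(scheme: KineticScheme, engine: str, stimulus, initial,
             duration_s: float, dt_s: float, seed=None,
             free_calcium_M: float = 1e-7, rng: np.random.Generator | None = None,
             noise_scale: float = 1.0, literal_variance: bool = False) -> SimulationResult:
    """Advance a population for duration_s at fixed dt under one engine.

    ``stimulus`` is either a fixed :class:`Environment` or a
    :class:`VoltageTrace` (resampled to ``dt_s`` if needed; must cover the
    duration).  The transition matrix is rebuilt from the instantaneous
    environment each step — rates are held piecewise-constant within a step.
    Identical seeds give identical trajectories.
    """
    if engine not in ENGINES:
        raise ConfigurationError(f"unknown engine {engine!r}; choose from {ENGINES}")
    if dt_s <= 0 or duration_s <= 0:
        raise ConfigurationError("duration_s and dt_s must be > 0")
    n_steps = int(round(duration_s / dt_s))
    trace, fixed_env = _resolve_environment(stimulus, free_calcium_M)
    if trace is not None:
        trace = trace.resample(dt_s)
        if len(trace) < n_steps:
            raise ConfigurationError(
                f"stimulus covers {trace.duration:g} s < duration {duration_s:g} s")
        volts = trace.values
        constant_trace = bool(np.ptp(volts) == 0.0)
    else:
        volts = None
        constant_trace = True

    if rng is None:
        rng = np.random.default_rng(seed)
    audit = RNGAudit()

    if engine in ("standard", "multinomial"):
        if not isinstance(initial, StateCounts):
            initial = StateCounts(np.asarray(initial))
        if initial.total <= 0:
            raise ConfigurationError("count engines need a positive initial total")
        state = initial
        out = np.empty((n_steps + 1, scheme.s), dtype=np.int64)
        out[0] = state.counts
    else:
        if isinstance(initial, StateCounts):
            frac = initial.fractions()
        elif isinstance(initial, StateFractions):
            frac = initial
        else:
            arr = np.asarray(initial, dtype=float)
            frac = StateFractions(arr / arr.sum(), arr.sum())
        state = frac
        out = np.empty((n_steps + 1, scheme.s), dtype=float)
        out[0] = state.counts_scale()

    step_fn = {"standard": step_standard, "multinomial": step_multinomial}.get(engine)

    P = None
    for k in range(n_steps):
        if P is None or not constant_trace:
            if fixed_env is not None:
                env = fixed_env
            else:
                env = Environment(membrane_voltage=float(volts[k]),
                                  free_calcium=free_calcium_M)
            P = transition_matrix(scheme, env, dt_s)
        if engine in ("standard", "multinomial"):
            state = step_fn(state, P, rng, audit)
            out[k + 1] = state.counts
        elif engine == "gaussian":
            state = step_gaussian(state, P, rng, audit,
                                  noise_scale=noise_scale,
                                  literal_variance=literal_variance)
            out[k + 1] = state.counts_scale()
        else:
            state = step_ode(state, P)
            out[k + 1] = state.counts_scale()

    times = dt_s * np.arange(n_steps + 1)
    return SimulationResult(times, out, scheme.state_names, engine, dt_s, audit)


@dataclass
class TrajectoryEnsemble:
    """Repeated runs: per-state mean and standard deviation over time.

    The standard deviation is the population sd over the runs axis (zero for
    a single run).  ``finals`` keeps each run's last occupancy vector so
    end-point distributions can be compared without storing every trajectory;
    full per-run trajectories are retained only when requested.
    """

    times: np.ndarray
    mean: np.ndarray  # (T+1, s)
    sd: np.ndarray    # (T+1, s)
    finals: np.ndarray  # (n_runs, s)
    n_runs: int
    state_names: list
    engine: str
    audit: RNGAudit
    runs: np.ndarray | None = None  # (n_runs, T+1, s) when kept

    def summary_dataframe(self) -> pd.DataFrame:
        T, s = self.mean.shape
        return pd.DataFrame({
            "time_s": np.repeat(self.times, s),
            "state": np.tile(np.asarray(self.state_names, dtype=object), T),
            "mean": self.mean.ravel(),
            "sd": self.sd.ravel(),
        })


def ensemble_seeds(base_seed, n_runs: int) -> list:
    """Deterministic per-run seed derivation: SeedSequence(base).spawn(n)."""
    return np.random.SeedSequence(base_seed).spawn(n_runs)


def run_ensemble(scheme: KineticScheme, engine: str, stimulus, initial,
                 duration_s: float, dt_s: float, n_runs: int, base_seed=0,
                 keep_runs: bool = False, **kwargs) -> TrajectoryEnsemble:
    """Independent repetitions with seeds spawned from one base seed.

    Mean/sd are accumulated streaming (sum and sum of squares) so large
    ensembles do not hold every trajectory in memory unless ``keep_runs``.
    Bit-exactly reproducible for a fixed ``base_seed``.
    """
    if n_runs < 1:
        raise ConfigurationError("n_runs must be >= 1")
    seeds = ensemble_seeds(base_seed, n_runs)
    total = RNGAudit()
    acc = acc2 = None
    finals = None
    kept = [] if keep_runs else None
    times = state_names = None
    for r, ss in enumerate(seeds):
        res = simulate(scheme, engine, stimulus, initial, duration_s, dt_s,
                       rng=np.random.default_rng(ss), **kwargs)
        x = res.states.astype(float)
        if acc is None:
            acc = np.zeros_like(x)
            acc2 = np.zeros_like(x)
            finals = np.empty((n_runs, x.shape[1]), dtype=res.states.dtype)
            times, state_names = res.times, res.state_names
        acc += x
        acc2 += x * x
        finals[r] = res.states[-1]
        total.merge(res.audit)
        if keep_runs:
            kept.append(res.states)
    mean = acc / n_runs
    var = np.maximum(acc2 / n_runs - mean**2, 0.0)
    sd = np.sqrt(var)
    runs = np.stack(kept) if keep_runs else None
    return TrajectoryEnsemble(times, mean, sd, finals, n_runs, state_names,
                              engine, total, runs)
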