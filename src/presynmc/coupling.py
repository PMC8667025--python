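"""Coupled presynaptic cascade: channels, calcium influx, buffer.

An action potential depolarizes the membrane, the five-state channels open,
each open channel admits calcium ions at a voltage-dependent single-channel
rate, and the admitted ions join a well-mixed free pool from which calbindin
binds and releases one ion per site transition.  The compartment is the
canonical 0.5 x 0.5 x 4 um presynaptic box (1 um^3 = 1e-15 L).

Every ion is accounted for: at every step of every stochastic run
``free + bound - cumulative_influx`` equals its initial value as an exact
integer identity.  The per-step update order is fixed and documented:
channel transitions, then influx through the channels that are open after
the transition, then buffer transitions against the updated pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .engines import RNGAudit, StateCounts, sample_flow_matrix
from .errors import ConfigurationError
from .kinetics import (AVOGADRO, Environment, KineticScheme, build_calbindin_scheme,
                       build_vdcc_scheme, calbindin_bound_ions, transition_matrix)
from .stimulus import VoltageTrace

__all__ = [
    "CalciumPool",
    "CalciumInfluxParams",
    "CoupledConfig",
    "CascadeResult",
    "ghk_influx_rate",
    "vdcc_influx_step",
    "calbindin_coupled_step",
    "calbindin_equilibrium_fractions",
    "initial_calbindin_counts",
    "run_presynaptic_cascade",
]

_FARADAY = 96485.33212  # C/mol
_GAS_R = 8.31446        # J/(mol K)


@dataclass
class CalciumPool:
    """Free calcium in the well-mixed compartment, as an integer ion count."""

    free_count: int
    volume: float = 1e-15  # liters
    cumulative_influx: int = 0

    def __post_init__(self):
        if self.free_count < 0:
            raise ConfigurationError("free_count must be >= 0")
        if self.volume <= 0:
            raise ConfigurationError("volume must be > 0")

    @property
    def concentration(self) -> float:
        """Molar free-calcium concentration."""
        return self.free_count / (self.volume * AVOGADRO)

    @classmethod
    def from_concentration(cls, molar: float, volume: float = 1e-15) -> "CalciumPool":
        return cls(int(round(molar * volume * AVOGADRO)), volume)


@dataclass(frozen=True)
class CalciumInfluxParams:
    """GHK-flux single-channel calcium entry.

    The entry rate per open channel is the Goldman-Hodgkin-Katz flux for a
    divalent ion, scaled by a single-channel permeability in L/s:

        rate(V) = p_s * N_A * u * ([Ca]_out - [Ca]_in * e^u) / (e^u - 1),
        u = zFV/(RT)

    The default permeability gives ~0.2 pA at -70 mV with 2 mM external
    calcium — a physiological single-channel scale.  Outward flux (beyond the
    reversal potential) is clipped to zero: efflux pathways are out of scope.
    """

    permeability: float = 1.0e-16  # L/s per channel
    ca_out: float = 2e-3           # M
    ca_in: float = 1e-7            # M
    temperature: float = 298.15    # K
    valence: int = 2

    def rate_per_channel(self, voltage_mV: float) -> float:
        """Ion entries per second through one open channel."""
        u = (self.valence * _FARADAY * voltage_mV * 1e-3
             / (_GAS_R * self.temperature))
        if abs(u) < 1e-9:
            driving = self.ca_out - self.ca_in
        else:
            driving = u * (self.ca_out - self.ca_in * math.exp(u)) / math.expm1(u)
        return max(self.permeability * AVOGADRO * driving, 0.0)


def ghk_influx_rate(voltage_mV: float, params: CalciumInfluxParams | None = None) -> float:
    return (params or CalciumInfluxParams()).rate_per_channel(voltage_mV)


def vdcc_influx_step(open_channels: int, voltage_mV: float,
                     params: CalciumInfluxParams, dt_s: float,
                     rng: np.random.Generator,
                     audit: RNGAudit | None = None) -> int:
    """Ions entering during one step through ``open_channels`` open channels.

    Each open channel admits a Poisson(k_Ca(V)*dt) number of ions; the sum of
    independent Poissons is drawn as a single Poisson variate.
    """
    if open_channels < 0:
        raise ConfigurationError("open_channels must be >= 0")
    if dt_s <= 0:
        raise ConfigurationError("dt_s must be > 0")
    mean = open_channels * params.rate_per_channel(voltage_mV) * dt_s
    if mean == 0.0:
        return 0
    draw = int(rng.poisson(mean))
    if audit is not None:
        audit.poisson_draws += 1
    return draw


# ---------------------------------------------------------------------------
# Calbindin <-> calcium pool coupling
# ---------------------------------------------------------------------------

def _binding_edge_mask(scheme: KineticScheme) -> np.ndarray:
    """Signed ion movement per edge: +1 consumes a free ion, -1 releases one."""
    bound = calbindin_bound_ions()
    src, dst = scheme.edge_arrays()
    return bound[dst] - bound[src]


def calbindin_coupled_step(calb_counts: StateCounts, pool: CalciumPool,
                           scheme: KineticScheme, dt_s: float,
                           rng: np.random.Generator, engine: str = "multinomial",
                           audit: RNGAudit | None = None
                           ) -> tuple[StateCounts, CalciumPool]:
    """Advance the buffer one step against the shared free-calcium pool.

    The transition matrix is built from the pool's instantaneous
    concentration.  Flows are sampled per edge so each site transition moves
    exactly one ion.  If sampled binding demand exceeds the available free
    calcium (rare at microsecond steps), excess binding events are cancelled
    in randomized edge order — those molecules stay in their source state —
    preserving non-negativity and the exact ledger.
    """
    if engine not in ("standard", "multinomial"):
        raise ConfigurationError(
            "calbindin_coupled_step needs a count engine (standard/multinomial); "
            "the deterministic mean-field path lives in run_presynaptic_cascade")
    env = Environment(membrane_voltage=0.0, free_calcium=pool.concentration)
    P = transition_matrix(scheme, env, dt_s)
    F = sample_flow_matrix(calb_counts, P, rng, engine, audit)
    src, dst = scheme.edge_arrays()
    ion_delta = _binding_edge_mask(scheme)  # per edge
    flows = F[src, dst].astype(np.int64)
    released = int(flows[ion_delta < 0].sum())
    consumed = int(flows[ion_delta > 0].sum())
    available = pool.free_count + released
    if consumed > available:
        deficit = consumed - available
        binding_edges = np.flatnonzero(ion_delta > 0)
        for e in rng.permutation(binding_edges):
            if deficit == 0:
                break
            cancel = min(int(flows[e]), deficit)
            if cancel:
                flows[e] -= cancel
                F[src[e], dst[e]] -= cancel
                F[src[e], src[e]] += cancel  # cancelled molecules stay put
                deficit -= cancel
        consumed = int(flows[ion_delta > 0].sum())
    new_counts = StateCounts(F.sum(axis=0))
    new_pool = replace(pool, free_count=pool.free_count + released - consumed)
    return new_counts, new_pool


def calbindin_equilibrium_fractions(calcium_M: float, rate_params: dict | None = None
                                    ) -> np.ndarray:
    """Product-form steady state over the 3x3 grid at clamped calcium.

    With independent sites, each site class is binomial with per-site
    occupancy c/(c+K), K = k_off/k_on; the joint over (a, b) is the product
    of the two binomials.
    """
    from .kinetics import default_calbindin_params
    p = rate_params or default_calbindin_params()
    out = np.empty(9)
    occs = {}
    for cls in ("high", "medium"):
        K = p[cls]["k_off"] / p[cls]["k_on"]
        occs[cls] = calcium_M / (calcium_M + K)
    for a in range(3):
        pa = math.comb(2, a) * occs["high"]**a * (1 - occs["high"])**(2 - a)
        for b in range(3):
            pb = math.comb(2, b) * occs["medium"]**b * (1 - occs["medium"])**(2 - b)
            out[3 * a + b] = pa * pb
    return out


def initial_calbindin_counts(n_molecules: int, calcium_M: float,
                             rng: np.random.Generator | None = None,
                             mode: str = "round",
                             rate_params: dict | None = None) -> StateCounts:
    """Distribute molecules over binding states at the resting steady state.

    ``mode='round'`` (default) uses largest-remainder deterministic rounding
    for reproducibility; ``mode='sample'`` draws one multinomial assignment.
    """
    probs = calbindin_equilibrium_fractions(calcium_M, rate_params)
    if mode == "sample":
        if rng is None:
            raise ConfigurationError("mode='sample' needs an rng")
        return StateCounts(rng.multinomial(n_molecules, probs))
    if mode != "round":
        raise ConfigurationError(f"unknown initialization mode {mode!r}")
    raw = probs * n_molecules
    base = np.floor(raw).astype(np.int64)
    short = n_molecules - int(base.sum())
    order = np.argsort(raw - base)[::-1]
    base[order[:short]] += 1
    return StateCounts(base)


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoupledConfig:
    """Study conditions for the coupled presynaptic run.

    Defaults are the canonical conditions: 65 channels all starting closed,
    45 uM calbindin in a 1 um^3 box (2.71e4 molecules), 100 nM resting free
    calcium, 10 ms horizon at 1 us steps.
    """

    n_vdcc: int = 65
    calbindin_concentration: float = 4.5e-5  # M
    volume: float = 1e-15                    # L
    duration_s: float = 0.01
    dt_s: float = 1e-6
    initial_calcium: float = 1e-7            # M
    engine: str = "multinomial"
    seed: int | None = 0
    influx: CalciumInfluxParams = field(default_factory=CalciumInfluxParams)
    clamp_calcium: bool = False  # hold the pool fixed for buffer-only studies
    calbindin_init: str = "round"
    # calcium level the buffer is equilibrated to at t=0; defaults to
    # initial_calcium.  Set lower than initial_calcium to study the buffering
    # of a calcium bolus by resting calbindin.
    calbindin_equilibrium_calcium: float | None = None

    @property
    def buffer_init_calcium(self) -> float:
        return (self.initial_calcium if self.calbindin_equilibrium_calcium is None
                else self.calbindin_equilibrium_calcium)

    @property
    def n_calbindin(self) -> int:
        n = int(round(self.calbindin_concentration * self.volume * AVOGADRO))
        if n <= 0:
            raise ConfigurationError("derived calbindin count must be > 0")
        return n


@dataclass
class CascadeResult:
    times: np.ndarray
    vdcc_counts: np.ndarray      # (T+1, 5) int
    calbindin_counts: np.ndarray  # (T+1, 9) int
    free_calcium: np.ndarray     # (T+1,) int ion counts
    influx_per_step: np.ndarray  # (T,) int
    audit: RNGAudit
    config: CoupledConfig
    vdcc_state_names: list
    calbindin_state_names: list

    @property
    def cumulative_influx(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum(self.influx_per_step)])

    @property
    def vdcc_fractions(self) -> np.ndarray:
        return self.vdcc_counts / self.config.n_vdcc

    @property
    def open_fraction(self) -> np.ndarray:
        return self.vdcc_fractions[:, -1]

    @property
    def bound_calcium(self) -> np.ndarray:
        return self.calbindin_counts @ calbindin_bound_ions()

    def ledger_residual(self) -> np.ndarray:
        """free + bound - cumulative influx, relative to its initial value.

        Identically zero at every step when the integer ledger holds.
        """
        total = self.free_calcium + self.bound_calcium - self.cumulative_influx
        return total - total[0]

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"time_s": self.times,
                "free_calcium": self.free_calcium,
                "cumulative_influx": self.cumulative_influx}
        for j, name in enumerate(self.vdcc_state_names):
            cols[f"vdcc_{name}"] = self.vdcc_counts[:, j]
        for j, name in enumerate(self.calbindin_state_names):
            cols[f"calb_{name}"] = self.calbindin_counts[:, j]
        return pd.DataFrame(cols)

    def summary(self) -> dict:
        open_frac = self.open_fraction
        peak = int(np.argmax(open_frac))
        return {
            "peak_open_fraction": float(open_frac[peak]),
            "time_of_peak_open_s": float(self.times[peak]),
            "total_influx": int(self.cumulative_influx[-1]),
            "final_free_calcium": int(self.free_calcium[-1]),
            "final_bound_calcium": int(self.bound_calcium[-1]),
        }


def run_presynaptic_cascade(config: CoupledConfig, stimulus: VoltageTrace) -> CascadeResult:
    """Run channels, influx, and buffer coupled through one calcium pool.

    Per-step order (operator splitting, fixed): (1) channel transitions under
    the instantaneous voltage, (2) Poisson influx through the now-open
    channels, (3) buffer transitions against the updated pool.  The integer
    calcium ledger holds exactly at every step.
    """
    if config.engine not in ("standard", "multinomial", "ode"):
        raise ConfigurationError(
            "coupled cascade supports engines 'standard', 'multinomial', 'ode'; "
            f"got {config.engine!r} (the Gaussian approximation cannot keep an "
            "exact integer ion ledger)")
    if config.engine == "ode":
        return _run_cascade_ode(config, stimulus)

    vdcc = build_vdcc_scheme()
    calb = build_calbindin_scheme()
    dt = config.dt_s
    n_steps = int(round(config.duration_s / dt))
    trace = stimulus.resample(dt)
    if len(trace) < n_steps:
        raise ConfigurationError("stimulus shorter than the configured duration")

    rng = np.random.default_rng(config.seed)
    audit = RNGAudit()
    pool = CalciumPool.from_concentration(config.initial_calcium, config.volume)
    vdcc_counts = StateCounts.single_state(5, 0, config.n_vdcc)
    calb_counts = initial_calbindin_counts(
        config.n_calbindin, config.buffer_init_calcium,
        rng=rng, mode=config.calbindin_init)

    V = np.empty((n_steps + 1, 5), dtype=np.int64)
    B = np.empty((n_steps + 1, 9), dtype=np.int64)
    free = np.empty(n_steps + 1, dtype=np.int64)
    influx = np.zeros(n_steps, dtype=np.int64)
    V[0], B[0], free[0] = vdcc_counts.counts, calb_counts.counts, pool.free_count

    for k in range(n_steps):
        volt = float(trace.values[k])
        env = Environment(membrane_voltage=volt, free_calcium=pool.concentration)
        P_vdcc = transition_matrix(vdcc, env, dt)
        F = sample_flow_matrix(vdcc_counts, P_vdcc, rng, config.engine, audit)
        vdcc_counts = StateCounts(F.sum(axis=0))

        entered = vdcc_influx_step(int(vdcc_counts.counts[-1]), volt,
                                   config.influx, dt, rng, audit)
        influx[k] = entered
        if not config.clamp_calcium:
            pool = replace(pool, free_count=pool.free_count + entered,
                           cumulative_influx=pool.cumulative_influx + entered)
        else:
            pool = replace(pool, cumulative_influx=pool.cumulative_influx + entered)

        before_free = pool.free_count
        calb_counts, new_pool = calbindin_coupled_step(
            calb_counts, pool, calb, dt, rng, config.engine, audit)
        if config.clamp_calcium:
            # buffer sees the clamped concentration; the pool itself is held
            influx[k] = entered
            pool = replace(pool, free_count=before_free)
        else:
            pool = new_pool

        V[k + 1], B[k + 1], free[k + 1] = vdcc_counts.counts, calb_counts.counts, pool.free_count

    times = dt * np.arange(n_steps + 1)
    return CascadeResult(times, V, B, free, influx, audit, config,
                         vdcc.state_names, calb.state_names)


def _run_cascade_ode(config: CoupledConfig, stimulus: VoltageTrace) -> CascadeResult:
    """Deterministic mean-field cascade (real-valued, reported rounded)."""
    vdcc = build_vdcc_scheme()
    calb = build_calbindin_scheme()
    dt = config.dt_s
    n_steps = int(round(config.duration_s / dt))
    trace = stimulus.resample(dt)
    if len(trace) < n_steps:
        raise ConfigurationError("stimulus shorter than the configured duration")
    bound = calbindin_bound_ions().astype(float)

    v = np.zeros(5)
    v[0] = config.n_vdcc
    b = calbindin_equilibrium_fractions(config.buffer_init_calcium) * config.n_calbindin
    free_f = config.initial_calcium * config.volume * AVOGADRO
    cum = 0.0

    V = np.empty((n_steps + 1, 5))
    B = np.empty((n_steps + 1, 9))
    free = np.empty(n_steps + 1)
    influx = np.zeros(n_steps)
    V[0], B[0], free[0] = v, b, free_f

    for k in range(n_steps):
        volt = float(trace.values[k])
        conc = free_f / (config.volume * AVOGADRO)
        env = Environment(membrane_voltage=volt, free_calcium=conc)
        v = v @ transition_matrix(vdcc, env, dt)
        entered = v[-1] * config.influx.rate_per_channel(volt) * dt
        influx[k] = entered
        cum += entered
        if not config.clamp_calcium:
            free_f += entered
        conc = free_f / (config.volume * AVOGADRO)
        env = Environment(membrane_voltage=volt, free_calcium=conc)
        b_new = b @ transition_matrix(calb, env, dt)
        if not config.clamp_calcium:
            free_f -= float((b_new - b) @ bound)
        b = b_new
        V[k + 1], B[k + 1], free[k + 1] = v, b, free_f

    times = dt * np.arange(n_steps + 1)
    return CascadeResult(times, V, B, free, influx, RNGAudit(), config,
                         vdcc.state_names, calb.state_names)
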