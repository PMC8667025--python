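"""Kinetic schemes and one-step transition-probability matrices.

A :class:`KineticScheme` is a directed graph of discrete molecular states with
a rate law on every edge.  Three rate-law kinds cover the presynaptic models
implemented here:

``constant``
    rate = base_rate (1/s); used for ligand unbinding.
``voltage_exp``
    rate = base_rate * exp(Vm / voltage_scale) with Vm in mV; the
    Hodgkin-Huxley-style exponential voltage dependence of channel gating.
    ``voltage_scale`` is *signed*: forward (alpha) rates use a positive scale
    so they grow with depolarization, backward (beta) rates a negative scale
    so they grow with repolarization.
``mass_action``
    rate = base_rate * [ligand] with base_rate in 1/(M*s); first-order
    association driven by the free-calcium concentration.

The discrete-time chain is advanced with the one-step matrix
``P[i, j] = k_ij(env) * dt`` for each edge and
``P[i, i] = 1 - sum_j P[i, j]``, valid only while every row's exit
probability stays below 1 — violating that is an error, never a silent
renormalization.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError, TimestepTooLargeError

AVOGADRO = 6.02214076e23

__all__ = [
    "AVOGADRO",
    "RateKind",
    "RateLaw",
    "Environment",
    "KineticState",
    "Transition",
    "KineticScheme",
    "transition_matrix",
    "max_admissible_dt",
    "build_vdcc_scheme",
    "build_calbindin_scheme",
    "load_preset",
    "PRESETS",
    "scheme_to_dict",
    "scheme_from_dict",
    "save_scheme",
    "load_scheme",
    "export_edge_list",
    "calbindin_state_name",
    "calbindin_bound_ions",
]


class RateKind(str, Enum):
    CONSTANT = "constant"
    VOLTAGE_EXP = "voltage_exp"
    MASS_ACTION = "mass_action"


@dataclass(frozen=True)
class Environment:
    """External drivers of the rate laws.

    membrane_voltage: mV.  free_calcium: molar concentration of free calcium.
    """

    membrane_voltage: float = -70.0
    free_calcium: float = 1e-7

    def __post_init__(self):
        if self.free_calcium < 0:
            raise ConfigurationError("free_calcium must be >= 0")
        if not math.isfinite(self.membrane_voltage):
            raise ConfigurationError("membrane_voltage must be finite")


@dataclass(frozen=True)
class RateLaw:
    kind: RateKind
    base_rate: float
    voltage_scale: float | None = None  # mV, signed; voltage_exp only
    ligand: str | None = None  # mass_action only

    def __post_init__(self):
        object.__setattr__(self, "kind", RateKind(self.kind))
        if self.base_rate < 0:
            raise ConfigurationError(f"base_rate must be >= 0, got {self.base_rate}")
        if self.kind is RateKind.VOLTAGE_EXP:
            if not self.voltage_scale:
                raise ConfigurationError("voltage_exp law requires nonzero voltage_scale")
        elif self.kind is RateKind.MASS_ACTION:
            if not self.ligand:
                raise ConfigurationError("mass_action law requires a ligand label")

    def evaluate(self, env: Environment) -> float:
        """Instantaneous rate (1/s) under the given environment."""
        if self.kind is RateKind.CONSTANT:
            return self.base_rate
        if self.kind is RateKind.VOLTAGE_EXP:
            return self.base_rate * math.exp(env.membrane_voltage / self.voltage_scale)
        return self.base_rate * env.free_calcium


@dataclass(frozen=True)
class KineticState:
    name: str
    index: int


@dataclass(frozen=True)
class Transition:
    source: int
    target: int
    law: RateLaw

    def __post_init__(self):
        if self.source == self.target:
            raise ConfigurationError("self-transitions are implicit; source must differ from target")


_KIND_CODE = {RateKind.CONSTANT: 0, RateKind.VOLTAGE_EXP: 1, RateKind.MASS_ACTION: 2}


class KineticScheme:
    """Validated state graph with vectorized rate evaluation.

    Connectivity is checked on the declared edge list (the structure of the
    scheme), not on the numeric rate values, so a scheme whose rates are all
    zero is still a valid — if inert — scheme.
    """

    def __init__(self, states: Sequence[KineticState], transitions: Sequence[Transition],
                 name: str = "scheme"):
        states = list(states)
        transitions = list(transitions)
        s = len(states)
        if s == 0:
            raise ConfigurationError("a scheme needs at least one state")
        if sorted(st.index for st in states) != list(range(s)):
            raise ConfigurationError("state indices must form a contiguous 0..s-1 range")
        names = [st.name for st in states]
        if len(set(names)) != s:
            raise ConfigurationError("state names must be unique")
        seen: set[tuple[int, int]] = set()
        for tr in transitions:
            if not (0 <= tr.source < s and 0 <= tr.target < s):
                raise ConfigurationError(f"transition {tr.source}->{tr.target} out of range")
            if (tr.source, tr.target) in seen:
                raise ConfigurationError(
                    f"duplicate transition {names[tr.source]}->{names[tr.target]}")
            seen.add((tr.source, tr.target))
        if s > 1:
            self._check_weakly_connected(s, transitions, names)

        self.name = name
        self.states = sorted(states, key=lambda st: st.index)
        self.transitions = transitions
        # flat arrays for vectorized rate evaluation
        self._src = np.array([t.source for t in transitions], dtype=np.intp)
        self._dst = np.array([t.target for t in transitions], dtype=np.intp)
        self._kind = np.array([_KIND_CODE[t.law.kind] for t in transitions], dtype=np.intp)
        self._base = np.array([t.law.base_rate for t in transitions], dtype=float)
        self._vscale = np.array(
            [t.law.voltage_scale if t.law.voltage_scale else np.inf for t in transitions],
            dtype=float)

    @staticmethod
    def _check_weakly_connected(s, transitions, names):
        adj = [[] for _ in range(s)]
        for tr in transitions:
            adj[tr.source].append(tr.target)
            adj[tr.target].append(tr.source)
        seen = {0}
        queue = deque([0])
        while queue:
            i = queue.popleft()
            for j in adj[i]:
                if j not in seen:
                    seen.add(j)
                    queue.append(j)
        if len(seen) != s:
            missing = [names[i] for i in range(s) if i not in seen]
            raise ConfigurationError(f"scheme graph is not weakly connected; unreachable: {missing}")

    # -- structural queries ------------------------------------------------

    @property
    def s(self) -> int:
        return len(self.states)

    @property
    def state_names(self) -> list[str]:
        return [st.name for st in self.states]

    @property
    def branch_counts(self) -> np.ndarray:
        """Out-degree b_i per state."""
        return np.bincount(self._src, minlength=self.s).astype(int)

    @property
    def max_branch(self) -> int:
        """b: the maximum number of adjacent states reachable from any state."""
        return int(self.branch_counts.max())

    def index_of(self, name: str) -> int:
        for st in self.states:
            if st.name == name:
                return st.index
        raise KeyError(name)

    # -- rate evaluation ---------------------------------------------------

    def rates(self, env: Environment) -> np.ndarray:
        """Per-transition rates (1/s), in edge-list order."""
        r = self._base.copy()
        vexp = self._kind == 1
        if vexp.any():
            r[vexp] *= np.exp(env.membrane_voltage / self._vscale[vexp])
        mass = self._kind == 2
        if mass.any():
            r[mass] *= env.free_calcium
        return r

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return self._src, self._dst


def max_admissible_dt(scheme: KineticScheme, env: Environment) -> float:
    """Largest dt for which every row's exit probability stays below 1."""
    rates = scheme.rates(env)
    exit_rates = np.bincount(scheme._src, weights=rates, minlength=scheme.s)
    worst = exit_rates.max()
    return math.inf if worst == 0 else 1.0 / worst


def transition_matrix(scheme: KineticScheme, env: Environment, dt: float) -> np.ndarray:
    """One-step row-stochastic matrix: off-diagonals k_ij*dt, diagonal the rest."""
    if dt <= 0:
        raise ConfigurationError(f"dt must be > 0, got {dt}")
    rates = scheme.rates(env)
    s = scheme.s
    P = np.zeros((s, s), dtype=float)
    np.add.at(P, (scheme._src, scheme._dst), rates * dt)
    exit_prob = P.sum(axis=1)
    if (exit_prob >= 1.0).any():
        i = int(np.argmax(exit_prob))
        exit_rates = np.bincount(scheme._src, weights=rates, minlength=s)
        raise TimestepTooLargeError(scheme.state_names[i], dt, 1.0 / exit_rates[i])
    P[np.diag_indices(s)] = 1.0 - exit_prob
    return P


# ---------------------------------------------------------------------------
# Built-in presynaptic schemes
# ---------------------------------------------------------------------------

VDCC_STATE_NAMES = ["C0", "C1", "C2", "C3", "O"]


def _load_packaged_yaml(fname: str) -> dict:
    text = resources.files("presynmc.data").joinpath(fname).read_text()
    return yaml.safe_load(text)


def default_vdcc_params() -> list[dict]:
    """Literature gating parameters for the four C0<->C1<->C2<->C3<->O steps."""
    return _load_packaged_yaml("vdcc5.yaml")["steps"]


def default_calbindin_params() -> dict:
    """Literature per-site on/off rates for the H and M site classes."""
    raw = _load_packaged_yaml("calbindin9.yaml")
    return {"high": dict(raw["high"]), "medium": dict(raw["medium"])}


def build_vdcc_scheme(rate_params: Sequence[Mapping] | None = None) -> KineticScheme:
    """Five-state voltage-dependent calcium channel: linear chain C0..C3, O.

    ``rate_params`` is a sequence of four mappings, one per step i (C_{i-1} to
    the next state), each providing ``alpha0``, ``v_alpha``, ``beta0``,
    ``v_beta`` (rates in 1/s, voltage scales in mV, all positive; the backward
    sign convention is applied internally).
    """
    if rate_params is None:
        rate_params = default_vdcc_params()
    if len(rate_params) != 4:
        raise ConfigurationError(f"VDCC scheme needs 4 rate steps, got {len(rate_params)}")
    states = [KineticState(n, i) for i, n in enumerate(VDCC_STATE_NAMES)]
    transitions = []
    for i, p in enumerate(rate_params):
        step = f"{VDCC_STATE_NAMES[i]}<->{VDCC_STATE_NAMES[i + 1]}"
        for key in ("alpha0", "v_alpha", "beta0", "v_beta"):
            if key not in p:
                raise ConfigurationError(f"missing parameter {key!r} for step {step}")
        transitions.append(Transition(i, i + 1, RateLaw(
            RateKind.VOLTAGE_EXP, float(p["alpha0"]), voltage_scale=+abs(float(p["v_alpha"])))))
        transitions.append(Transition(i + 1, i, RateLaw(
            RateKind.VOLTAGE_EXP, float(p["beta0"]), voltage_scale=-abs(float(p["v_beta"])))))
    return KineticScheme(states, transitions, name="vdcc5")


def calbindin_state_name(a: int, b: int) -> str:
    return f"H{a}M{b}"


def calbindin_state_index(a: int, b: int) -> int:
    return 3 * a + b


def calbindin_bound_ions(scheme_or_s=None) -> np.ndarray:
    """Ions bound per state (a+b), in state-index order of the 3x3 grid."""
    return np.array([a + b for a in range(3) for b in range(3)], dtype=int)


def build_calbindin_scheme(rate_params: Mapping | None = None) -> KineticScheme:
    """Nine-state calbindin buffer on the 3x3 occupancy grid HaMb.

    ``rate_params`` maps site classes ``high`` / ``medium`` to per-site
    ``k_on`` (1/(M*s)) and ``k_off`` (1/s).  Statistical multiplicity for two
    identical sites is applied here: binding the first site of a class is
    2x the per-site on-rate, binding the second 1x; unbinding from single
    occupancy is 1x the per-site off-rate, from double occupancy 2x.  If your
    constants already include multiplicity, pre-divide them.
    """
    if rate_params is None:
        rate_params = default_calbindin_params()
    for cls in ("high", "medium"):
        p = rate_params[cls]
        if float(p["k_on"]) < 0 or float(p["k_off"]) < 0:
            raise ConfigurationError(f"negative rate for {cls}-affinity site")
    kH_on, kH_off = float(rate_params["high"]["k_on"]), float(rate_params["high"]["k_off"])
    kM_on, kM_off = float(rate_params["medium"]["k_on"]), float(rate_params["medium"]["k_off"])

    states = [KineticState(calbindin_state_name(a, b), calbindin_state_index(a, b))
              for a in range(3) for b in range(3)]
    transitions = []
    for a in range(3):
        for b in range(3):
            i = calbindin_state_index(a, b)
            if a < 2:  # bind H site: 2x for first, 1x for second
                transitions.append(Transition(i, calbindin_state_index(a + 1, b), RateLaw(
                    RateKind.MASS_ACTION, (2 - a) * kH_on, ligand="calcium")))
            if a > 0:  # unbind H site: 1x from single, 2x from double
                transitions.append(Transition(i, calbindin_state_index(a - 1, b), RateLaw(
                    RateKind.CONSTANT, a * kH_off)))
            if b < 2:
                transitions.append(Transition(i, calbindin_state_index(a, b + 1), RateLaw(
                    RateKind.MASS_ACTION, (2 - b) * kM_on, ligand="calcium")))
            if b > 0:
                transitions.append(Transition(i, calbindin_state_index(a, b - 1), RateLaw(
                    RateKind.CONSTANT, b * kM_off)))
    return KineticScheme(states, transitions, name="calbindin9")


PRESETS = {"vdcc5": build_vdcc_scheme, "calbindin9": build_calbindin_scheme}


def load_preset(name: str) -> KineticScheme:
    try:
        return PRESETS[name]()
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


# ---------------------------------------------------------------------------
# Round-trippable scheme config and edge-list export
# ---------------------------------------------------------------------------

def scheme_to_dict(scheme: KineticScheme) -> dict:
    out = {"name": scheme.name, "states": scheme.state_names, "transitions": []}
    for tr in scheme.transitions:
        d = {"source": scheme.state_names[tr.source],
             "target": scheme.state_names[tr.target],
             "kind": tr.law.kind.value,
             "base_rate": tr.law.base_rate}
        if tr.law.kind is RateKind.VOLTAGE_EXP:
            d["voltage_scale"] = tr.law.voltage_scale
        if tr.law.kind is RateKind.MASS_ACTION:
            d["ligand"] = tr.law.ligand
        out["transitions"].append(d)
    return out


def scheme_from_dict(d: Mapping) -> KineticScheme:
    names = list(d["states"])
    idx = {n: i for i, n in enumerate(names)}
    states = [KineticState(n, i) for i, n in enumerate(names)]
    transitions = []
    for row in d["transitions"]:
        law = RateLaw(RateKind(row["kind"]), float(row["base_rate"]),
                      voltage_scale=row.get("voltage_scale"),
                      ligand=row.get("ligand"))
        transitions.append(Transition(idx[row["source"]], idx[row["target"]], law))
    return KineticScheme(states, transitions, name=d.get("name", "scheme"))


def save_scheme(scheme: KineticScheme, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scheme_to_dict(scheme), fh, sort_keys=False)


def load_scheme(path) -> KineticScheme:
    with open(path) as fh:
        return scheme_from_dict(yaml.safe_load(fh))


def export_edge_list(scheme: KineticScheme) -> str:
    """Tab-separated edge list: source, target, kind, base_rate, scale."""
    lines = ["source\ttarget\tkind\tbase_rate\tscale"]
    for tr in scheme.transitions:
        scale = tr.law.voltage_scale if tr.law.kind is RateKind.VOLTAGE_EXP else (
            tr.law.ligand if tr.law.kind is RateKind.MASS_ACTION else "")
        lines.append(f"{scheme.state_names[tr.source]}\t{scheme.state_names[tr.target]}\t"
                     f"{tr.law.kind.value}\t{tr.law.base_rate:g}\t{scale}")
    return "\n".join(lines) + "\n"
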