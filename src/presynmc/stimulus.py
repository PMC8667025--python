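"""Membrane-voltage stimulus traces.

The voltage-dependent rates are driven by a uniformly sampled membrane
potential time series.  An action-potential template (difference of
exponentials) is built in; arbitrary two-column time/voltage text files can
be loaded and are linearly resampled to the simulation timestep.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, FormatError

__all__ = [
    "VoltageTrace",
    "make_action_potential",
    "constant_trace",
    "load_voltage_trace",
    "save_voltage_trace",
    "concatenate_traces",
]


@dataclass(frozen=True)
class VoltageTrace:
    """Uniformly sampled membrane potential (mV) starting at t0, step dt (s)."""

    t0: float
    dt: float
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.dt <= 0:
            raise ConfigurationError("trace dt must be > 0")
        if v.ndim != 1 or v.size == 0:
            raise ConfigurationError("trace values must be a non-empty 1-D array")
        if not np.all(np.isfinite(v)):
            raise ConfigurationError("trace contains non-finite values")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        return self.dt * self.values.size

    def value_at(self, t: float) -> float:
        """Nearest-sample lookup, clamped to the trace ends."""
        i = int(round((t - self.t0) / self.dt))
        return float(self.values[min(max(i, 0), self.values.size - 1)])

    def resample(self, dt: float) -> "VoltageTrace":
        """Linear resampling to a new step; identity when dt already matches."""
        if np.isclose(dt, self.dt, rtol=1e-12, atol=0.0):
            return self
        n_new = max(int(round(self.duration / dt)), 1)
        t_new = self.t0 + dt * np.arange(n_new)
        v_new = np.interp(t_new, self.times, self.values)
        return VoltageTrace(self.t0, dt, v_new)


def constant_trace(voltage_mV: float, duration_s: float, dt_s: float) -> VoltageTrace:
    n = max(int(round(duration_s / dt_s)), 1)
    return VoltageTrace(0.0, dt_s, np.full(n, float(voltage_mV)))


def make_action_potential(resting_mV: float = -70.0, peak_mV: float = 30.0,
                          onset_s: float = 1e-3, rise_tau_s: float = 2e-4,
                          fall_tau_s: float = 5e-4, duration_s: float = 10e-3,
                          dt_s: float = 1e-6) -> VoltageTrace:
    """Double-exponential action-potential template.

    After onset the depolarization follows
    ``A * (exp(-t'/tau_fall) - exp(-t'/tau_rise))`` with the amplitude ``A``
    normalized so the waveform peaks exactly at ``peak_mV``, rising from and
    monotonically returning to ``resting_mV``.
    """
    if rise_tau_s <= 0 or fall_tau_s <= 0:
        raise ConfigurationError("time constants must be > 0")
    if onset_s < 0 or duration_s <= onset_s:
        raise ConfigurationError("require duration_s > onset_s >= 0")
    if dt_s <= 0:
        raise ConfigurationError("dt_s must be > 0")
    n = max(int(round(duration_s / dt_s)), 1)
    t = dt_s * np.arange(n)
    v = np.full(n, float(resting_mV))
    if peak_mV == resting_mV:
        return VoltageTrace(0.0, dt_s, v)
    tp = t - onset_s
    active = tp > 0
    if fall_tau_s == rise_tau_s:
        # limit of the difference form: t' * exp(1 - t'/tau) / tau peaks at 1
        shape = np.where(active, tp / rise_tau_s * np.exp(1.0 - tp / rise_tau_s), 0.0)
    else:
        # analytic peak of exp(-t/tf) - exp(-t/tr)
        t_star = (rise_tau_s * fall_tau_s / (fall_tau_s - rise_tau_s)
                  * np.log(fall_tau_s / rise_tau_s))
        norm = np.exp(-t_star / fall_tau_s) - np.exp(-t_star / rise_tau_s)
        shape = np.where(active,
                         (np.exp(-tp / fall_tau_s) - np.exp(-tp / rise_tau_s)) / norm,
                         0.0)
    v = resting_mV + (peak_mV - resting_mV) * shape
    return VoltageTrace(0.0, dt_s, v)


def load_voltage_trace(source, dt_s: float) -> VoltageTrace:
    """Read a two-column (time_s, voltage_mV) text stream or path.

    Whitespace- or comma-separated; '#' comments and blank lines are skipped.
    Times must be strictly increasing; the trace is linearly resampled to
    ``dt_s`` with end values clamped outside the tabulated range.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source) as fh:
            return load_voltage_trace(fh, dt_s)
    times, volts = [], []
    for lineno, line in enumerate(source, start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        parts = stripped.replace(",", " ").split()
        if len(parts) != 2:
            raise FormatError(f"line {lineno}: expected 2 columns, got {len(parts)}")
        try:
            t, v = float(parts[0]), float(parts[1])
        except ValueError:
            raise FormatError(f"line {lineno}: unparseable row {stripped!r}") from None
        times.append(t)
        volts.append(v)
    if len(times) < 2:
        raise FormatError("need at least 2 rows of (time, voltage)")
    times = np.asarray(times)
    volts = np.asarray(volts)
    if not np.all(np.diff(times) > 0):
        bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 2
        raise FormatError(f"line {bad}: times must be strictly increasing")
    duration = times[-1] - times[0]
    n = max(int(round(duration / dt_s)) + 1, 1)
    t_new = times[0] + dt_s * np.arange(n)
    v_new = np.interp(t_new, times, volts)  # np.interp clamps to end values
    return VoltageTrace(float(times[0]), dt_s, v_new)


def save_voltage_trace(trace: VoltageTrace, path_or_stream) -> None:
    if isinstance(path_or_stream, (str, bytes)) or hasattr(path_or_stream, "__fspath__"):
        with open(path_or_stream, "w") as fh:
            save_voltage_trace(trace, fh)
        return
    for t, v in zip(trace.times, trace.values):
        path_or_stream.write(f"{t:.9g} {v:.9g}\n")


def concatenate_traces(traces) -> VoltageTrace:
    """Join traces with a common dt back to back (e.g. stimulus trains)."""
    traces = list(traces)
    if not traces:
        raise ConfigurationError("nothing to concatenate")
    dt = traces[0].dt
    if any(not np.isclose(tr.dt, dt) for tr in traces):
        raise ConfigurationError("all traces must share the same dt")
    return VoltageTrace(traces[0].t0, dt, np.concatenate([tr.values for tr in traces]))
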