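"""Simulation driver: forward-Euler integration of a clamp protocol, trace
recording, and a higher-order reference integrator used as a test oracle.

:func:`run` is the production path — plain forward Euler at a fixed step
(default 0.01 ms), recording voltage, net current, and per-channel current
and conductance at every step.  :func:`reference_run` computes the same
trajectory with a classical fixed-step 4th-order Runge-Kutta scheme; it is
deliberately independent of the Euler code path and exists so tests can check
the first-order scheme against a much more accurate integration of the same
ODE system.

Conductance traces report g_max times the gate product for ohmic channels
(identical to current over driving force) and the chord conductance
I/(V - E_Nernst) for the constant-field calcium channels, zero where the
driving force vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .channels import (
    ACurrentChannel,
    GHKChannel,
    OhmicChannel,
    a_current_conductance,
    gate_steady_state,
    gate_time_constant,
)
from .membrane import (
    MembraneModel,
    MembraneState,
    NumericalInstabilityError,
    channel_currents,
    find_rest,
    initial_state,
)
from .protocol import ClampProtocol, stimulus_at, validate

__all__ = ["SimulationConfig", "TimeSeriesResult", "run", "reference_run",
           "spike_count"]

#: Default explicit-Euler stability guard on dt, ms.
DT_GUARD_MS = 0.1


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical settings for a run.

    ``dt`` defaults to 0.01 ms — fast Na activation (tau well below 0.1 ms
    near threshold) needs sub-0.1 ms explicit steps; steps above 0.1 ms are
    rejected unless ``allow_large_dt`` is set.  ``initial_voltage`` seeds the
    current-clamp run (gates start at their steady state there);
    ``auto_rest`` replaces it with the numerically located resting potential.
    ``temperature`` (K) is applied when building the default model.
    """

    dt: float = 0.01
    initial_voltage: float = -65.0
    temperature: float = 295.0
    auto_rest: bool = False
    allow_large_dt: bool = False
    clamp_sign_printed: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.dt > DT_GUARD_MS and not self.allow_large_dt:
            raise ValueError(
                f"dt={self.dt} ms exceeds the {DT_GUARD_MS} ms stability "
                f"guard; set allow_large_dt=True to override")


@dataclass
class TimeSeriesResult:
    """Recorded traces: one sample per integration step (plus t=0).

    ``currents`` and ``conductances`` map channel key -> trace (nA / uS).
    All traces share the same length; times are uniformly spaced.
    """

    times: np.ndarray
    voltage: np.ndarray
    net_current: np.ndarray
    currents: dict[str, np.ndarray] = field(default_factory=dict)
    conductances: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.times)
        if n == 0:
            raise ValueError("empty trace")
        for name, arr in [("voltage", self.voltage),
                          ("net_current", self.net_current),
                          *self.currents.items(),
                          *self.conductances.items()]:
            if len(arr) != n:
                raise ValueError(f"trace {name!r} has length {len(arr)}, "
                                 f"expected {n}")
        if n > 1:
            dts = np.diff(self.times)
            if not np.all(dts > 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-12):
                raise ValueError("times must be uniformly spaced")

    @property
    def channel_keys(self) -> list[str]:
        return list(self.currents.keys())

    def __len__(self) -> int:
        return len(self.times)


def _num_steps(total_ms: float, dt: float) -> int:
    # tolerate binary rounding when dt divides the duration
    return int(np.floor(total_ms / dt + 1e-9))


def _chord_conductance(ch, gate_values: dict[str, float], voltage: float,
                       current: float, temperature: float) -> float:
    if isinstance(ch, OhmicChannel):
        g = ch.g_max
        for gk in ch.gates:
            g *= gate_values[gk.name] ** gk.exponent
        return g
    if isinstance(ch, ACurrentChannel):
        return a_current_conductance(ch, gate_values["m1"], gate_values["h1"],
                                     gate_values["m2"], gate_values["h2"])
    assert isinstance(ch, GHKChannel)
    driving = voltage - ch.reversal(temperature)
    if abs(driving) < 1e-9:
        return 0.0
    return current / driving


def _resolve_baseline(model: MembraneModel, protocol: ClampProtocol) -> float:
    if protocol.baseline is not None:
        return protocol.baseline
    if protocol.mode == "current":
        return 0.0
    return find_rest(model)


def run(model: MembraneModel, protocol: ClampProtocol,
        config: SimulationConfig | None = None) -> TimeSeriesResult:
    """Integrate the protocol with forward Euler and record all traces.

    Gates start at their steady state for the initial voltage (the resolved
    holding baseline in voltage mode).  Trace length is
    ``floor(total/dt) + 1``.  Raises :class:`NumericalInstabilityError`
    naming the failing step if the state becomes non-finite.
    """
    config = config or SimulationConfig()
    validate(protocol)
    dt = config.dt
    baseline = _resolve_baseline(model, protocol)
    if protocol.mode == "voltage":
        v0 = stimulus_at(protocol, 0.0, baseline)
    elif config.auto_rest:
        v0 = find_rest(model)
    else:
        v0 = config.initial_voltage
    state = initial_state(model, v0)

    n_steps = _num_steps(protocol.total_ms, dt)
    n = n_steps + 1
    ckeys = list(model.channels.keys())
    times = np.empty(n)
    voltage = np.empty(n)
    net_current = np.empty(n)
    cur = {k: np.empty(n) for k in ckeys}
    cond = {k: np.empty(n) for k in ckeys}

    from .membrane import _advance_gates_and_calcium

    for k in range(n):
        t = k * dt
        stim = stimulus_at(protocol, min(t, protocol.total_ms), baseline)
        if protocol.mode == "voltage":
            state = replace(state, voltage=stim)
        if not np.isfinite(state.voltage):
            raise NumericalInstabilityError(
                f"non-finite voltage at step {k} (t={t:.4g} ms); "
                f"reduce dt below {dt} ms")
        currents = channel_currents(model, state)
        i_sum = sum(currents.values())
        times[k] = t
        voltage[k] = state.voltage
        if protocol.mode == "voltage":
            net_current[k] = -i_sum if config.clamp_sign_printed else i_sum
        else:
            net_current[k] = stim
        for ckey in ckeys:
            ch = model.channels[ckey]
            gv = {gk.name: state.gates[f"{ckey}/{gk.name}"]
                  for gk in ch.gates}
            cur[ckey][k] = currents[ckey]
            cond[ckey][k] = _chord_conductance(ch, gv, state.voltage,
                                               currents[ckey],
                                               model.temperature)
        if k == n_steps:
            break
        gates, _, ca = _advance_gates_and_calcium(model, state,
                                                  state.voltage, currents, dt)
        if protocol.mode == "voltage":
            state = MembraneState(time=t + dt, voltage=state.voltage,
                                  gates=gates, calcium=ca)
        else:
            v_new = state.voltage + dt / model.capacitance * (stim - i_sum)
            state = MembraneState(time=t + dt, voltage=v_new, gates=gates,
                                  calcium=ca)
    return TimeSeriesResult(times=times, voltage=voltage,
                            net_current=net_current, currents=cur,
                            conductances=cond)


def reference_run(model: MembraneModel, protocol: ClampProtocol,
                  config: SimulationConfig | None = None) -> TimeSeriesResult:
    """Same trajectory via classical fixed-step 4th-order Runge-Kutta.

    A test oracle only: gates are not clamped inside stages (the smooth ODE
    keeps them in range), and the recording schema matches :func:`run` so
    traces are directly comparable at equal dt.
    """
    config = config or SimulationConfig()
    validate(protocol)
    dt = config.dt
    baseline = _resolve_baseline(model, protocol)
    if protocol.mode == "voltage":
        v0 = stimulus_at(protocol, 0.0, baseline)
    elif config.auto_rest:
        v0 = find_rest(model)
    else:
        v0 = config.initial_voltage
    gate_keys = model.gate_keys()
    gate_kin = []
    for ckey, ch in model.channels.items():
        for gk in ch.gates:
            gate_kin.append(gk)
    pool = model.calcium_pool
    st0 = initial_state(model, v0)
    y = np.array([st0.voltage] + [st0.gates[k] for k in gate_keys]
                 + [st0.calcium])

    def make_state(t: float, y: np.ndarray) -> MembraneState:
        return MembraneState(time=t, voltage=float(y[0]),
                             gates={k: float(v) for k, v
                                    in zip(gate_keys, y[1:-1])},
                             calcium=float(y[-1]))

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        tt = min(max(t, 0.0), protocol.total_ms)
        stim = stimulus_at(protocol, tt, baseline)
        v = stim if protocol.mode == "voltage" else float(y[0])
        ca = float(y[-1])
        st = make_state(tt, y)
        if protocol.mode == "voltage":
            st = replace(st, voltage=v)
        currents = channel_currents(model, st, voltage=v)
        dy = np.empty_like(y)
        if protocol.mode == "voltage":
            dy[0] = 0.0
        else:
            dy[0] = (stim - sum(currents.values())) / model.capacitance
        for i, (key, gk) in enumerate(zip(gate_keys, gate_kin), start=1):
            x = float(y[i])
            dy[i] = (gate_steady_state(gk, v, ca) - x) / gate_time_constant(gk, v)
        i_ca = currents.get("ca_t", 0.0) + currents.get("ca_l", 0.0)
        dy[-1] = -pool.influx_scale * i_ca - (ca - pool.ca_rest) / pool.tau_ca
        return dy

    n_steps = _num_steps(protocol.total_ms, dt)
    n = n_steps + 1
    ckeys = list(model.channels.keys())
    times = np.empty(n)
    voltage = np.empty(n)
    net_current = np.empty(n)
    cur = {k: np.empty(n) for k in ckeys}
    cond = {k: np.empty(n) for k in ckeys}

    for k in range(n):
        t = k * dt
        stim = stimulus_at(protocol, min(t, protocol.total_ms), baseline)
        if protocol.mode == "voltage":
            y[0] = stim
        st = make_state(t, y)
        currents = channel_currents(model, st)
        i_sum = sum(currents.values())
        times[k] = t
        voltage[k] = st.voltage
        if protocol.mode == "voltage":
            net_current[k] = -i_sum if config.clamp_sign_printed else i_sum
        else:
            net_current[k] = stim
        for ckey in ckeys:
            ch = model.channels[ckey]
            gv = {gk.name: st.gates[f"{ckey}/{gk.name}"] for gk in ch.gates}
            cur[ckey][k] = currents[ckey]
            cond[ckey][k] = _chord_conductance(ch, gv, st.voltage,
                                               currents[ckey],
                                               model.temperature)
        if k == n_steps:
            break
        k1 = rhs(t, y)
        k2 = rhs(t + dt / 2, y + dt / 2 * k1)
        k3 = rhs(t + dt / 2, y + dt / 2 * k2)
        k4 = rhs(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y)):
            raise NumericalInstabilityError(
                f"non-finite reference state at step {k + 1}; reduce dt")
    return TimeSeriesResult(times=times, voltage=voltage,
                            net_current=net_current, currents=cur,
                            conductances=cond)


def spike_count(trace: np.ndarray, threshold: float = 0.0) -> int:
    """Number of upward threshold crossings (strictly below -> at-or-above)."""
    v = np.asarray(trace, dtype=float)
    if v.size == 0:
        raise ValueError("empty voltage trace")
    below = v[:-1] < threshold
    at_or_above = v[1:] >= threshold
    return int(np.count_nonzero(below & at_or_above))
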