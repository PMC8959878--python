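"""Single-compartment membrane: channel assembly and the two clamp-mode
update laws.

Current clamp integrates the membrane equation

    C dV/dt = I_applied - sum_n I_n

with forward Euler (all right-hand sides evaluated at the start of the step:
voltage update uses start-of-step gates, gates and the calcium pool advance at
the start-of-step voltage).  Voltage clamp pins V to the holding value (ideal
clamp, no series resistance) and records the net clamp current as the negative
sum of the ionic currents, matching the published sign convention: outward
ionic current positive, depolarizing applied current positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .channels import (
    ACurrentChannel,
    CalciumPool,
    GHKChannel,
    OhmicChannel,
    a_current,
    advance_gate,
    build_default_channels,
    gate_steady_state,
    ghk_current,
    ohmic_current,
    update_calcium,
)

__all__ = [
    "MembraneModel",
    "MembraneState",
    "build_default_model",
    "init_gates_at_voltage",
    "initial_state",
    "channel_currents",
    "net_ionic_current",
    "step_current_clamp",
    "step_voltage_clamp",
    "find_rest",
    "NumericalInstabilityError",
]

Channel = OhmicChannel | GHKChannel | ACurrentChannel


class NumericalInstabilityError(RuntimeError):
    """Raised when the explicit Euler scheme produced a non-finite state."""


@dataclass(frozen=True)
class MembraneModel:
    """A single isopotential compartment carrying a set of channels.

    ``capacitance`` in nF (default 0.01).  ``channels`` is an ordered mapping
    keyed by the stable roster keys; the default model carries exactly the
    eleven mechanisms.  ``temperature`` (K) enters the Nernst and GHK
    relations only — no Q10 scaling of kinetics.
    """

    capacitance: float = 0.01
    channels: dict[str, Channel] = field(default_factory=dict)
    calcium_pool: CalciumPool = field(default_factory=CalciumPool)
    temperature: float = 295.0

    def __post_init__(self) -> None:
        if self.capacitance <= 0:
            raise ValueError("capacitance must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    def gate_keys(self) -> list[str]:
        """Flat ``channel/gate`` keys in roster order."""
        keys = []
        for ckey, ch in self.channels.items():
            for gk in ch.gates:
                keys.append(f"{ckey}/{gk.name}")
        return keys


@dataclass(frozen=True)
class MembraneState:
    """Instantaneous membrane state.

    ``gates`` maps ``channel/gate`` -> value in [0,1]; ``calcium`` is the
    intracellular free-calcium concentration (mM); ``last_net_current`` holds
    the recorded clamp current (nA) after a voltage-clamp step.
    """

    time: float
    voltage: float
    gates: dict[str, float]
    calcium: float
    last_net_current: float = 0.0


def build_default_model(capacitance: float = 0.01,
                        temperature: float = 295.0,
                        calcium_pool: CalciumPool | None = None,
                        **channel_kwargs) -> MembraneModel:
    """The default eleven-channel mammalian-style membrane.

    ``channel_kwargs`` are forwarded to
    :func:`ionclamp.channels.build_default_channels` (``magnitudes``,
    ``reversals``, ``gate_overrides``).
    """
    return MembraneModel(
        capacitance=capacitance,
        channels=build_default_channels(temperature=temperature,
                                        **channel_kwargs),
        calcium_pool=calcium_pool or CalciumPool(),
        temperature=temperature,
    )


def init_gates_at_voltage(model: MembraneModel, v0: float,
                          ca0: float | None = None) -> dict[str, float]:
    """Set every gate to its steady state at (v0, ca0): a fixed point of the
    gate dynamics, so one Euler step at constant v0 changes nothing."""
    if not math.isfinite(v0):
        raise ValueError("v0 must be finite")
    ca = model.calcium_pool.ca_rest if ca0 is None else ca0
    gates = {}
    for ckey, ch in model.channels.items():
        for gk in ch.gates:
            gates[f"{ckey}/{gk.name}"] = gate_steady_state(gk, v0, ca)
    return gates


def initial_state(model: MembraneModel, v0: float,
                  ca0: float | None = None) -> MembraneState:
    """Membrane state at t=0 with gates initialized at steady state."""
    ca = model.calcium_pool.ca_rest if ca0 is None else ca0
    return MembraneState(time=0.0, voltage=v0,
                         gates=init_gates_at_voltage(model, v0, ca),
                         calcium=ca)


def _channel_current(ckey: str, ch: Channel, state: MembraneState,
                     voltage: float, temperature: float) -> float:
    gv = {gk.name: state.gates[f"{ckey}/{gk.name}"] for gk in ch.gates}
    if isinstance(ch, GHKChannel):
        return ghk_current(ch, gv, voltage, temperature)
    if isinstance(ch, ACurrentChannel):
        return a_current(ch, gv["m1"], gv["h1"], gv["m2"], gv["h2"], voltage)
    return ohmic_current(ch, gv, voltage)


def channel_currents(model: MembraneModel, state: MembraneState,
                     voltage: float | None = None) -> dict[str, float]:
    """Instantaneous current (nA) of every channel at the given state.

    ``voltage`` overrides ``state.voltage`` (used by the voltage clamp).
    Raises ``KeyError`` naming the missing gate if state and model disagree.
    """
    v = state.voltage if voltage is None else voltage
    return {ckey: _channel_current(ckey, ch, state, v, model.temperature)
            for ckey, ch in model.channels.items()}


def net_ionic_current(model: MembraneModel, state: MembraneState,
                      voltage: float | None = None) -> float:
    """Sum of all channel currents, nA (outward positive)."""
    return sum(channel_currents(model, state, voltage).values())


def _advance_gates_and_calcium(model: MembraneModel, state: MembraneState,
                               voltage: float, currents: dict[str, float],
                               dt: float) -> tuple[dict[str, float], CalciumPool, float]:
    gates = {}
    for ckey, ch in model.channels.items():
        for gk in ch.gates:
            key = f"{ckey}/{gk.name}"
            gates[key] = advance_gate(state.gates[key], gk, voltage, dt,
                                      calcium=state.calcium)
    i_ca = currents.get("ca_t", 0.0) + currents.get("ca_l", 0.0)
    pool = replace(model.calcium_pool, ca=state.calcium)
    pool = update_calcium(pool, i_ca, dt)
    return gates, pool, pool.ca


def step_current_clamp(model: MembraneModel, state: MembraneState,
                       i_applied: float, dt: float) -> MembraneState:
    """One fully explicit Euler step under current clamp.

    ``V' = V + (dt/C) (I_applied - sum I_n)`` with all right-hand sides taken
    at the start of the step.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    currents = channel_currents(model, state)
    i_net = sum(currents.values())
    v_new = state.voltage + dt / model.capacitance * (i_applied - i_net)
    if not math.isfinite(v_new):
        raise NumericalInstabilityError(
            f"non-finite voltage after step at t={state.time:.4g} ms "
            f"(dt={dt} ms); reduce dt")
    gates, _, ca = _advance_gates_and_calcium(model, state, state.voltage,
                                              currents, dt)
    return MembraneState(time=state.time + dt, voltage=v_new, gates=gates,
                         calcium=ca, last_net_current=i_applied)


def step_voltage_clamp(model: MembraneModel, state: MembraneState,
                       v_hold: float, dt: float,
                       printed_sign: bool = True) -> MembraneState:
    """One Euler step under ideal voltage clamp (instantaneous settling).

    Voltage is pinned to ``v_hold``; gates and calcium advance at ``v_hold``;
    the recorded clamp current is ``-sum I_n`` (``printed_sign=False`` flips
    the recorded sign to ``+sum I_n``).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    currents = channel_currents(model, state, voltage=v_hold)
    i_net = -sum(currents.values()) if printed_sign else sum(currents.values())
    gates, _, ca = _advance_gates_and_calcium(model, state, v_hold,
                                              currents, dt)
    return MembraneState(time=state.time + dt, voltage=v_hold, gates=gates,
                         calcium=ca, last_net_current=i_net)


def find_rest(model: MembraneModel, v_lo: float = -90.0, v_hi: float = -40.0,
              tol: float = 1e-9) -> float:
    """Numerically locate the resting potential: the zero of the steady-state
    net ionic current on [v_lo, v_hi].

    The steady-state current uses every gate at its steady state (calcium at
    rest).  The interval is scanned on a 0.5 mV grid for the most
    hyperpolarized sign change, then refined with Brent's method.
    """
    from scipy.optimize import brentq

    def i_ss(v: float) -> float:
        st = initial_state(model, v)
        return net_ionic_current(model, st)

    n = int(round((v_hi - v_lo) / 0.5))
    vs = [v_lo + i * (v_hi - v_lo) / n for i in range(n + 1)]
    prev_v, prev_i = vs[0], i_ss(vs[0])
    if prev_i == 0.0:
        return prev_v
    for v in vs[1:]:
        cur = i_ss(v)
        if cur == 0.0:
            return v
        if prev_i * cur < 0:
            return float(brentq(i_ss, prev_v, v, xtol=tol))
        prev_v, prev_i = v, cur
    raise ValueError(f"no resting potential found in [{v_lo}, {v_hi}] mV")
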