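"""Ion-channel mechanisms: gating kinetics, current laws, and the calcium pool.

The membrane carries eleven Hodgkin-Huxley-style mechanisms.  Ohmic channels
(Na, K, Cl, the two leaks, A, M, KCa, AHP) obey ``I = g_max * prod(gate^p) *
(V - E)`` with the reversal ``E`` fixed or derived from ion concentrations by
the Nernst equation.  The two calcium channels (T-type and L-type) follow the
Goldman-Hodgkin-Katz constant-field relation, which captures the strong
rectification produced by the ~4 orders of magnitude calcium gradient.

Gating variables relax first-order toward a voltage-dependent steady state
``x_inf(V)`` with time constant ``tau(V)``:

    dx/dt = (x_inf(V) - x) / tau(V)

Steady states are Boltzmann sigmoids, time constants are bell curves over
voltage; every constant lives in the default parameter table at the bottom of
this module and can be overridden through the config file.  Calcium-sensitive
gates (KCa, AHP) multiply in a Michaelis factor ``ca / (ca + Kd)``.

Units throughout: mV, ms, nA, uS, nF, mM, K.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "GateKinetics",
    "OhmicChannel",
    "GHKChannel",
    "ACurrentChannel",
    "CalciumPool",
    "nernst_potential",
    "ghk_flux",
    "ghk_current",
    "gate_steady_state",
    "gate_time_constant",
    "advance_gate",
    "ohmic_current",
    "a_current_conductance",
    "a_current",
    "update_calcium",
    "CHANNEL_KEYS",
    "DEFAULT_CONCENTRATIONS",
    "build_default_channels",
]

logger = logging.getLogger(__name__)

#: CODATA 2018 molar gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314462618
#: CODATA 2018 Faraday constant, C mol^-1.
FARADAY = 96485.33212

#: Dimensionless threshold below which the GHK flux switches to its series
#: expansion around V = 0 (|zFV/RT| < this).
_GHK_SERIES_THRESHOLD = 1e-4


def nernst_potential(valence: int, conc_out: float, conc_in: float,
                     temperature: float) -> float:
    """Nernst (reversal) potential in mV.

    Parameters
    ----------
    valence : int
        Ion charge number z (nonzero; negative for anions).
    conc_out, conc_in : float
        Extracellular / intracellular concentrations, mM (both > 0).
    temperature : float
        Absolute temperature, K (> 0).
    """
    if conc_out <= 0:
        raise ValueError(f"conc_out must be positive, got {conc_out}")
    if conc_in <= 0:
        raise ValueError(f"conc_in must be positive, got {conc_in}")
    if valence == 0:
        raise ValueError("valence must be nonzero")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return (GAS_CONSTANT * temperature / (valence * FARADAY)
            * math.log(conc_out / conc_in) * 1000.0)


@dataclass(frozen=True)
class GateKinetics:
    """One Hodgkin-Huxley gating variable.

    ``steady_state`` is a Boltzmann sigmoid ``1/(1+exp(-(V-v_half)/slope))``
    (positive slope: activation; negative: inactivation), optionally scaled by
    a calcium Michaelis factor.  ``time_constant`` is
    ``tau_min + tau_amp * exp(-((V-tau_vpeak)/tau_sigma)^2)`` — strictly
    positive for tau_min > 0.

    ``exponent`` is the integer power the gate enters the conductance with.
    ``ca_kd`` (mM), when set, multiplies the steady state by ``ca/(ca+Kd)``;
    ``ca_only`` gates (AHP) drop the voltage dependence entirely.
    """

    name: str
    v_half: float = 0.0
    slope: float = 10.0
    tau_min: float = 1.0
    tau_amp: float = 0.0
    tau_vpeak: float = 0.0
    tau_sigma: float = 30.0
    exponent: int = 1
    ca_kd: float | None = None
    ca_only: bool = False

    def __post_init__(self) -> None:
        if self.tau_min <= 0:
            raise ValueError(f"gate {self.name}: tau_min must be > 0")
        if self.tau_amp < 0:
            raise ValueError(f"gate {self.name}: tau_amp must be >= 0")
        if self.exponent < 1:
            raise ValueError(f"gate {self.name}: exponent must be >= 1")

    def steady_state(self, voltage: float, calcium: float = 0.0) -> float:
        return gate_steady_state(self, voltage, calcium)

    def time_constant(self, voltage: float) -> float:
        return gate_time_constant(self, voltage)


def gate_steady_state(kinetics: GateKinetics, voltage: float,
                      calcium: float = 0.0) -> float:
    """Steady-state value x_inf in [0, 1] at the given voltage (and calcium)."""
    if kinetics.ca_only:
        kd = kinetics.ca_kd if kinetics.ca_kd is not None else 1.0
        ca = max(calcium, 0.0)
        return ca / (ca + kd)
    x = (voltage - kinetics.v_half) / kinetics.slope
    # guard exp overflow far outside the physiological range
    if x < -500.0:
        s = 0.0
    elif x > 500.0:
        s = 1.0
    else:
        s = 1.0 / (1.0 + math.exp(-x))
    if kinetics.ca_kd is not None:
        ca = max(calcium, 0.0)
        s *= ca / (ca + kinetics.ca_kd)
    return s


def gate_time_constant(kinetics: GateKinetics, voltage: float) -> float:
    """Relaxation time constant tau(V) in ms, strictly positive."""
    if kinetics.tau_amp == 0.0:
        return kinetics.tau_min
    z = (voltage - kinetics.tau_vpeak) / kinetics.tau_sigma
    return kinetics.tau_min + kinetics.tau_amp * math.exp(-z * z)


def advance_gate(value: float, kinetics: GateKinetics, voltage: float,
                 dt: float, calcium: float = 0.0) -> float:
    """One forward-Euler step of the gate ODE, clamped to [0, 1].

    ``x' = x + dt * (x_inf - x) / tau``.  Overshoot outside the unit interval
    (possible when dt approaches tau) is clamped with a debug log.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    x_inf = gate_steady_state(kinetics, voltage, calcium)
    tau = gate_time_constant(kinetics, voltage)
    new = value + dt * (x_inf - value) / tau
    if new < 0.0 or new > 1.0:
        logger.debug("gate %s overshot to %.3g at V=%.2f mV (dt=%g, tau=%g); "
                     "clamping", kinetics.name, new, voltage, dt, tau)
        new = min(1.0, max(0.0, new))
    return new


@dataclass(frozen=True)
class OhmicChannel:
    """Ohmic (linear driving-force) channel: I = g_max * gates * (V - E).

    ``g_max`` in uS, ``reversal`` in mV.  ``gates`` may be empty (pure leak).
    """

    name: str
    g_max: float
    reversal: float
    gates: tuple[GateKinetics, ...] = ()

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValueError(f"channel {self.name}: g_max must be >= 0")


def ohmic_current(channel: OhmicChannel, gate_values: dict[str, float],
                  voltage: float) -> float:
    """Instantaneous ohmic current in nA (uS * mV = nA).

    ``gate_values`` maps gate name -> current value; each gate enters with its
    configured exponent.
    """
    g = channel.g_max
    for gk in channel.gates:
        g *= gate_values[gk.name] ** gk.exponent
    return g * (voltage - channel.reversal)


@dataclass(frozen=True)
class GHKChannel:
    """Constant-field (Goldman-Hodgkin-Katz) channel.

    ``p_max`` is a lumped permeability scale chosen so the current comes out
    in nA with concentrations in mM and voltage in mV (membrane area and the
    z^2 F^2 / RT prefactor are folded in); see :func:`ghk_flux`.
    """

    name: str
    p_max: float
    valence: int
    conc_in: float
    conc_out: float
    gates: tuple[GateKinetics, ...] = ()

    def __post_init__(self) -> None:
        if self.p_max < 0:
            raise ValueError(f"channel {self.name}: p_max must be >= 0")
        if self.conc_in <= 0:
            raise ValueError(f"channel {self.name}: conc_in must be > 0")
        if self.conc_out <= 0:
            raise ValueError(f"channel {self.name}: conc_out must be > 0")

    def reversal(self, temperature: float) -> float:
        """Nernst potential of the permeant ion, mV."""
        return nernst_potential(self.valence, self.conc_out, self.conc_in,
                                temperature)


def ghk_flux(valence: int, conc_in: float, conc_out: float, voltage: float,
             temperature: float) -> float:
    """Normalized GHK flux (mM units): u*(ci - co*exp(-u))/(1 - exp(-u)).

    ``u = zFV/RT`` is the reduced voltage.  The removable singularity at
    u = 0 is handled with a 4th-order series of u/(1-exp(-u)) for
    |u| < 1e-4, keeping the current continuous through V = 0.  The flux is
    zero exactly at the Nernst potential and positive for outward current.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    u = valence * FARADAY * (voltage * 1e-3) / (GAS_CONSTANT * temperature)
    if abs(u) < _GHK_SERIES_THRESHOLD:
        # u/(1-e^-u) = 1 + u/2 + u^2/12 - u^4/720 + O(u^6)
        factor = 1.0 + u / 2.0 + u * u / 12.0 - u ** 4 / 720.0
        return factor * (conc_in - conc_out * math.exp(-u))
    if u > 500.0:
        # e^-u underflows; the flux is purely the efflux limb u*c_in
        return u * conc_in
    if u < -500.0:
        # influx limb u*c_out (multiply through by e^u before the limit)
        return u * conc_out
    return u * (conc_in - conc_out * math.exp(-u)) / (1.0 - math.exp(-u))


def ghk_current(channel: GHKChannel, gate_values: dict[str, float],
                voltage: float, temperature: float) -> float:
    """GHK channel current in nA: gate product x p_max x constant-field flux."""
    g = channel.p_max
    for gk in channel.gates:
        g *= gate_values[gk.name] ** gk.exponent
    return g * ghk_flux(channel.valence, channel.conc_in, channel.conc_out,
                        voltage, temperature)


@dataclass(frozen=True)
class ACurrentChannel:
    """Transient (A-type) potassium channel with two weighted kinetic
    components.

    Inactivation proceeds with two time constants: a fast component (m1, h1)
    carrying 60% of the gating weight and a slow component (m2, h2) carrying
    40%, so the conductance is

        g = g_max * (0.6 * m1 * h1 + 0.4 * m2 * h2)

    The weights sum to one exactly, so with both component products at unity
    the conductance equals g_max.
    """

    name: str
    g_max: float
    reversal: float
    component1: tuple[GateKinetics, GateKinetics]
    component2: tuple[GateKinetics, GateKinetics]
    weight1: float = 0.6
    weight2: float = 0.4

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValueError(f"channel {self.name}: g_max must be >= 0")
        if self.weight1 + self.weight2 != 1.0:
            raise ValueError(f"channel {self.name}: component weights must "
                             f"sum to 1, got {self.weight1 + self.weight2}")

    @property
    def gates(self) -> tuple[GateKinetics, ...]:
        return self.component1 + self.component2


def a_current_conductance(channel: ACurrentChannel, m1: float, h1: float,
                          m2: float, h2: float) -> float:
    """Instantaneous A-current conductance in uS."""
    return channel.g_max * (channel.weight1 * m1 * h1
                            + channel.weight2 * m2 * h2)


def a_current(channel: ACurrentChannel, m1: float, h1: float, m2: float,
              h2: float, voltage: float) -> float:
    """A-current in nA: weighted two-component conductance times driving force."""
    return a_current_conductance(channel, m1, h1, m2, h2) \
        * (voltage - channel.reversal)


@dataclass(frozen=True)
class CalciumPool:
    """Single well-mixed intracellular free-calcium pool.

    Calcium current influx (inward = negative current) raises [Ca]; removal
    relaxes first-order back to the resting level:

        d[Ca]/dt = -influx_scale * I_Ca - ([Ca] - ca_rest) / tau_ca

    ``influx_scale`` (mM nA^-1 ms^-1) lumps the shell volume and charge-to-
    concentration conversion of a thin submembrane shell.
    """

    ca: float = 5e-5
    ca_rest: float = 5e-5
    tau_ca: float = 20.0
    influx_scale: float = 5e-4

    def __post_init__(self) -> None:
        if self.ca < 0:
            raise ValueError("ca must be >= 0")
        if self.ca_rest < 0:
            raise ValueError("ca_rest must be >= 0")
        if self.tau_ca <= 0:
            raise ValueError("tau_ca must be > 0")


def update_calcium(pool: CalciumPool, i_ca_total: float, dt: float) -> CalciumPool:
    """One Euler step of the calcium pool; result floored at zero.

    ``i_ca_total`` is the summed CaT + CaL current (nA, inward negative).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    dca = -pool.influx_scale * i_ca_total - (pool.ca - pool.ca_rest) / pool.tau_ca
    return replace(pool, ca=max(0.0, pool.ca + dt * dca))


# ---------------------------------------------------------------------------
# Default parameter table
# ---------------------------------------------------------------------------

#: Stable roster order of the 11 channel mechanisms.
CHANNEL_KEYS = ("na", "k", "cl", "na_leak", "k_leak", "a", "m", "ahp",
                "kca", "ca_t", "ca_l")

#: Mammalian-style default concentrations (mM): (valence, out, in).
DEFAULT_CONCENTRATIONS = {
    "na": (1, 145.0, 15.0),
    "k": (1, 5.0, 140.0),
    "cl": (-1, 110.0, 10.0),
    "ca": (2, 2.0, 5e-5),
}

# Per-channel gate kinetics.  Steady states are Boltzmann, time constants
# bell-shaped; constants follow the canonical mammalian formulations of each
# mechanism family (fast transient Na, delayed-rectifier K, two-component A,
# slow non-inactivating M, low-threshold CaT, high-threshold non-inactivating
# CaL, calcium-gated KCa/AHP).  Each channel's "model card" is in
# docs/methods.md; everything here is overridable from the config file.
_GATE_TABLE: dict[str, tuple[GateKinetics, ...]] = {
    "na": (
        GateKinetics("m", v_half=-30.0, slope=7.0, tau_min=0.04,
                     tau_amp=0.30, tau_vpeak=-38.0, tau_sigma=30.0,
                     exponent=3),
        GateKinetics("h", v_half=-55.0, slope=-7.0, tau_min=0.5,
                     tau_amp=6.0, tau_vpeak=-55.0, tau_sigma=20.0),
    ),
    "k": (
        GateKinetics("n", v_half=-30.0, slope=9.0, tau_min=0.5,
                     tau_amp=4.5, tau_vpeak=-50.0, tau_sigma=30.0,
                     exponent=4),
    ),
    # voltage-gated Cl kept minimal: a single activation gate whose kinetics
    # default to a fully open, voltage-flat profile (ohmic Cl conductance)
    "cl": (),
    "na_leak": (),
    "k_leak": (),
    "a": (
        GateKinetics("m1", v_half=-45.0, slope=8.0, tau_min=0.3,
                     tau_amp=1.0, tau_vpeak=-50.0, tau_sigma=30.0),
        GateKinetics("h1", v_half=-70.0, slope=-6.0, tau_min=5.0,
                     tau_amp=10.0, tau_vpeak=-70.0, tau_sigma=25.0),
        GateKinetics("m2", v_half=-45.0, slope=8.0, tau_min=0.3,
                     tau_amp=1.0, tau_vpeak=-50.0, tau_sigma=30.0),
        GateKinetics("h2", v_half=-70.0, slope=-6.0, tau_min=30.0,
                     tau_amp=60.0, tau_vpeak=-70.0, tau_sigma=25.0),
    ),
    "m": (
        GateKinetics("m", v_half=-35.0, slope=10.0, tau_min=30.0,
                     tau_amp=70.0, tau_vpeak=-45.0, tau_sigma=35.0),
    ),
    "ahp": (
        GateKinetics("q", tau_min=80.0, ca_kd=5e-4, ca_only=True),
    ),
    "kca": (
        GateKinetics("c", v_half=-20.0, slope=12.0, tau_min=2.0,
                     tau_amp=10.0, tau_vpeak=-30.0, tau_sigma=40.0,
                     ca_kd=5e-4),
    ),
    "ca_t": (
        GateKinetics("m", v_half=-52.0, slope=5.0, tau_min=0.5,
                     tau_amp=2.0, tau_vpeak=-60.0, tau_sigma=25.0,
                     exponent=2),
        GateKinetics("h", v_half=-72.0, slope=-5.0, tau_min=5.0,
                     tau_amp=15.0, tau_vpeak=-70.0, tau_sigma=25.0),
    ),
    "ca_l": (
        GateKinetics("m", v_half=-20.0, slope=6.0, tau_min=0.5,
                     tau_amp=2.0, tau_vpeak=-25.0, tau_sigma=25.0,
                     exponent=2),
    ),
}

#: Default maximal conductances (uS) / permeability scales (nA/mM).
DEFAULT_MAGNITUDES = {
    "na": 1.2,
    "k": 0.36,
    "cl": 0.001,
    "na_leak": 0.0003,
    "k_leak": 0.002,
    "a": 0.05,
    "m": 0.005,
    "ahp": 0.005,
    "kca": 0.01,
    "ca_t": 0.002,
    "ca_l": 0.002,
}

#: Which ion each ohmic channel's reversal is derived from.
_REVERSAL_ION = {
    "na": "na", "na_leak": "na",
    "k": "k", "k_leak": "k", "a": "k", "m": "k", "ahp": "k", "kca": "k",
    "cl": "cl",
}


def build_default_channels(temperature: float = 295.0,
                           magnitudes: dict[str, float] | None = None,
                           reversals: dict[str, float] | None = None,
                           gate_overrides: dict[str, dict[str, dict]] | None = None,
                           ) -> dict[str, OhmicChannel | GHKChannel | ACurrentChannel]:
    """Build the default 11-channel roster.

    Reversal potentials of the ohmic channels are derived from the default
    mammalian concentrations via Nernst at ``temperature`` unless given
    explicitly in ``reversals``.  ``magnitudes`` overrides g_max/p_max per
    channel key; ``gate_overrides`` maps channel key -> gate name -> field
    dict (e.g. ``{"na": {"m": {"v_half": -35.0}}}``).
    """
    mags = dict(DEFAULT_MAGNITUDES)
    if magnitudes:
        unknown = set(magnitudes) - set(CHANNEL_KEYS)
        if unknown:
            raise KeyError(f"unknown channel keys: {sorted(unknown)}")
        mags.update(magnitudes)
    revs = dict(reversals or {})
    gate_overrides = gate_overrides or {}

    def gates_for(key: str) -> tuple[GateKinetics, ...]:
        base = _GATE_TABLE[key]
        ov = gate_overrides.get(key)
        if not ov:
            return base
        out = []
        for gk in base:
            if gk.name in ov:
                out.append(replace(gk, **ov[gk.name]))
            else:
                out.append(gk)
        return tuple(out)

    def reversal_for(key: str) -> float:
        if key in revs:
            return revs[key]
        z, co, ci = DEFAULT_CONCENTRATIONS[_REVERSAL_ION[key]]
        return nernst_potential(z, co, ci, temperature)

    channels: dict[str, OhmicChannel | GHKChannel | ACurrentChannel] = {}
    for key in CHANNEL_KEYS:
        if key in ("ca_t", "ca_l"):
            z, co, ci = DEFAULT_CONCENTRATIONS["ca"]
            channels[key] = GHKChannel(key, p_max=mags[key], valence=z,
                                       conc_in=ci, conc_out=co,
                                       gates=gates_for(key))
        elif key == "a":
            g = gates_for(key)
            channels[key] = ACurrentChannel(key, g_max=mags[key],
                                            reversal=reversal_for(key),
                                            component1=(g[0], g[1]),
                                            component2=(g[2], g[3]))
        else:
            channels[key] = OhmicChannel(key, g_max=mags[key],
                                         reversal=reversal_for(key),
                                         gates=gates_for(key))
    return channels
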