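"""Channel-mechanism unit tests: Nernst, GHK, gating, A current, calcium."""

import math

import pytest

from ionclamp.channels import (
    ACurrentChannel,
    CalciumPool,
    FARADAY,
    GAS_CONSTANT,
    GateKinetics,
    GHKChannel,
    OhmicChannel,
    a_current,
    a_current_conductance,
    advance_gate,
    build_default_channels,
    gate_steady_state,
    gate_time_constant,
    ghk_current,
    ghk_flux,
    nernst_potential,
    ohmic_current,
    update_calcium,
)
from ionclamp.membrane import init_gates_at_voltage

# (RT/F) ln 10 at 295.15 K with CODATA constants, mV — pinned by direct
# formula evaluation.
NERNST_DECADE_295_15 = 58.56408539238873


class TestNernst:
    def test_equal_concentrations_zero(self):
        assert nernst_potential(1, 10.0, 10.0, 295.0) == 0.0

    def test_decade_ratio_pinned_value(self):
        v = nernst_potential(1, 100.0, 10.0, 295.15)
        assert v == pytest.approx(NERNST_DECADE_295_15, abs=1e-9)

    def test_valence_two_halves_potential(self):
        v1 = nernst_potential(1, 100.0, 10.0, 295.15)
        v2 = nernst_potential(2, 100.0, 10.0, 295.15)
        assert v2 == pytest.approx(v1 / 2.0, rel=1e-14)

    @pytest.mark.parametrize("kwargs,msg", [
        (dict(valence=1, conc_out=0.0, conc_in=1.0, temperature=295.0),
         "conc_out"),
        (dict(valence=1, conc_out=1.0, conc_in=-2.0, temperature=295.0),
         "conc_in"),
        (dict(valence=0, conc_out=1.0, conc_in=1.0, temperature=295.0),
         "valence"),
        (dict(valence=1, conc_out=1.0, conc_in=1.0, temperature=0.0),
         "temperature"),
    ])
    def test_domain_errors_name_offending_field(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            nernst_potential(**kwargs)


def _ca_channel(p_max=1.0, gates=()):
    return GHKChannel("ca_t", p_max=p_max, valence=2, conc_in=5e-5,
                      conc_out=2.0, gates=gates)


class TestGHK:
    def test_zero_permeability_zero_current(self):
        ch = _ca_channel(p_max=0.0)
        for v in (-80.0, 0.0, 40.0):
            assert ghk_current(ch, {}, v, 295.0) == 0.0

    def test_vanishes_at_nernst_potential_bisection_oracle(self):
        """The GHK flux root, located by bisection, is the Nernst potential;
        the current there is zero to 1e-9 nA."""
        ch = _ca_channel()
        e_rev = nernst_potential(2, 2.0, 5e-5, 295.0)
        lo, hi = -150.0, 250.0
        flo = ghk_flux(2, 5e-5, 2.0, lo, 295.0)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            fmid = ghk_flux(2, 5e-5, 2.0, mid, 295.0)
            if flo * fmid <= 0:
                hi = mid
            else:
                lo, flo = mid, fmid
        assert 0.5 * (lo + hi) == pytest.approx(e_rev, abs=1e-9)
        assert abs(ghk_current(ch, {}, e_rev, 295.0)) <= 1e-9

    def test_zero_voltage_limit_matches_lhopital(self):
        """I(V -> 0) -> p_max (c_in - c_out) in the lumped unit system,
        checked against evaluation just off zero."""
        ch = _ca_channel()
        i0 = ghk_current(ch, {}, 0.0, 295.0)
        assert i0 == pytest.approx(1.0 * (5e-5 - 2.0), rel=1e-9)
        for v in (1e-6, -1e-6):
            assert ghk_current(ch, {}, v, 295.0) == pytest.approx(i0,
                                                                  rel=1e-6)

    def test_series_and_direct_branches_agree_at_threshold(self):
        """Continuity at V = 0: the 4th-order series and the direct formula,
        evaluated at the same voltage near the |zFV/RT| = 1e-4 switch point,
        agree to 1e-9 nA."""
        ci, co = 5e-5, 2.0
        v_switch = 1e-4 * GAS_CONSTANT * 295.0 / (2 * FARADAY) * 1000.0
        for v in (v_switch * 0.999, -v_switch * 0.999,
                  v_switch * 1.001, -v_switch * 1.001):
            u = 2 * FARADAY * (v * 1e-3) / (GAS_CONSTANT * 295.0)
            direct = u * (ci - co * math.exp(-u)) / (1.0 - math.exp(-u))
            series = (1.0 + u / 2 + u * u / 12 - u ** 4 / 720) \
                * (ci - co * math.exp(-u))
            assert abs(direct - series) <= 1e-9
            # the implementation's value matches both branches
            got = ghk_flux(2, ci, co, v, 295.0)
            assert got == pytest.approx(direct, abs=1e-9)

    def test_single_zero_crossing_in_physiological_range(self):
        e_rev = nernst_potential(2, 2.0, 5e-5, 295.0)
        vs = [v / 2.0 for v in range(-300, 201)]  # -150..100 mV
        signs = [ghk_flux(2, 5e-5, 2.0, v, 295.0) < 0 for v in vs]
        crossings = sum(a != b for a, b in zip(signs, signs[1:]))
        # E_Ca ~ +135 mV exceeds +100 mV so no crossing below it
        assert crossings == (1 if e_rev < 100.0 else 0)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError, match="temperature"):
            ghk_current(_ca_channel(), {}, 10.0, -1.0)


class TestGating:
    def test_boltzmann_half_activation(self):
        gk = GateKinetics("m", v_half=-30.0, slope=7.0)
        assert gate_steady_state(gk, -30.0) == pytest.approx(0.5)

    def test_activation_monotone_between_extremes(self):
        gk = GateKinetics("m", v_half=-30.0, slope=7.0)
        assert gate_steady_state(gk, 100.0) >= gate_steady_state(gk, -100.0)

    def test_calcium_gate_zero_without_calcium(self):
        gk = GateKinetics("c", v_half=-20.0, slope=12.0, ca_kd=5e-4)
        assert gate_steady_state(gk, 50.0, calcium=0.0) == 0.0

    def test_steady_state_is_fixed_point_of_euler_step(self):
        gk = GateKinetics("m", v_half=-30.0, slope=7.0, tau_min=1.0)
        x_inf = gate_steady_state(gk, -42.0)
        assert advance_gate(x_inf, gk, -42.0, 0.1) == pytest.approx(
            x_inf, abs=1e-15)

    def test_single_step_forced_value(self):
        # x=0, x_inf=1, tau=1 ms, dt=0.1 ms -> 0.1
        gk = GateKinetics("m", v_half=0.0, slope=1e-9, tau_min=1.0)
        assert advance_gate(0.0, gk, 100.0, 0.1) == pytest.approx(0.1)

    def test_repeated_steps_match_geometric_closed_form(self):
        """n Euler steps at fixed voltage equal
        x_inf + (x0 - x_inf)(1 - dt/tau)^n exactly."""
        gk = GateKinetics("h", v_half=-55.0, slope=-7.0, tau_min=4.0)
        v, dt, x0, n = -40.0, 0.05, 0.9, 137
        x_inf = gate_steady_state(gk, v)
        tau = gate_time_constant(gk, v)
        x = x0
        for _ in range(n):
            x = advance_gate(x, gk, v, dt)
        expected = x_inf + (x0 - x_inf) * (1.0 - dt / tau) ** n
        assert x == pytest.approx(expected, abs=1e-12)

    def test_overshoot_clamped_to_unit_interval(self):
        gk = GateKinetics("m", v_half=-60.0, slope=5.0, tau_min=0.01)
        assert advance_gate(0.0, gk, 40.0, 0.1) <= 1.0
        gk2 = GateKinetics("h", v_half=-60.0, slope=-5.0, tau_min=0.01)
        assert advance_gate(1.0, gk2, 40.0, 0.1) >= 0.0

    def test_nonpositive_dt_rejected(self):
        gk = GateKinetics("m")
        with pytest.raises(ValueError, match="dt"):
            advance_gate(0.5, gk, -40.0, 0.0)


class TestOhmic:
    CH = OhmicChannel("k_leak", g_max=1.0, reversal=-80.0)

    def test_zero_at_reversal(self):
        assert ohmic_current(self.CH, {}, -80.0) == 0.0

    def test_unit_arithmetic(self):
        assert ohmic_current(self.CH, {}, -70.0) == pytest.approx(10.0)

    def test_linear_in_g_max(self):
        half = OhmicChannel("k_leak", g_max=0.5, reversal=-80.0)
        assert ohmic_current(half, {}, -70.0) == pytest.approx(
            ohmic_current(self.CH, {}, -70.0) / 2.0)

    def test_odd_symmetry_about_reversal(self):
        for d in (1.0, 13.7, 55.0):
            assert ohmic_current(self.CH, {}, -80.0 + d) == pytest.approx(
                -ohmic_current(self.CH, {}, -80.0 - d))

    def test_gate_exponent_applied(self):
        gk = GateKinetics("n", exponent=4)
        ch = OhmicChannel("k", g_max=2.0, reversal=-80.0, gates=(gk,))
        assert ohmic_current(ch, {"n": 0.5}, -70.0) == pytest.approx(
            2.0 * 0.5 ** 4 * 10.0)


def _a_channel(g_max=1.0):
    gk = GateKinetics
    return ACurrentChannel("a", g_max=g_max, reversal=-80.0,
                           component1=(gk("m1"), gk("h1")),
                           component2=(gk("m2"), gk("h2")))


class TestACurrent:
    def test_first_component_carries_sixty_percent(self):
        ch = _a_channel()
        assert a_current_conductance(ch, 1.0, 1.0, 0.0, 0.0) == \
            pytest.approx(0.6)

    def test_second_component_carries_forty_percent(self):
        ch = _a_channel()
        assert a_current_conductance(ch, 0.0, 0.0, 1.0, 1.0) == \
            pytest.approx(0.4)

    def test_full_activation_reaches_g_max(self):
        ch = _a_channel(g_max=0.05)
        assert a_current_conductance(ch, 1.0, 1.0, 1.0, 1.0) == \
            pytest.approx(0.05)

    def test_current_uses_driving_force(self):
        ch = _a_channel()
        assert a_current(ch, 1.0, 1.0, 1.0, 1.0, -70.0) == pytest.approx(10.0)
        assert a_current(ch, 1.0, 1.0, 1.0, 1.0, -80.0) == 0.0

    def test_weights_must_sum_to_one(self):
        gk = GateKinetics
        with pytest.raises(ValueError, match="sum to 1"):
            ACurrentChannel("a", g_max=1.0, reversal=-80.0,
                            component1=(gk("m1"), gk("h1")),
                            component2=(gk("m2"), gk("h2")),
                            weight1=0.6, weight2=0.5)

    def test_shared_kinetics_components_collapse(self):
        """With identical kinetics and state in both components, the split is
        invisible: conductance equals g_max times the common product."""
        ch = _a_channel(g_max=2.0)
        for m, h in [(0.3, 0.8), (1.0, 0.5)]:
            assert a_current_conductance(ch, m, h, m, h) == \
                pytest.approx(2.0 * m * h)


class TestCalciumPool:
    def test_rest_is_fixed_point(self):
        pool = CalciumPool(ca=5e-5, ca_rest=5e-5)
        assert update_calcium(pool, 0.0, 0.1).ca == pytest.approx(5e-5)

    def test_steady_state_under_constant_inward_current(self):
        """Holding I_Ca = -I drives the pool to
        ca_rest + influx_scale * I * tau_ca (derivative-zero balance)."""
        pool = CalciumPool(ca=5e-5, ca_rest=5e-5, tau_ca=20.0,
                           influx_scale=5e-4)
        i_ca = -0.1
        expected = 5e-5 + 5e-4 * 0.1 * 20.0
        for _ in range(20000):
            pool = update_calcium(pool, i_ca, 0.05)
        assert pool.ca == pytest.approx(expected, rel=1e-6)

    def test_zero_influx_exponential_decay(self):
        """Free decay matches (ca0-rest) e^(-t/tau) + rest at Euler
        first-order accuracy."""
        ca0, rest, tau, dt = 1e-3, 5e-5, 20.0, 0.01
        pool = CalciumPool(ca=ca0, ca_rest=rest, tau_ca=tau)
        n = 2000  # 20 ms = one time constant
        for _ in range(n):
            pool = update_calcium(pool, 0.0, dt)
        exact = (ca0 - rest) * math.exp(-n * dt / tau) + rest
        assert pool.ca == pytest.approx(exact, rel=1e-3)

    def test_zero_influx_monotone_convergence(self):
        pool = CalciumPool(ca=2e-3, ca_rest=5e-5, tau_ca=10.0)
        prev = pool.ca
        for _ in range(5000):
            pool = update_calcium(pool, 0.0, 0.05)
            assert pool.ca <= prev + 1e-18
            prev = pool.ca
        assert pool.ca == pytest.approx(5e-5, rel=1e-3)

    def test_floor_at_zero(self):
        pool = CalciumPool(ca=1e-9, ca_rest=0.0, tau_ca=1.0,
                           influx_scale=5e-4)
        # strong outward calcium current would push ca negative
        assert update_calcium(pool, 10.0, 1.0).ca == 0.0


class TestGateInitialization:
    def test_init_is_fixed_point_of_one_step(self, default_model):
        gates = init_gates_at_voltage(default_model, -65.0)
        ca = default_model.calcium_pool.ca_rest
        for ckey, ch in default_model.channels.items():
            for gk in ch.gates:
                before = gates[f"{ckey}/{gk.name}"]
                after = advance_gate(before, gk, -65.0, 0.01, calcium=ca)
                assert abs(after - before) <= 1e-12

    def test_init_idempotent(self, default_model):
        a = init_gates_at_voltage(default_model, -52.5)
        b = init_gates_at_voltage(default_model, -52.5)
        assert a == b

    def test_hyperpolarized_sodium_gates(self, default_model):
        """At -100 mV the Na activation gate is shut and the inactivation
        gate fully available."""
        gates = init_gates_at_voltage(default_model, -100.0)
        assert gates["na/m"] < 0.01
        assert gates["na/h"] > 0.99


class TestDefaultRoster:
    def test_eleven_channels_in_order(self):
        chans = build_default_channels()
        assert list(chans.keys()) == ["na", "k", "cl", "na_leak", "k_leak",
                                      "a", "m", "ahp", "kca", "ca_t", "ca_l"]

    def test_gate_invariants_across_physiological_range(self):
        """Every gate's steady state stays in [0,1] and its time constant
        positive over [-150, 100] mV."""
        chans = build_default_channels()
        for ch in chans.values():
            for gk in ch.gates:
                for v in range(-150, 101, 5):
                    s = gate_steady_state(gk, float(v), calcium=1e-3)
                    assert 0.0 <= s <= 1.0
                    assert gate_time_constant(gk, float(v)) > 0.0

    def test_cal_does_not_inactivate(self):
        chans = build_default_channels()
        assert all(gk.slope > 0 for gk in chans["ca_l"].gates)

    def test_magnitude_override(self):
        chans = build_default_channels(magnitudes={"na": 2.4})
        assert chans["na"].g_max == 2.4
        with pytest.raises(KeyError):
            build_default_channels(magnitudes={"nax": 1.0})

    def test_gate_override(self):
        chans = build_default_channels(
            gate_overrides={"na": {"m": {"v_half": -35.0}}})
        m = [g for g in chans["na"].gates if g.name == "m"][0]
        assert m.v_half == -35.0
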