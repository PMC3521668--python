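"""Gating kinetics: bounds, fixed points, closed-form agreement."""

import math

import numpy as np
import pytest
import yaml

from iosim import channels as ch

V_GRID = np.linspace(-120.0, 60.0, 361)
VOLTAGE_GATES = [g for g in ch.GATE_TABLE if g != "s"]


@pytest.mark.parametrize("gate", sorted(ch.GATE_TABLE))
def test_steady_state_bounded(gate):
    ca_grid = [0.0, 1.0, 50.0, 1e4] if gate == "s" else [None]
    for ca in ca_grid:
        vals = [ch.gate_steady_state(gate, v, ca if ca is not None else 3.7)
                for v in V_GRID]
        assert all(0.0 <= x <= 1.0 for x in vals)


@pytest.mark.parametrize("gate", VOLTAGE_GATES)
def test_time_constants_positive(gate):
    if ch.GATE_TABLE[gate].tau_form == "instant":
        with pytest.raises(ValueError):
            ch.gate_time_constant(gate, 0.0)
        return
    taus = [ch.gate_time_constant(gate, v, 3.7) for v in V_GRID]
    assert all(t > 0 for t in taus)


@pytest.mark.parametrize("gate", [g for g in VOLTAGE_GATES
                                  if ch.GATE_TABLE[g].ss_form == "boltzmann"])
def test_boltzmann_half_activation_and_limits(gate):
    p = ch.GATE_TABLE[gate].ss
    assert ch.gate_steady_state(gate, p["v_half"]) == pytest.approx(0.5)
    lo, hi = ch.gate_steady_state(gate, -1e4), ch.gate_steady_state(gate, 1e4)
    if p["k"] > 0:  # activation
        assert lo < 1e-9 and hi > 1 - 1e-9
    else:  # inactivation
        assert lo > 1 - 1e-9 and hi < 1e-9
    # monotone in V
    vals = [ch.gate_steady_state(gate, v) for v in V_GRID]
    diffs = np.diff(vals)
    assert (diffs >= 0).all() or (diffs <= 0).all()


def test_cal_activation_matches_independent_closed_form():
    """T-type activation on a 1 mV grid vs an inline re-coding of the
    Boltzmann form (half-activation −61 mV, slope 4.2 mV)."""
    for v in np.arange(-120.0, 61.0, 1.0):
        expected = 1.0 / (1.0 + math.exp(-(v + 61.0) / 4.2))
        assert ch.gate_steady_state("k", v) == expected
    # and its inactivation partner
    for v in np.arange(-120.0, 61.0, 1.0):
        expected = 1.0 / (1.0 + math.exp((v + 85.5) / 8.5))
        assert ch.gate_steady_state("l", v) == expected


def test_gate_derivative_fixed_point_and_direction():
    for gate in ["h", "n", "l", "q", "r", "x_s"]:
        v = -55.0
        x_inf = ch.gate_steady_state(gate, v, 3.7)
        assert ch.gate_derivative(gate, x_inf, v, 3.7) == pytest.approx(0.0, abs=1e-15)
        assert ch.gate_derivative(gate, 0.0, v, 3.7) > 0
        assert ch.gate_derivative(gate, 1.0, v, 3.7) < 0


def test_voltage_clamp_relaxation_matches_exponential():
    """RK4-integrated gate under voltage clamp vs x(t) = x∞(1 − e^(−t/τ))."""
    v = -30.0
    dt = 0.001
    for gate in ["h", "n", "l"]:
        x_inf = ch.gate_steady_state(gate, v)
        tau = ch.gate_time_constant(gate, v)
        x = 0.0
        t = 0.0
        for _ in range(int(5.0 / dt)):
            k1 = ch.gate_derivative(gate, x, v)
            k2 = ch.gate_derivative(gate, x + dt / 2 * k1, v)
            k3 = ch.gate_derivative(gate, x + dt / 2 * k2, v)
            k4 = ch.gate_derivative(gate, x + dt * k3, v)
            x += dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += dt
        exact = x_inf * (1.0 - math.exp(-t / tau))
        assert abs(x - exact) / exact < 1e-6


def test_current_density_zero_cases():
    cal = ch.CHANNEL_TABLE["CaL"]
    gates = {"k": 0.5, "l": 0.5}
    assert ch.current_density(cal, gates, cal.reversal_potential) == 0.0
    assert ch.current_density(cal, {"k": 0.0, "l": 0.7}, -50.0) == 0.0
    # outward-positive sign convention: K current above E_K is positive
    kdr = ch.CHANNEL_TABLE["Kdr_s"]
    assert ch.current_density(kdr, {"n": 0.5}, 0.0) > 0


def test_kca_calcium_dependence():
    kca = ch.CHANNEL_TABLE["KCa"]
    with pytest.raises(ValueError):
        ch.current_density(kca, {"s": 0.5}, -50.0)  # missing calcium
    # at zero calcium the activation's steady state is exactly zero
    assert ch.gate_steady_state("s", -50.0, ca=0.0) == 0.0


def test_unknown_gate_id_is_configuration_error():
    with pytest.raises(KeyError):
        ch.gate_steady_state("zz", -50.0)


def test_current_continuity_in_voltage():
    cal = ch.CHANNEL_TABLE["CaL"]
    gates = {"k": 0.6, "l": 0.1}
    vv = np.arange(-100.0, 40.0, 0.01)
    iv = np.array([ch.current_density(cal, gates, v) for v in vv])
    assert np.abs(np.diff(iv)).max() < cal.max_conductance * 1.0


def test_parameter_table_round_trips_through_yaml():
    blob = yaml.safe_dump({"gates": ch.gate_table_dict(),
                           "channels": ch.channel_table_dict()})
    back = yaml.safe_load(blob)
    assert back["gates"] == ch.gate_table_dict()
    assert back["channels"] == ch.channel_table_dict()
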