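"""Integration: reproducibility, convergence, stimuli, calibration."""

import numpy as np
import pytest

from iosim.analysis import dominant_frequency
from iosim.network import build_grid
from iosim.simulate import (
    SimulationDivergence,
    StimulusElement,
    StimulusProtocol,
    calibrate_imposed_sinusoid,
    integrate,
    intrinsic_sto_extrema,
    random_phase_states,
    settle,
    single_cell_network,
)


def test_bit_exact_reproducibility():
    net = build_grid(2, 2, heterogeneous=True, seed=3)
    el = StimulusElement(cells=(0,), amplitude=5.5, unit="pA", onset=50.0, duration=20.0)
    a = integrate(net, protocol=StimulusProtocol([el]), duration=300.0, seed=1)
    b = integrate(net, protocol=StimulusProtocol([el]), duration=300.0, seed=1)
    np.testing.assert_array_equal(a.v, b.v)
    assert a.metadata["params_hash"] == b.metadata["params_hash"]


def test_dt_refinement_converges(single_cell_run):
    """Halving dt changes the final somatic voltage of a 2 s default run by
    far less than 0.1 mV (4th-order integrator on a smooth limit cycle)."""
    net = single_cell_network()
    y0 = settle(net, settle_ms=1000.0)
    a = integrate(net, duration=2000.0, dt=0.025, y0=y0)
    b = integrate(net, duration=2000.0, dt=0.0125, y0=y0, record_every=4)
    assert abs(a.v_soma(0)[-1] - b.v_soma(0)[-1]) < 0.1


def test_divergence_aborts_with_diagnostic():
    net = single_cell_network()
    el = StimulusElement(cells=(0,), compartment="soma", amplitude=1e4,
                         unit="uA/cm2", onset=0.0, duration=100.0)
    with pytest.raises(SimulationDivergence, match="ms"):
        integrate(net, protocol=StimulusProtocol([el]), duration=100.0)


def test_input_validation():
    net = single_cell_network()
    with pytest.raises(ValueError):
        integrate(net, duration=-5.0)
    with pytest.raises(ValueError):
        integrate(net, duration=10.0, dt=0.5)
    with pytest.raises(ValueError):
        StimulusElement(cells=(0,), onset=-1.0)
    with pytest.raises(ValueError):
        StimulusElement(cells=(0,), compartment="nucleus")


def test_stimulus_onsets_quantized_to_grid():
    el = StimulusElement(cells=(0,), amplitude=1.0, unit="uA/cm2",
                         onset=10.0101, duration=20.007)
    arrs = StimulusProtocol([el]).arrays(dt=0.025)
    onset, dur = arrs[4][0], arrs[5][0]
    assert onset == pytest.approx(round(10.0101 / 0.025) * 0.025)
    assert dur == pytest.approx(round(20.007 / 0.025) * 0.025)


def test_intrinsic_sto_frequency_and_range(single_cell_run):
    v = single_cell_run.v_soma(0)
    f = dominant_frequency(v, single_cell_run.dt_rec)
    assert 5.0 < f < 9.0  # detailed band is asserted in the acceptance suite
    assert -150 < v.min() and v.max() < 80


def test_random_phase_states_deterministic_and_distinct():
    net = build_grid(2, 2, heterogeneous=True, seed=9)
    a = random_phase_states(net, rng=5)
    b = random_phase_states(net, rng=5)
    np.testing.assert_array_equal(a, b)
    c = random_phase_states(net, rng=6)
    assert not np.array_equal(a, c)
    # cells start at distinct phases: somatic voltages differ
    assert np.ptp(a[:, 1]) > 0.5


def test_sto_amplitude_monotone_in_gcal():
    """Isolated-cell STO amplitude is monotone non-decreasing over the
    heterogeneity range of the T-type conductance."""
    amps = []
    for g in [0.55, 0.625, 0.7, 0.8, 0.9]:
        net = single_cell_network(g_cal=g)
        y0 = settle(net, settle_ms=2500.0)
        res = integrate(net, duration=1500.0, y0=y0)
        v = res.v_soma(0)
        amps.append((v.max() - v.min()) / 2)
    assert all(b >= a - 1e-6 for a, b in zip(amps, amps[1:]))
    assert amps[-1] > 8.0 and amps[0] < 1.0


@pytest.fixture(scope="module")
def calibrated():
    return calibrate_imposed_sinusoid()


class TestImposedSinusoid:
    def test_extrema_match_intrinsic(self, calibrated):
        net = single_cell_network()
        y0 = settle(net)
        res = integrate(net, protocol=StimulusProtocol([calibrated]),
                        duration=3000.0, y0=y0)
        v = res.v_soma(0)[res.t >= 1000.0]
        vmax_t, vmin_t = intrinsic_sto_extrema()
        assert abs(v.max() - vmax_t) < 0.2
        assert abs(v.min() - vmin_t) < 0.2

    def test_imposed_frequency_is_5hz(self, calibrated):
        net = single_cell_network()
        y0 = settle(net)
        res = integrate(net, protocol=StimulusProtocol([calibrated]),
                        duration=4000.0, y0=y0)
        v = res.v_soma(0)[res.t >= 1000.0]
        f = dominant_frequency(v, res.dt_rec)
        assert f == pytest.approx(5.0, abs=1000.0 / 3000.0)  # one spectral bin

    def test_zero_amplitude_reverts_to_intrinsic(self):
        net = single_cell_network()
        y0 = settle(net)
        res = integrate(net, duration=3000.0, y0=y0)
        f = dominant_frequency(res.v_soma(0)[res.t >= 500.0], res.dt_rec)
        assert 6.0 <= f <= 8.0
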