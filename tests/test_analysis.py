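"""Measurement toolchain vs constructed ground truth and analytic signals."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iosim import analysis
from iosim.synth import SyntheticTraceSpec, generate_fixture


def make_sine(freq=7.0, amp=5.0, base=-57.0, dt=0.05, dur=600.0, noise=0.0, seed=0):
    t = np.arange(0.0, dur, dt)
    v = base + amp * np.sin(2 * np.pi * freq * t * 1e-3)
    if noise:
        v = v + np.random.default_rng(seed).normal(0, noise, len(t))
    return t, v


def spike_time_at_phase(phi, freq=7.0, cycles=3):
    return (phi % (2 * np.pi) + 2 * np.pi * cycles) / (2 * np.pi * freq) * 1000.0


def test_detect_aps_flat_and_quiet_traces():
    assert analysis.detect_aps(np.full(5000, -60.0), 0.05) == []
    _, v = make_sine()
    assert analysis.detect_aps(v, 0.05) == []


def test_detect_aps_finds_inserted_template():
    spec = SyntheticTraceSpec(insertion_phases=(0.3 * np.pi,))
    t, v, truth = generate_fixture(spec)
    aps = analysis.detect_aps(v, spec.dt)
    assert len(aps) == 1
    assert aps[0].peak_time == pytest.approx(truth[0]["spike_time"], abs=spec.dt)
    assert aps[0].onset_time < aps[0].peak_time


@pytest.mark.parametrize("n_spikelets", [0, 1, 3, 5])
def test_spikelet_count_recovers_ground_truth(n_spikelets):
    spec = SyntheticTraceSpec(insertion_phases=(0.4 * np.pi,),
                              spikelet_count=n_spikelets,
                              adp_plateau_ms=16.0)
    t, v, truth = generate_fixture(spec)
    ap = analysis.detect_aps(v, spec.dt)[0]
    m = analysis.count_spikelets(v, spec.dt, ap, truth[0]["sto_peak_level"])
    assert m.spikelet_count == n_spikelets
    assert m.adp_complete
    for mt, tt in zip(m.spikelet_times, truth[0]["spikelet_times"]):
        assert mt == pytest.approx(tt, abs=0.2)
    assert all(m.adp_window[0] <= s <= m.adp_window[1] for s in m.spikelet_times)
    assert m.adp_duration == pytest.approx(truth[0]["adp_duration"], abs=0.15)
    assert m.adp_duration > 0


def test_spikelet_count_invariances():
    """Counting is invariant to a uniform voltage offset and to resampling
    at twice the rate."""
    spec = SyntheticTraceSpec(insertion_phases=(0.4 * np.pi,), spikelet_count=3)
    t, v, truth = generate_fixture(spec)
    ap = analysis.detect_aps(v, spec.dt)[0]
    base = analysis.count_spikelets(v, spec.dt, ap, truth[0]["sto_peak_level"])

    ap_off = analysis.detect_aps(v + 20.0, spec.dt)[0]
    shifted = analysis.count_spikelets(v + 20.0, spec.dt, ap_off,
                                       truth[0]["sto_peak_level"] + 20.0)
    assert shifted.spikelet_count == base.spikelet_count

    spec2 = SyntheticTraceSpec(insertion_phases=(0.4 * np.pi,), spikelet_count=3,
                               dt=spec.dt / 2)
    t2, v2, truth2 = generate_fixture(spec2)
    ap2 = analysis.detect_aps(v2, spec2.dt)[0]
    fine = analysis.count_spikelets(v2, spec2.dt, ap2, truth2[0]["sto_peak_level"])
    assert fine.spikelet_count == base.spikelet_count


def test_adp_incomplete_when_trace_clipped():
    spec = SyntheticTraceSpec(insertion_phases=(0.4 * np.pi,), spikelet_count=2)
    t, v, truth = generate_fixture(spec)
    cut = int((truth[0]["spike_time"] + 5.0) / spec.dt)
    ap = analysis.detect_aps(v[:cut], spec.dt)[0]
    m = analysis.count_spikelets(v[:cut], spec.dt, ap, truth[0]["sto_peak_level"])
    assert not m.adp_complete


def test_measure_ahp_against_construction():
    spec = SyntheticTraceSpec(insertion_phases=(0.4 * np.pi,), ahp_hold_ms=100.0)
    t, v, truth = generate_fixture(spec)
    ap = analysis.detect_aps(v, spec.dt)[0]
    m = analysis.count_spikelets(v, spec.dt, ap, truth[0]["sto_peak_level"])
    dur, complete = analysis.measure_ahp(v, spec.dt, ap, m.adp_window[1])
    assert complete
    assert dur == pytest.approx(truth[0]["ahp_duration"], abs=1.0)
    # clipped before recovery -> incomplete
    cut = int((truth[0]["adp_end_time"] + 50.0) / spec.dt)
    dur2, complete2 = analysis.measure_ahp(v[:cut], spec.dt, ap, m.adp_window[1])
    assert not complete2


@pytest.mark.parametrize("phi,expected", [
    (0.5 * np.pi, 0.5 * np.pi),  # spike at the peak
    (0.0, 0.0),                  # upward zero-crossing
    (1.5 * np.pi, 1.5 * np.pi),  # trough
])
def test_phase_estimator_on_pure_sine(phi, expected):
    t, v = make_sine()
    pe = analysis.estimate_phase(v, 0.05, spike_time_at_phase(phi))
    err = abs((pe.phase - expected + np.pi) % (2 * np.pi) - np.pi)
    assert err < 0.02 * np.pi
    assert pe.frequency == pytest.approx(7.0, rel=0.02)
    assert pe.amplitude == pytest.approx(5.0, rel=0.05)
    assert pe.anchor in ("two-maxima", "two-minima")


def test_phase_estimator_unbiased_over_cycle():
    t, v = make_sine()
    errs = []
    for k in range(64):
        phi = k * 2 * np.pi / 64
        pe = analysis.estimate_phase(v, 0.05, spike_time_at_phase(phi))
        errs.append(abs((pe.phase - phi + np.pi) % (2 * np.pi) - np.pi))
    assert max(errs) < 0.02 * np.pi


def test_phase_estimator_under_noise():
    """SNR 10 Monte Carlo: mean absolute phase error below 0.05π."""
    rng = np.random.default_rng(7)
    errs = []
    for i in range(100):
        phi = rng.uniform(0, 2 * np.pi)
        t, v = make_sine(noise=0.5, seed=i)
        pe = analysis.estimate_phase(v, 0.05, spike_time_at_phase(phi))
        errs.append(abs((pe.phase - phi + np.pi) % (2 * np.pi) - np.pi))
    assert np.mean(errs) < 0.05 * np.pi


def test_phase_estimator_refuses_short_history():
    t, v = make_sine(dur=150.0)  # ~1 period: fewer than 2 peaks + 2 troughs
    with pytest.raises(analysis.InsufficientOscillation):
        analysis.estimate_phase(v, 0.05, 140.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(freq=st.floats(4.0, 9.0), amp=st.floats(1.0, 10.0),
       phi=st.floats(0.0, 2 * np.pi))
def test_phase_estimator_property(freq, amp, phi):
    t, v = make_sine(freq=freq, amp=amp, dur=5000.0 / freq)
    pe = analysis.estimate_phase(v, 0.05, spike_time_at_phase(phi, freq=freq))
    err = abs((pe.phase - phi + np.pi) % (2 * np.pi) - np.pi)
    assert err < 0.02 * np.pi


def test_sto_amplitude_estimator():
    t, v = make_sine(amp=5.0)
    a = analysis.estimate_sto_amplitude(v, 0.05, spike_time_at_phase(0.3 * np.pi))
    assert a == pytest.approx(5.0, abs=0.05)
    with pytest.raises(analysis.InsufficientOscillation):
        analysis.estimate_sto_amplitude(v[:100], 0.05, 4.9)


def test_sto_peak_level_on_quiescent_trace():
    lvl = analysis.sto_peak_level(np.full(10000, -59.4), 0.05, 9000)
    assert lvl == pytest.approx(-59.4)


def test_dendrosomatic_charge_analytic():
    """Rectangular coupling current: 1 µA/cm² for 10 ms -> 0.01 µC/cm²."""
    from iosim.cell import DEFAULT_CELL
    from iosim.network import build_grid
    from iosim.simulate import SimulationResult, StimulusProtocol

    p = DEFAULT_CELL
    dt = 0.05
    t = np.arange(0, 50.0, dt)
    v = np.zeros((len(t), 1, 3))
    dv = 1.0 / (p.g_int / p.p_soma_dend)  # ΔV giving exactly 1 µA/cm²
    sel = (t >= 10.0) & (t <= 20.0)
    v[sel, 0, 1] = dv  # soma above dendrite
    res = SimulationResult(t=t, v=v, final_state=np.zeros((1, 14)), dt=dt,
                           dt_rec=dt, network=build_grid(1, 1), base_params=p,
                           g_cal=np.array([0.7]), protocol=StimulusProtocol())
    q = analysis.dendrosomatic_charge(res, 0, (10.0, 20.0))
    assert q == pytest.approx(0.01, rel=1e-6)
    # V_soma == V_dend -> zero
    assert analysis.dendrosomatic_charge(res, 0, (30.0, 40.0)) == 0.0


def _fake_result(traces, dt=0.05):
    from iosim.cell import DEFAULT_CELL
    from iosim.network import build_grid
    from iosim.simulate import StimulusProtocol, SimulationResult

    n = traces.shape[0]
    t = np.arange(traces.shape[1]) * dt
    v = np.zeros((traces.shape[1], n, 3))
    v[:, :, 1] = traces.T
    v[:, :, 0] = traces.T
    rows = 1
    net = build_grid(rows, n)
    return SimulationResult(t=t, v=v, final_state=np.zeros((n, 14)), dt=dt,
                            dt_rec=dt, network=net, base_params=DEFAULT_CELL,
                            g_cal=np.full(n, 0.7), protocol=StimulusProtocol())


def test_synchrony_identical_traces():
    t = np.arange(0, 2000.0, 0.05)
    tr = -57 + 6 * np.sin(2 * np.pi * 7 * t * 1e-3)
    res = _fake_result(np.vstack([tr, tr, tr]))
    sm = analysis.synchrony_metrics(res, t=1500.0)
    assert sm.mean_pairwise_phase_difference == pytest.approx(0.0, abs=1.0)
    assert sm.synchrony_ratio == pytest.approx(1.0, abs=0.01)
    assert sm.mean_sto_amplitude == pytest.approx(6.0, abs=0.1)


def test_synchrony_counterphase():
    t = np.arange(0, 2000.0, 0.05)
    a = -57 + 6 * np.sin(2 * np.pi * 7 * t * 1e-3)
    b = -57 - 6 * np.sin(2 * np.pi * 7 * t * 1e-3)
    res = _fake_result(np.vstack([a, b]))
    sm = analysis.synchrony_metrics(res, t=1500.0)
    assert sm.mean_pairwise_phase_difference == pytest.approx(180.0, abs=5.0)
    assert sm.synchrony_ratio == pytest.approx(0.0, abs=0.03)


def test_synchrony_requires_multicell():
    t = np.arange(0, 1000.0, 0.05)
    res = _fake_result((-57 + 6 * np.sin(2 * np.pi * 7 * t * 1e-3))[None, :])
    with pytest.raises(ValueError):
        analysis.synchrony_metrics(res, t=800.0)


def test_phase_bin_table_single_bin():
    metrics = [analysis.SpikeMetrics(ap_onset_time=0, na_peak_time=1,
                                     spikelet_count=2,
                                     sto_phase_at_spike=0.5 * np.pi)
               for _ in range(5)]
    tbl = analysis.phase_bin_spikelet_table(metrics, n_bins=8)
    assert len(tbl) == 8
    occupied = tbl[~tbl["no_spikes"]]
    assert len(occupied) == 1
    assert occupied.iloc[0]["mean_spikelets"] == 2.0
    assert occupied.iloc[0]["count_2"] == 5
    assert tbl["no_spikes"].sum() == 7


def test_dominant_frequency_pure_sine():
    t, v = make_sine(freq=6.5, dur=5000.0)
    assert analysis.dominant_frequency(v, 0.05) == pytest.approx(6.5, abs=0.21)
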