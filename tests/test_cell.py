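"""Cell assembly: coupling currents, passive dynamics, dual-path agreement."""

import numpy as np
import pytest
from scipy.linalg import expm

from iosim import _kernel
from iosim.cell import (
    CellParams,
    DEFAULT_CELL,
    NSTATE,
    cell_derivative,
    decompose_soma_currents,
    initial_state,
    internal_coupling_current,
    pa_to_density,
)
from iosim.network import build_grid, gap_current
from iosim.simulate import integrate, single_cell_network


def random_states(rng, n):
    y = np.empty((n, NSTATE))
    y[:, :3] = rng.uniform(-90.0, 20.0, (n, 3))
    y[:, 3:6] = rng.uniform(0.0, 1.0, (n, 3))
    y[:, 6] = rng.uniform(0.0, 10.0, n)
    y[:, 7:] = rng.uniform(0.0, 1.0, (n, 7))
    return y


def test_internal_coupling_basics():
    assert internal_coupling_current(-50.0, -50.0, 0.13, 0.25) == 0.0
    i1 = internal_coupling_current(-40.0, -50.0, 0.13, 0.25)
    i2 = internal_coupling_current(-30.0, -50.0, 0.13, 0.25)
    assert i2 == pytest.approx(2 * i1)
    with pytest.raises(ValueError):
        internal_coupling_current(0, 0, -1.0, 0.25)


def test_internal_coupling_conserves_charge():
    """Area-weighted soma->dendrite and dendrite->soma currents cancel."""
    rng = np.random.default_rng(0)
    p = DEFAULT_CELL
    for _ in range(100):
        vs, vd = rng.uniform(-80, 20, 2)
        i_ds = internal_coupling_current(vs, vd, p.g_int, p.p_soma_dend)
        i_sd = internal_coupling_current(vd, vs, p.g_int, 1 - p.p_soma_dend)
        # per-area currents weighted by the compartments' area shares
        assert p.p_soma_dend * i_ds + (1 - p.p_soma_dend) * i_sd == pytest.approx(0.0, abs=1e-12)


def _passive_params():
    return CellParams(g_cal=0, g_na_s=0, g_kdr_s=0, g_k_s=0, g_cah=0, g_kca=0,
                      g_h=0, g_na_a=0, g_k_a=0)


def test_rest_state_has_zero_derivative():
    p = _passive_params()
    y = initial_state(p, v0=p.e_leak)
    dy = cell_derivative(y, p)
    assert np.allclose(dy[:3], 0.0, atol=1e-12)


def test_passive_relaxation_matches_linear_system():
    """With channels off, the 3-compartment voltages follow the closed-form
    solution of the linear leak+coupling system (matrix exponential)."""
    p = _passive_params()
    net = single_cell_network()
    y0 = initial_state(p, v0=p.e_leak)
    y0[0], y0[1], y0[2] = -80.0, -55.0, -70.0
    res = integrate(net, p, duration=200.0, y0=y0[None, :])
    # dV/dt = A (V - E_leak) with A from the leak and coupling conductances
    gi, psd, pas, cm = p.g_int, p.p_soma_dend, p.p_axon_soma, p.c_m
    a = np.array([
        [-(p.g_ld + gi / (1 - psd)), gi / (1 - psd), 0.0],
        [gi / psd, -(p.g_ls + gi / psd + gi / (1 - pas)), gi / (1 - pas)],
        [0.0, gi / pas, -(p.g_la + gi / pas)],
    ]) / cm
    v0 = np.array([-80.0, -55.0, -70.0]) - p.e_leak
    for k in [100, 1000, len(res.t) - 1]:
        t = res.t[k]
        exact = p.e_leak + expm(a * t) @ v0
        sim = res.v[k, 0, :]
        assert np.abs(sim - exact).max() / np.abs(v0).max() < 1e-5


def test_passive_energy_strictly_decreasing():
    """Area-weighted quadratic deviation from leak reversal is a Lyapunov
    function of the passive system: strictly decreasing along trajectories."""
    p = _passive_params()
    net = single_cell_network()
    y0 = initial_state(p, v0=p.e_leak)
    y0[:3] = [-80.0, -55.0, -70.0]
    res = integrate(net, p, duration=100.0, y0=y0[None, :])
    # weights that symmetrize the coupling matrix (relative membrane areas)
    w = np.array([1 - p.p_soma_dend, p.p_soma_dend,
                  p.p_soma_dend * p.p_axon_soma / (1 - p.p_axon_soma)])
    energy = ((res.v[:, 0, :] - p.e_leak) ** 2 * w).sum(axis=1)
    assert (np.diff(energy) < 0).all()


def test_kernel_matches_reference_derivative():
    """The compiled kernel and the channels/cell composition agree to
    machine precision on random states (gap currents included)."""
    rng = np.random.default_rng(42)
    net = build_grid(3, 3)
    indptr, indices = net.csr()
    P = _kernel.pack_params(DEFAULT_CELL, net.g_gap_max, True)
    neigh = [[] for _ in range(9)]
    for i, j in net.edges:
        neigh[i].append(j)
        neigh[j].append(i)
    for _ in range(10):
        y = random_states(rng, 9)
        gcal = rng.uniform(0.55, 0.9, 9)
        sd, ss = rng.uniform(-2, 2, 9), rng.uniform(-2, 2, 9)
        dy = np.empty((9, NSTATE))
        _kernel._deriv(y, gcal, P, indptr, indices, sd, ss, dy)
        for i in range(9):
            igap = sum(gap_current(y[i, 0], y[j, 0], net.g_gap_max) for j in neigh[i])
            ref = cell_derivative(y[i], DEFAULT_CELL.with_gcal(gcal[i]),
                                  sd[i], ss[i], igap)
            assert np.abs(ref - dy[i]).max() <= 1e-12 * max(1.0, np.abs(ref).max())


def test_nonfinite_state_rejected():
    y = initial_state()
    y[1] = np.nan
    with pytest.raises(FloatingPointError, match="v_soma"):
        cell_derivative(y, DEFAULT_CELL)


def test_state_invariants_along_trajectory():
    """Gating bounds and calcium non-negativity hold at every stored step."""
    net = single_cell_network()
    res = integrate(net, duration=1000.0, store_state=True)
    gates = res.state[:, 0, 7:]
    dend_gates = res.state[:, 0, 3:6]
    ca = res.state[:, 0, 6]
    assert gates.min() >= 0.0 and gates.max() <= 1.0
    assert dend_gates.min() >= 0.0 and dend_gates.max() <= 1.0
    assert ca.min() >= 0.0


def test_pa_conversion_is_linear_and_auditable():
    from iosim.cell import DENDRITE_AREA_CM2

    assert pa_to_density(1.0) == pytest.approx(1e-6 / DENDRITE_AREA_CM2)
    assert pa_to_density(5.5) == pytest.approx(5.5 * pa_to_density(1.0))


@pytest.fixture(scope="module")
def sto_run():
    from iosim.simulate import settle

    net = single_cell_network()
    y0 = settle(net, settle_ms=1500.0)
    return integrate(net, duration=1000.0, y0=y0, store_state=True)


class TestSomaCurrentDecomposition:
    def test_kirchhoff_residual(self, sto_run):
        dec = decompose_soma_currents(sto_run, 0, 300.0, 600.0)
        vs = sto_run.v_soma(0)
        sel = (sto_run.t >= 300.0) & (sto_run.t <= 600.0)
        dv_fd = np.gradient(vs, sto_run.dt_rec)[sel]
        resid = dec["I_cap"] - sto_run.base_params.c_m * dv_fd
        scale = max(np.abs(dec[k]).max() for k in
                    ["I_CaL", "I_Na_s", "I_Kdr_s", "I_K_s", "I_ls", "I_ds", "I_as"])
        assert np.abs(resid).max() / scale < 1e-6

    def test_cal_depolarizes_upstroke(self, sto_run):
        dec = decompose_soma_currents(sto_run, 0, 300.0, 600.0)
        sel = (sto_run.t >= 300.0) & (sto_run.t <= 600.0)
        dv = np.gradient(sto_run.v_soma(0), sto_run.dt_rec)[sel]
        # outward-positive: a depolarizing current is negative
        assert dec["I_CaL"][dv > 0.05].max() < 0

    def test_coupling_repolarizes_downstroke(self, sto_run):
        dec = decompose_soma_currents(sto_run, 0, 300.0, 600.0)
        sel = (sto_run.t >= 300.0) & (sto_run.t <= 600.0)
        dv = np.gradient(sto_run.v_soma(0), sto_run.dt_rec)[sel]
        assert dec["I_ds"][dv < -0.05].min() > 0

    def test_requires_stored_state(self):
        net = single_cell_network()
        res = integrate(net, duration=50.0)
        with pytest.raises(ValueError, match="store"):
            decompose_soma_currents(res, 0)

    def test_window_outside_trajectory(self, sto_run):
        with pytest.raises(ValueError):
            decompose_soma_currents(sto_run, 0, 5000.0, 6000.0)
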