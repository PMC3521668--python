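"""Single-cell model: three compartments (dendrite, soma, axon hillock).

The membrane equation of each compartment balances its ionic currents, its
leak, the ohmic internal coupling currents and any injected current:

    C_m dV/dt = −(Σ I_ion + I_leak + Σ I_internal + I_gap) + I_injected

Internal coupling between two compartments is scaled by the receiving
compartment's share of the cell surface: the current into the soma from the
dendrite is (g_int / p_soma_dend)·(V_soma − V_dend) (outward-positive),
while the dendrite sees (g_int / (1 − p_soma_dend))·(V_dend − V_soma); the
same conductance g_int seen through complementary area fractions conserves
charge.  This module is the readable reference implementation; `simulate`
runs a compiled kernel that must agree with it to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np

from . import channels as ch
from .channels import CHANNEL_TABLE, GATE_TABLE, gate_steady_state

__all__ = [
    "CellParams",
    "DEFAULT_CELL",
    "STATE_VARS",
    "NSTATE",
    "initial_state",
    "steady_gate_state",
    "internal_coupling_current",
    "cell_derivative",
    "soma_current_components",
    "decompose_soma_currents",
    "pa_to_density",
    "DENDRITE_AREA_CM2",
]

# Dendritic compartment area used to convert injected currents printed in pA
# into the current densities (µA/cm²) the model equations use.  Named here so
# the conversion is auditable: 1 pA on the dendrite = 1e-6/AREA µA/cm².
# Calibrated once against the cell's firing behavior (see docs/methods.md).
DENDRITE_AREA_CM2 = 1.05e-6  # 105 µm²


def pa_to_density(amplitude_pa: float, area_cm2: float = DENDRITE_AREA_CM2) -> float:
    """Convert an absolute injected current (pA) to a density (µA/cm²)."""
    return amplitude_pa * 1.0e-6 / area_cm2


# State vector layout (per cell).  Voltages in mV, gates dimensionless,
# calcium in the model's dimensionless units.
STATE_VARS = (
    "v_dend", "v_soma", "v_axon",
    "r", "s", "q", "ca",          # dendrite: CaH act, KCa act, h act, [Ca2+]
    "k", "l", "h", "n", "x_s",    # soma: CaL act/inact, Na inact, Kdr act, slow K act
    "h_a", "x_a",                 # axon: Na inact, K act
)
NSTATE = len(STATE_VARS)
IDX = {name: i for i, name in enumerate(STATE_VARS)}

# Gate state indices and the compartment voltage each gate follows.
GATE_IDX = {"r": 3, "s": 4, "q": 5, "k": 7, "l": 8, "h": 9, "n": 10, "x_s": 11,
            "h_a": 12, "x_a": 13}
GATE_VCOMP = {"r": 0, "s": 0, "q": 0, "k": 1, "l": 1, "h": 1, "n": 1, "x_s": 1,
              "h_a": 2, "x_a": 2}


@dataclass(frozen=True)
class CellParams:
    """All conductances (mS/cm²), reversals (mV) and geometry for one cell.

    ``g_cal`` is the per-cell heterogeneity knob (T-type calcium conductance);
    the default 0.7 mS/cm² is the value the sampler keeps as the population
    mean.  ``p_soma_dend`` is the somatic fraction of the soma+dendrite
    surface; ``p_axon_soma`` the axonal fraction of the soma+axon surface.
    """

    g_cal: float = 0.7
    g_na_s: float = 150.0
    g_kdr_s: float = 9.0
    g_k_s: float = 5.0
    g_ls: float = 0.016
    g_cah: float = 4.5
    g_kca: float = 35.0
    g_h: float = 0.125
    g_ld: float = 0.016
    g_na_a: float = 240.0
    g_k_a: float = 20.0
    g_la: float = 0.016
    g_int: float = 0.13           # internal coupling conductance
    p_soma_dend: float = 0.25     # soma : soma+dendrite area ratio
    p_axon_soma: float = 0.15     # axon : soma+axon area ratio
    c_m: float = 1.0              # µF/cm²
    e_na: float = 55.0
    e_k: float = -75.0
    e_ca: float = 120.0
    e_h: float = -43.0
    e_leak: float = 10.0
    ca_influx: float = 3.0
    ca_decay: float = 0.075

    def __post_init__(self):
        for name in ("g_cal", "g_na_s", "g_kdr_s", "g_k_s", "g_ls", "g_cah", "g_kca",
                     "g_h", "g_ld", "g_na_a", "g_k_a", "g_la", "g_int", "c_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 < self.p_soma_dend < 1 and 0 < self.p_axon_soma < 1):
            raise ValueError("area fractions must lie in (0, 1)")

    def with_gcal(self, g_cal: float) -> "CellParams":
        return replace(self, g_cal=g_cal)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CellParams":
        return cls(**d)


DEFAULT_CELL = CellParams()


def steady_gate_state(v: float, ca: float = 3.7152) -> dict[str, float]:
    """All (non-instantaneous) gates at steady state for a uniform voltage."""
    return {g: gate_steady_state(g, v, ca) for g in GATE_IDX}


def initial_state(params: CellParams = DEFAULT_CELL, v0: float = -60.0) -> np.ndarray:
    """Canonical initial condition: uniform voltage, gates at steady state.

    The calcium pool starts at its fixed point for the steady I_CaH at v0.
    A settle period (default 1000 ms in the protocols) is still required
    before measurements, as the limit cycle takes time to establish.
    """
    y = np.empty(NSTATE)
    y[0] = y[1] = y[2] = v0
    # calcium fixed point: ca* = -influx·I_CaH(v0, r_inf)/decay
    r_inf = gate_steady_state("r", v0)
    i_cah = params.g_cah * r_inf**2 * (v0 - params.e_ca)
    ca0 = max(-params.ca_influx * i_cah / params.ca_decay, 0.0)
    gates = steady_gate_state(v0, ca0)
    for name, idx in GATE_IDX.items():
        y[idx] = gates[name]
    y[IDX["ca"]] = ca0
    return y


def internal_coupling_current(v_from: float, v_to: float, g_int: float,
                              area_fraction: float) -> float:
    """Ohmic internal current leaving compartment ``from`` toward ``to``.

    Positive = outward from the ``from`` compartment.  ``area_fraction`` is
    the ``from`` compartment's share of the joint surface, so the same g_int
    produces area-weighted, charge-conserving currents on the two sides.
    """
    if g_int < 0:
        raise ValueError("g_int must be non-negative")
    return (g_int / area_fraction) * (v_from - v_to)


def soma_current_components(y: np.ndarray, params: CellParams) -> dict[str, float]:
    """Each somatic membrane/coupling current (µA/cm², outward-positive)."""
    vd, vs, va = y[0], y[1], y[2]
    gv = {name: y[idx] for name, idx in GATE_IDX.items()}
    return {
        "I_CaL": ch.current_density(CHANNEL_TABLE["CaL"], gv, vs, g_max=params.g_cal),
        "I_Na_s": ch.current_density(CHANNEL_TABLE["Na_s"], gv, vs, g_max=params.g_na_s),
        "I_Kdr_s": ch.current_density(CHANNEL_TABLE["Kdr_s"], gv, vs, g_max=params.g_kdr_s),
        "I_K_s": ch.current_density(CHANNEL_TABLE["K_s"], gv, vs, g_max=params.g_k_s),
        "I_ls": params.g_ls * (vs - params.e_leak),
        "I_ds": internal_coupling_current(vs, vd, params.g_int, params.p_soma_dend),
        "I_as": internal_coupling_current(vs, va, params.g_int, 1.0 - params.p_axon_soma),
    }


def cell_derivative(
    y: np.ndarray,
    params: CellParams = DEFAULT_CELL,
    i_stim_dend: float = 0.0,
    i_stim_soma: float = 0.0,
    i_gap_dend: float = 0.0,
) -> np.ndarray:
    """Time derivative of the full cell state (reference implementation).

    ``i_gap_dend`` is the total gap-junction current leaving the dendrite
    (outward-positive); stimulus currents are positive-depolarizing.
    """
    if not np.all(np.isfinite(y)):
        bad = [STATE_VARS[i] for i in np.flatnonzero(~np.isfinite(y))]
        raise FloatingPointError(f"non-finite state components: {bad}")
    vd, vs, va = y[0], y[1], y[2]
    ca = y[IDX["ca"]]
    gv = {name: y[idx] for name, idx in GATE_IDX.items()}

    # dendrite
    i_cah = ch.current_density(CHANNEL_TABLE["CaH"], gv, vd, g_max=params.g_cah)
    i_kca = ch.current_density(CHANNEL_TABLE["KCa"], gv, vd, calcium=ca, g_max=params.g_kca)
    i_h = ch.current_density(CHANNEL_TABLE["h"], gv, vd, g_max=params.g_h)
    i_ld = params.g_ld * (vd - params.e_leak)
    i_sd = internal_coupling_current(vd, vs, params.g_int, 1.0 - params.p_soma_dend)
    dvd = (-(i_cah + i_kca + i_h + i_ld + i_sd + i_gap_dend) + i_stim_dend) / params.c_m

    # soma
    sc = soma_current_components(y, params)
    dvs = (-sum(sc.values()) + i_stim_soma) / params.c_m

    # axon hillock
    i_na_a = ch.current_density(CHANNEL_TABLE["Na_a"], gv, va, g_max=params.g_na_a)
    i_k_a = ch.current_density(CHANNEL_TABLE["K_a"], gv, va, g_max=params.g_k_a)
    i_la = params.g_la * (va - params.e_leak)
    i_sa = internal_coupling_current(va, vs, params.g_int, params.p_axon_soma)
    dva = -(i_na_a + i_k_a + i_la + i_sa) / params.c_m

    dy = np.empty(NSTATE)
    dy[0], dy[1], dy[2] = dvd, dvs, dva
    for name, idx in GATE_IDX.items():
        v = y[GATE_VCOMP[name]]
        dy[idx] = ch.gate_derivative(name, y[idx], v, ca)
    dy[IDX["ca"]] = -params.ca_influx * i_cah - params.ca_decay * ca
    return dy


def decompose_soma_currents(result, cell: int = 0, t_start: float | None = None,
                            t_stop: float | None = None) -> dict[str, np.ndarray]:
    """Per-current somatic time series over a window of a stored trajectory.

    Requires the full state history (``store_state=True`` at simulation
    time).  Returns every somatic component plus the capacitive current
    ``I_cap = C_m dV_s/dt`` computed from the model equations, so that
    ``I_cap + Σ components = I_injected`` holds identically (Kirchhoff).
    """
    if result.state is None:
        raise ValueError("state history not stored; re-run with store_state=True "
                         "(CLI: --store-currents)")
    t = result.t
    lo = 0 if t_start is None else int(np.searchsorted(t, t_start))
    hi = len(t) if t_stop is None else int(np.searchsorted(t, t_stop, side="right"))
    if lo >= hi:
        raise ValueError("requested window lies outside the stored trajectory")
    params = result.cell_params[cell]
    names = ["I_CaL", "I_Na_s", "I_Kdr_s", "I_K_s", "I_ls", "I_ds", "I_as"]
    out = {k: np.empty(hi - lo) for k in names + ["I_cap", "I_stim_soma"]}
    for j, i in enumerate(range(lo, hi)):
        y = result.state[i, cell]
        sc = soma_current_components(y, params)
        for k in names:
            out[k][j] = sc[k]
        i_stim = result.stim_soma_at(t[i], cell)
        out["I_stim_soma"][j] = i_stim
        out["I_cap"][j] = -sum(sc.values()) + i_stim
    out["t"] = t[lo:hi].copy()
    return out
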