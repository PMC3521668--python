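"""Time integration of coupled IO networks and stimulation protocols.

Integrator: fixed-step 4th-order Runge–Kutta, dt = 0.025 ms by default; the
voltage history is recorded every ``record_every`` steps (0.05 ms by
default).  Runs are bit-exactly reproducible from (inputs, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernel
from .cell import CellParams, DEFAULT_CELL, NSTATE, initial_state, pa_to_density
from .network import NetworkSpec, build_grid

__all__ = [
    "StimulusElement",
    "StimulusProtocol",
    "SimulationResult",
    "SimulationDivergence",
    "integrate",
    "single_cell_network",
    "settle",
    "random_phase_states",
    "calibrate_imposed_sinusoid",
    "intrinsic_sto_extrema",
]

DEFAULT_DT = 0.025  # ms
DEFAULT_RECORD_EVERY = 2  # -> 0.05 ms sampling


class SimulationDivergence(RuntimeError):
    pass


@dataclass(frozen=True)
class StimulusElement:
    """One stimulus: block pulse or sinusoid, targeting one compartment.

    ``amplitude``/``offset`` are in pA if ``unit == "pA"`` (converted to
    current density with the dendritic area constant) or directly in µA/cm²
    if ``unit == "uA/cm2"``.  The sinusoid is evaluated in absolute run time,
    amp·sin(2πf·t + phase) + offset, and gated to [onset, onset+duration).
    """

    cells: tuple[int, ...]
    compartment: str = "dend"  # "dend" | "soma"
    kind: str = "block_pulse"  # "block_pulse" | "sinusoid"
    amplitude: float = 0.0
    unit: str = "pA"
    onset: float = 0.0  # ms
    duration: float = 0.0  # ms
    frequency: float = 0.0  # Hz, sinusoid only
    phase: float = 0.0  # rad, sinusoid only
    offset: float = 0.0  # same unit as amplitude

    def __post_init__(self):
        if self.onset < 0 or self.duration < 0:
            raise ValueError("onset and duration must be non-negative")
        if self.compartment not in ("dend", "soma"):
            raise ValueError("compartment must be 'dend' or 'soma'")
        if self.kind not in ("block_pulse", "sinusoid"):
            raise ValueError("kind must be 'block_pulse' or 'sinusoid'")
        if self.unit not in ("pA", "uA/cm2"):
            raise ValueError("unit must be 'pA' or 'uA/cm2'")

    def density(self, value: float) -> float:
        return pa_to_density(value) if self.unit == "pA" else value


@dataclass
class StimulusProtocol:
    elements: list[StimulusElement] = field(default_factory=list)

    def shifted(self, dt_ms: float) -> "StimulusProtocol":
        """Same protocol with every onset shifted by ``dt_ms``."""
        els = [StimulusElement(**{**asdict(e), "cells": tuple(e.cells),
                                  "onset": e.onset + dt_ms}) for e in self.elements]
        return StimulusProtocol(els)

    def arrays(self, dt: float) -> tuple[np.ndarray, ...]:
        """Flatten to kernel arrays; onsets/durations quantized to the dt grid
        (ties toward the earlier sample)."""
        rows = []
        for e in self.elements:
            onset = round(e.onset / dt) * dt
            dur = round(e.duration / dt) * dt
            for c in e.cells:
                rows.append((c, 0 if e.compartment == "dend" else 1,
                             0 if e.kind == "block_pulse" else 1,
                             e.density(e.amplitude), onset, dur,
                             e.frequency, e.phase, e.density(e.offset)))
        if not rows:
            rows = [(0, 0, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)]
        a = np.array(rows, dtype=np.float64)
        return (a[:, 0].astype(np.int64), a[:, 1].astype(np.int64),
                a[:, 2].astype(np.int64), a[:, 3], a[:, 4], a[:, 5],
                a[:, 6], a[:, 7], a[:, 8])

    def to_dict(self) -> dict:
        return {"elements": [dict(asdict(e), cells=list(e.cells)) for e in self.elements]}

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls([StimulusElement(**dict(e, cells=tuple(e["cells"])))
                    for e in d["elements"]])


EMPTY_PROTOCOL = StimulusProtocol()

DEND, SOMA, AXON = 0, 1, 2


@dataclass
class SimulationResult:
    """Uniformly sampled voltage (and optionally state) history of one run."""

    t: np.ndarray  # (n_rec,), ms
    v: np.ndarray  # (n_rec, n_cells, 3): dend, soma, axon
    final_state: np.ndarray  # (n_cells, NSTATE)
    dt: float
    dt_rec: float
    network: NetworkSpec
    base_params: CellParams
    g_cal: np.ndarray  # per-cell
    protocol: StimulusProtocol
    state: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.v.shape[1]

    def v_soma(self, cell: int = 0) -> np.ndarray:
        return self.v[:, cell, SOMA]

    def v_dend(self, cell: int = 0) -> np.ndarray:
        return self.v[:, cell, DEND]

    def v_axon(self, cell: int = 0) -> np.ndarray:
        return self.v[:, cell, AXON]

    @property
    def cell_params(self) -> list[CellParams]:
        return [self.base_params.with_gcal(g) for g in self.g_cal]

    def _stim_at(self, t: float, cell: int, compartment: str) -> float:
        tot = 0.0
        for e in self.protocol.elements:
            if cell in e.cells and e.compartment == compartment and \
                    e.onset <= t < e.onset + e.duration:
                if e.kind == "block_pulse":
                    tot += e.density(e.amplitude)
                else:
                    tot += e.density(e.amplitude) * np.sin(
                        2 * np.pi * e.frequency * t * 1e-3 + e.phase
                    ) + e.density(e.offset)
        return tot

    def stim_soma_at(self, t: float, cell: int) -> float:
        return self._stim_at(t, cell, "soma")

    def stim_dend_at(self, t: float, cell: int) -> float:
        return self._stim_at(t, cell, "dend")


def _params_hash(network: NetworkSpec, params: CellParams, protocol: StimulusProtocol,
                 duration: float, dt: float, seed) -> str:
    blob = json.dumps(
        {"network": network.to_dict(), "cell": params.to_dict(),
         "protocol": protocol.to_dict(), "duration": duration, "dt": dt, "seed": seed},
        sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def integrate(
    network: NetworkSpec,
    cell_params: CellParams | list[CellParams] = DEFAULT_CELL,
    protocol: StimulusProtocol = EMPTY_PROTOCOL,
    duration: float = 1000.0,
    dt: float = DEFAULT_DT,
    seed: int | None = None,
    y0: np.ndarray | None = None,
    t0: float = 0.0,
    record_every: int = DEFAULT_RECORD_EVERY,
    store_state: bool = False,
) -> SimulationResult:
    """Integrate the coupled network for ``duration`` ms from ``y0``.

    Cells may differ only in g_CaL (the model's heterogeneity knob): pass a
    base ``CellParams`` and set per-cell values in ``network.g_cal``, or pass
    a list of ``CellParams`` differing only in ``g_cal``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dt <= 0 or dt > 0.05:
        raise ValueError("dt must be in (0, 0.05] ms")
    n = network.n_cells
    if isinstance(cell_params, CellParams):
        base = cell_params
        g_cal = np.full(n, base.g_cal) if network.g_cal is None \
            else np.asarray(network.g_cal, dtype=float)
    else:
        if len(cell_params) != n:
            raise ValueError("need one CellParams per cell")
        base = cell_params[0]
        for cp in cell_params[1:]:
            if cp.with_gcal(base.g_cal) != base:
                raise ValueError("cells may differ only in g_cal")
        g_cal = np.array([cp.g_cal for cp in cell_params])
    if len(g_cal) != n:
        raise ValueError("g_cal length does not match cell count")

    if y0 is None:
        y0 = np.tile(initial_state(base), (n, 1))
    y0 = np.asarray(y0, dtype=np.float64)
    if y0.shape != (n, NSTATE):
        raise ValueError(f"y0 must have shape ({n}, {NSTATE})")

    P = _kernel.pack_params(base, network.g_gap_max, network.gap_voltage_dependent)
    indptr, indices = network.csr()
    st = protocol.arrays(dt)
    n_steps = int(round(duration / dt))

    V, S, yf, status, fail_step = _kernel.integrate_rk4(
        y0, g_cal, P, indptr, indices, *st,
        dt, n_steps, record_every, store_state, t0)
    if status != 0:
        t_fail = t0 + fail_step * dt
        raise SimulationDivergence(
            f"integration diverged at t = {t_fail:.3f} ms (|V| > 150 mV or non-finite)")

    t = t0 + np.arange(V.shape[0]) * dt * record_every
    meta = {
        "integrator": "rk4",
        "dt": dt,
        "dt_rec": dt * record_every,
        "seed": seed,
        "t0": t0,
        "duration": duration,
        "params_hash": _params_hash(network, base, protocol, duration, dt, seed),
    }
    return SimulationResult(
        t=t, v=V, final_state=yf, dt=dt, dt_rec=dt * record_every,
        network=network, base_params=base, g_cal=g_cal, protocol=protocol,
        state=S if store_state else None, metadata=meta)


def single_cell_network(g_cal: float | None = None,
                        gap_voltage_dependent: bool = True) -> NetworkSpec:
    """An uncoupled 1×1 'network' for isolated-cell runs."""
    spec = build_grid(1, 1, gap_voltage_dependent=gap_voltage_dependent)
    if g_cal is not None:
        spec.g_cal = np.array([g_cal])
    return spec


def settle(network: NetworkSpec, cell_params: CellParams = DEFAULT_CELL,
           settle_ms: float = 1500.0, dt: float = DEFAULT_DT,
           protocol: StimulusProtocol = EMPTY_PROTOCOL) -> np.ndarray:
    """Integrate from the canonical initial condition; return the final state.

    Used as the discard period before any measurement, so the limit cycle is
    established.
    """
    res = integrate(network, cell_params, protocol, duration=settle_ms, dt=dt,
                    record_every=max(1, int(round(settle_ms / dt / 50))))
    return res.final_state


def _dominant_period_ms(v: np.ndarray, dt_rec: float) -> float | None:
    """Dominant STO period from the spectral peak; None if flat (< 0.1 mV)."""
    x = v - v.mean()
    if x.max() - x.min() < 0.1:
        return None
    w = np.hanning(len(x))
    freq = np.fft.rfftfreq(len(x), d=dt_rec * 1e-3)
    p = np.abs(np.fft.rfft(x * w)) ** 2
    fpk = freq[1:][np.argmax(p[1:])]
    if fpk <= 0:
        return None
    return 1000.0 / fpk


def random_phase_states(
    network: NetworkSpec,
    cell_params: CellParams = DEFAULT_CELL,
    rng: np.random.Generator | int = 0,
    settle_ms: float = 1500.0,
    dt: float = DEFAULT_DT,
) -> np.ndarray:
    """Initial states with every cell on its own limit cycle at a random phase.

    Each cell is integrated in isolation for ``settle_ms`` plus an
    independently drawn extra time uniform in [0, one intrinsic period), then
    the states are assembled for the coupled run.  Cells without a detectable
    oscillation (below the oscillation onset) get no extra time.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = network.n_cells
    uncoupled = NetworkSpec(rows=network.rows, cols=network.cols, edges=network.edges,
                            g_gap_max=0.0, g_cal=network.g_cal,
                            gap_voltage_dependent=network.gap_voltage_dependent)
    res = integrate(uncoupled, cell_params, duration=settle_ms, dt=dt)
    keep = res.t >= settle_ms - 1000.0
    states = res.final_state.copy()
    single = build_grid(1, 1)
    for i in range(n):
        period = _dominant_period_ms(res.v[keep, i, SOMA], res.dt_rec)
        extra = rng.uniform(0.0, period) if period is not None else 0.0
        if extra < dt:
            continue
        single.g_cal = np.array([res.g_cal[i]])
        r1 = integrate(single, cell_params, duration=max(extra, dt), dt=dt,
                       y0=states[i][None, :], record_every=10 ** 6)
        states[i] = r1.final_state[0]
    return states


def intrinsic_sto_extrema(cell_params: CellParams = DEFAULT_CELL,
                          g_cal: float | None = None,
                          settle_ms: float = 1500.0, measure_ms: float = 1000.0,
                          dt: float = DEFAULT_DT) -> tuple[float, float]:
    """(V_max, V_min) of the isolated cell's intrinsic somatic STO."""
    net = single_cell_network(g_cal)
    y0 = settle(net, cell_params, settle_ms, dt)[...]
    res = integrate(net, cell_params, duration=measure_ms, dt=dt, y0=y0)
    v = res.v_soma(0)
    return float(v.max()), float(v.min())


def calibrate_imposed_sinusoid(
    cell_params: CellParams = DEFAULT_CELL,
    frequency: float = 5.0,
    tol_mv: float = 0.2,
    max_iter: int = 25,
    dt: float = DEFAULT_DT,
) -> StimulusElement:
    """Calibrate a somatic sinusoidal current so the imposed membrane
    oscillation spans the same max/min as the cell's intrinsic STO.

    Returns a soma-targeted sinusoid element (density units) with onset 0 and
    a very long duration; shift/trim it for use in a protocol.  Raises if the
    max/min cannot be matched within ``tol_mv`` in ``max_iter`` iterations.
    """
    vmax_t, vmin_t = intrinsic_sto_extrema(cell_params, dt=dt)
    net = single_cell_network()
    y0 = settle(net, cell_params, 1500.0, dt)
    amp = 0.5  # µA/cm²
    off = 0.0
    gain = None
    for _ in range(max_iter):
        el = StimulusElement(cells=(0,), compartment="soma", kind="sinusoid",
                             amplitude=amp, unit="uA/cm2", onset=0.0, duration=1e7,
                             frequency=frequency, offset=off)
        res = integrate(net, cell_params, StimulusProtocol([el]),
                        duration=3000.0, dt=dt, y0=y0)
        v = res.v_soma(0)[res.t >= 1000.0]
        e_max = float(v.max()) - vmax_t
        e_min = float(v.min()) - vmin_t
        if abs(e_max) < tol_mv and abs(e_min) < tol_mv:
            return el
        if gain is None:
            swing = (v.max() - v.min()) / 2.0
            gain = amp / max(swing, 1e-3)  # µA/cm² per mV of half-swing
        # damped proportional update: residual difference drives the amplitude,
        # residual sum the offset
        amp -= 0.6 * gain * (e_max - e_min) / 2.0
        off -= 0.6 * gain * (e_max + e_min) / 2.0
        amp = max(amp, 1e-4)
    raise RuntimeError("sinusoid calibration did not converge "
                       f"(residuals {e_max:+.2f}/{e_min:+.2f} mV)")
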