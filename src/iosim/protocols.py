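"""Batch experiment drivers: phase-dependency, ensemble-synchrony and g_CaL
sweep campaigns, with aggregation into per-trial metric tables.

Every campaign is deterministic under its root seed: per-trial randomness is
derived with ``numpy.random.SeedSequence(root_seed).spawn``, so trials can be
reordered or parallelized without changing results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell import CellParams, DEFAULT_CELL
from .network import NetworkSpec, build_grid
from .simulate import (
    StimulusElement,
    StimulusProtocol,
    calibrate_imposed_sinusoid,
    integrate,
    random_phase_states,
    settle,
)
from . import analysis

__all__ = [
    "ExperimentConfig",
    "run_phase_dependency",
    "run_ensemble_synchrony",
    "run_synchronization",
    "run_gcal_sweep",
]

# Pulse amplitudes the campaigns use (pA): phase-dependency pulses are
# 20 ms at 5.5 pA; ensemble-synchrony pulses 6 pA (5 pA on 1×3 grids).
PULSE_PA_PHASE_DEP = 5.5
PULSE_PA_ENSEMBLE = 6.0
PULSE_PA_ENSEMBLE_1X3 = 5.0
PULSE_MS = 20.0
AP_WINDOW_MS = 50.0  # a trial counts as a full AP if a somatic spike falls
                     # within this window after pulse onset
SETTLE_MS = 1500.0
PRE_ONSET_MS = 450.0  # phase-dependency: first onset after the settle state
POST_MS = 600.0  # post-pulse window: covers ADP + AHP recovery


@dataclass
class ExperimentConfig:
    kind: str  # "phase_dependency" | "ensemble_synchrony" | "gcal_sweep"
    rows: int = 3
    cols: int = 3
    n_trials: int = 100
    root_seed: int = 0
    dt: float = 0.025
    pulse_pa: float | None = None
    extras: dict = field(default_factory=dict)


def _spike_row(base: dict, m: analysis.SpikeMetrics | None) -> dict:
    row = dict(base)
    if m is None:
        row.update(spike=False)
        return row
    row.update(
        spike=True,
        ap_onset_time=m.ap_onset_time,
        na_peak_time=m.na_peak_time,
        spikelet_count=m.spikelet_count,
        adp_amplitude=m.adp_amplitude,
        adp_duration=m.adp_duration,
        adp_complete=m.adp_complete,
        ahp_duration=m.ahp_duration if m.ahp_complete else np.nan,
        ahp_complete=m.ahp_complete,
        dendrosomatic_charge=m.dendrosomatic_charge,
        phase=m.sto_phase_at_spike,
        sto_amplitude=m.sto_amplitude_pre_spike,
    )
    return row


def _measure_trial(res, cell: int, stim_onset: float):
    """Detect the evoked AP (within AP_WINDOW_MS of pulse onset) and measure it.

    Returns (SpikeMetrics | None, pre-stimulus STO amplitude | nan).  The
    pre-stimulus amplitude is measured on the STO period directly preceding
    the pulse, so it is untouched by the pulse-driven depolarization.
    """
    v = res.v_soma(cell)
    dt = res.dt_rec
    t0 = res.t[0]
    try:
        amp_prestim = analysis.estimate_sto_amplitude(v, dt, stim_onset, t0=t0)
    except analysis.InsufficientOscillation:
        amp_prestim = np.nan
    aps = [a for a in analysis.detect_aps(v, dt, t0=t0)
           if stim_onset <= a.peak_time <= stim_onset + AP_WINDOW_MS]
    if not aps:
        return None, amp_prestim
    ap = aps[0]
    lvl = analysis.sto_peak_level(v, dt, int(round((stim_onset - t0) / dt)))
    m = analysis.measure_spike(v, dt, ap, lvl, t0=t0, result=res, cell=cell)
    return m, amp_prestim


def run_phase_dependency(
    n_trials: int = 100,
    onset_step_ms: float = 2.0,
    conditions: tuple[str, ...] = ("intrinsic/full", "intrinsic/single",
                                   "imposed/full", "imposed/single"),
    cell_params: CellParams = DEFAULT_CELL,
    pulse_pa: float = PULSE_PA_PHASE_DEP,
    root_seed: int = 0,
    dt: float = 0.025,
) -> pd.DataFrame:
    """Phase-dependency campaign on a homogeneous 3×3 network.

    For each condition (STO mode intrinsic or imposed-5 Hz × stimulation of
    the full network or the center cell only), ``n_trials`` pulses (20 ms,
    ``pulse_pa``) are applied to the dendrites with onsets advancing by
    ``onset_step_ms`` per trial, and the evoked AP of the center cell is
    measured.  Returns one row per trial.
    """
    net = build_grid(3, 3)
    center = net.center
    y0 = settle(net, cell_params, SETTLE_MS, dt)
    sine = None
    y0_imposed = None
    rows = []
    for cond in conditions:
        sto_mode, stim_mode = cond.split("/")
        cells = tuple(range(net.n_cells)) if stim_mode == "full" else (center,)
        base_elements = []
        if sto_mode == "imposed":
            if sine is None:
                sine = calibrate_imposed_sinusoid(cell_params, dt=dt)
                # establish the imposed oscillation before the trials
                imp = StimulusElement(cells=(center,), compartment="soma",
                                      kind="sinusoid", amplitude=sine.amplitude,
                                      unit="uA/cm2", onset=0.0, duration=1e7,
                                      frequency=sine.frequency, offset=sine.offset)
                res0 = integrate(net, cell_params, StimulusProtocol([imp]),
                                 duration=SETTLE_MS, dt=dt, y0=y0, record_every=10**5)
                y0_imposed = res0.final_state
            base_elements = [StimulusElement(
                cells=(center,), compartment="soma", kind="sinusoid",
                amplitude=sine.amplitude, unit="uA/cm2", onset=0.0, duration=1e7,
                frequency=sine.frequency, phase=sine.phase, offset=sine.offset)]
            y_start, t_start = y0_imposed, SETTLE_MS
        else:
            y_start, t_start = y0, 0.0
        for trial in range(n_trials):
            onset = t_start + PRE_ONSET_MS + trial * onset_step_ms
            pulse = StimulusElement(cells=cells, compartment="dend",
                                    kind="block_pulse", amplitude=pulse_pa,
                                    unit="pA", onset=onset, duration=PULSE_MS)
            res = integrate(net, cell_params,
                            StimulusProtocol(base_elements + [pulse]),
                            duration=onset - t_start + PULSE_MS + POST_MS,
                            dt=dt, y0=y_start, t0=t_start)
            m, amp_prestim = _measure_trial(res, center, onset)
            rows.append(_spike_row(
                {"condition": cond, "sto_mode": sto_mode, "stim_mode": stim_mode,
                 "trial": trial, "stim_onset": onset,
                 "sto_amplitude_prestim": amp_prestim}, m))
    return pd.DataFrame(rows)


def run_ensemble_synchrony(
    rows_cols: tuple[int, int] = (3, 3),
    n_trials: int = 700,
    cell_params: CellParams = DEFAULT_CELL,
    root_seed: int = 0,
    dt: float = 0.025,
    pulse_pa: float | None = None,
    measure_synchrony: bool = False,
) -> pd.DataFrame:
    """Ensemble-synchrony campaign on heterogeneous networks.

    Per trial: a fresh heterogeneous network (g_CaL uniform on [0.55, 0.9],
    mean 0.7) is initialized with random phase differences; a 20 ms dendritic
    pulse (6 pA; 5 pA on 1×3 grids) hits the center cell at a random onset
    uniform in [200, 900] ms; trials with a full-blown AP are analyzed for
    STO phase, spikelet count and pre-spike STO amplitude.
    """
    r, c = rows_cols
    if pulse_pa is None:
        pulse_pa = PULSE_PA_ENSEMBLE_1X3 if r * c <= 3 else PULSE_PA_ENSEMBLE
    seeds = np.random.SeedSequence(root_seed).spawn(n_trials)
    out = []
    for trial in range(n_trials):
        rng = np.random.default_rng(seeds[trial])
        net_seed = int(rng.integers(2**31 - 1))
        net = build_grid(r, c, heterogeneous=True, seed=net_seed)
        y0 = random_phase_states(net, cell_params, rng=rng, dt=dt)
        onset = float(rng.uniform(200.0, 900.0))
        pulse = StimulusElement(cells=(net.center,), compartment="dend",
                                kind="block_pulse", amplitude=pulse_pa,
                                unit="pA", onset=onset, duration=PULSE_MS)
        res = integrate(net, cell_params, StimulusProtocol([pulse]),
                        duration=onset + PULSE_MS + POST_MS, dt=dt, y0=y0,
                        seed=net_seed)
        m, amp_prestim = _measure_trial(res, net.center, onset)
        base = {"trial": trial, "rows": r, "cols": c, "stim_onset": onset,
                "pulse_pa": pulse_pa, "net_seed": net_seed,
                "sto_amplitude_prestim": amp_prestim}
        if measure_synchrony and net.n_cells > 1:
            try:
                sm = analysis.synchrony_metrics(res, t=onset)
                base["synchrony_ratio_at_stim"] = sm.synchrony_ratio
                base["mean_amp_at_stim"] = sm.mean_sto_amplitude
            except ValueError:
                pass
        out.append(_spike_row(base, m))
    return pd.DataFrame(out)


def run_synchronization(
    rows_cols: tuple[int, int] = (3, 3),
    n_seeds: int = 50,
    duration: float = 1500.0,
    cell_params: CellParams = DEFAULT_CELL,
    root_seed: int = 0,
    dt: float = 0.025,
    threshold_mv: float = 5.5,
) -> pd.DataFrame:
    """Unstimulated synchronization runs (heterogeneous, random phases).

    Per seed: time of the first crossing of the mean-STO-amplitude threshold,
    the synchrony ratio at that instant (cross-correlation method and the
    amplitude-proxy method side by side), and the settling time at which all
    cells share one STO period (coefficient of variation of per-cell dominant
    periods < 1%).
    """
    r, c = rows_cols
    seeds = np.random.SeedSequence(root_seed).spawn(n_seeds)
    rows = []
    for i in range(n_seeds):
        rng = np.random.default_rng(seeds[i])
        net_seed = int(rng.integers(2**31 - 1))
        net = build_grid(r, c, heterogeneous=True, seed=net_seed)
        y0 = random_phase_states(net, cell_params, rng=rng, dt=dt)
        res = integrate(net, cell_params, duration=duration, dt=dt, y0=y0)
        sm_end = analysis.synchrony_metrics(res, t=res.t[-1], threshold_mv=threshold_mv)
        cross = sm_end.time_to_amplitude_threshold
        row = {"seed_index": i, "net_seed": net_seed,
               "crossing_ms": cross,
               "settling_ms": settling_time(res),
               "final_mean_amp": sm_end.mean_sto_amplitude}
        if cross is not None:
            sm = analysis.synchrony_metrics(res, t=cross, threshold_mv=threshold_mv)
            row["synchrony_ratio_xcorr"] = sm.synchrony_ratio
            row["synchrony_ratio_proxy"] = sm.synchrony_ratio_amplitude_proxy
            row["phase_diff_deg"] = sm.mean_pairwise_phase_difference
        rows.append(row)
    return pd.DataFrame(rows)


def settling_time(res, window_ms: float = 500.0, step_ms: float = 25.0,
                  cov_threshold: float = 0.01) -> float | None:
    """Earliest time from which all cells share one dominant STO period.

    Per-cell periods are mean inter-peak intervals in a sliding window; the
    network counts as settled from the first window whose across-cell
    coefficient of variation is below ``cov_threshold`` and stays below it
    for the rest of the run.  Window statistics are stamped at the window
    center, matching the amplitude-time-series convention.  Returns the
    settling time (ms), or None.
    """
    from scipy.signal import find_peaks

    vs = res.v[:, :, 1].T
    dt = res.dt_rec
    n_cells, n_samp = vs.shape
    w = int(round(window_ms / dt))
    step = int(round(step_ms / dt))
    starts = np.arange(0, n_samp - w, step)
    cov = np.full(len(starts), np.inf)
    for j, s in enumerate(starts):
        periods = []
        ok = True
        for i in range(n_cells):
            seg = vs[i, s:s + w]
            prom = max(0.02, 0.1 * (seg.max() - seg.min()) / 2.0)
            pk, _ = find_peaks(seg, prominence=prom)
            if len(pk) < 3:
                ok = False
                break
            periods.append(np.mean(np.diff(pk)) * dt)
        if ok:
            periods = np.asarray(periods)
            cov[j] = periods.std() / periods.mean()
    settled = cov < cov_threshold
    # first window from which the criterion holds through the end of the run
    for j in range(len(starts)):
        if settled[j:].all() and settled[j]:
            return float(res.t[0] + (starts[j] + w / 2.0) * dt)
    return None


def run_gcal_sweep(
    g_values: tuple[float, ...] = (0.55, 0.65, 0.7, 0.8, 0.9),
    n_trials: int = 100,
    onset_step_ms: float = 2.0,
    cell_params: CellParams = DEFAULT_CELL,
    pulse_pa: float = PULSE_PA_PHASE_DEP,
    root_seed: int = 0,
    dt: float = 0.025,
) -> pd.DataFrame:
    """T-type conductance sweep: single-cell stimulation in a homogeneous
    9-cell network at each g_CaL, onsets sweeping the STO cycle; returns
    per-trial spikelet count, ADP duration and dendrosomatic charge."""
    rows = []
    for g in g_values:
        params = cell_params.with_gcal(g)
        net = build_grid(3, 3)
        center = net.center
        y0 = settle(net, params, SETTLE_MS, dt)
        for trial in range(n_trials):
            onset = PRE_ONSET_MS + trial * onset_step_ms
            pulse = StimulusElement(cells=(center,), compartment="dend",
                                    kind="block_pulse", amplitude=pulse_pa,
                                    unit="pA", onset=onset, duration=PULSE_MS)
            res = integrate(net, params, StimulusProtocol([pulse]),
                            duration=onset + PULSE_MS + POST_MS, dt=dt, y0=y0)
            m, amp_prestim = _measure_trial(res, center, onset)
            rows.append(_spike_row({"g_cal": g, "trial": trial,
                                    "stim_onset": onset,
                                    "sto_amplitude_prestim": amp_prestim}, m))
    return pd.DataFrame(rows)
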