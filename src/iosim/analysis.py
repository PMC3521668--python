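"""Trace measurements: AP/spikelet detection, ADP/AHP metrics, STO phase and
amplitude, dendrosomatic charge, and network synchrony.

Phase convention: the fitted sinewave is written A·sin(θ) with A > 0, so the
STO peak maps to θ = 0.5π and the trough to θ = 1.5π; phases are reported in
[0, 2π).  All voltage traces are uniformly sampled somatic potentials (mV)
with sample interval ``dt`` (ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import find_peaks

__all__ = [
    "APDetection",
    "SpikeMetrics",
    "PhaseEstimate",
    "SynchronyMetrics",
    "InsufficientOscillation",
    "detect_aps",
    "count_spikelets",
    "measure_ahp",
    "estimate_phase",
    "estimate_sto_amplitude",
    "sto_peak_level",
    "dominant_frequency",
    "dendrosomatic_charge",
    "synchrony_metrics",
    "amplitude_timeseries",
    "phase_bin_spikelet_table",
    "measure_spike",
]

SPIKELET_PROMINENCE = 0.3  # mV; floor below which ADP ripples are not counted


class InsufficientOscillation(ValueError):
    """Raised when a phase/amplitude estimate is requested without the
    required preceding oscillation (two peaks + two troughs)."""


@dataclass(frozen=True)
class APDetection:
    onset_time: float  # ms
    peak_time: float  # ms
    onset_idx: int
    peak_idx: int


@dataclass
class PhaseEstimate:
    phase: float  # rad in [0, 2π)
    frequency: float  # Hz
    amplitude: float  # mV
    rmse: float  # mV
    anchor: str  # "two-maxima" | "two-minima"


@dataclass
class SpikeMetrics:
    """Per-AP measurements (times in ms relative to the trace's time base)."""

    ap_onset_time: float
    na_peak_time: float
    spikelet_count: int = 0
    spikelet_times: list = field(default_factory=list)
    adp_amplitude: float = np.nan  # mV, from the AP-onset level
    adp_duration: float = np.nan  # ms
    ahp_duration: float = np.nan  # ms
    dendrosomatic_charge: float = np.nan  # µC/cm² over the ADP window
    sto_phase_at_spike: float = np.nan  # rad
    sto_amplitude_pre_spike: float = np.nan  # mV, half peak-to-trough
    adp_complete: bool = True
    ahp_complete: bool = True
    adp_window: tuple = (np.nan, np.nan)  # (start, end) ms


@dataclass
class SynchronyMetrics:
    mean_pairwise_phase_difference: float  # degrees
    synchrony_ratio: float  # 1 − diff/180
    mean_sto_amplitude: float  # mV
    time_to_amplitude_threshold: float | None  # ms, first crossing of 5.5 mV
    synchrony_ratio_amplitude_proxy: float | None = None


# --- spike detection -------------------------------------------------------

def detect_aps(v: np.ndarray, dt: float, height: float = -20.0,
               prominence: float = 20.0, refractory_ms: float = 20.0,
               onset_window_ms: float = 12.0, upstroke_mv_per_ms: float = 1.5,
               t0: float = 0.0) -> list[APDetection]:
    """Detect somatic sodium spikes; one detection per spike.

    The AP onset is the point of maximal second time-derivative of the
    voltage on the oscillation preceding the sodium peak: the search is
    restricted to samples before dV/dt first exceeds
    ``upstroke_mv_per_ms`` (the departure from the sinusoid — the STO's own
    slope stays well below this), so the onset sits at the foot of the spike
    on the STO rather than mid-upstroke.  Detections closer than
    ``refractory_ms`` are merged (the larger peak wins).
    """
    v = np.asarray(v, dtype=float)
    peaks, _ = find_peaks(v, height=height, prominence=prominence,
                          distance=max(1, int(round(refractory_ms / dt))))
    dv = np.diff(v) / dt
    out = []
    for p in peaks:
        i0 = max(0, p - int(round(onset_window_ms / dt)))
        up = p
        for i in range(i0, p):
            if dv[i] > upstroke_mv_per_ms:
                up = i
                break
        seg = v[i0:up + 2]
        if len(seg) < 5:
            onset_idx = max(i0, up - 1)
        else:
            d2 = np.diff(seg, 2)
            onset_idx = min(i0 + 1 + int(np.argmax(d2)), up)
        out.append(APDetection(onset_time=t0 + onset_idx * dt, peak_time=t0 + p * dt,
                               onset_idx=onset_idx, peak_idx=int(p)))
    return out


def sto_peak_level(v: np.ndarray, dt: float, before_idx: int,
                   lookback_ms: float = 170.0, prominence: float = 0.3) -> float:
    """Voltage attained at the peak of the STO preceding index ``before_idx``.

    The last oscillation peak in the lookback window is used; if no peak is
    prominent enough (quiescent cell), the window maximum is returned.
    """
    i0 = max(0, before_idx - int(round(lookback_ms / dt)))
    seg = np.asarray(v[i0:before_idx], dtype=float)
    if len(seg) < 3:
        raise ValueError("not enough samples before the spike to measure the STO peak")
    pks, _ = find_peaks(seg, prominence=prominence)
    if len(pks):
        return float(seg[pks[-1]])
    return float(seg.max())


def _primary_na_end(v: np.ndarray, dt: float, peak_idx: int, ref_level: float,
                    dvdt_thresh: float = -0.5, cap_ms: float = 2.0) -> int:
    """End of the primary sodium spike = start of the ADP window.

    First sample after the Na peak where V has fallen below the STO-peak
    level, or where dV/dt has relaxed back above ``dvdt_thresh`` mV/ms,
    whichever is later; capped at ``cap_ms`` after the peak.
    """
    cap = min(len(v) - 1, peak_idx + int(round(cap_ms / dt)))
    dv = np.diff(v) / dt
    i_below = cap
    for i in range(peak_idx + 1, cap + 1):
        if v[i] < ref_level:
            i_below = i
            break
    i_slope = cap
    started_falling = False
    for i in range(peak_idx + 1, cap + 1):
        if i - 1 < len(dv):
            if dv[i - 1] < dvdt_thresh:
                started_falling = True
            elif started_falling and dv[i - 1] > dvdt_thresh:
                i_slope = i
                break
    return min(max(i_below, i_slope), cap)


def count_spikelets(v: np.ndarray, dt: float, ap: APDetection,
                    sto_peak: float, prominence: float = SPIKELET_PROMINENCE,
                    smooth_ms: float = 0.2, t0: float = 0.0) -> SpikeMetrics:
    """Spikelet count/times and ADP amplitude/duration for one detected AP.

    Spikelets are the local maxima over the span of the calcium
    depolarization that follows the primary sodium spike; the ADP ends when
    the membrane potential falls back to the level attained at the preceding
    STO peak (``sto_peak``).  The ADP segment is lightly smoothed (Gaussian,
    ``smooth_ms``) and the prominence threshold is raised above the
    ``prominence`` floor when measurement noise is detected (robust estimate
    from second differences), so counts are stable on noisy recordings while
    noise-free model output keeps the plain 0.3 mV floor.
    """
    from scipy.ndimage import gaussian_filter1d

    v = np.asarray(v, dtype=float)
    m = SpikeMetrics(ap_onset_time=ap.onset_time, na_peak_time=ap.peak_time)
    start = _primary_na_end(v, dt, ap.peak_idx, sto_peak)
    end = None
    for i in range(start, len(v)):
        if v[i] <= sto_peak:
            end = i
            break
    if end is None:
        m.adp_complete = False
        end = len(v) - 1
    seg = v[start:end + 1]
    if len(seg) >= 5:
        # include the sodium downstroke as left context so the prominence of
        # a spikelet near the window edge is not clipped by the boundary
        ext = max(0, start - int(round(2.0 / dt)))
        seg_ext = v[ext:end + 1]
        s_samp = max(1.0, smooth_ms / dt)
        smooth = gaussian_filter1d(seg_ext, s_samp, mode="nearest")
        d2 = np.diff(seg, 2)
        sigma = np.median(np.abs(d2 - np.median(d2))) / 0.6745 / np.sqrt(6.0)
        sigma_s = sigma / np.sqrt(2.0 * s_samp * np.sqrt(np.pi))
        prom = max(prominence, 5.0 * sigma_s)
        pks, _ = find_peaks(smooth, prominence=prom)
        pks = [p for p in pks if p >= start - ext]
        m.spikelet_count = int(len(pks))
        m.spikelet_times = [t0 + (ext + p) * dt for p in pks]
    m.adp_duration = (end - start) * dt
    onset_level = v[ap.onset_idx]
    # height of the calcium plateau above the AP-onset level; the median over
    # the ADP window is insensitive to the spikelet tops riding on it
    m.adp_amplitude = float(np.median(seg) - onset_level) if len(seg) else np.nan
    m.adp_window = (t0 + start * dt, t0 + end * dt)
    return m


def measure_ahp(v: np.ndarray, dt: float, ap: APDetection, adp_end_time: float,
                pre_ap_level: float | None = None, t0: float = 0.0) -> tuple[float, bool]:
    """AHP duration: from the end of the ADP until the membrane potential
    returns to the level preceding the AP.  Returns (duration_ms, complete)."""
    v = np.asarray(v, dtype=float)
    if pre_ap_level is None:
        pre_ap_level = float(v[ap.onset_idx])
    i_adp = int(round((adp_end_time - t0) / dt))
    # enter the hyperpolarized phase...
    i_enter = None
    for i in range(i_adp, len(v)):
        if v[i] < pre_ap_level:
            i_enter = i
            break
    if i_enter is None:
        return 0.0, True  # never hyperpolarized below the pre-AP level
    # ...and recover from it
    for i in range(i_enter, len(v)):
        if v[i] >= pre_ap_level:
            return (i - i_adp) * dt, True
    return (len(v) - 1 - i_adp) * dt, False


# --- STO phase and amplitude ----------------------------------------------

def _refined_extrema(v: np.ndarray, dt: float, end_idx: int,
                     prominence: float | None = None,
                     smooth_ms: float = 2.0, min_spacing_ms: float = 25.0):
    """Peak and trough times before ``end_idx``, refined by local 2nd-order
    polynomial fits.  Returns (peak_times, trough_times, peak_vals, trough_vals).

    The trace is lightly smoothed and extrema closer than ``min_spacing_ms``
    are suppressed so measurement noise does not masquerade as oscillation
    cycles (olivary STO periods are two orders of magnitude longer).
    """
    from scipy.ndimage import gaussian_filter1d

    seg = np.asarray(v[:end_idx], dtype=float)
    if len(seg) < 10:
        raise InsufficientOscillation("trace too short for extremum detection")
    if smooth_ms > 0:
        seg = gaussian_filter1d(seg, max(1.0, smooth_ms / dt), mode="nearest")
    if prominence is None:
        prominence = max(0.1, 0.2 * (seg.max() - seg.min()) / 2.0)
    spacing = max(1, int(round(min_spacing_ms / dt)))

    def refine(idx: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        times, vals = [], []
        if len(idx) >= 2:
            half = max(3, int(0.08 * np.median(np.diff(idx))))
        else:
            half = 3
        for i in idx:
            lo, hi = max(0, i - half), min(len(x), i + half + 1)
            tt = np.arange(lo, hi) * dt
            c = np.polyfit(tt - tt.mean(), x[lo:hi], 2)
            if abs(c[0]) > 1e-12:
                t_ext = tt.mean() - c[1] / (2 * c[0])
                t_ext = min(max(t_ext, tt[0]), tt[-1])
                v_ext = np.polyval(c, t_ext - tt.mean())
            else:
                t_ext, v_ext = i * dt, x[i]
            times.append(t_ext)
            vals.append(v_ext)
        return np.array(times), np.array(vals)

    pk, _ = find_peaks(seg, prominence=prominence, distance=spacing)
    tr, _ = find_peaks(-seg, prominence=prominence, distance=spacing)
    pk_t, pk_v = refine(pk, seg)
    tr_t, tr_v = refine(tr, -seg)
    return pk_t, tr_t, pk_v, -tr_v


def _fit_sine(t: np.ndarray, v: np.ndarray, a0, f0, phi0, c0) -> tuple[np.ndarray, float]:
    def resid(x):
        a, f, phi, c = x
        return a * np.sin(2 * np.pi * f * t * 1e-3 + phi) + c - v

    sol = least_squares(resid, x0=[a0, f0, phi0, c0], method="lm", max_nfev=400)
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    a, f, phi, c = sol.x
    if a < 0:  # normalize to A > 0 so peak <-> 0.5π
        a, phi = -a, phi + np.pi
    return np.array([a, f, phi, c]), rmse


def estimate_phase(v: np.ndarray, dt: float, spike_time: float,
                   onset_time: float | None = None, t0: float = 0.0,
                   prominence: float | None = None) -> PhaseEstimate:
    """STO phase of a spike: sinewave fit to the two periods preceding it.

    A sinewave A·sin(2πft+φ)+c is least-squares fitted over the two STO
    periods immediately preceding the AP onset, initialized from
    polynomial-refined extremum locations; the two-maxima and two-minima
    anchorings are both fitted and the lower-RMSE fit is kept.  The returned
    phase is that of the sodium-spike maximum (``spike_time``) relative to
    the fit, in [0, 2π) with the peak at 0.5π.

    Requires two peaks and two troughs before the spike; otherwise raises
    :class:`InsufficientOscillation`.
    """
    v = np.asarray(v, dtype=float)
    if onset_time is None:
        onset_time = spike_time
    end_idx = int(round((onset_time - t0) / dt))
    if end_idx < 10:
        raise InsufficientOscillation("no oscillation preceding the spike")
    pk_t, tr_t, pk_v, tr_v = _refined_extrema(v, dt, end_idx, prominence)
    if len(pk_t) < 2 or len(tr_t) < 2:
        raise InsufficientOscillation(
            f"need two peaks and two troughs before the AP (found {len(pk_t)} peaks, "
            f"{len(tr_t)} troughs)")

    c0 = (np.mean(pk_v[-2:]) + np.mean(tr_v[-2:])) / 2.0
    a0 = max((np.mean(pk_v[-2:]) - np.mean(tr_v[-2:])) / 2.0, 1e-3)
    best = None
    for anchor, ts in (("two-maxima", pk_t[-2:]), ("two-minima", tr_t[-2:])):
        period = ts[-1] - ts[0]
        if period <= 0:
            continue
        f0 = 1000.0 / period
        target = 0.5 * np.pi if anchor == "two-maxima" else 1.5 * np.pi
        phi0 = target - 2 * np.pi * f0 * ts[-1] * 1e-3
        lo = max(0, end_idx - int(round(2 * period / dt)))
        tt = t0 + np.arange(lo, end_idx) * dt
        try:
            x, rmse = _fit_sine(tt, v[lo:end_idx], a0, f0, phi0, c0)
        except Exception:
            continue
        if best is None or rmse < best[1]:
            best = (x, rmse, anchor)
    if best is None:
        raise InsufficientOscillation("sinewave fit failed for both anchorings")
    x, rmse, anchor = best
    phase = float(np.mod(2 * np.pi * x[1] * spike_time * 1e-3 + x[2], 2 * np.pi))
    return PhaseEstimate(phase=phase, frequency=float(x[1]), amplitude=float(x[0]),
                         rmse=rmse, anchor=anchor)


def estimate_sto_amplitude(v: np.ndarray, dt: float, spike_time: float,
                           onset_time: float | None = None, t0: float = 0.0,
                           prominence: float | None = None) -> float:
    """Half peak-to-trough amplitude of the STO period directly preceding the
    spike: (max − min)/2 over the one period before the AP onset."""
    v = np.asarray(v, dtype=float)
    if onset_time is None:
        onset_time = spike_time
    end_idx = int(round((onset_time - t0) / dt))
    pk_t, tr_t, _, _ = _refined_extrema(v, dt, end_idx, prominence)
    periods = [np.diff(ts)[-1] for ts in (pk_t, tr_t) if len(ts) >= 2]
    if not periods:
        raise InsufficientOscillation("need one full STO period before the spike")
    period = float(np.mean(periods))
    lo = max(0, end_idx - int(round(period / dt)))
    seg = v[lo:end_idx]
    return float((seg.max() - seg.min()) / 2.0)


def dominant_frequency(v: np.ndarray, dt: float) -> float:
    """Dominant frequency (Hz) of a trace by FFT spectral peak (Hann window)."""
    x = np.asarray(v, dtype=float)
    x = x - x.mean()
    w = np.hanning(len(x))
    freq = np.fft.rfftfreq(len(x), d=dt * 1e-3)
    p = np.abs(np.fft.rfft(x * w)) ** 2
    return float(freq[1:][np.argmax(p[1:])])


# --- charge flow and synchrony ---------------------------------------------

def dendrosomatic_charge(result, cell: int, window: tuple[float, float]) -> float:
    """Charge flowing from soma to dendrite (µC/cm² of somatic membrane)
    over a time window: the integral of the internal coupling current
    (g_int/p_soma)·(V_soma − V_dend), positive = soma→dendrite."""
    t_lo, t_hi = window
    p = result.base_params
    sel = (result.t >= t_lo) & (result.t <= t_hi)
    if not np.any(sel):
        raise ValueError("window lies outside the stored trajectory")
    i_ds = (p.g_int / p.p_soma_dend) * (result.v[sel, cell, 1] - result.v[sel, cell, 0])
    return float(np.trapezoid(i_ds, result.t[sel]) * 1e-3)  # µA/cm²·ms → µC/cm²


def amplitude_timeseries(v: np.ndarray, dt: float, period_ms: float,
                         step_ms: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-trace STO amplitude over time: half peak-to-trough over a sliding
    window of one period, stamped at the window center (the unbiased
    convention for sliding statistics).  Returns (times, amplitudes)."""
    w = max(2, int(round(period_ms / dt)))
    step = max(1, int(round(step_ms / dt)))
    idx = np.arange(w, len(v), step)
    amps = np.empty(len(idx))
    for j, i in enumerate(idx):
        seg = v[i - w:i]
        amps[j] = (seg.max() - seg.min()) / 2.0
    return (idx - w / 2.0) * dt, amps


def _pairwise_phase_deg(traces: np.ndarray, dt: float, period_ms: float) -> float:
    """Mean pairwise STO phase difference (degrees) from cross-correlation
    lags of mean-subtracted somatic traces, over the supplied window."""
    n = traces.shape[0]
    max_lag = int(round(period_ms / 2.0 / dt))
    x = traces - traces.mean(axis=1, keepdims=True)
    diffs = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = x[i], x[j]
            best, best_lag = -np.inf, 0
            for lag in range(-max_lag, max_lag + 1):
                if lag >= 0:
                    c = np.dot(a[lag:], b[:len(b) - lag])
                else:
                    c = np.dot(a[:lag], b[-lag:])
                if c > best:
                    best, best_lag = c, lag
            diffs.append(abs(best_lag) * dt / period_ms * 360.0)
    return float(np.mean(diffs)) if diffs else 0.0


def synchrony_metrics(result, t: float, threshold_mv: float = 5.5,
                      max_amplitude: float | None = None) -> SynchronyMetrics:
    """Ensemble synchrony of a multi-cell run, evaluated at time ``t``.

    The mean pairwise phase difference is measured by cross-correlation over
    the two STO periods ending at ``t`` and mapped to the synchrony ratio
    (180° → 0, 0° → 1).  The mean STO amplitude across cells and the first
    time it crosses ``threshold_mv`` are measured over the whole run.  The
    amplitude-proxy ratio (mean amplitude at ``t`` relative to the maximum
    attained mean amplitude) is reported side by side.
    """
    if result.n_cells < 2:
        raise ValueError("synchrony metrics require a multi-cell simulation")
    vs = result.v[:, :, 1].T  # (n_cells, n_rec)
    dt = result.dt_rec
    # common period from the late segment
    late = vs[:, vs.shape[1] // 2:]
    periods = []
    for i in range(vs.shape[0]):
        f = dominant_frequency(late[i], dt)
        if f > 0.5:
            periods.append(1000.0 / f)
    period = float(np.median(periods)) if periods else 140.0

    amp_t = None
    amps_all = []
    for i in range(vs.shape[0]):
        ts, amps = amplitude_timeseries(vs[i], dt, period)
        amps_all.append(amps)
    amps_all = np.array(amps_all)
    mean_amp = amps_all.mean(axis=0)
    ts_abs = result.t[0] + ts
    crossing = None
    above = mean_amp > threshold_mv
    if np.any(above):
        crossing = float(ts_abs[int(np.argmax(above))])

    j = int(np.clip(np.searchsorted(ts_abs, t), 0, len(mean_amp) - 1))
    amp_at_t = float(mean_amp[j])

    i_hi = int(round((t - result.t[0]) / dt))
    i_lo = max(0, i_hi - int(round(2 * period / dt)))
    if i_hi - i_lo < 10:
        raise ValueError("not enough trace before t for phase comparison")
    diff_deg = _pairwise_phase_deg(vs[:, i_lo:i_hi], dt, period)
    ratio = 1.0 - diff_deg / 180.0

    amp_max = float(mean_amp.max()) if max_amplitude is None else max_amplitude
    proxy = amp_at_t / amp_max if amp_max > 0 else None
    return SynchronyMetrics(
        mean_pairwise_phase_difference=diff_deg,
        synchrony_ratio=ratio,
        mean_sto_amplitude=amp_at_t,
        time_to_amplitude_threshold=crossing,
        synchrony_ratio_amplitude_proxy=proxy,
    )


# --- aggregation ------------------------------------------------------------

def phase_bin_spikelet_table(metrics: list[SpikeMetrics], n_bins: int = 8) -> pd.DataFrame:
    """Per-phase-bin spikelet distributions and the firing-window mask.

    Returns one row per 45° bin (for n_bins=8): counts of each spikelet
    value, number of spikes, mean spikelet count, and a ``no_spikes`` flag
    for bins in which no spike occurred (the no-firing phase range).
    """
    width = 2 * np.pi / n_bins
    rows = []
    valid = [m for m in metrics if np.isfinite(m.sto_phase_at_spike)]
    max_spk = max((m.spikelet_count for m in valid), default=0)
    for b in range(n_bins):
        lo, hi = b * width, (b + 1) * width
        sel = [m for m in valid if lo <= m.sto_phase_at_spike < hi]
        row = {"bin": b, "phase_lo": lo, "phase_hi": hi, "n_spikes": len(sel),
               "mean_spikelets": float(np.mean([m.spikelet_count for m in sel]))
               if sel else np.nan,
               "no_spikes": len(sel) == 0}
        for k in range(max_spk + 1):
            row[f"count_{k}"] = sum(1 for m in sel if m.spikelet_count == k)
        rows.append(row)
    return pd.DataFrame(rows)


def measure_spike(v: np.ndarray, dt: float, ap: APDetection, sto_peak: float,
                  t0: float = 0.0, prominence: float = SPIKELET_PROMINENCE,
                  result=None, cell: int | None = None) -> SpikeMetrics:
    """Full per-AP measurement bundle: spikelets + ADP + AHP + phase +
    pre-spike STO amplitude (+ dendrosomatic charge when ``result`` given).

    Phase/amplitude fields are NaN when the preceding oscillation is
    insufficient for the estimators (their stated refusal condition).
    """
    m = count_spikelets(v, dt, ap, sto_peak, prominence=prominence, t0=t0)
    if m.adp_complete:
        dur, complete = measure_ahp(v, dt, ap, m.adp_window[1], t0=t0)
        m.ahp_duration, m.ahp_complete = dur, complete
    else:
        m.ahp_complete = False
    try:
        pe = estimate_phase(v, dt, ap.peak_time, onset_time=ap.onset_time, t0=t0)
        m.sto_phase_at_spike = pe.phase
    except InsufficientOscillation:
        pass
    try:
        m.sto_amplitude_pre_spike = estimate_sto_amplitude(
            v, dt, ap.peak_time, onset_time=ap.onset_time, t0=t0)
    except InsufficientOscillation:
        pass
    if result is not None and cell is not None and m.adp_complete:
        m.dendrosomatic_charge = dendrosomatic_charge(result, cell, m.adp_window)
    return m
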