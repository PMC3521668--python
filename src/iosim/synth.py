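"""Synthetic voltage-trace fixtures with exact, constructed ground truth.

The generator builds an STO-like sinusoid with stereotyped AP templates
(sodium spike, decaying ADP plateau carrying Gaussian spikelet bumps,
piecewise-linear AHP) inserted at requested phases.  Every inserted AP's
true metrics — spikelet count/times, ADP duration, AHP duration, phase,
STO amplitude — are computed analytically from the construction and returned
alongside the trace, so the measurement operators can be validated against
known answers (including under additive noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SyntheticTraceSpec", "generate_fixture"]


@dataclass
class SyntheticTraceSpec:
    sto_freq_hz: float = 7.0
    sto_amp_mv: float = 5.0
    baseline_mv: float = -57.0
    dt: float = 0.05  # ms
    noise_sd_mv: float = 0.0
    insertion_phases: tuple[float, ...] = (0.5 * math.pi,)
    # AP template
    na_rise_ms: float = 1.0
    na_fall_ms: float = 1.0
    na_height_mv: float = 60.0  # above the onset level
    adp_above_sto_peak_mv: float = 18.0  # plateau start level above the STO peak
    adp_plateau_ms: float = 12.0
    adp_plateau_decay_mv: float = 1.5  # linear droop across the plateau
    spikelet_count: int = 2
    spikelet_prominence_mv: float = 2.0
    spikelet_spacing_ms: float = 2.5
    spikelet_sigma_ms: float = 0.35
    adp_fall_ms: float = 4.0
    ahp_depth_mv: float = 8.0  # floor below the onset level
    ahp_hold_ms: float = 100.0
    ahp_rise_ms: float = 60.0
    blend_ms: float = 30.0

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.sto_freq_hz

    def template_length_ms(self) -> float:
        return (self.na_rise_ms + self.na_fall_ms + self.adp_plateau_ms +
                self.adp_fall_ms + self.ahp_hold_ms + self.ahp_rise_ms + self.blend_ms)


def _template(spec: SyntheticTraceSpec, v_onset: float, sto_peak: float):
    """Piecewise template V(τ) for τ ≥ 0 from the onset, plus ground truth.

    Returns (tau_grid_fn, truth) where truth holds the analytic landmark
    times relative to the onset.
    """
    r, f = spec.na_rise_ms, spec.na_fall_ms
    v_peak = v_onset + spec.na_height_mv
    p0 = sto_peak + spec.adp_above_sto_peak_mv  # plateau start level
    p1 = p0 - spec.adp_plateau_decay_mv  # plateau end level
    t_plat0 = r + f
    t_plat1 = t_plat0 + spec.adp_plateau_ms
    ahp_floor = v_onset - spec.ahp_depth_mv
    t_floor = t_plat1 + spec.adp_fall_ms
    t_rise0 = t_floor + spec.ahp_hold_ms
    t_rise1 = t_rise0 + spec.ahp_rise_ms
    v_rise_end = v_onset + 1.0  # overshoot so the pre-AP level is crossed

    # spikelet bump centers, kept inside the plateau with a margin (the ADP
    # measurement window opens 2 ms after the Na peak = 1 ms into the plateau)
    centers = [t_plat0 + 1.6 + i * spec.spikelet_spacing_ms
               for i in range(spec.spikelet_count)]
    if centers and centers[-1] > t_plat1 - 1.0:
        raise ValueError("spikelet bumps do not fit in the ADP plateau")

    def base(tau: np.ndarray) -> np.ndarray:
        v = np.empty_like(tau)
        seg1 = tau < r
        v[seg1] = v_onset + (v_peak - v_onset) * tau[seg1] / r
        seg2 = (tau >= r) & (tau < t_plat0)
        v[seg2] = v_peak + (p0 - v_peak) * (tau[seg2] - r) / f
        seg3 = (tau >= t_plat0) & (tau < t_plat1)
        v[seg3] = p0 + (p1 - p0) * (tau[seg3] - t_plat0) / spec.adp_plateau_ms
        seg4 = (tau >= t_plat1) & (tau < t_floor)
        v[seg4] = p1 + (ahp_floor - p1) * (tau[seg4] - t_plat1) / spec.adp_fall_ms
        seg5 = (tau >= t_floor) & (tau < t_rise0)
        v[seg5] = ahp_floor
        seg6 = (tau >= t_rise0) & (tau < t_rise1)
        v[seg6] = ahp_floor + (v_rise_end - ahp_floor) * (tau[seg6] - t_rise0) / spec.ahp_rise_ms
        v[tau >= t_rise1] = v_rise_end
        return v

    def full(tau: np.ndarray) -> np.ndarray:
        v = base(tau)
        for c in centers:
            v = v + spec.spikelet_prominence_mv * np.exp(
                -0.5 * ((tau - c) / spec.spikelet_sigma_ms) ** 2)
        return v

    # analytic landmarks
    # ADP end: where the fall segment crosses the STO-peak level
    frac = (p1 - sto_peak) / (p1 - ahp_floor)
    t_adp_end = t_plat1 + frac * spec.adp_fall_ms
    # AHP recovery: where the rise segment crosses the pre-AP (onset) level
    frac_up = (v_onset - ahp_floor) / (v_rise_end - ahp_floor)
    t_recover = t_rise0 + frac_up * spec.ahp_rise_ms
    truth = {
        "na_peak": r,
        "adp_end": t_adp_end,
        "adp_duration": t_adp_end - (r + 2.0),  # ADP window starts 2 ms post-peak
        "ahp_duration": t_recover - t_adp_end,
        "spikelet_count": spec.spikelet_count,
        "spikelet_times": centers,
        "template_end": t_rise1,
    }
    return full, truth


def generate_fixture(spec: SyntheticTraceSpec, seed: int = 0,
                     duration_ms: float | None = None):
    """Build the trace.  Returns (t, v, ground_truth_list).

    Each ground-truth entry holds absolute times (ms) plus the construction's
    exact metric values for the corresponding inserted AP.
    """
    P = spec.period_ms
    tmpl_len = spec.template_length_ms()
    min_gap = tmpl_len + 2.4 * P
    lead = 2.6 * P

    # place insertions: requested phase, each at least min_gap after the last
    onsets = []
    truths = []
    t_min = lead
    omega = 2 * math.pi * spec.sto_freq_hz / 1000.0  # rad per ms
    phases = []
    for phi in spec.insertion_phases:
        # spike (na peak) at phase phi: onset precedes the peak by na_rise
        k = math.ceil((t_min + spec.na_rise_ms) * omega / (2 * math.pi))
        while True:
            t_peak = (phi % (2 * math.pi) + 2 * math.pi * k) / omega
            if t_peak - spec.na_rise_ms >= t_min:
                break
            k += 1
        # snap the onset to the sample grid so the template starts exactly on
        # a sample; the true phase is recomputed from the snapped peak time
        onset = round((t_peak - spec.na_rise_ms) / spec.dt) * spec.dt
        onsets.append(onset)
        phases.append((omega * (onset + spec.na_rise_ms)) % (2 * math.pi))
        t_min = onset + min_gap

    if duration_ms is None:
        duration_ms = (onsets[-1] if onsets else lead) + tmpl_len + 2.0 * P
    n = int(round(duration_ms / spec.dt)) + 1
    t = np.arange(n) * spec.dt
    v = spec.baseline_mv + spec.sto_amp_mv * np.sin(omega * t)
    sto_peak = spec.baseline_mv + spec.sto_amp_mv

    for onset, phi in zip(onsets, phases):
        v_onset = spec.baseline_mv + spec.sto_amp_mv * math.sin(omega * onset)
        tmpl, tr = _template(spec, v_onset, sto_peak)
        i0 = int(round(onset / spec.dt))
        i1 = min(n, i0 + int(round(tmpl_len / spec.dt)))
        tau = t[i0:i1] - onset
        vt = tmpl(tau)
        # blend the template tail back onto the sinusoid after the AHP rise
        w = np.clip((tau - tr["template_end"]) / spec.blend_ms, 0, 1)
        v[i0:i1] = (1 - w) * vt + w * v[i0:i1]
        truths.append({
            "onset_time": onset,
            "spike_time": onset + tr["na_peak"],
            "phase": phi % (2 * math.pi),
            "spikelet_count": tr["spikelet_count"],
            "spikelet_times": [onset + c for c in tr["spikelet_times"]],
            "adp_end_time": onset + tr["adp_end"],
            "adp_duration": tr["adp_duration"],
            "ahp_duration": tr["ahp_duration"],
            "sto_amplitude": spec.sto_amp_mv,
            "sto_peak_level": sto_peak,
            "onset_level": v_onset,
        })

    if spec.noise_sd_mv > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, spec.noise_sd_mv, size=n)
    return t, v, truths
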