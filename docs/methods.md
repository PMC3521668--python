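# Methods

## Model

Each inferior-olive (IO) cell is a three-compartment conductance-based model:
dendrite, soma, axon hillock. The membrane equation of a compartment is

    C_m dV/dt = −( Σ I_ion + I_leak + Σ I_internal + I_gap ) + I_inj

with C_m = 1 µF/cm², all currents outward-positive and injected currents
positive-depolarizing. Ionic currents are I = g_max · (gating product) ·
(V − E); every gating variable obeys dx/dt = (x∞(V) − x)/τ(V). The complete
coefficient table (one row per gate: Boltzmann parameters or α/β rate forms,
time-constant forms) is in `iosim.channels.GATE_TABLE`; the conductance
inventory with reversal potentials and exponents is `CHANNEL_TABLE`.

The parameterization follows the established two-compartment IO cell model
lineage this three-compartment model descends from, with the axon hillock
added (fast Na⁺, fast K⁺, leak) and the somatic Na⁺/K⁺ currents in their
reworked form. Channel inventory:

* dendrite — high-threshold (P/Q-type) Ca²⁺ `r²` (g = 4.5 mS/cm²),
  Ca²⁺-dependent K⁺ `s` (35), h-current `q` (0.125), leak (0.016);
* soma — low-threshold (T-type) Ca²⁺ `k³l` (g_CaL, default 0.7, the per-cell
  heterogeneity parameter), fast Na⁺ `m∞³h` (150, activation instantaneous),
  delayed-rectifier K⁺ `n⁴` (9), slow K⁺ `x_s⁴` (5), leak (0.016);
* axon hillock — fast Na⁺ `m∞³h` (240), fast K⁺ `x⁴` (20), leak (0.016).

Reversals: E_Na 55, E_K −75, E_Ca 120, E_h −43, E_leak 10 mV. Dendritic
calcium follows d[Ca]/dt = −3·I_CaH − 0.075·[Ca] in the source model's
dimensionless concentration units (kept deliberately: matching the source
exactly outweighs unit purity). Internal coupling is ohmic with
g_int = 0.13 mS/cm² seen through complementary area fractions
(soma:dendrite 0.25, axon:soma 0.15), which makes the two sides of each
junction charge-conserving. The transcription was validated against the
published cell behavior before any other work: at g_CaL = 0.7 the model
produces a 7.6 Hz somatic STO of amplitude 6.41 mV against the published
6–8 Hz / 6.4 mV, with no tuning.

Gap junctions connect dendrites of Chebyshev-distance-1 grid neighbors
(up to eight, no wraparound) with

    I_gap = g_gap · f(ΔV) · ΔV,   f(ΔV) = 0.8·e^(−ΔV²/100) + 0.2

and g_gap = 0.04 mS/cm² as the maximal conductance. A purely ohmic variant
(f ≡ 1) is available (`gap_voltage_dependent=False`, recorded in run
metadata); in our synchronization experiments the two variants behave almost
identically, so the lineage's voltage-dependent form is the default.

### Stimulus-current conversion

Experiment protocols state injected currents in pA; the model equations use
densities. The conversion constant `DENDRITE_AREA_CM2 = 1.05e-6 cm²`
(105 µm²) is a named, auditable parameter. It was calibrated once against
the published firing behavior — a 20 ms dendritic pulse threshold of
~4–5 µA/cm², a firing window of roughly half the STO cycle at 5.5 pA
(ours: ≈1.6π–0.6π against the published ≈1.6π–0.5π), and an ensemble AP
yield near two-thirds at 6 pA — and then frozen. All pulse amplitudes used
by the campaigns (5.5 / 6 / 5 pA, 20 ms) go through this single constant.

### Numerics

Fixed-step classical Runge–Kutta (RK4), dt = 0.025 ms, in a numba-compiled
kernel; voltages recorded every second step (0.05 ms). The kernel is pinned
to a readable pure-Python reference (`iosim.cell.cell_derivative`, composed
from `iosim.channels`) to ≤ 1e-12 on random states. Halving dt changes the
final somatic voltage of a 2 s run by ~3e-11 mV; the passive (channels-off)
system matches the matrix-exponential solution to < 1e-5 relative. Stimulus
onsets are quantized to the dt grid (ties toward the earlier sample).
Integration aborts with a diagnostic if any |V| exceeds 150 mV or becomes
non-finite. Runs are bit-exactly reproducible from their configuration; the
removable singularities of the linexp rate forms are filled at |x| < 1e-9.

Initial conditions: all compartments at −60 mV (or the leak reversal for
passive tests), gates at steady state, calcium at its fixed point; every
measurement is preceded by a ≥ 1000 ms settle period (campaigns use
1500 ms). Random-phase network initialization integrates each cell in
isolation for the settle period plus an independently drawn extra time
uniform in [0, that cell's intrinsic period), then couples; cells below the
oscillation onset get no extra time. Campaign randomness derives from one
root seed through `numpy.random.SeedSequence.spawn`, so trials are
order-independent and parallelizable without changing results.

## Measurement conventions

* **AP detection** — somatic peaks above −20 mV with ≥ 20 mV prominence,
  20 ms refractory merging. **Onset**: maximal second time-derivative on the
  oscillation before the departure from the sinusoid, operationalized as the
  samples before dV/dt first exceeds 1.5 mV/ms (the STO's own slope stays
  below ~0.5 mV/ms; the pulse-driven ramp and Na⁺ upstroke are far above).
* **Primary Na⁺ spike end** (ADP window start): first sample after the Na⁺
  peak where V falls below the preceding STO-peak level or dV/dt relaxes
  back above −0.5 mV/ms, whichever is later, capped at 2 ms post-peak.
* **Spikelets** — local maxima over the ADP span (window start to the return
  to the STO-peak level), prominence floor 0.3 mV (configurable). The
  segment is smoothed (Gaussian, 0.2 ms) and the floor is raised to 5× the
  robust noise estimate from second differences when measurement noise is
  present, so counts are stable on noisy recordings while noise-free model
  output keeps the plain floor. The left context (Na⁺ downstroke) is
  included in the prominence computation so a spikelet near the window edge
  is not clipped. Sensitivity: on model traces the counts are unchanged for
  floors between 0.2 and 0.8 mV (model spikelets are ≥ ~1 mV).
* **ADP amplitude** — median voltage over the ADP window minus the onset
  level: the height of the calcium plateau above the takeoff point,
  insensitive to the spikelet tops riding on it.
* **ADP duration** — window start to the return to the preceding STO-peak
  level. **AHP duration** — from ADP end until the voltage, after dipping
  below the pre-AP (onset) level, first recovers to it; flagged incomplete
  if the trace ends first.
* **STO phase** — A·sin(2πft+φ)+c least-squares fit over exactly the two
  periods preceding the AP onset, initialized from polynomial-refined
  extremum locations; the two-maxima and two-minima anchorings are both
  fitted and the lower-RMSE fit kept. Phase convention A·sin(θ), peak ↔
  0.5π, reported at the Na⁺-peak time in [0, 2π). Requires two peaks and
  two troughs before the spike; otherwise the estimator refuses (raises)
  rather than guessing. Bias < 0.02π on noiseless sines; mean error < 0.05π
  at SNR 10.
* **STO amplitude** — half peak-to-trough over the one period preceding the
  AP onset. Campaign tables additionally record the amplitude over the
  period preceding the *stimulus*, which is the right quantity for
  amplitude-stratified analyses because the pre-AP window of an evoked
  spike contains the pulse-driven ramp.
* **Dendrosomatic charge** — time integral of (g_int/p_soma)(V_s − V_d)
  over the ADP window, in µC/cm², positive soma→dendrite.
* **Synchrony** — mean pairwise phase difference across cells by
  cross-correlation lag over the two periods preceding the evaluation time,
  mapped to the ratio 1 − Δφ/180°; alongside it the amplitude-proxy ratio
  (mean STO amplitude relative to the maximum attained mean amplitude),
  which is the approximation the reference analysis used. Amplitude over
  time is a sliding one-period (max−min)/2, stamped at the window center;
  the settling-time detector (across-cell coefficient of variation of
  per-cell mean inter-peak intervals < 1%, sustained to the end of the run,
  500 ms windows) uses the same center-stamping convention.

## Experiment campaigns and the sizes used here

* **Phase dependency** — homogeneous 3×3 grid, 100 pulses (20 ms, 5.5 pA)
  with onsets advancing 2 ms per trial, under intrinsic or imposed-5 Hz STO
  × full-network or center-cell-only stimulation. The imposed STO is a
  calibrated somatic sinusoidal current (current clamp, not voltage clamp)
  whose resulting membrane max/min match the intrinsic STO's within 0.2 mV;
  only the recorded (center) cell receives it by default. 
* **T-type sweep** — the same single-cell-stimulation protocol at several
  g_CaL values; reproduces one spikelet per AP at 0.55 mS/cm², 0–3 at 0.7,
  ≥4 at 0.9.
* **Ensemble synchrony** — per trial a fresh heterogeneous network (g_CaL
  i.i.d. uniform on [0.55, 0.9], mean-corrected to 0.7 ± 0.01), random-phase
  initialization, one 20 ms pulse (6 pA; 5 pA on 1×3) to the center cell at
  an onset uniform in [200, 900] ms; a trial counts as a full AP if a
  somatic spike occurs within 50 ms of pulse onset. The original campaign
  size is 700 trials per grid; the test suite and acceptance script run 200
  (3×3), which puts a binomial standard error of ~3.3 points on the yield.
* **Synchronization** — unstimulated heterogeneous networks from random
  phases; 50 seeds (3×3) / 20 seeds (5×5) here against 250 in the original.

## What the synthetic fixtures do and do not show

`iosim.synth` builds sinusoids with piecewise-analytic AP templates whose
landmark times (spikelet centers, ADP end, AHP recovery) are computed in
closed form, so every measurement operator is validated against exact
ground truth, including under additive Gaussian noise. The fixtures emulate
the *geometry* of olivary traces (STO, fast spike, decaying plateau with
bumps, long AHP), not their biophysics: passing fixture tests certifies the
measurement definitions, not the model; the model itself is checked against
the published electrophysiology by the acceptance suite. Real recordings
additionally contain drift, non-sinusoidal STO shapes and non-stationary
noise that the fixtures do not model.

## Known limitations

* The rate equations come from the model lineage rather than from this
  model's own supplementary description (unavailable here). The intrinsic
  STO (frequency, amplitude, g_CaL dependence), spike shape bands, firing
  window and spikelet statistics reproduce the published values closely,
  but two network-level statistics deviate: the mean time for 3×3 networks
  to recover 5.5 mV mean STO amplitude is ~310–360 ms here against the
  published 241 ± 11 ms, and the mean spikelet count does not fall with
  pre-stimulus STO amplitude over the sampled 4–7 mV range (weakly positive
  instead), because non-synchronized cells here fire ~1.2-spikelet APs
  where ~2 were reported. Both are documented in the acceptance suite as
  failing expectations rather than hidden.
* Isolated cells at g_CaL = 0.55 mS/cm² sit just below the oscillation
  onset (damped fixed point); they oscillate visibly only when coupled to
  higher-conductance neighbors, consistent with the amplitude-normalizing
  role of gap junctions.
* No temperature scaling, stochastic gating, synaptic receptors, or
  morphologically detailed dendrites; clusters up to 5×5 only.
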