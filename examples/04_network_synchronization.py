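"""Synchronization of a heterogeneous coupled cluster.

Builds a 3×3 network with per-cell T-type conductances drawn from
[0.55, 0.9] mS/cm² (mean 0.7), starts every cell on its own limit cycle at
a random phase, couples them at t = 0 and tracks the ensemble: gap-junction
loading initially suppresses the STO amplitude; as the cells pull each other
into phase the mean amplitude recovers.  Prints the settling time (common
STO period across cells), the time the mean amplitude first exceeds 5.5 mV,
and the synchrony ratio at that moment (1 = in phase, 0 = counterphase).
"""

from iosim.analysis import synchrony_metrics
from iosim.network import build_grid
from iosim.protocols import settling_time
from iosim.simulate import integrate, random_phase_states

net = build_grid(3, 3, heterogeneous=True, seed=42)
print("per-cell g_CaL:", [f"{g:.2f}" for g in net.g_cal])

y0 = random_phase_states(net, rng=42)
res = integrate(net, duration=1500.0, y0=y0)

t_settle = settling_time(res)
sm = synchrony_metrics(res, t=res.t[-1])
print(f"settling time (common period): {t_settle:.0f} ms")
if sm.time_to_amplitude_threshold is not None:
    at_cross = synchrony_metrics(res, t=sm.time_to_amplitude_threshold)
    print(f"mean amplitude crosses 5.5 mV at {sm.time_to_amplitude_threshold:.0f} ms")
    print(f"synchrony ratio at crossing  : "
          f"{at_cross.synchrony_ratio_amplitude_proxy:.2f} (amplitude proxy), "
          f"{at_cross.synchrony_ratio:.2f} (cross-correlation)")
print(f"final mean STO amplitude      : {sm.mean_sto_amplitude:.2f} mV")
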