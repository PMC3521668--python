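"""Gating kinetics and ionic current densities for the three-compartment IO cell.

Every gate is one row in :data:`GATE_TABLE`; every conductance is one row in
:data:`CHANNEL_TABLE`.  The rows hold named coefficients only — the functional
forms are implemented once, in :func:`gate_steady_state` and
:func:`gate_time_constant` — so an independent re-evaluation of the closed
forms can be compared against this module coefficient by coefficient.

Units: voltage mV, time ms, conductance mS/cm², current density µA/cm².
Sign convention: positive membrane current = outward; injected stimulus
currents are positive-depolarizing.

Calcium is tracked in the source model's dimensionless concentration units,
not molar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

__all__ = [
    "Gate",
    "ChannelKinetics",
    "CalciumPool",
    "GATE_TABLE",
    "CHANNEL_TABLE",
    "REVERSAL",
    "gate_steady_state",
    "gate_time_constant",
    "gate_derivative",
    "current_density",
    "gate_table_dict",
    "channel_table_dict",
]

# Reversal potentials (mV), shared across compartments.
REVERSAL = {
    "na": 55.0,
    "k": -75.0,
    "ca": 120.0,
    "h": -43.0,
    "leak": 10.0,
}


@dataclass(frozen=True)
class Gate:
    """One gating variable: steady-state and time-constant coefficient row.

    ``ss_form`` / ``tau_form`` select the closed form; ``ss`` / ``tau`` hold
    its named coefficients.  ``tau_form="instant"`` marks a gate that is
    evaluated at steady state (no ODE).  ``ss_form="ca_linear"`` marks the
    calcium-gated activation of the Ca-dependent K current, whose forward
    rate depends on [Ca²⁺] instead of voltage.
    """

    name: str
    ss_form: str
    ss: Mapping[str, float]
    tau_form: str
    tau: Mapping[str, float] = field(default_factory=dict)

    def steady_state(self, v: float, ca: float | None = None) -> float:
        return gate_steady_state(self.name, v, ca)

    def time_constant(self, v: float, ca: float | None = None) -> float:
        return gate_time_constant(self.name, v, ca)


def _linexp(a: float, c: float, d: float, v: float) -> float:
    """a·(v−c)/(1−exp(−(v−c)/d)), with the removable singularity at v=c filled."""
    x = v - c
    if abs(x) < 1e-9:
        return a * d
    return a * x / (1.0 - math.exp(-x / d))


def _linexp_neg(a: float, c: float, d: float, v: float) -> float:
    """a·(v−c)/(exp((v−c)/d)−1), singularity at v=c filled (β_r form)."""
    x = v - c
    if abs(x) < 1e-9:
        return a * d
    return a * x / (math.exp(x / d) - 1.0)


def _rates(name: str, v: float, ca: float | None) -> tuple[float, float]:
    """Forward/backward rates (1/ms) for alpha-beta gates."""
    g = GATE_TABLE[name]
    p = g.ss
    if g.ss_form == "ab_sigmoid_linexp":  # r: CaH activation
        alpha = p["a_a"] / (1.0 + math.exp(-(v - p["a_c"]) / p["a_d"]))
        beta = _linexp_neg(p["b_a"], p["b_c"], p["b_d"], v)
    elif g.ss_form == "ab_linexp_exp":  # x_s / x_a: K activation
        alpha = _linexp(p["a_a"], p["a_c"], p["a_d"], v)
        beta = p["b_a"] * math.exp(-p["b_k"] * (v - p["b_c"]))
    elif g.ss_form == "ca_linear":  # s: KCa activation
        if ca is None:
            raise ValueError(f"gate {name!r} requires a calcium concentration")
        alpha = min(p["a_per_ca"] * ca, p["a_cap"])
        beta = p["b"]
    else:  # pragma: no cover - guarded by dispatch in callers
        raise KeyError(f"gate {name!r} has no alpha/beta form")
    return alpha, beta


def gate_steady_state(gate_id: str, v: float, ca: float | None = None) -> float:
    """Steady-state value of a gating variable at membrane potential ``v`` (mV).

    For the calcium-gated ``s`` the steady state depends on ``ca`` instead.
    Always in [0, 1].
    """
    try:
        g = GATE_TABLE[gate_id]
    except KeyError:
        raise KeyError(f"unknown gate id {gate_id!r}; known: {sorted(GATE_TABLE)}") from None
    if g.ss_form == "boltzmann":
        # k > 0: activation (rises with v); k < 0: inactivation.
        # exponent clipped so extreme clamp voltages saturate instead of overflow
        z = min(max((g.ss["v_half"] - v) / g.ss["k"], -700.0), 700.0)
        return 1.0 / (1.0 + math.exp(z))
    alpha, beta = _rates(gate_id, v, ca)
    return alpha / (alpha + beta)


def gate_time_constant(gate_id: str, v: float, ca: float | None = None) -> float:
    """Relaxation time constant (ms) of a gating variable; strictly positive."""
    try:
        g = GATE_TABLE[gate_id]
    except KeyError:
        raise KeyError(f"unknown gate id {gate_id!r}; known: {sorted(GATE_TABLE)}") from None
    p = g.tau
    if g.tau_form == "const":
        return p["tau"]
    if g.tau_form == "instant":
        raise ValueError(f"gate {gate_id!r} is instantaneous (no time constant)")
    if g.tau_form == "exp":
        # a·exp(−(v−c)/d)
        return p["a"] * math.exp(-(v - p["c"]) / p["d"])
    if g.tau_form == "exp_offset":
        # o + a·exp((v−c)/d)
        return p["o"] + p["a"] * math.exp((v - p["c"]) / p["d"])
    if g.tau_form == "peaked_exp":
        # o + a·exp((v−c1)/d1) / (1 + exp((v−c2)/d2))
        return p["o"] + p["a"] * math.exp((v - p["c1"]) / p["d1"]) / (
            1.0 + math.exp((v - p["c2"]) / p["d2"])
        )
    if g.tau_form == "recip_two_exp":
        # 1 / (exp(a1·v+b1) + exp(a2·v+b2))
        return 1.0 / (math.exp(p["a1"] * v + p["b1"]) + math.exp(p["a2"] * v + p["b2"]))
    if g.tau_form == "recip_rates":
        alpha, beta = _rates(gate_id, v, ca)
        return p.get("scale", 1.0) / (alpha + beta)
    raise KeyError(f"gate {gate_id!r}: unknown tau form {g.tau_form!r}")


def gate_derivative(gate_id: str, gate_value: float, v: float, ca: float | None = None) -> float:
    """First-order relaxation dx/dt = (x_inf(v) − x)/τ(v), in 1/ms."""
    x_inf = gate_steady_state(gate_id, v, ca)
    tau = gate_time_constant(gate_id, v, ca)
    return (x_inf - gate_value) / tau


# --- gate table -----------------------------------------------------------
# One row per gating variable.  Somatic: k,l (T-type Ca), m,h (Na), n (fast K),
# x_s (slow K).  Dendritic: r (P/Q-type Ca), s (Ca-dependent K), q (h-current).
# Axonal: m_a,h_a (Na), x_a (K).

GATE_TABLE: dict[str, Gate] = {
    "k": Gate("k", "boltzmann", {"v_half": -61.0, "k": 4.2}, "const", {"tau": 1.0}),
    "l": Gate(
        "l",
        "boltzmann",
        {"v_half": -85.5, "k": -8.5},
        "peaked_exp",
        {"o": 35.0, "a": 20.0, "c1": -160.0, "d1": 30.0, "c2": -84.0, "d2": 7.3},
    ),
    "m": Gate("m", "boltzmann", {"v_half": -30.0, "k": 5.5}, "instant"),
    "h": Gate(
        "h", "boltzmann", {"v_half": -70.0, "k": -5.8}, "exp", {"a": 3.0, "c": -40.0, "d": 33.0}
    ),
    "n": Gate(
        "n",
        "boltzmann",
        {"v_half": -3.0, "k": 10.0},
        "exp_offset",
        {"o": 5.0, "a": 47.0, "c": -50.0, "d": 900.0},
    ),
    "x_s": Gate(
        "x_s",
        "ab_linexp_exp",
        {"a_a": 0.13, "a_c": -25.0, "a_d": 10.0, "b_a": 1.69, "b_k": 0.0125, "b_c": -35.0},
        "recip_rates",
    ),
    "r": Gate(
        "r",
        "ab_sigmoid_linexp",
        {"a_a": 1.7, "a_c": 5.0, "a_d": 13.9, "b_a": 0.02, "b_c": -8.5, "b_d": 5.0},
        "recip_rates",
        {"scale": 5.0},
    ),
    "s": Gate(
        "s", "ca_linear", {"a_per_ca": 2.0e-5, "a_cap": 0.01, "b": 0.015}, "recip_rates"
    ),
    "q": Gate(
        "q",
        "boltzmann",
        {"v_half": -80.0, "k": -4.0},
        "recip_two_exp",
        {"a1": -0.086, "b1": -14.6, "a2": 0.070, "b2": -1.87},
    ),
    "m_a": Gate("m_a", "boltzmann", {"v_half": -30.0, "k": 5.5}, "instant"),
    "h_a": Gate(
        "h_a", "boltzmann", {"v_half": -60.0, "k": -5.8}, "exp", {"a": 1.5, "c": -40.0, "d": 33.0}
    ),
    "x_a": Gate(
        "x_a",
        "ab_linexp_exp",
        {"a_a": 0.13, "a_c": -25.0, "a_d": 10.0, "b_a": 1.69, "b_k": 0.0125, "b_c": -35.0},
        "recip_rates",
    ),
}


@dataclass(frozen=True)
class ChannelKinetics:
    """One ionic conductance: gating product, reversal, maximal conductance."""

    name: str
    compartment: str  # "dend" | "soma" | "axon"
    gates: tuple[tuple[str, int], ...]  # (gate_id, exponent); instantaneous gates allowed
    reversal_potential: float  # mV
    max_conductance: float  # mS/cm² (default; g_CaL is overridden per cell)
    needs_calcium: bool = False


CHANNEL_TABLE: dict[str, ChannelKinetics] = {
    # Dendrite: high-threshold (P/Q-type) Ca, Ca-dependent K, h-current.
    "CaH": ChannelKinetics("CaH", "dend", (("r", 2),), REVERSAL["ca"], 4.5),
    "KCa": ChannelKinetics("KCa", "dend", (("s", 1),), REVERSAL["k"], 35.0, needs_calcium=True),
    "h": ChannelKinetics("h", "dend", (("q", 1),), REVERSAL["h"], 0.125),
    # Soma: low-threshold (T-type) Ca, fast Na, delayed-rectifier + slow K.
    "CaL": ChannelKinetics("CaL", "soma", (("k", 3), ("l", 1)), REVERSAL["ca"], 0.7),
    "Na_s": ChannelKinetics("Na_s", "soma", (("m", 3), ("h", 1)), REVERSAL["na"], 150.0),
    "Kdr_s": ChannelKinetics("Kdr_s", "soma", (("n", 4),), REVERSAL["k"], 9.0),
    "K_s": ChannelKinetics("K_s", "soma", (("x_s", 4),), REVERSAL["k"], 5.0),
    # Axon hillock: fast Na, fast K.
    "Na_a": ChannelKinetics("Na_a", "axon", (("m_a", 3), ("h_a", 1)), REVERSAL["na"], 240.0),
    "K_a": ChannelKinetics("K_a", "axon", (("x_a", 4),), REVERSAL["k"], 20.0),
}


@dataclass
class CalciumPool:
    """Dendritic calcium pool (dimensionless concentration units).

    d[Ca]/dt = −influx_coeff · I_CaH − decay_rate · [Ca]; inward I_CaH is
    negative under the outward-positive convention, so Ca influx raises the
    concentration.
    """

    concentration: float = 3.7152
    influx_coeff: float = 3.0  # per (µA/cm²) of I_CaH
    decay_rate: float = 0.075  # 1/ms

    def derivative(self, i_cah: float) -> float:
        return -self.influx_coeff * i_cah - self.decay_rate * self.concentration


def current_density(
    channel: ChannelKinetics,
    gate_values: Mapping[str, float],
    v: float,
    calcium: float | None = None,
    g_max: float | None = None,
) -> float:
    """Ionic current density (µA/cm², positive = outward).

    Instantaneous gates (``m``, ``m_a``) are evaluated at steady state if not
    supplied in ``gate_values``.  ``g_max`` overrides the table default (used
    for the per-cell heterogeneous g_CaL).
    """
    if channel.needs_calcium and calcium is None:
        raise ValueError(f"channel {channel.name!r} requires a calcium concentration")
    g = channel.max_conductance if g_max is None else g_max
    prod = 1.0
    for gate_id, expo in channel.gates:
        if gate_id in gate_values:
            x = gate_values[gate_id]
        elif GATE_TABLE[gate_id].tau_form == "instant":
            x = gate_steady_state(gate_id, v, calcium)
        else:
            raise KeyError(f"missing value for gate {gate_id!r} of channel {channel.name!r}")
        prod *= x**expo
    return g * prod * (v - channel.reversal_potential)


def gate_table_dict() -> dict:
    """Gate table as plain nested dicts (for config serialization)."""
    return {name: asdict(g) for name, g in GATE_TABLE.items()}


def channel_table_dict() -> dict:
    out = {}
    for name, c in CHANNEL_TABLE.items():
        d = asdict(c)
        d["gates"] = [list(g) for g in c.gates]  # YAML-friendly
        out[name] = d
    return out
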