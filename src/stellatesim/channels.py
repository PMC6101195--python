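"""Gating kinetics and current laws for the nine active conductances.

Unit contract throughout: voltage in mV, time in ms, concentrations in mM,
conductances in mS/cm2, current densities in uA/cm2 (so that g * (V - E)
needs no extra conversion, and dV/dt = I/C_m is in mV/ms for C_m in uF/cm2).

Eight channels (NaF, KDR, HCN fast/slow, NaP, KA, HVA, LVA, KM) use
Hodgkin-Huxley gating particles with first-order kinetics
``dm/dt = (m_inf - m)/tau_m``. Sodium, potassium and HCN currents are Ohmic;
the two calcium currents use the Goldman-Hodgkin-Katz driving force. The SK
channel is a six-state Markov scheme gated by cytosolic calcium, and the
calcium pool itself decays first-order toward its 100-nM resting level.

Rate functions of the form x/(1 - exp(-x)) have removable singularities that
are evaluated by their analytic limit (see :func:`xexprel`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

FARADAY = 96485.332  # C/mol
CELSIUS = 34.0
TEMPERATURE_K = CELSIUS + 273.15  # 307.15 K

E_NA = 50.0   # mV
E_K = -90.0   # mV
E_H = -20.0   # mV
E_LEAK = -77.0  # mV; passive rest with all active conductances removed

CA_OUT = 2.0       # mM extracellular calcium
CA_REST = 1e-4     # mM (100 nM) resting/steady-state cytosolic calcium
CA_SHELL_DEPTH = 0.1  # um, depth of the cytosolic calcium shell

# Thermal voltage RT/F at 34 C in mV, using the 25 mV @ 20 C convention of
# compartmental simulators (the lineage of these channel models); halved for
# a divalent ion. The GHK zero-current potential is GHK_VSLOPE * ln(co/ci).
KTF_MV = 25.0 * TEMPERATURE_K / 293.15
GHK_VSLOPE = KTF_MV / 2.0

# SK six-state scheme rates on the model's ms time base. The calcium binding
# rate constant is 10 per uM per s = 0.01 per uM per ms and multiplies [Ca].
SK_ALPHA = 0.01   # /uM/ms
SK_BETA = 5e-4    # /ms
SK_GAMMA = 0.6    # /ms
SK_DELTA = 0.4    # /ms

# Hooks for temperature scaling of gate kinetics; the model equations are
# already stated at 34 C, so these default to 1 and are not exposed on the
# parameter table.
Q10_TAU_SCALE = 1.0


def xexprel(x):
    """x / (1 - exp(-x)) with its analytic limit 1 at x = 0.

    Both rate-function shapes in the model reduce to this helper:
    a*x/(1-exp(-x)) directly, and a*x/(exp(x)-1) as ``a*xexprel(-x)``.
    """
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-9
    safe = np.where(small, 1.0, x)
    return np.where(small, 1.0 + x / 2.0, safe / (-np.expm1(-safe)))


def _sigmoid(x):
    # guarded logistic; x may reach +/- 1e3 at table edges
    return 1.0 / (1.0 + np.exp(np.clip(x, -500.0, 500.0)))


# ---------------------------------------------------------------------------
# steady states and time constants, one pair of functions per gate
# ---------------------------------------------------------------------------

def naf_m_inf(v, vhalf=-26.1, k=9.38):
    return _sigmoid((vhalf - v) / k)


def naf_m_tau(v, f=1.0):
    alpha = 4.0 * xexprel((v + 33.0) / 9.0)
    beta = 27.6 * xexprel(-(v + 58.0) / 12.0)
    return f * Q10_TAU_SCALE / (alpha + beta)


def naf_h_inf(v, vhalf=-23.8, k=6.1):
    return 1.0 - _sigmoid((vhalf - v) / k)


def naf_h_tau(v, f=1.0):
    alpha = 0.36 * xexprel(-(v + 48.0) / 12.0)
    beta = 0.4 * xexprel((v + 11.0) / 6.0)
    return f * Q10_TAU_SCALE / (alpha + beta)


def kdr_n_inf(v, vhalf=-17.6, k=19.6):
    return _sigmoid((vhalf - v) / k)


def kdr_n_tau(v, f=1.0):
    alpha = 0.2 * xexprel((v + 38.0) / 10.0)
    beta = 0.6294 * xexprel(-(v + 47.0) / 35.0)
    return f * Q10_TAU_SCALE / (alpha + beta)


def hcn_fast_inf(v, vhalf=74.2, k=9.78, power=1.36):
    # fractional power applied to the whole sigmoid bracket, as specified
    return (1.0 + np.exp(np.clip((v + vhalf) / k, -500.0, 500.0))) ** (-power)


def hcn_fast_tau(v, f=1.0):
    return f * Q10_TAU_SCALE * 0.51 / (
        np.exp((v - 1.7) / 10.0) + np.exp(-(v + 340.0) / 52.0)
    )


def hcn_slow_inf(v, vhalf=2.83, k=15.9, power=58.5):
    return (1.0 + np.exp(np.clip((v + vhalf) / k, -500.0, 500.0))) ** (-power)


def hcn_slow_tau(v, f=1.0):
    return f * Q10_TAU_SCALE * 5.6 / (
        np.exp((v - 17.0) / 14.0) + np.exp(-(v + 260.0) / 43.0)
    )


def nap_m_inf(v, vhalf=48.7, k=4.4):
    return _sigmoid(-(v + vhalf) / k)


def nap_m_tau(v, f=1.0):
    # rates 0.091(V+38)/(1-e^{-(V+38)/5}) and -0.062(V+38)/(1-e^{(V+38)/5}) /ms
    alpha = 0.455 * xexprel((v + 38.0) / 5.0)
    beta = 0.31 * xexprel(-(v + 38.0) / 5.0)
    return f * Q10_TAU_SCALE / (alpha + beta)


def nap_h_inf(v, vhalf=48.8, k=9.9):
    return _sigmoid((v + vhalf) / k)


def nap_h_tau(v, f=1.0):
    # per-ms rates; alpha has a true pole at V = 49.1 mV where the summed
    # rate can go negative, so the sum is floored (gate frozen at spike peak,
    # harmless for a gate with ~seconds kinetics).
    v = np.asarray(v, dtype=float)
    alpha = -2.88e-6 * (v + 17.049) / (-np.expm1(np.clip((v - 49.1) / 4.63, -500, 500)))
    beta = 6.94e-6 * (v + 64.409) / (-np.expm1(np.clip(-(v + 447.0) / 2.63, -500, 500)))
    rate = np.maximum(alpha + beta, 1e-9)
    return f * Q10_TAU_SCALE / rate


def ka_m_inf(v, vhalf=-18.3, k=15.0):
    return _sigmoid((vhalf - v) / k)


def ka_m_tau(v, f=1.0):
    alpha = 0.15 * xexprel((v + 18.3) / 15.0)
    beta = 0.15 * xexprel(-(v + 18.3) / 15.0)
    return f * Q10_TAU_SCALE / (alpha + beta)


def ka_h_inf(v, vhalf=-58.0, k=8.2):
    return 1.0 - _sigmoid((vhalf - v) / k)


def ka_h_tau(v, f=1.0, as_printed=False):
    alpha = 0.082 * xexprel(-(v + 58.0) / 8.2)
    if as_printed:
        # literal transcription with the (V+8.2) shift in beta's exponential
        v = np.asarray(v, dtype=float)
        beta = 0.082 * ((v + 58.0) / 8.2) / (-np.expm1(np.clip(-(v + 8.2) / 8.2, -500, 500)))
    else:
        beta = 0.082 * xexprel((v + 58.0) / 8.2)
    return f * Q10_TAU_SCALE / np.maximum(alpha + beta, 1e-9)


def hva_m_inf(v, vhalf=11.1, k=8.4):
    return _sigmoid(-(v + vhalf) / k)


def hva_m_tau(v, f=1.0):
    return np.full_like(np.asarray(v, dtype=float), 0.92 * f * Q10_TAU_SCALE)


def hva_h_inf(v, vhalf=37.0, k=9.0):
    return _sigmoid((v + vhalf) / k)


def hva_h_tau(v, f=1.0):
    return np.full_like(np.asarray(v, dtype=float), 250.0 * f * Q10_TAU_SCALE)


def lva_m_inf(v, vhalf=-52.4, k=8.2):
    return _sigmoid((vhalf - v) / k)


def lva_m_tau(v, f=1.0):
    v = np.asarray(v, dtype=float)
    term1 = 8.967 * xexprel((v + 7.88) / 10.0)
    term2 = 0.046 * np.exp(-v / 22.73)
    return f * Q10_TAU_SCALE / (term1 + term2)


def lva_h_inf(v, vhalf=-88.2, k=6.67):
    return 1.0 - _sigmoid((vhalf - v) / k)


def lva_h_tau(v, f=1.0):
    v = np.asarray(v, dtype=float)
    rate = 1.6e-4 * np.exp(-(v + 79.5) / 20.0) + _sigmoid(-(v + 5.0) / 10.0)
    return 1.2 * f * Q10_TAU_SCALE / rate


def km_m_inf(v, vhalf=-40.0, k=-10.0):
    # k is negative as tabulated: (V - vhalf)/k then yields activation with
    # depolarization without any sign fix-up.
    return _sigmoid((v - vhalf) / k)


def km_m_tau(v, f=1.0):
    v = np.asarray(v, dtype=float)
    num = np.exp(np.clip(0.10584 * (v + 42.0), -500, 500))
    den = 0.009 * (1.0 + np.exp(np.clip(0.2646 * (v + 42.0), -500, 500)))
    return f * Q10_TAU_SCALE * (60.0 + num / den)


def lva_calcium_inactivation(ca_mM):
    """Calcium-dependent LVA inactivation s([Ca]) = 0.001/(0.001 + [Ca])."""
    ca = np.asarray(ca_mM, dtype=float)
    if np.any(ca < 0):
        raise ValueError("calcium concentration must be non-negative")
    return 0.001 / (0.001 + ca)


# ---------------------------------------------------------------------------
# gate registry: steady state / time constant by (channel, role)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GateSpec:
    """One Hodgkin-Huxley gating particle of a named channel.

    ``exponent`` is the power applied to the gate variable in the current law
    (for HCN the fractional power sits inside the steady-state sigmoid and
    the exponent here is 1).
    """

    channel: str
    role: str  # "activation" | "inactivation"
    exponent: float
    vhalf: float
    slope: float
    f_scale: float = 1.0

    def __post_init__(self):
        if self.slope == 0:
            raise ValueError("gate slope must be nonzero")


_GATE_FUNCS = {
    ("NaF", "activation"): (naf_m_inf, naf_m_tau),
    ("NaF", "inactivation"): (naf_h_inf, naf_h_tau),
    ("KDR", "activation"): (kdr_n_inf, kdr_n_tau),
    ("HCNf", "activation"): (hcn_fast_inf, hcn_fast_tau),
    ("HCNs", "activation"): (hcn_slow_inf, hcn_slow_tau),
    ("NaP", "activation"): (nap_m_inf, nap_m_tau),
    ("NaP", "inactivation"): (nap_h_inf, nap_h_tau),
    ("KA", "activation"): (ka_m_inf, ka_m_tau),
    ("KA", "inactivation"): (ka_h_inf, ka_h_tau),
    ("HVA", "activation"): (hva_m_inf, hva_m_tau),
    ("HVA", "inactivation"): (hva_h_inf, hva_h_tau),
    ("LVA", "activation"): (lva_m_inf, lva_m_tau),
    ("LVA", "inactivation"): (lva_h_inf, lva_h_tau),
    ("KM", "activation"): (km_m_inf, km_m_tau),
}

GATE_EXPONENTS = {
    "NaF": {"activation": 3, "inactivation": 1},
    "KDR": {"activation": 4},
    "HCNf": {"activation": 1},
    "HCNs": {"activation": 1},
    "NaP": {"activation": 1, "inactivation": 1},
    "KA": {"activation": 1, "inactivation": 1},
    "HVA": {"activation": 3, "inactivation": 1},
    "LVA": {"activation": 2, "inactivation": 1},
    "KM": {"activation": 1},
}


def default_gate_spec(channel: str, role: str) -> GateSpec:
    inf_fn, _ = _GATE_FUNCS[(channel, role)]
    import inspect

    sig = inspect.signature(inf_fn)
    return GateSpec(
        channel=channel,
        role=role,
        exponent=GATE_EXPONENTS[channel][role],
        vhalf=sig.parameters["vhalf"].default,
        slope=sig.parameters["k"].default,
    )


def gate_steady_state(gate: GateSpec, v):
    """Steady-state open fraction of a gating particle at voltage ``v`` (mV)."""
    inf_fn, _ = _GATE_FUNCS[(gate.channel, gate.role)]
    return inf_fn(v, vhalf=gate.vhalf, k=gate.slope)


def gate_time_constant(gate: GateSpec, v):
    """Gate relaxation time constant at ``v``, in ms (strictly positive)."""
    _, tau_fn = _GATE_FUNCS[(gate.channel, gate.role)]
    return tau_fn(v, f=gate.f_scale)


# ---------------------------------------------------------------------------
# current laws
# ---------------------------------------------------------------------------

def ohmic_current(g_max, gates, v, e_rev):
    """I = g * (gate product) * (V - E), in uA/cm2 for g in mS/cm2.

    ``gates`` is the already-exponentiated gate product (e.g. m**3 * h).
    """
    if np.any(np.asarray(g_max) < 0):
        raise ValueError("maximal conductance must be non-negative")
    return g_max * gates * (v - e_rev)


def ghk_driving_force(v, ca_i, ca_o=CA_OUT):
    """Goldman-Hodgkin-Katz driving term for a divalent ion, in mV.

    ``-s * (1 - (ci/co) * exp(v/s)) * efun(v/s)`` with s = RT/2F in mV and
    efun(x) = x/(e^x - 1); the removable singularity at V = 0 takes its
    analytic limit. Multiplying by a permeability scale in mS/cm2 yields a
    current density in uA/cm2 (the convention of compartmental simulators,
    where the tabulated calcium-channel "conductances" are permeability
    scales). Zero exactly at the Nernst potential (RT/2F) ln(co/ci); negative
    (inward) below it.
    """
    v = np.asarray(v, dtype=float)
    nu = v / GHK_VSLOPE
    efun = xexprel(-nu)  # nu/(e^nu - 1)
    return -GHK_VSLOPE * (1.0 - (np.asarray(ca_i, dtype=float) / ca_o)
                          * np.exp(np.clip(nu, -500, 500))) * efun


def ghk_current(perm_scale, gates, v, ca_i, ca_o=CA_OUT):
    """Calcium-channel current density (uA/cm2); inward currents negative."""
    if np.any(np.asarray(ca_i) <= 0) or ca_o <= 0:
        raise ValueError("calcium concentrations must be positive")
    if np.any(np.asarray(perm_scale) < 0):
        raise ValueError("permeability scale must be non-negative")
    return perm_scale * gates * ghk_driving_force(v, ca_i, ca_o)


# ---------------------------------------------------------------------------
# SK channel: six-state Markov scheme
# ---------------------------------------------------------------------------
# States 0..3 are closed C1..C4 linked by three sequential calcium-binding
# steps (forward rate SK_ALPHA * [Ca] in uM, backward SK_BETA); states 4 and
# 5 are open, reached from C3 and C4 by gamma (opening) / delta (closing).
# This wiring follows the classic sequential-binding SK gating scheme; only
# the four rate constants are prescribed, the topology is a documented
# modeling choice.

SK_N_STATES = 6
SK_EDGES = (
    # (from, to, kind) with kind "bind" (alpha*[Ca]), "unbind" (beta),
    # "open" (gamma), "close" (delta)
    (0, 1, "bind"), (1, 0, "unbind"),
    (1, 2, "bind"), (2, 1, "unbind"),
    (2, 3, "bind"), (3, 2, "unbind"),
    (2, 4, "open"), (4, 2, "close"),
    (3, 5, "open"), (5, 3, "close"),
)
SK_OPEN_STATES = (4, 5)


def sk_rates(opening: str = "gamma") -> tuple[float, float, float, float]:
    """(kon per uM, koff, kopen, kclose) in /ms for the chosen rate wiring.

    The inset scheme prints only the four rate constants; which of gamma and
    delta is the opening rate is a figure-level ambiguity. ``opening="gamma"``
    assigns gamma (600/s) to closed->open; ``opening="delta"`` assigns delta
    (400/s) to closed->open and gamma to open->closed.
    """
    if opening == "gamma":
        return SK_ALPHA, SK_BETA, SK_GAMMA, SK_DELTA
    if opening == "delta":
        return SK_ALPHA, SK_BETA, SK_DELTA, SK_GAMMA
    raise ValueError(f"unknown SK opening-rate assignment: {opening!r}")


def _sk_edge_rate(kind: str, ca_mM: float, rates) -> float:
    kon_per_uM, koff, kopen, kclose = rates
    if kind == "bind":
        return kon_per_uM * (ca_mM * 1000.0)  # [Ca] in uM
    if kind == "unbind":
        return koff
    if kind == "open":
        return kopen
    return kclose


def sk_rate_matrix(ca_mM: float, opening: str = "gamma") -> np.ndarray:
    """Generator matrix Q (6x6, /ms): Q[i, j] is the i->j rate for i != j,
    and rows sum to zero (probability conservation)."""
    if ca_mM < 0:
        raise ValueError("calcium concentration must be non-negative")
    rates = sk_rates(opening)
    q = np.zeros((SK_N_STATES, SK_N_STATES))
    for i, j, kind in SK_EDGES:
        q[i, j] += _sk_edge_rate(kind, ca_mM, rates)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def sk_steady_state(ca_mM: float, opening: str = "gamma") -> np.ndarray:
    """Stationary occupancies from the null space of the generator."""
    q = sk_rate_matrix(ca_mM, opening)
    # stationary distribution p solves p Q = 0 with sum(p) = 1
    a = np.vstack([q.T, np.ones(SK_N_STATES)])
    b = np.zeros(SK_N_STATES + 1)
    b[-1] = 1.0
    p, *_ = np.linalg.lstsq(a, b, rcond=None)
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def sk_open_fraction_ss(ca_mM: float, opening: str = "gamma") -> float:
    """Steady-state SK open probability; 0 at zero calcium, nondecreasing."""
    p = sk_steady_state(ca_mM, opening)
    return float(p[list(SK_OPEN_STATES)].sum())


# ---------------------------------------------------------------------------
# calcium pool
# ---------------------------------------------------------------------------

def ca_derivative(ca_mM, i_ca_mA_per_cm2, tau_ca_ms):
    """d[Ca]/dt (mM/ms) for the shell pool.

    Influx term -10000 * I_Ca / (36 * dpt * F) with I_Ca in mA/cm2 and
    dpt = 0.1 um, plus first-order decay toward the 100-nM resting level.
    Inward (negative) calcium current raises [Ca].
    """
    influx = -10000.0 * i_ca_mA_per_cm2 / (36.0 * CA_SHELL_DEPTH * FARADAY)
    return influx + (CA_REST - ca_mM) / tau_ca_ms


# ---------------------------------------------------------------------------
# audit serialization
# ---------------------------------------------------------------------------

def channel_spec() -> dict:
    """Serializable description of every channel's gates, exponents and law."""
    law = {
        "NaF": "ohmic(E_Na)", "KDR": "ohmic(E_K)", "HCNf": "ohmic(E_h)",
        "HCNs": "ohmic(E_h)", "NaP": "ohmic(E_Na)", "KA": "ohmic(E_K)",
        "HVA": "ghk(Ca)", "LVA": "ghk(Ca) * s([Ca])", "KM": "ohmic(E_K)",
    }
    out = {"units": {"v": "mV", "t": "ms", "g": "mS/cm2", "i": "uA/cm2"},
           "channels": {}}
    for (channel, role), (inf_fn, tau_fn) in _GATE_FUNCS.items():
        spec = default_gate_spec(channel, role)
        entry = out["channels"].setdefault(
            channel, {"current_law": law[channel], "gates": {}}
        )
        entry["gates"][role] = {
            "exponent": spec.exponent,
            "vhalf_mV": spec.vhalf,
            "slope_mV": spec.slope,
            "steady_state": inf_fn.__name__,
            "time_constant": tau_fn.__name__,
        }
    out["channels"]["SK"] = {
        "current_law": "ohmic(E_K) * open_fraction",
        "markov": {
            "n_states": SK_N_STATES,
            "open_states": list(SK_OPEN_STATES),
            "edges": [list(e) for e in SK_EDGES],
            "rates_per_ms": {"alpha_per_uM": SK_ALPHA, "beta": SK_BETA,
                             "gamma": SK_GAMMA, "delta": SK_DELTA},
        },
    }
    return out


def channel_spec_yaml() -> str:
    return yaml.safe_dump(channel_spec(), sort_keys=False)
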