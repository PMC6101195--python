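"""Single-compartment stellate-cell model assembly and integration.

The model is a cylinder of 70-um diameter and 75-um length (lateral surface
only, the convention of compartmental simulators); membrane dynamics couple
the voltage, fourteen Hodgkin-Huxley gate variables, the six SK Markov
occupancies and the cytosolic calcium shell. Current-clamp stimuli are
sampled waveforms in pA; integration is exponential-Euler for gates and
forward-Euler for V and [Ca] at a fixed step (default 25 us).

Two integration routes exist: the production route in
:mod:`stellatesim._kernels` (compiled, voltage-tabulated kinetics) and
:func:`integrate_reference`, a slow direct-evaluation loop used to
cross-validate the tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from stellatesim import _kernels, channels
from stellatesim.channels import CA_REST, E_H, E_K, E_LEAK, E_NA
from stellatesim.parameters import N_PARAMETERS, load_parameter_space

DIAMETER_UM = 70.0
LENGTH_UM = 75.0
MEMBRANE_AREA_CM2 = math.pi * (DIAMETER_UM * 1e-4) * (LENGTH_UM * 1e-4)

DEFAULT_DT = 0.025  # ms (25 us)
SETTLE_DURATION = 6000.0  # ms: 5 s of settling plus the 1-s rest window

TABLE_VMIN = -120.0
TABLE_VMAX = 60.0
TABLE_DV = 0.01


class SimulationError(RuntimeError):
    """Numerical divergence, reported with the simulated time of failure."""

    def __init__(self, message: str, t_ms: float | None = None):
        super().__init__(message)
        self.t_ms = t_ms


# gate table: (inf_fn, tau_fn, vhalf key, slope key, tau-scale key)
_GATE_PARAMS = (
    (channels.naf_m_inf, channels.naf_m_tau, "v_m_naf", "k_m_naf", "f_m_naf"),
    (channels.naf_h_inf, channels.naf_h_tau, "v_h_naf", "k_h_naf", "f_h_naf"),
    (channels.kdr_n_inf, channels.kdr_n_tau, "v_n_kdr", "k_n_kdr", "f_n_kdr"),
    (channels.hcn_fast_inf, channels.hcn_fast_tau, "v_mf_hcn", "k_mf_hcn", "f_mf_hcn"),
    (channels.hcn_slow_inf, channels.hcn_slow_tau, "v_ms_hcn", "k_ms_hcn", "f_ms_hcn"),
    (channels.nap_m_inf, channels.nap_m_tau, "v_m_nap", "k_m_nap", "f_m_nap"),
    (channels.nap_h_inf, channels.nap_h_tau, "v_h_nap", "k_h_nap", "f_h_nap"),
    (channels.ka_m_inf, channels.ka_m_tau, "v_m_ka", "k_m_ka", "f_m_ka"),
    (channels.ka_h_inf, channels.ka_h_tau, "v_h_ka", "k_h_ka", "f_h_ka"),
    (channels.hva_m_inf, channels.hva_m_tau, "v_m_hva", "k_m_hva", "f_m_hva"),
    (channels.hva_h_inf, channels.hva_h_tau, "v_h_hva", "k_h_hva", "f_h_hva"),
    (channels.lva_m_inf, channels.lva_m_tau, "v_m_lva", "k_m_lva", "f_m_lva"),
    (channels.lva_h_inf, channels.lva_h_tau, "v_h_lva", "k_h_lva", "f_h_lva"),
    (channels.km_m_inf, channels.km_m_tau, "v_m_km", "k_m_km", "f_m_km"),
)

N_GATES = len(_GATE_PARAMS)

# conductance parameters and their conversion to mS/cm2
_CONDUCTANCE_SCALE = {
    "g_naf": 1.0, "g_kdr": 1.0, "g_hcn": 1e-3, "g_nap": 1e-3, "g_ka": 1e-3,
    "g_hva": 1.0, "g_lva": 1e-3, "g_km": 1.0, "g_sk": 1e-3,
}


@dataclass(frozen=True)
class ModelConfig:
    """Resolutions of the model's documented formulation ambiguities.

    ``sk_opening``: which printed rate is the SK closed->open transition
    ("gamma" or "delta"; the inset figure does not disambiguate).
    ``ka_betah_as_printed``: use the literal KA beta_h transcription instead
    of the symmetric form.
    """

    sk_opening: str = "gamma"
    ka_betah_as_printed: bool = False


def compile_constants(p: pd.Series, config: ModelConfig) -> np.ndarray:
    const = np.empty(19)
    const[0] = p["g_naf"]
    const[1] = p["g_kdr"]
    const[2] = p["g_hcn"] * 1e-3
    const[3] = p["hcn_ms_mf"]
    const[4] = p["g_nap"] * 1e-3
    const[5] = p["g_ka"] * 1e-3
    const[6] = p["g_hva"]
    const[7] = p["g_lva"] * 1e-3
    const[8] = p["g_km"]
    const[9] = p["g_sk"] * 1e-3
    const[10] = 1.0 / p["r_m"]  # kOhm.cm2 -> mS/cm2
    const[11] = E_LEAK
    const[12] = p["c_m"]
    const[13] = p["tau_ca"]
    const[14] = 1e-6 / MEMBRANE_AREA_CM2  # pA -> uA/cm2
    kon_per_uM, koff, kopen, kclose = channels.sk_rates(config.sk_opening)
    const[15] = kon_per_uM * 1000.0  # per mM of calcium
    const[16] = koff
    const[17] = kopen
    const[18] = kclose
    return const


@dataclass
class ModelState:
    """Full dynamical state; serializable, sufficient for exact restart."""

    v: float
    gates: np.ndarray  # (14,)
    sk: np.ndarray  # (6,) occupancies, sum 1
    ca: float  # mM

    def copy(self) -> "ModelState":
        return ModelState(self.v, self.gates.copy(), self.sk.copy(), self.ca)


@dataclass
class Stimulus:
    """A sampled current-clamp waveform in pA at fixed step ``dt`` (ms)."""

    kind: str
    current_pA: np.ndarray
    dt: float
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return len(self.current_pA) * self.dt

    @property
    def t(self) -> np.ndarray:
        return np.arange(1, len(self.current_pA) + 1) * self.dt


@dataclass
class Trace:
    """Uniformly sampled membrane trajectory plus the injected stimulus.

    ``t[i]`` is the time at the end of integration step i (so ``t`` starts
    at ``dt``); ``v`` in mV, ``ca`` in mM, ``stim_pA`` in pA.
    """

    t: np.ndarray
    v: np.ndarray
    ca: np.ndarray
    stim_pA: np.ndarray
    dt: float
    meta: dict = field(default_factory=dict)

    def window(self, t0: float, t1: float) -> "Trace":
        """Sub-trace with t0 < t <= t1 (times re-referenced to the slice)."""
        sel = (self.t > t0 + 1e-9) & (self.t <= t1 + 1e-9)
        return Trace(
            self.t[sel] - t0, self.v[sel], self.ca[sel], self.stim_pA[sel],
            self.dt, dict(self.meta),
        )

    def to_hdf5(self, path, **attrs) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            for name in ("t", "v", "ca", "stim_pA"):
                fh.create_dataset(name, data=getattr(self, name))
            fh.attrs["dt"] = self.dt
            for key, val in {**self.meta, **attrs}.items():
                fh.attrs[key] = val

    @classmethod
    def from_hdf5(cls, path) -> "Trace":
        import h5py

        with h5py.File(path, "r") as fh:
            data = {name: fh[name][...] for name in ("t", "v", "ca", "stim_pA")}
            dt = float(fh.attrs["dt"])
            meta = {k: v for k, v in fh.attrs.items() if k != "dt"}
        return cls(data["t"], data["v"], data["ca"], data["stim_pA"], dt, meta)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_ms": self.t, "v_mV": self.v, "ca_mM": self.ca, "i_pA": self.stim_pA}
        )


class CellModel:
    """A parameter vector compiled into an integrable single-compartment cell."""

    def __init__(self, params: pd.Series, config: ModelConfig | None = None):
        self.params = params.astype(float)
        self.config = config or ModelConfig()
        self.area_cm2 = MEMBRANE_AREA_CM2
        self.const = compile_constants(self.params, self.config)
        self._tables: dict[float, tuple] = {}

    @property
    def r_in_passive_MOhm(self) -> float:
        """Closed-form passive input resistance R_m / area, in MOhm."""
        return self.params["r_m"] * 1e3 / self.area_cm2 * 1e-6

    @property
    def tau_passive_ms(self) -> float:
        return self.params["r_m"] * self.params["c_m"]  # kOhm.cm2 * uF/cm2 = ms

    def gate_steady_states(self, v: float) -> np.ndarray:
        p = self.params
        out = np.empty(N_GATES)
        for i, (inf_fn, _tau_fn, vk, kk, _fk) in enumerate(_GATE_PARAMS):
            out[i] = inf_fn(v, vhalf=p[vk], k=p[kk])
        return out

    def gate_time_constants(self, v) -> np.ndarray:
        p = self.params
        v = np.asarray(v, dtype=float)
        out = np.empty((N_GATES,) + v.shape)
        for i, (_inf_fn, tau_fn, _vk, _kk, fk) in enumerate(_GATE_PARAMS):
            out[i] = tau_fn(v, f=p[fk])
        return out

    def tables(self, dt: float) -> tuple:
        """Voltage-tabulated kinetics for step ``dt`` (memoized)."""
        key = round(float(dt), 9)
        if key not in self._tables:
            self._tables[key] = _build_tables(self, dt)
        return self._tables[key]


def _build_tables(model: CellModel, dt: float):
    vgrid = np.arange(TABLE_VMIN, TABLE_VMAX + TABLE_DV / 2, TABLE_DV)
    p = model.params
    minf = np.empty((N_GATES, len(vgrid)))
    gfac = np.empty_like(minf)
    for i, (inf_fn, tau_fn, vk, kk, fk) in enumerate(_GATE_PARAMS):
        minf[i] = inf_fn(vgrid, vhalf=p[vk], k=p[kk])
        if tau_fn is channels.ka_h_tau:
            tau = tau_fn(vgrid, f=p[fk], as_printed=model.config.ka_betah_as_printed)
        else:
            tau = tau_fn(vgrid, f=p[fk])
        gfac[i] = -np.expm1(-dt / tau)
    nu = vgrid / channels.GHK_VSLOPE
    efun = channels.xexprel(-nu)
    ghk_a = -channels.GHK_VSLOPE * efun
    ghk_b = channels.GHK_VSLOPE * np.exp(nu) * efun / channels.CA_OUT
    return minf, gfac, ghk_a, ghk_b


def build_model(p: pd.Series | dict, config: ModelConfig | None = None) -> CellModel:
    """Validate a 55-parameter vector and compile it into a :class:`CellModel`.

    The leak reversal is fixed at -77 mV so the passive cell (all active
    conductances zero) rests there.
    """
    if isinstance(p, dict):
        p = pd.Series(p)
    space = load_parameter_space()
    missing = [n for n in space.names if n not in p.index]
    if missing:
        raise ValueError(f"missing parameters: {missing}")
    if len(p.index) != N_PARAMETERS:
        p = p[space.names]
    for g in _CONDUCTANCE_SCALE:
        if p[g] < 0:
            raise ValueError(f"conductance {g} must be non-negative, got {p[g]}")
    if p["r_m"] <= 0 or p["c_m"] <= 0 or p["tau_ca"] <= 0:
        raise ValueError("passive and calcium parameters must be positive")
    return CellModel(p[space.names], config)


def init_state(model: CellModel, v0: float = E_LEAK) -> ModelState:
    """State with every gate at its steady state for ``v0`` and the calcium
    pool and SK scheme at their zero-current equilibrium."""
    return ModelState(
        v=v0,
        gates=model.gate_steady_states(v0),
        sk=channels.sk_steady_state(CA_REST, model.config.sk_opening),
        ca=CA_REST,
    )


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------

def _check_duration(duration_ms: float):
    if duration_ms <= 0:
        raise ValueError("stimulus duration must be positive")


def make_step(
    amplitude_pA: float,
    onset_ms: float = 0.0,
    duration_ms: float = 500.0,
    total_ms: float | None = None,
    dt: float = DEFAULT_DT,
) -> Stimulus:
    _check_duration(duration_ms)
    total = duration_ms + onset_ms if total_ms is None else total_ms
    n = int(round(total / dt))
    t = np.arange(1, n + 1) * dt
    wave = np.where((t > onset_ms) & (t <= onset_ms + duration_ms), amplitude_pA, 0.0)
    return Stimulus(
        "step", wave, dt,
        {"amplitude_pA": amplitude_pA, "onset_ms": onset_ms,
         "duration_ms": duration_ms},
    )


def make_chirp(
    peak_to_peak_pA: float = 40.0,
    f0_Hz: float = 0.0,
    f1_Hz: float = 15.0,
    duration_ms: float = 15000.0,
    dt: float = DEFAULT_DT,
) -> Stimulus:
    """Constant-amplitude sinusoid whose frequency sweeps linearly f0 -> f1."""
    _check_duration(duration_ms)
    n = int(round(duration_ms / dt))
    t = np.arange(1, n + 1) * dt  # ms
    t_s = t / 1000.0
    T_s = duration_ms / 1000.0
    phase = 2.0 * np.pi * (f0_Hz * t_s + (f1_Hz - f0_Hz) * t_s**2 / (2.0 * T_s))
    wave = (peak_to_peak_pA / 2.0) * np.sin(phase)
    return Stimulus(
        "chirp", wave, dt,
        {"peak_to_peak_pA": peak_to_peak_pA, "f0_Hz": f0_Hz, "f1_Hz": f1_Hz,
         "duration_ms": duration_ms},
    )


def make_gwn(
    sigma_pA: float,
    duration_ms: float,
    dt: float = DEFAULT_DT,
    rng: np.random.Generator | None = None,
) -> Stimulus:
    """Zero-mean Gaussian white noise, one independent draw per step."""
    _check_duration(duration_ms)
    if rng is None:
        rng = np.random.default_rng()
    n = int(round(duration_ms / dt))
    wave = rng.normal(0.0, sigma_pA, size=n)
    return Stimulus("gwn", wave, dt, {"sigma_pA": sigma_pA, "duration_ms": duration_ms})


def make_zero(duration_ms: float, dt: float = DEFAULT_DT) -> Stimulus:
    _check_duration(duration_ms)
    n = int(round(duration_ms / dt))
    return Stimulus("zero", np.zeros(n), dt, {"duration_ms": duration_ms})


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def simulate(
    model: CellModel,
    state: ModelState,
    stimulus: Stimulus,
    dt: float | None = None,
) -> tuple[Trace, ModelState]:
    """Integrate ``model`` from ``state`` under ``stimulus``.

    Deterministic given (model, state, stimulus, dt). Does not mutate the
    input state; returns the trace and the final state.
    """
    dt = stimulus.dt if dt is None else dt
    if abs(dt - stimulus.dt) > 1e-12:
        raise ValueError("stimulus must be sampled at the integration step")
    minf, gfac, ghk_a, ghk_b = model.tables(dt)
    st = state.copy()
    wave = np.ascontiguousarray(stimulus.current_pA, dtype=np.float64)
    v_out = np.empty(len(wave))
    ca_out = np.empty(len(wave))
    status, step, v, ca = _kernels.integrate_tables(
        st.v, st.gates, st.sk, st.ca, wave, dt, model.const,
        minf, gfac, ghk_a, ghk_b, TABLE_VMIN, TABLE_DV, v_out, ca_out,
    )
    if status != _kernels.STATUS_OK:
        raise SimulationError(
            f"integration diverged at t = {step * dt:.3f} ms (V = {v:.1f} mV)",
            t_ms=step * dt,
        )
    st.v, st.ca = v, ca
    trace = Trace(
        t=np.arange(1, len(wave) + 1) * dt,
        v=v_out, ca=ca_out, stim_pA=wave, dt=dt,
        meta={"kind": stimulus.kind, **stimulus.meta},
    )
    return trace, st


def settle(
    model: CellModel,
    duration_ms: float = SETTLE_DURATION,
    dt: float = DEFAULT_DT,
    state: ModelState | None = None,
) -> tuple[Trace, ModelState]:
    """Relax the model with zero injected current (default 6 s: 5 s of
    settling plus the 1-s resting-potential window)."""
    if state is None:
        state = init_state(model)
    return simulate(model, state, make_zero(duration_ms, dt))


def integrate_reference(
    model: CellModel,
    state: ModelState,
    stimulus: Stimulus,
) -> tuple[Trace, ModelState]:
    """Direct-evaluation integrator (no lookup tables): the in-repo oracle.

    Same stepping scheme as the production kernel but every rate is computed
    from the formulas in :mod:`stellatesim.channels` at each step. Orders of
    magnitude slower; intended for short cross-validation runs only.
    """
    dt = stimulus.dt
    p = model.params
    c = model.const
    st = state.copy()
    wave = stimulus.current_pA
    n = len(wave)
    v_out = np.empty(n)
    ca_out = np.empty(n)
    v, ca = st.v, st.ca
    gates, sk = st.gates, st.sk
    kon_scale, koff, kopen, kclose = (c[15], c[16], c[17], c[18])
    for i in range(n):
        for g, (inf_fn, tau_fn, vk, kk, fk) in enumerate(_GATE_PARAMS):
            mi = float(inf_fn(v, vhalf=p[vk], k=p[kk]))
            tau = float(tau_fn(v, f=p[fk]))
            gates[g] += (mi - gates[g]) * -math.expm1(-dt / tau)
        kon = kon_scale * ca
        f01 = kon * sk[0] - koff * sk[1]
        f12 = kon * sk[1] - koff * sk[2]
        f23 = kon * sk[2] - koff * sk[3]
        f24 = kopen * sk[2] - kclose * sk[4]
        f35 = kopen * sk[3] - kclose * sk[5]
        sk[0] -= dt * f01
        sk[1] += dt * (f01 - f12)
        sk[2] += dt * (f12 - f23 - f24)
        sk[3] += dt * (f23 - f35)
        sk[4] += dt * f24
        sk[5] += dt * f35
        ghkdf = float(channels.ghk_driving_force(v, ca))
        i_ion = (
            c[0] * gates[0] ** 3 * gates[1] * (v - E_NA)
            + c[1] * gates[2] ** 4 * (v - E_K)
            + c[2] * (gates[4] + c[3] * gates[3]) * (v - E_H)
            + c[4] * gates[5] * gates[6] * (v - E_NA)
            + c[5] * gates[7] * gates[8] * (v - E_K)
            + c[8] * gates[13] * (v - E_K)
            + c[9] * (sk[4] + sk[5]) * (v - E_K)
            + c[10] * (v - E_LEAK)
        )
        i_ca = (
            c[6] * gates[9] ** 3 * gates[10] * ghkdf
            + c[7] * gates[11] ** 2 * gates[12]
            * float(channels.lva_calcium_inactivation(ca)) * ghkdf
        )
        i_ion += i_ca
        v += dt * (wave[i] * c[14] - i_ion) / c[12]
        ca += dt * float(channels.ca_derivative(ca, i_ca * 1e-3, c[13]))
        v_out[i] = v
        ca_out[i] = ca
        if not (-200.0 < v < 200.0) or ca <= 0 or math.isnan(v):
            raise SimulationError(
                f"reference integration diverged at t = {i * dt:.3f} ms", i * dt
            )
    st.v, st.ca = v, ca
    trace = Trace(np.arange(1, n + 1) * dt, v_out, ca_out, wave, dt,
                  {"kind": stimulus.kind, **stimulus.meta})
    return trace, st
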