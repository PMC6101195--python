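"""The ten intrinsic electrophysiological measurements and their protocols.

Measurements operate on :class:`~stellatesim.simulator.Trace` objects so they
can be tested against synthetic ground-truth traces independently of the ODE
solver; :func:`measure_all` runs the full protocol battery on a model.

Protocols (all starting from the settled state after 5 s of zero current):
  * resting potential and its SD: mean/SD of V over the 5-6 s window;
  * sag: -200 pA for 1 s, steady-state over peak deflection;
  * input resistance: -100..+100 pA in 20-pA steps, slope of the V-I line
    read at 1 s;
  * excitability: 100-pA and 400-pA 500-ms steps (spike counts N100/N400,
    spike amplitude V_AP from the first 400-pA spike);
  * impedance: 0-15 Hz chirp over 15 s at 40 pA peak-to-peak, giving
    |Z(f)|, resonance frequency f_R, strength Q_R, and total inductive
    phase Phi_L;
  * membrane-potential oscillations: 100-300 pA in 10-pA steps for 5 s,
    spectra of the final 3 s giving f_MPO/V_avg/V_MPO per current and the
    perithreshold frequency f_osc.

Spikes are upward crossings of -20 mV with a 1-ms lockout; this threshold
separates the sub-25-mV oscillation cluster from full action potentials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from stellatesim.simulator import (
    DEFAULT_DT,
    SETTLE_DURATION,
    CellModel,
    ModelState,
    Trace,
    make_chirp,
    make_step,
    settle,
    simulate,
)

SPIKE_THRESHOLD = -20.0  # mV
SPIKE_LOCKOUT = 1.0  # ms
IMPEDANCE_BAND = (0.5, 15.0)  # Hz
MPO_CURRENTS_PA = tuple(range(100, 301, 10))
MPO_DURATION = 5000.0  # ms
MPO_ANALYSIS_WINDOW = 3000.0  # ms (final 3 s)
MPO_MIN_AMPLITUDE = 0.5  # mV peak-to-peak for a sweep to count as oscillating
STEADY_READ_MS = 10.0  # steady-state reads average the final 10 ms


class MeasurementError(ValueError):
    """A trace does not contain what the measurement requires."""


@dataclass
class MeasurementSet:
    """The ten validation measurements plus auxiliary quantities.

    Undefined quantities (e.g. f_osc for a model with no subthreshold
    oscillatory sweep, V_AP with no spike) are NaN.
    """

    v_rmp: float = np.nan
    v_sd: float = np.nan
    sag: float = np.nan
    r_in: float = np.nan
    q_r: float = np.nan
    f_r: float = np.nan
    f_osc: float = np.nan
    n100: float = np.nan
    n400: float = np.nan
    v_ap: float = np.nan
    phi_l: float = np.nan  # total inductive phase, rad*Hz
    mpo_table: pd.DataFrame | None = field(default=None, repr=False)

    def as_series(self) -> pd.Series:
        return pd.Series(
            {k: getattr(self, k) for k in
             ("v_rmp", "v_sd", "sag", "r_in", "q_r", "f_r", "f_osc",
              "n100", "n400", "v_ap", "phi_l")}
        )


@dataclass
class ImpedanceProfile:
    """|Z(f)| (MOhm) and phase (rad) on the chirp's analysis band."""

    f_Hz: np.ndarray
    z_MOhm: np.ndarray
    phase_rad: np.ndarray

    def resonance(self) -> tuple[float, float]:
        i = int(np.argmax(self.z_MOhm))
        i05 = int(np.argmin(np.abs(self.f_Hz - 0.5)))
        return float(self.f_Hz[i]), float(self.z_MOhm[i] / self.z_MOhm[i05])

    def inductive_phase(self) -> float:
        pos = np.where(self.phase_rad > 0, self.phase_rad, 0.0)
        return float(np.trapezoid(pos, self.f_Hz))


# ---------------------------------------------------------------------------
# spike detection
# ---------------------------------------------------------------------------

def spike_times(
    trace: Trace,
    threshold: float = SPIKE_THRESHOLD,
    lockout: float = SPIKE_LOCKOUT,
) -> np.ndarray:
    """Times (ms) of upward threshold crossings with a refractory lockout."""
    v = trace.v
    idx = np.flatnonzero((v[1:] >= threshold) & (v[:-1] < threshold)) + 1
    if len(idx) == 0:
        return np.empty(0)
    times = trace.t[idx]
    keep = [0]
    for k in range(1, len(times)):
        if times[k] - times[keep[-1]] >= lockout:
            keep.append(k)
    return times[keep]


def count_spikes(trace: Trace, t0: float = -np.inf, t1: float = np.inf) -> int:
    """Number of spikes with t0 < t <= t1."""
    st = spike_times(trace)
    return int(np.sum((st > t0) & (st <= t1)))


# ---------------------------------------------------------------------------
# trace-level measurements
# ---------------------------------------------------------------------------

def measure_rmp(trace: Trace, window: tuple[float, float] | None = None) -> tuple[float, float]:
    """(mean, SD) of V over the resting window (default: final 1 s)."""
    if window is None:
        window = (trace.t[-1] - 1000.0, trace.t[-1])
    t0, t1 = window
    sel = (trace.t > t0 + 1e-9) & (trace.t <= t1 + 1e-9)
    if not sel.any():
        raise MeasurementError("trace does not cover the resting window")
    v = trace.v[sel]
    return float(v.mean()), float(v.std())


def measure_sag(trace: Trace, onset_ms: float, duration_ms: float) -> float:
    """V_SS / V_peak for a hyperpolarizing step, deflections from the
    pre-step baseline; V_peak is the extreme deflection within the step."""
    pre = (trace.t > onset_ms - STEADY_READ_MS) & (trace.t <= onset_ms)
    if not pre.any():
        pre = trace.t <= onset_ms
    baseline = float(trace.v[pre].mean())
    instep = (trace.t > onset_ms) & (trace.t <= onset_ms + duration_ms)
    defl = trace.v[instep] - baseline
    if len(defl) == 0 or np.abs(defl).max() < 1e-9:
        raise MeasurementError("no voltage deflection during the step")
    v_peak = defl[np.argmax(np.abs(defl))]
    tail = (trace.t > onset_ms + duration_ms - STEADY_READ_MS) & (
        trace.t <= onset_ms + duration_ms
    )
    v_ss = float(trace.v[tail].mean() - baseline)
    return float(v_ss / v_peak)


def fit_input_resistance(currents_pA: np.ndarray, deflections_mV: np.ndarray) -> float:
    """Slope of the V-I line in MOhm (mV/pA = GOhm, scaled by 1000)."""
    slope = np.polyfit(np.asarray(currents_pA, float),
                       np.asarray(deflections_mV, float), 1)[0]
    return float(slope * 1000.0)


def measure_vap(trace: Trace, v_rmp: float, window_ms: float = 10.0) -> float:
    """Peak of the first action potential minus V_RMP (mV)."""
    st = spike_times(trace)
    if len(st) == 0:
        raise MeasurementError("no action potential in trace")
    sel = (trace.t >= st[0] - 1.0) & (trace.t <= st[0] + window_ms)
    return float(trace.v[sel].max() - v_rmp)


def impedance_profile(trace: Trace, band: tuple[float, float] = IMPEDANCE_BAND) -> ImpedanceProfile:
    """Impedance from the ratio of Fourier transforms of V and I."""
    n = len(trace.v)
    vf = np.fft.rfft(trace.v - trace.v.mean())
    cf = np.fft.rfft(trace.stim_pA - trace.stim_pA.mean())
    f = np.fft.rfftfreq(n, trace.dt / 1000.0)
    sel = (f >= band[0] - 1e-9) & (f <= band[1] + 1e-9)
    z = vf[sel] / cf[sel]
    return ImpedanceProfile(f[sel], np.abs(z) * 1000.0, np.angle(z))


def mpo_spectrum(trace: Trace) -> tuple[float, float, float]:
    """(f_MPO, V_avg, V_MPO) of a steady-current sweep segment.

    Rectangular-window Fourier transform of the mean-subtracted segment; the
    peak search excludes the DC bin. Sweeps whose peak-to-peak amplitude is
    below ``MPO_MIN_AMPLITUDE`` are reported as non-oscillating (f_MPO = 0).
    """
    v = trace.v
    v_avg = float(v.mean())
    v_mpo = float(v.max() - v.min())
    if v_mpo < MPO_MIN_AMPLITUDE:
        return 0.0, v_avg, v_mpo
    spec = np.abs(np.fft.rfft(v - v_avg))
    f = np.fft.rfftfreq(len(v), trace.dt / 1000.0)
    k = int(np.argmax(spec[1:]) + 1)
    return float(f[k]), v_avg, v_mpo


# ---------------------------------------------------------------------------
# model-level protocol battery
# ---------------------------------------------------------------------------

def measure_rin(model: CellModel, state: ModelState, v_rmp: float,
                dt: float = DEFAULT_DT) -> tuple[float, bool]:
    """Input resistance from the 11-sweep V-I protocol.

    Returns (R_in in MOhm, spike_flag); a spike during any sweep flags the
    estimate as unreliable.
    """
    currents = np.arange(-100, 101, 20)
    deflections = []
    spiked = False
    for amp in currents:
        tr, _ = simulate(model, state, make_step(amp, 0.0, 1000.0, 1000.0, dt))
        if count_spikes(tr) > 0:
            spiked = True
        tail = tr.t > 1000.0 - STEADY_READ_MS
        deflections.append(tr.v[tail].mean() - v_rmp)
    return fit_input_resistance(currents, np.asarray(deflections)), spiked


def mpo_scan(model: CellModel, state: ModelState, dt: float = DEFAULT_DT,
             currents_pA=MPO_CURRENTS_PA) -> pd.DataFrame:
    """Per-current (f_MPO, V_avg, V_MPO, spike count) over the 21 depolarizing
    sweeps; analysis uses the final 3 s of each 5-s sweep."""
    rows = []
    for amp in currents_pA:
        tr, _ = simulate(model, state, make_step(amp, 0.0, MPO_DURATION, MPO_DURATION, dt))
        seg = tr.window(MPO_DURATION - MPO_ANALYSIS_WINDOW, MPO_DURATION)
        n_spk = count_spikes(seg)
        f_mpo, v_avg, v_mpo = mpo_spectrum(seg)
        rows.append({"i_pA": amp, "f_mpo": f_mpo, "v_avg": v_avg,
                     "v_mpo": v_mpo, "n_spikes": n_spk})
    return pd.DataFrame(rows)


def perithreshold_frequency(mpo_table: pd.DataFrame) -> float:
    """f_osc: f_MPO of the largest zero-spike sweep, provided that sweep
    oscillates; NaN when undefined (used to invalidate models)."""
    sub = mpo_table[mpo_table["n_spikes"] == 0]
    if len(sub) == 0:
        return np.nan
    row = sub.loc[sub["i_pA"].idxmax()]
    if row["f_mpo"] > 0 and row["v_mpo"] >= MPO_MIN_AMPLITUDE:
        return float(row["f_mpo"])
    return np.nan


def measure_all(
    model: CellModel,
    dt: float = DEFAULT_DT,
    stages: tuple[str, ...] = ("rest", "steps", "sag", "rin", "chirp", "mpo"),
    settled: tuple[Trace, ModelState] | None = None,
) -> MeasurementSet:
    """Run the protocol battery and assemble the :class:`MeasurementSet`.

    ``stages`` selects which protocols run (the settle stage always runs);
    skipped stages leave their measurements NaN.
    """
    m = MeasurementSet()
    if settled is None:
        settled = settle(model, SETTLE_DURATION, dt)
    rest_trace, state = settled
    m.v_rmp, m.v_sd = measure_rmp(
        rest_trace, (SETTLE_DURATION - 1000.0, SETTLE_DURATION)
    )

    if "steps" in stages:
        tr100, _ = simulate(model, state, make_step(100.0, 0.0, 500.0, 500.0, dt))
        m.n100 = count_spikes(tr100, 0.0, 500.0)
        tr400, _ = simulate(model, state, make_step(400.0, 0.0, 500.0, 500.0, dt))
        m.n400 = count_spikes(tr400, 0.0, 500.0)
        if m.n400 > 0:
            m.v_ap = measure_vap(tr400, m.v_rmp)

    if "sag" in stages:
        tr_sag, _ = simulate(
            model, state, make_step(-200.0, 100.0, 1000.0, 1200.0, dt)
        )
        m.sag = measure_sag(tr_sag, 100.0, 1000.0)

    if "rin" in stages:
        m.r_in, _ = measure_rin(model, state, m.v_rmp, dt)

    if "chirp" in stages:
        tr_chirp, _ = simulate(model, state, make_chirp(dt=dt))
        if count_spikes(tr_chirp) == 0:
            prof = impedance_profile(tr_chirp)
            m.f_r, m.q_r = prof.resonance()
            m.phi_l = prof.inductive_phase()

    if "mpo" in stages:
        m.mpo_table = mpo_scan(model, state, dt)
        m.f_osc = perithreshold_frequency(m.mpo_table)

    return m
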