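"""Synthetic ground-truth voltage traces for testing measurement code.

Each generator builds a :class:`~stellatesim.simulator.Trace` whose
measurement-relevant features are known exactly from the construction
parameters, so every measurement operation can be verified independently of
the ODE solver: flat resting traces, sinusoidal membrane-potential
oscillations of known frequency and amplitude, sag-shaped step responses
with prescribed peak and steady-state deflections, and spike trains with
prescribed spike times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from stellatesim.simulator import DEFAULT_DT, Trace

KINDS = ("flat", "sinusoid", "sag", "spikes", "composite")


@dataclass(frozen=True)
class SyntheticTraceSpec:
    """Ground-truth description of a synthetic trace.

    ``params`` per kind:
      flat:      level_mV
      sinusoid:  baseline_mV, freq_Hz, p2p_mV (peak-to-peak amplitude)
      sag:       baseline_mV, peak_deflection_mV, ss_deflection_mV,
                 onset_ms, step_ms, tau_ms, amplitude_pA
      spikes:    baseline_mV, spike_times_ms, peak_mV, width_ms
      composite: baseline_mV, freq_Hz, p2p_mV, spike_times_ms, peak_mV, width_ms
    ``noise_sd_mV`` adds white Gaussian noise (requires an rng).
    """

    kind: str
    duration_ms: float
    dt: float = DEFAULT_DT
    params: dict = field(default_factory=dict)
    noise_sd_mV: float = 0.0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unsupported synthetic trace kind: {self.kind!r}")
        if self.duration_ms <= 0 or self.dt <= 0:
            raise ValueError("duration and sampling interval must be positive")


def _sinusoid(t, baseline, freq_Hz, p2p):
    return baseline + 0.5 * p2p * np.sin(2e-3 * np.pi * freq_Hz * t)


def _paste_spikes(v, t, spike_times_ms, peak, width):
    # triangular spike waveform: guarantees a single threshold crossing
    half = width / 2.0
    for ts in np.atleast_1d(spike_times_ms):
        sel = np.abs(t - ts) <= half
        v[sel] = np.maximum(v[sel], peak * (1.0 - np.abs(t[sel] - ts) / half)
                            + v[sel] * np.abs(t[sel] - ts) / half)
    return v


def make_synthetic_trace(
    spec: SyntheticTraceSpec, rng: np.random.Generator | None = None
) -> Trace:
    """Materialize ``spec`` into a Trace (stimulus channel as specified or 0)."""
    n = int(round(spec.duration_ms / spec.dt))
    t = np.arange(1, n + 1) * spec.dt
    p = spec.params
    stim = np.zeros(n)

    if spec.kind == "flat":
        v = np.full(n, float(p.get("level_mV", -62.0)))

    elif spec.kind == "sinusoid":
        v = _sinusoid(t, p.get("baseline_mV", -55.0), p["freq_Hz"], p["p2p_mV"])

    elif spec.kind == "sag":
        baseline = p.get("baseline_mV", -62.0)
        onset = p.get("onset_ms", 100.0)
        step = p.get("step_ms", 1000.0)
        tau = p.get("tau_ms", 50.0)
        vp, vss = p["peak_deflection_mV"], p["ss_deflection_mV"]
        v = np.full(n, baseline, dtype=float)
        instep = (t > onset) & (t <= onset + step)
        ts = t[instep] - onset
        # instantaneous jump to the peak deflection relaxing to steady state
        v[instep] = baseline + vss + (vp - vss) * np.exp(-ts / tau)
        after = t > onset + step
        v[after] = baseline
        stim[instep] = p.get("amplitude_pA", -200.0)

    elif spec.kind == "spikes":
        v = np.full(n, float(p.get("baseline_mV", -62.0)))
        v = _paste_spikes(v, t, p.get("spike_times_ms", ()),
                          p.get("peak_mV", 40.0), p.get("width_ms", 2.0))

    else:  # composite: sinusoid + spike train
        v = _sinusoid(t, p.get("baseline_mV", -55.0), p["freq_Hz"], p["p2p_mV"])
        v = _paste_spikes(v, t, p.get("spike_times_ms", ()),
                          p.get("peak_mV", 40.0), p.get("width_ms", 2.0))

    if spec.noise_sd_mV > 0:
        if rng is None:
            raise ValueError("noise requested but no rng provided")
        v = v + rng.normal(0.0, spec.noise_sd_mV, size=n)

    return Trace(t, v, np.full(n, 1e-4), stim, spec.dt,
                 {"kind": f"synthetic-{spec.kind}", **{k: v for k, v in p.items()
                  if np.isscalar(v)}})


def rc_chirp_response(
    r_MOhm: float,
    c_pF: float | None = None,
    tau_ms: float = 40.0,
    chirp=None,
) -> Trace:
    """Analytic voltage response of a passive RC membrane to a chirp.

    Ground truth for impedance code: |Z(f)| = R / sqrt(1 + (2 pi f R C)^2)
    with a strictly lagging phase. The response is computed in the frequency
    domain from the exact transfer function.
    """
    from stellatesim.simulator import make_chirp

    if chirp is None:
        chirp = make_chirp()
    i = chirp.current_pA
    f = np.fft.rfftfreq(len(i), chirp.dt / 1000.0)
    tau_s = tau_ms / 1000.0
    z = (r_MOhm / 1000.0) / (1.0 + 2j * np.pi * f * tau_s)  # GOhm: mV/pA
    v = np.fft.irfft(np.fft.rfft(i) * z, n=len(i))
    return Trace(chirp.t, v, np.full(len(i), 1e-4), i, chirp.dt,
                 {"kind": "synthetic-rc", "r_MOhm": r_MOhm, "tau_ms": tau_ms})
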