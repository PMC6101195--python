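"""Compiled fixed-step integrator for the single-compartment model.

The inner loop advances the 22-dimensional state (V, 14 gate variables, 6 SK
occupancies, [Ca]) with exponential-Euler gate updates and forward-Euler
voltage/calcium updates at a fixed step (default 25 us). Voltage-dependent
gate steady states, exponential-Euler relaxation factors and the two GHK
coefficients are pre-tabulated on a fine voltage grid (0.01 mV) and linearly
interpolated, the classic rate-table optimization; table construction lives
in :mod:`stellatesim.simulator` so all kinetic formulas have a single source
in :mod:`stellatesim.channels`.

Constant-array layout (see ``simulator.compile_constants``):
  0 g_naf  1 g_kdr  2 g_hcn_slow  3 hcn_fast_ratio  4 g_nap  5 g_ka
  6 g_hva  7 g_lva  8 g_km  9 g_sk  10 g_leak  11 e_leak  12 c_m
  13 tau_ca  14 inj_scale (pA -> uA/cm2)
  15 sk_kon_per_mM  16 sk_koff  17 sk_kopen  18 sk_kclose (all /ms)
All conductances mS/cm2.
"""

import numba
import numpy as np

from stellatesim.channels import (
    CA_REST,
    CA_SHELL_DEPTH,
    E_H,
    E_K,
    E_NA,
    FARADAY,
)

N_GATES = 14
N_SK = 6

_CA_INFLUX_SCALE = -10.0 / (36.0 * CA_SHELL_DEPTH * FARADAY)
# -10000 * (uA -> mA) / (36 * dpt * F): applied directly to uA/cm2 currents

STATUS_OK = 0
STATUS_DIVERGED = 1


@numba.njit(cache=True)
def integrate_tables(
    v0,
    gates,
    sk,
    ca0,
    stim_pA,
    dt,
    const,
    minf,
    gfac,
    ghk_a,
    ghk_b,
    vmin,
    dv,
    v_out,
    ca_out,
):
    """Advance the model over ``len(stim_pA)`` steps; records post-step V/Ca.

    ``gates`` and ``sk`` are updated in place; returns
    (status, step_of_failure, final_v, final_ca).
    """
    n = stim_pA.shape[0]
    ngrid = ghk_a.shape[0]
    xmax = float(ngrid - 1) - 1e-9
    v = v0
    ca = ca0

    g_naf = const[0]
    g_kdr = const[1]
    g_hcn = const[2]
    ratio = const[3]
    g_nap = const[4]
    g_ka = const[5]
    g_hva = const[6]
    g_lva = const[7]
    g_km = const[8]
    g_sk = const[9]
    g_leak = const[10]
    e_leak = const[11]
    c_m = const[12]
    tau_ca = const[13]
    inj_scale = const[14]
    sk_kon_per_mM = const[15]
    sk_koff = const[16]
    sk_kopen = const[17]
    sk_kclose = const[18]

    for t in range(n):
        x = (v - vmin) / dv
        if x < 0.0:
            x = 0.0
        elif x > xmax:
            x = xmax
        i0 = int(x)
        w = x - i0
        w1 = 1.0 - w

        for g in range(N_GATES):
            mi = minf[g, i0] * w1 + minf[g, i0 + 1] * w
            gf = gfac[g, i0] * w1 + gfac[g, i0 + 1] * w
            gates[g] += (mi - gates[g]) * gf

        # SK Markov scheme: flux-form forward Euler conserves total occupancy
        kon = sk_kon_per_mM * ca
        f01 = kon * sk[0] - sk_koff * sk[1]
        f12 = kon * sk[1] - sk_koff * sk[2]
        f23 = kon * sk[2] - sk_koff * sk[3]
        f24 = sk_kopen * sk[2] - sk_kclose * sk[4]
        f35 = sk_kopen * sk[3] - sk_kclose * sk[5]
        sk[0] -= dt * f01
        sk[1] += dt * (f01 - f12)
        sk[2] += dt * (f12 - f23 - f24)
        sk[3] += dt * (f23 - f35)
        sk[4] += dt * f24
        sk[5] += dt * f35

        ghkdf = (ghk_a[i0] * w1 + ghk_a[i0 + 1] * w) + ca * (
            ghk_b[i0] * w1 + ghk_b[i0 + 1] * w
        )

        i_naf = g_naf * gates[0] * gates[0] * gates[0] * gates[1] * (v - E_NA)
        n2 = gates[2] * gates[2]
        i_kdr = g_kdr * n2 * n2 * (v - E_K)
        i_h = g_hcn * (gates[4] + ratio * gates[3]) * (v - E_H)
        i_nap = g_nap * gates[5] * gates[6] * (v - E_NA)
        i_ka = g_ka * gates[7] * gates[8] * (v - E_K)
        i_hva = g_hva * gates[9] * gates[9] * gates[9] * gates[10] * ghkdf
        s_ca = 0.001 / (0.001 + ca)
        i_lva = g_lva * gates[11] * gates[11] * gates[12] * s_ca * ghkdf
        i_km = g_km * gates[13] * (v - E_K)
        i_sk = g_sk * (sk[4] + sk[5]) * (v - E_K)
        i_leak = g_leak * (v - e_leak)

        i_ion = (
            i_naf + i_kdr + i_h + i_nap + i_ka + i_hva + i_lva + i_km + i_sk + i_leak
        )
        v += dt * (stim_pA[t] * inj_scale - i_ion) / c_m
        i_ca = i_hva + i_lva  # uA/cm2
        ca += dt * (_CA_INFLUX_SCALE * i_ca + (CA_REST - ca) / tau_ca)

        v_out[t] = v
        ca_out[t] = ca

        if not (-200.0 < v < 200.0) or ca <= 0.0 or v != v:
            return STATUS_DIVERGED, t, v, ca

    return STATUS_OK, n, v, ca
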