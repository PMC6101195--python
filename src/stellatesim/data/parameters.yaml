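# The 55 passive and active parameters of the layer II stellate cell model:
# hand-tuned base value plus the uniform sampling range used by the stochastic
# population search. Conductances span 0.5-2x their base value, time-constant
# scale factors 0.8-1.2x, half-maximal voltages +/-5 mV, slopes +/-20%.
# Units are as conventionally reported (mS/cm2 or uS/cm2 for conductances,
# mV for half-voltages and slopes, dimensionless scale factors).
# Note: the KM activation slope is negative; its interval is stored
# (min, max) = (-12, -8) so min <= base <= max holds.
parameters:
  # --- fast sodium (NaF) ---
  - {name: g_naf,      unit: mS/cm2, base: 4.2,    min: 2.1,    max: 8.5,    description: maximal NaF conductance}
  - {name: v_m_naf,    unit: mV,     base: -26.1,  min: -31.1,  max: -21.1,  description: NaF activation half-voltage}
  - {name: k_m_naf,    unit: mV,     base: 9.38,   min: 7.51,   max: 11.26,  description: NaF activation slope}
  - {name: f_m_naf,    unit: "",     base: 1.0,    min: 0.8,    max: 1.2,    description: NaF activation tau scale}
  - {name: v_h_naf,    unit: mV,     base: -23.8,  min: -28.8,  max: -18.8,  description: NaF inactivation half-voltage}
  - {name: k_h_naf,    unit: mV,     base: 6.1,    min: 4.9,    max: 7.3,    description: NaF inactivation slope}
  - {name: f_h_naf,    unit: "",     base: 1.0,    min: 0.8,    max: 1.2,    description: NaF inactivation tau scale}
  # --- delayed rectifier potassium (KDR) ---
  - {name: g_kdr,      unit: mS/cm2, base: 3.2,    min: 1.5,    max: 6.4,    description: maximal KDR conductance}
  - {name: v_n_kdr,    unit: mV,     base: -17.6,  min: -22.6,  max: -12.6,  description: KDR activation half-voltage}
  - {name: k_n_kdr,    unit: mV,     base: 19.6,   min: 15.7,   max: 23.6,   description: KDR activation slope}
  - {name: f_n_kdr,    unit: "",     base: 1.0,    min: 0.8,    max: 1.2,    description: KDR activation tau scale}
  # --- hyperpolarization-activated cationic (HCN) ---
  - {name: g_hcn,      unit: uS/cm2, base: 33.3,   min: 16.0,   max: 67.0,   description: maximal slow-HCN conductance}
  - {name: hcn_ms_mf,  unit: "",     base: 1.85,   min: 1.5,    max: 2.2,    description: fast-to-slow HCN conductance ratio}
  - {name: v_mf_hcn,   unit: mV,     base: 74.2,   min: 69.2,   max: 79.2,   description: fast HCN activation half-voltage (enters as V + v)}
  - {name: v_ms_hcn,   unit: mV,     base: 2.83,   min: -2.17,  max: 7.83,   description: slow HCN activation half-voltage (enters as V + v)}
  - {name: k_mf_hcn,   unit: mV,     base: 9.78,   min: 7.8,    max: 11.7,   description: fast HCN activation slope}
  - {name: k_ms_hcn,   unit: mV,     base: 15.9,   min: 12.7,   max: 19.1,   description: slow HCN activation slope}
  - {name: f_mf_hcn,   unit: "",     base: 1.0,    min: 0.8,    max: 1.2,    description: fast HCN tau scale}
  - {name: f_ms_hcn,   unit: "",     base: 1.0,    min: 0.8,    max: 1.2,    description: slow HCN tau scale}
  # --- persistent sodium (NaP) ---
  - {name: g_nap,      unit: uS/cm2, base: 34.0,   min: 17.0,   max: 68.0,   description: maximal NaP conductance}
  - {name: v_m_nap,    unit: mV,     base: 48.7,   min: 43.7,   max: 53.7,   description: NaP activation half-voltage (enters as V + v)}
  - {name: k_m_nap,    unit: mV,     base: 4.4,    min: 3.52,   max: 5.28,   description: NaP activation slope}
  - {name: f_m_nap,    unit: "",     base: 1.0,    min: 0.8,    max: 1.2,    description: NaP activation tau scale}
  - {name: v_h_nap,    unit: mV,     base: 48.8,   min: 43.8,   max: 53.8,   description: NaP inactivation half-voltage (enters as V + v)}
  - {name: k_h_nap,    unit: mV,     base: 9.9,    min: 7.9,    max: 11.9,   description: NaP inactivation slope}
  - {name: f_h_nap,    unit: "",     base: 1.0,    min: 0.8,    max: 1.2,    description: NaP inactivation tau scale}
  # --- A-type potassium (KA) ---
  - {name: g_ka,       unit: uS/cm2, base: 25.0,   min: 12.5,   max: 50.0,   description: maximal KA conductance}
  - {name: v_m_ka,     unit: mV,     base: -18.3,  min: -23.3,  max: -13.3,  description: KA activation half-voltage}
  - {name: k_m_ka,     unit: mV,     base: 15.0,   min: 12.0,   max: 18.0,   description: KA activation slope}
  - {name: f_m_ka,     unit: "",     base: 1.0,    min: 0.8,    max: 1.2,    description: KA activation tau scale}
  - {name: v_h_ka,     unit: mV,     base: -58.0,  min: -63.0,  max: -53.0,  description: KA inactivation half-voltage}
  - {name: k_h_ka,     unit: mV,     base: 8.2,    min: 6.6,    max: 9.8,    description: KA inactivation slope}
  - {name: f_h_ka,     unit: "",     base: 1.0,    min: 0.8,    max: 1.2,    description: KA inactivation tau scale}
  # --- high-voltage-activated calcium (HVA) ---
  - {name: g_hva,      unit: mS/cm2, base: 0.18,   min: 0.09,   max: 0.36,   description: maximal HVA permeability scale}
  - {name: v_m_hva,    unit: mV,     base: 11.1,   min: 6.1,    max: 16.1,   description: HVA activation half-voltage (enters as V + v)}
  - {name: k_m_hva,    unit: mV,     base: 8.4,    min: 6.7,    max: 10.0,   description: HVA activation slope}
  - {name: f_m_hva,    unit: "",     base: 1.0,    min: 0.8,    max: 1.2,    description: HVA activation tau scale}
  - {name: v_h_hva,    unit: mV,     base: 37.0,   min: 32.0,   max: 42.0,   description: HVA inactivation half-voltage (enters as V + v)}
  - {name: k_h_hva,    unit: mV,     base: 9.0,    min: 7.2,    max: 10.8,   description: HVA inactivation slope}
  - {name: f_h_hva,    unit: "",     base: 1.0,    min: 0.8,    max: 1.2,    description: HVA inactivation tau scale}
  # --- low-voltage-activated calcium (LVA) ---
  - {name: g_lva,      unit: uS/cm2, base: 90.0,   min: 41.9,   max: 167.6,  description: maximal LVA permeability scale}
  - {name: v_m_lva,    unit: mV,     base: -52.4,  min: -57.4,  max: -47.4,  description: LVA activation half-voltage}
  - {name: k_m_lva,    unit: mV,     base: 8.2,    min: 6.5,    max: 9.8,    description: LVA activation slope}
  - {name: f_m_lva,    unit: "",     base: 1.0,    min: 0.8,    max: 1.2,    description: LVA activation tau scale}
  - {name: v_h_lva,    unit: mV,     base: -88.2,  min: -93.2,  max: -83.2,  description: LVA inactivation half-voltage}
  - {name: k_h_lva,    unit: mV,     base: 6.67,   min: 5.34,   max: 8.01,   description: LVA inactivation slope}
  - {name: f_h_lva,    unit: "",     base: 1.0,    min: 0.8,    max: 1.2,    description: LVA inactivation tau scale}
  # --- M-type potassium (KM) ---
  - {name: g_km,       unit: mS/cm2, base: 0.12,   min: 0.06,   max: 0.25,   description: maximal KM conductance}
  - {name: v_m_km,     unit: mV,     base: -40.0,  min: -45.0,  max: -35.0,  description: KM activation half-voltage}
  - {name: k_m_km,     unit: mV,     base: -10.0,  min: -12.0,  max: -8.0,   description: KM activation slope (negative as printed)}
  - {name: f_m_km,     unit: "",     base: 1.0,    min: 0.8,    max: 1.2,    description: KM activation tau scale}
  # --- calcium-activated potassium (SK) ---
  - {name: g_sk,       unit: uS/cm2, base: 52.0,   min: 26.0,   max: 104.0,  description: maximal SK conductance}
  # --- passive and calcium handling ---
  - {name: r_m,        unit: kOhm.cm2, base: 40.0, min: 20.0,   max: 80.0,   description: specific membrane resistance}
  - {name: tau_ca,     unit: ms,     base: 78.0,   min: 39.0,   max: 156.0,  description: cytosolic calcium decay time constant}
  - {name: c_m,        unit: uF/cm2, base: 1.0,    min: 0.75,   max: 1.25,   description: specific membrane capacitance}
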