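# Physiologically admissible ranges for the ten intrinsic measurements of
# layer II stellate cells used to validate stochastically generated models.
# A null bound means unconstrained on that side. Comparisons are inclusive.
bounds:
  - {name: v_rmp, unit: mV,  lower: -65.0, upper: -60.0, description: resting membrane potential}
  - {name: v_sd,  unit: mV,  lower: null,  upper: 0.01,  description: SD of resting membrane potential}
  - {name: sag,   unit: "",  lower: 0.35,  upper: 0.65,  description: sag ratio (steady-state over peak deflection)}
  - {name: r_in,  unit: MOhm, lower: 35.0, upper: 65.0,  description: input resistance}
  - {name: q_r,   unit: "",  lower: null,  upper: 3.5,   description: resonance strength}
  - {name: f_r,   unit: Hz,  lower: 3.0,   upper: 12.0,  description: resonance frequency}
  - {name: f_osc, unit: Hz,  lower: 3.0,   upper: 12.0,  description: perithreshold membrane-potential-oscillation frequency}
  - {name: n100,  unit: "",  lower: 0.0,   upper: 0.0,   description: spike count for a 100-pA 500-ms step}
  - {name: n400,  unit: "",  lower: 7.0,   upper: 16.0,  description: spike count for a 400-pA 500-ms step}
  - {name: v_ap,  unit: mV,  lower: 75.0,  upper: null,  description: action potential amplitude above rest}
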