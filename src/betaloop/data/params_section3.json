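{
  "notes": "Analysis point of the cortex-STN-GPe loop model. Weights (w_SG, w_GS, w_CC, w_CS, w_GG), constant inputs (C, Str), the averaged membrane time constant tau, and the basal-ganglia sigmoid constants (M_S, B_S, M_G, B_G) are the fitted/physiological point values. The four cortical sigmoid constants (M_E, B_E, M_I, B_I) are known only as physiological ranges (M_E in [50,80], B_E in [0,20], M_I in [20,330], B_I in [0,20] spk/s); the values here are the package's calibrated completion, selected by scan_and_io.calibrate_cortical_constants so that the minimal critical transmission delay of the loop equals 3.6807 ms with the onset carried by the STN-GPe loop and a later cortical-loop crossing. T is left at the critical delay; override it for simulations.",
  "tau": 10.0,
  "w_SG": 2.56,
  "w_GS": 3.22,
  "w_CC": 2.75,
  "w_CS": 6.6,
  "w_GG": 0.9,
  "C": 277.94,
  "Str": 40.51,
  "M_S": 300.0,
  "B_S": 10.0,
  "M_G": 400.0,
  "B_G": 20.0,
  "M_E": 80.0,
  "B_E": 20.0,
  "M_I": 100.0,
  "B_I": 0.47216082644523416,
  "T": 3.6807
}
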