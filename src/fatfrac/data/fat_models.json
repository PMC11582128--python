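{
  "peanut_oil_phantom_9peak": {
    "description": "9-peak peanut-oil/agarose phantom fat spectrum measured by STEAM MRS at 7 T; frequency shifts in ppm relative to water, amplitudes normalized to unit sum.",
    "shift_ppm": [-3.93, -3.51, -3.22, -2.79, -2.57, -2.05, -0.73, -0.51, 0.52],
    "rel_amp":   [0.082, 0.623, 0.015, 0.096, 0.048, 0.009, 0.026, 0.018, 0.083]
  },
  "subcutaneous_invivo_8peak": {
    "description": "8-peak subcutaneous adipose tissue fat spectrum measured by STEAM MRS at 7 T in the calf; shifts in ppm relative to water.",
    "shift_ppm": [-3.66, -3.24, -2.91, -2.49, -2.27, -1.71, -0.39, 0.78],
    "rel_amp":   [0.083, 0.688, 0.010, 0.098, 0.042, 0.006, 0.013, 0.060]
  },
  "single_peak": {
    "description": "Single dominant methylene peak at -3.3 ppm; the model used for NSA* echo-time optimization maps.",
    "shift_ppm": [-3.3],
    "rel_amp":   [1.0]
  }
}
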