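{
 "name": "bioreactor_bega",
 "description": "Weight loss (%) of a D-mannose glycopolymer degrading in a bioreactor fed with Bega River water.",
 "times": [
  0,
  2,
  3,
  6,
  7,
  8,
  9,
  10,
  14,
  15,
  16,
  17,
  20,
  21,
  22,
  23
 ],
 "values": [
  0,
  33.339,
  34.055,
  34.187,
  34.621,
  35.267,
  36.797,
  36.8,
  41.924,
  42,
  43.581,
  52.419,
  55.4,
  55.4,
  60.17,
  60.647
 ],
 "interpolated": [
  false,
  false,
  false,
  false,
  false,
  false,
  false,
  false,
  false,
  false,
  false,
  false,
  false,
  false,
  false,
  false
 ],
 "reference_params": {
  "w1_inf": 35.448,
  "T1": 0.7459,
  "tau": 12.3486,
  "w2_inf": 48.849,
  "T2": 14.6307,
  "w0": 0.0
 },
 "initial_guess": null,
 "reference_cw": [
  0,
  33.0208,
  34.8129,
  35.4366,
  35.445,
  35.4472,
  35.4478,
  35.4479,
  40.6618,
  43.5446,
  46.237,
  48.7515,
  55.3413,
  57.2543,
  59.0409,
  60.7095
 ],
 "reference_dw": [
  0,
  0.3182,
  -0.7579,
  -1.2496,
  -0.824,
  -0.1802,
  1.3492,
  1.3521,
  1.2622,
  -1.5446,
  -2.656,
  3.6675,
  0.0587,
  -1.8543,
  1.1291,
  -0.0625
 ],
 "reference_panel": {
  "rmse": 1.4959,
  "mse": 2.2376,
  "r2": 0.9892,
  "r": 0.9945,
  "rae": 0.0188
 },
 "notes": "reference_panel is the published indicator row for the double-exponential dead-time model on this dataset and is reproducible from the stored series and parameters."
}
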