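{
  "comment": "Ring-current intensity factors relative to benzene. 'DC-H' is the proton set; 'calibrated-N' is the 15N set recalibrated against the base-pair triplet lookup table.",
  "zbar_angstrom": 0.64,
  "radius_angstrom": {"six_membered": 1.39, "five_membered": 1.182},
  "sets": {
    "DC-H": {"Gua-5": 0.81, "Gua-6": 0.49, "Ade-5": 0.95, "Ade-6": 0.83, "Cyt": 0.31, "Ura": 0.24},
    "calibrated-N": {"Gua-5": 2.60, "Gua-6": 0.11, "Ade-5": 3.57, "Ade-6": 0.06, "Cyt": 0.84, "Ura": 1.32}
  }
}
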