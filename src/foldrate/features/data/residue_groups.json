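{
  "g1": "ILMV",
  "g2": "DE",
  "g3": "FWY",
  "g4": "NQSC",
  "g5": "HKR",
  "g6": "AGPT"
}
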