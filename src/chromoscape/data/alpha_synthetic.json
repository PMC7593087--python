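{
  "comment": "Synthetic stand-in type-type interaction table (epsilon units). The trained per-pair values are not reproduced here; this constructed set honours the published ordering constraint: B-B contacts are the most favourable, A-A and A-B are comparable to each other and significantly weaker.",
  "alpha": {
    "A1-A1": -0.27,
    "A1-A2": -0.27,
    "A1-B1": -0.26,
    "A1-B2": -0.26,
    "A1-B3": -0.26,
    "A2-A2": -0.28,
    "A2-B1": -0.27,
    "A2-B2": -0.27,
    "A2-B3": -0.28,
    "B1-B1": -0.30,
    "B1-B2": -0.30,
    "B1-B3": -0.31,
    "B2-B2": -0.33,
    "B2-B3": -0.36,
    "B3-B3": -0.44
  }
}
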