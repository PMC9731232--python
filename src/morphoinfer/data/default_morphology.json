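{
  "slot_types": ["head", "pharynx", "intestine", "intestine", "intestine", "intestine", "pharynx", "tail"],
  "ex_star": [
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    [3.5, 2.5, 1.5, 0.5, -0.5, -1.5, -2.5, -3.5]
  ],
  "expression_amplitude": 4.0,
  "tau": 2.0,
  "k": 0.5
}
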