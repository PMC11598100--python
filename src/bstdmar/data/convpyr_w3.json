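{
  "h1": [
    0.04628984628883405,
    0.20521529555705875,
    0.3101541019326432,
    0.20521529555705875,
    0.04628984628883405
  ],
  "h2": [
    -0.03346512652282566,
    -0.3938486187526605,
    -0.6898416230454034,
    -0.3938486187526605,
    -0.03346512652282566
  ],
  "g": [
    0.47013827291344923,
    1.815093459201285,
    0.47013827291344923
  ],
  "weight_exponent": 3.0
}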