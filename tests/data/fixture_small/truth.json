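{
  "center_distribution": [
    0.008258258258258256,
    0.2263813813813814,
    0.23045545545545545,
    0.23175675675675675,
    0.0038638638638638628,
    0.007077077077077075,
    0.22727227227227229,
    0.0059659659659659645,
    0.0058458458458458444,
    0.009669669669669667,
    0.0024224224224224217,
    0.004064064064064063,
    0.004704704704704704,
    0.0039339339339339325,
    0.005535535535535534,
    0.006566566566566565,
    0.005345345345345343,
    0.006876876876876875,
    0.0010810810810810809,
    0.0029229229229229222,
    0.0
  ],
  "n_positive": 11,
  "sites": {
    "synth_0000": [
      1,
      5
    ],
    "synth_0001": [
      22,
      25,
      55
    ],
    "synth_0002": [
      57
    ],
    "synth_0003": [
      6,
      31
    ],
    "synth_0004": [
      7,
      20,
      53
    ]
  },
  "spec": {
    "L": 7,
    "background": null,
    "chain_length": 60,
    "flank_emissions": {},
    "margin": 0,
    "n_chains": 5,
    "preferred": "CHDE",
    "rsa_max": 0.85,
    "rsa_neg": [
      [
        0.12,
        0.08,
        0.3
      ],
      [
        0.45,
        0.15,
        0.4
      ],
      [
        0.7,
        0.08,
        0.3
      ]
    ],
    "rsa_pos": [
      [
        0.25,
        0.04,
        0.4
      ],
      [
        0.35,
        0.04,
        0.3
      ],
      [
        0.45,
        0.04,
        0.3
      ]
    ],
    "seed": 0,
    "site_density": 2.0,
    "ss_neg": {
      "C": 0.4,
      "E": 0.25,
      "H": 0.35
    },
    "ss_pos": {
      "C": 0.8,
      "E": 0.1,
      "H": 0.1
    },
    "theta": 0.9,
    "with_annotations": true
  }
}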