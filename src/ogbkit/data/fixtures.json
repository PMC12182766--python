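{
  "fixtures": {
    "Xenograft Collagen": {
      "target_W_mA": 129.27,
      "target_W_mB": 87.47,
      "target_AC_A": 0.997,
      "micropore_volume": 10.945,
      "regime": "MIXED",
      "target_C_C": 1.24
    },
    "Osteon II": {
      "target_W_mA": 93.63,
      "target_W_mB": 31.73,
      "target_AC_A": 0.803,
      "micropore_volume": 0.124,
      "regime": "MACRO",
      "target_C_C": 1.69
    },
    "Maxresorb": {
      "target_W_mA": 115.10,
      "target_W_mB": 41.93,
      "target_AC_A": 0.753,
      "micropore_volume": 0.128,
      "regime": "MACRO",
      "target_C_C": 1.28
    },
    "MSP": {
      "target_W_mA": 80.12,
      "target_W_mB": 28.60,
      "target_AC_A": 0.681,
      "micropore_volume": 0.715,
      "regime": "MACRO",
      "target_C_C": 1.03
    },
    "Cerabone": {
      "target_W_mA": 59.13,
      "target_W_mB": 19.10,
      "target_AC_A": 0.563,
      "micropore_volume": 0.525,
      "regime": "MACRO",
      "target_C_C": 1.25
    },
    "Bio-OSS": {
      "target_W_mA": 131.13,
      "target_W_mB": 59.00,
      "target_AC_A": 0.703,
      "micropore_volume": 88.226,
      "regime": "MICRO",
      "target_C_C": 1.02
    }
  },
  "reference_degassing": {
    "description": "Nine-time-point mean percentages of the remaining liquid volume during passive degassing of the reference fraction, with 95 % confidence-interval bounds over triplicates.",
    "t_min": [0.0, 2.5, 5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0],
    "mean_pct": [100.0, 99.6, 98.3, 95.9, 91.2, 85.0, 82.3, 81.5, 81.3],
    "ci_low_pct": [100.0, 98.2, 96.4, 93.3, 87.7, 82.4, 80.7, 79.1, 80.4],
    "ci_high_pct": [100.0, 101.0, 100.3, 98.4, 94.6, 87.7, 84.0, 83.9, 82.1]
  }
}
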