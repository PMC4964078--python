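{
  "name": "oncotype",
  "description": "Unscaled Oncotype DX recurrence-score group structure: 16 prognostic genes in 7 weighted groups. Housekeeping normalizers (ACTB, GAPDH, TFRC, RPLP0, GUS) are intentionally absent; group floors and the 0-100 rescaling are omitted because scoring operates on per-gene Z values.",
  "groups": {
    "grb7": {
      "coefficient": 0.47,
      "divisor": 1.0,
      "direction": "poor",
      "weights": {"GRB7": 0.9, "ERBB2": 0.1}
    },
    "er": {
      "coefficient": -0.34,
      "divisor": 3.2,
      "direction": "good",
      "weights": {"ESR1": 0.8, "PGR": 1.2, "BCL2": 1.0, "SCUBE2": 1.0}
    },
    "proliferation": {
      "coefficient": 1.04,
      "divisor": 5.0,
      "direction": "poor",
      "weights": {"BIRC5": 1.0, "MKI67": 1.0, "MYBL2": 1.0, "CCNB1": 1.0, "AURKA": 1.0}
    },
    "invasion": {
      "coefficient": 0.1,
      "divisor": 2.0,
      "direction": "poor",
      "weights": {"CTSL2": 1.0, "MMP11": 1.0}
    },
    "cd68": {
      "coefficient": 0.05,
      "divisor": 1.0,
      "direction": "poor",
      "weights": {"CD68": 1.0}
    },
    "gstm1": {
      "coefficient": -0.08,
      "divisor": 1.0,
      "direction": "good",
      "weights": {"GSTM1": 1.0}
    },
    "bag1": {
      "coefficient": -0.07,
      "divisor": 1.0,
      "direction": "good",
      "weights": {"BAG1": 1.0}
    }
  }
}
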