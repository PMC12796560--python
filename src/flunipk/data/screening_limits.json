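{
  "description": "Screening-limit scenario set: regulatory plasma/urine thresholds (ng/mL) compared in the detection-time analyses. operational_rss = urine_sl / plasma_sl.",
  "version": 1,
  "pairs": [
    {"label": "ifha_isl",      "plasma_sl": 1.0, "urine_sl": 100.0},
    {"label": "candidate_2_70", "plasma_sl": 2.0, "urine_sl": 70.0},
    {"label": "candidate_3_100", "plasma_sl": 3.0, "urine_sl": 100.0},
    {"label": "hisa",          "plasma_sl": 4.0, "urine_sl": 100.0},
    {"label": "rmtc",          "plasma_sl": 5.0, "urine_sl": 100.0}
  ]
}
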