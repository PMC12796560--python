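{
  "description": "Published population parameters for flunixin IV disposition in horses (three-compartment model, joint plasma-urine fit). theta/omega order: V1, V2, V3, Cl, Cl2, Cl3, Rss. Volumes mL/kg, clearances mL/kg/h, Rss dimensionless. omega is the full covariance matrix of log-scale between-subject random effects.",
  "version": 1,
  "parameter_names": ["V1", "V2", "V3", "Cl", "Cl2", "Cl3", "Rss"],
  "theta": [121.00, 8.90, 31.68, 47.36, 0.22, 7.54, 35.93],
  "omega": [
    [0.032,  0.047,  0.011,  0.030, -0.016, -0.027,  0.083],
    [0.047,  0.335,  0.070,  0.051,  0.181,  0.049,  0.098],
    [0.011,  0.070,  0.140,  0.032,  0.117,  0.190,  0.000],
    [0.030,  0.051,  0.032,  0.085,  0.050,  0.030,  0.151],
    [-0.016, 0.181,  0.117,  0.050,  0.303,  0.237,  0.030],
    [-0.027, 0.049,  0.190,  0.030,  0.237,  0.352, -0.035],
    [0.083,  0.098,  0.000,  0.151,  0.030, -0.035,  0.683]
  ],
  "sigma_plasma_prop": 0.15,
  "sigma_plasma_add": 0.12,
  "sigma_urine_prop": 0.42,
  "sigma_urine_add": 0.11
}
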