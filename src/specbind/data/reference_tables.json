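{
  "description": "Published derived quantities for the trametinib-HSA system, used by the reproduce command as its fixture input.",
  "tau0_ns": 5.073,
  "stern_volmer": [
    {"temperature_K": 298, "k_sv_per_M": 67020.0, "k_sv_se_per_M": 300.0, "r_corr": 0.9979, "k_q_per_M_s": 1.321e13},
    {"temperature_K": 304, "k_sv_per_M": 59810.0, "k_sv_se_per_M": 170.0, "r_corr": 0.9936, "k_q_per_M_s": 1.179e13},
    {"temperature_K": 310, "k_sv_per_M": 56640.0, "k_sv_se_per_M": 230.0, "r_corr": 0.9957, "k_q_per_M_s": 1.116e13}
  ],
  "lifetimes": [
    {"quencher_uM": 0.0, "tau_ns": [3.102, 0.604, 6.796], "alpha": [0.362, 0.062, 0.576], "avg_tau_ns": 5.073, "chi2": 1.093},
    {"quencher_uM": 4.0, "tau_ns": [2.926, 0.440, 6.662], "alpha": [0.403, 0.050, 0.547], "avg_tau_ns": 4.846, "chi2": 1.054},
    {"quencher_uM": 8.0, "tau_ns": [2.962, 0.544, 6.648], "alpha": [0.426, 0.059, 0.515], "avg_tau_ns": 4.717, "chi2": 1.106}
  ],
  "binding": [
    {"temperature_K": 298, "k_per_M": 68260.0, "n_sites": 1.049, "r_corr": 0.9968, "delta_g_kj": -27.53},
    {"temperature_K": 304, "k_per_M": 36180.0, "n_sites": 1.024, "r_corr": 0.9921, "delta_g_kj": -26.69},
    {"temperature_K": 310, "k_per_M": 23340.0, "n_sites": 1.016, "r_corr": 0.9937, "delta_g_kj": -25.86}
  ],
  "thermodynamics": {"delta_h_kj": -68.93, "delta_s_j": -138.95},
  "eem_peaks": {
    "free_protein": [
      {"peak": "I", "ex_nm": 280, "em_nm": 338, "intensity": 587.254},
      {"peak": "II", "ex_nm": 225, "em_nm": 340, "intensity": 728.174}
    ],
    "with_ligand": [
      {"peak": "I", "ex_nm": 280, "em_nm": 337, "intensity": 514.769},
      {"peak": "II", "ex_nm": 225, "em_nm": 338, "intensity": 411.384}
    ]
  },
  "alpha_helix_pct_approx": 53.0
}
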