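{
  "version": 1,
  "description": "Phenomenological coating parameters per protocol regime. Values are invented calibrations constrained by the qualitative velocity orderings and linear/step-out structure of each regime; magnitudes are schematic.",
  "beta_ref": 0.5,
  "qualitative": {
    "sweep_1_19": {"at_f": 19.0, "fastest": "biotin_peg3_amine", "slowest": "biotin"},
    "sweep_10_100": {"from_f": 50.0, "fastest": "biotin_chitosan"},
    "beta_sweep_14Hz": {"non_monotone_in_inv_beta": ["biotin_chitosan"]}
  },
  "regimes": {
    "sweep_1_19": {
      "avidin": {"c": 0.30, "f_c0": 60.0, "p": 0.5, "sigma_U": 0.10, "B_th": 0.1, "g_shape": 0.02},
      "biotin": {"c": 0.22, "f_c0": 60.0, "p": 0.5, "sigma_U": 0.10, "B_th": 0.1, "g_shape": 0.02},
      "biotin_peg3_amine": {"c": 0.40, "f_c0": 60.0, "p": 0.5, "sigma_U": 0.12, "B_th": 0.1, "g_shape": 0.12},
      "biotin_chitosan": {"c": 0.31, "f_c0": 60.0, "p": 0.5, "sigma_U": 0.30, "B_th": 0.1, "g_shape": 0.12}
    },
    "sweep_5_50": {
      "avidin": {"c": 0.22, "f_c0": 150.0, "p": 0.5, "sigma_U": 0.10, "B_th": 0.1, "g_shape": 0.02},
      "biotin": {"c": 0.22, "f_c0": 150.0, "p": 0.5, "sigma_U": 0.10, "B_th": 0.1, "g_shape": 0.02},
      "biotin_peg3_amine": {"c": 0.16, "f_c0": 150.0, "p": 0.5, "sigma_U": 0.10, "B_th": 0.1, "g_shape": 0.12},
      "biotin_chitosan": {"c": 0.42, "f_c0": 150.0, "p": 0.5, "sigma_U": 0.10, "B_th": 0.1, "g_shape": 0.12}
    },
    "sweep_10_100": {
      "avidin": {"c": 0.24, "f_c0": 160.0, "p": 0.6, "sigma_U": 0.10, "B_th": 0.1, "g_shape": 0.02},
      "biotin": {"c": 0.30, "f_c0": 160.0, "p": 0.6, "sigma_U": 0.10, "B_th": 0.1, "g_shape": 0.02},
      "biotin_peg3_amine": {"c": 0.23, "f_c0": 160.0, "p": 0.6, "sigma_U": 0.10, "B_th": 0.1, "g_shape": 0.12},
      "biotin_chitosan": {"c": 0.40, "f_c0": 160.0, "p": 0.6, "sigma_U": 0.10, "B_th": 0.1, "g_shape": 0.12}
    },
    "beta_sweep_14Hz": {
      "avidin": {"c": 0.26, "f_c0": 35.0, "p": 1.0, "sigma_U": 0.10, "B_th": 0.1, "g_shape": 0.02},
      "biotin": {"c": 0.24, "f_c0": 30.0, "p": 1.0, "sigma_U": 0.10, "B_th": 0.1, "g_shape": 0.02, "bump_amp": 0.25, "bump_inv_beta": 3.0, "bump_width": 1.0},
      "biotin_peg3_amine": {"c": 0.30, "f_c0": 35.0, "p": 1.0, "sigma_U": 0.10, "B_th": 0.1, "g_shape": 0.12},
      "biotin_chitosan": {"c": 0.32, "f_c0": 30.0, "p": 1.0, "sigma_U": 0.12, "B_th": 0.1, "g_shape": 0.12, "bump_amp": 0.8, "bump_inv_beta": 3.0, "bump_width": 1.0}
    },
    "static_sweep_15Hz": {
      "avidin": {"c": 0.28, "f_c0": 40.0, "p": 0.5, "sigma_U": 0.10, "B_th": 0.1, "g_shape": 0.02},
      "biotin": {"c": 0.24, "f_c0": 40.0, "p": 0.5, "sigma_U": 0.10, "B_th": 0.1, "g_shape": 0.02},
      "biotin_peg3_amine": {"c": 0.34, "f_c0": 40.0, "p": 0.5, "sigma_U": 0.10, "B_th": 0.1, "g_shape": 0.12},
      "biotin_chitosan": {"c": 0.30, "f_c0": 40.0, "p": 0.5, "sigma_U": 0.10, "B_th": 0.1, "g_shape": 0.12}
    }
  }
}
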