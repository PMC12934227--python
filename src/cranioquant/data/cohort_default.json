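{
  "age_split": 20.0,
  "arms": [
    {
      "group": "MLD",
      "n_subjects": 20,
      "sex_ratio_male": 0.34,
      "entry_age_range": [4.0, 12.0],
      "n_scans": 3,
      "scan_interval_years": 2.0,
      "icv_intercept": {"mean": 1250.0, "sd": 100.0, "male_offset": 80.0},
      "thickness_intercept": {"mean": 5.0, "sd": 0.8, "male_offset": -0.2},
      "d_icv": {"under20": [-18.8, 22.4], "over20": [-4.01, 8.29]},
      "d_thickness": {"under20": [0.10, 0.25], "over20": [0.16, 0.14]},
      "icv_noise_sd": 7.0,
      "thickness_noise_sd": 0.05
    },
    {
      "group": "MLD",
      "n_subjects": 14,
      "sex_ratio_male": 0.34,
      "entry_age_range": [22.0, 45.0],
      "n_scans": 3,
      "scan_interval_years": 2.0,
      "icv_intercept": {"mean": 1350.0, "sd": 110.0, "male_offset": 130.0},
      "thickness_intercept": {"mean": 6.5, "sd": 0.9, "male_offset": -0.3},
      "d_icv": {"under20": [-18.8, 22.4], "over20": [-4.01, 8.29]},
      "d_thickness": {"under20": [0.10, 0.25], "over20": [0.16, 0.14]},
      "icv_noise_sd": 7.0,
      "thickness_noise_sd": 0.05
    },
    {
      "group": "MS",
      "n_subjects": 199,
      "sex_ratio_male": 0.336,
      "entry_age_range": [25.0, 55.0],
      "n_scans": 3,
      "scan_interval_years": 2.0,
      "icv_intercept": {"mean": 1350.0, "sd": 110.0, "male_offset": 130.0},
      "thickness_intercept": {"mean": 6.5, "sd": 0.9, "male_offset": -0.3},
      "d_icv": {"under20": [0.0, 0.0], "over20": [-2.99, 2.69]},
      "d_thickness": {"under20": [0.0, 0.0], "over20": [0.04, 0.09]},
      "icv_noise_sd": 7.0,
      "thickness_noise_sd": 0.05
    },
    {
      "group": "control",
      "n_subjects": 12,
      "sex_ratio_male": 0.48,
      "entry_age_range": [4.0, 12.0],
      "n_scans": 3,
      "scan_interval_years": 2.0,
      "icv_intercept": {"mean": 1250.0, "sd": 100.0, "male_offset": 80.0},
      "thickness_intercept": {"mean": 5.0, "sd": 0.8, "male_offset": -0.2},
      "d_icv": {"under20": [38.2, 29.5], "over20": [-1.36, 2.51]},
      "d_thickness": {"under20": [0.007, 0.14], "over20": [-0.003, 0.064]},
      "icv_noise_sd": 7.0,
      "thickness_noise_sd": 0.05
    },
    {
      "group": "control",
      "n_subjects": 52,
      "sex_ratio_male": 0.48,
      "entry_age_range": [25.0, 55.0],
      "n_scans": 3,
      "scan_interval_years": 2.0,
      "icv_intercept": {"mean": 1350.0, "sd": 110.0, "male_offset": 130.0},
      "thickness_intercept": {"mean": 6.5, "sd": 0.9, "male_offset": -0.3},
      "d_icv": {"under20": [38.2, 29.5], "over20": [-1.36, 2.51]},
      "d_thickness": {"under20": [0.007, 0.14], "over20": [-0.003, 0.064]},
      "icv_noise_sd": 7.0,
      "thickness_noise_sd": 0.05
    }
  ]
}
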