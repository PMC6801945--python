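{
  "version": 1,
  "description": "Published English calibration coefficient set (median quantile regression of device percent time on school stage, sex, and composite recall score). Units: percent time per unit predictor; sex coded 0 = boy, 1 = girl.",
  "coefficients": [
    {
      "outcome": "in_school",
      "values": {
        "intercept_primary": 45.51,
        "intercept_secondary": 13.72,
        "sex_coef": -11.34,
        "yap_by_primary": 1.78,
        "yap_by_secondary": 7.31
      },
      "standard_errors": {
        "intercept_primary": 9.14,
        "intercept_secondary": 5.58,
        "sex_coef": 2.47,
        "yap_by_primary": 2.33,
        "yap_by_secondary": 1.66
      },
      "tau": 0.5,
      "n": 200
    },
    {
      "outcome": "out_of_school",
      "values": {
        "intercept_primary": 12.75,
        "intercept_secondary": 2.61,
        "sex_coef": -1.61,
        "yap_by_primary": 2.01,
        "yap_by_secondary": 4.44
      },
      "standard_errors": {
        "intercept_primary": 5.01,
        "intercept_secondary": 3.41,
        "sex_coef": 1.95,
        "yap_by_primary": 2.06,
        "yap_by_secondary": 1.18
      },
      "tau": 0.5,
      "n": 196
    },
    {
      "outcome": "weekend",
      "values": {
        "intercept_primary": 15.17,
        "intercept_secondary": 8.44,
        "sex_coef": -4.33,
        "yap_by_primary": 1.13,
        "yap_by_secondary": 1.44
      },
      "standard_errors": {
        "intercept_primary": 5.02,
        "intercept_secondary": 3.18,
        "sex_coef": 1.56,
        "yap_by_primary": 1.22,
        "yap_by_secondary": 0.90
      },
      "tau": 0.5,
      "n": 187
    },
    {
      "outcome": "sb_out_of_school",
      "values": {
        "intercept_primary": 34.92,
        "intercept_secondary": 48.95,
        "sex_coef": 1.61,
        "yap_by_primary": -0.84,
        "yap_by_secondary": 5.65
      },
      "standard_errors": {
        "intercept_primary": 12.71,
        "intercept_secondary": 8.91,
        "sex_coef": 2.99,
        "yap_by_primary": 5.22,
        "yap_by_secondary": 2.54
      },
      "tau": 0.5,
      "n": 196
    }
  ]
}
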