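{
  "version": 1,
  "comment": "Printed constants from the source study's tables; fixtures, not computed values.",
  "adjusted_params": {"r": 0.0374286, "K": 225062093.9465337, "N0": 76398000},
  "initial_fitted": {"K": 230343677.2780429, "r": 0.0356036},
  "initial_initial": {"K": 230343707.2780429, "r": 0.036006736285777},
  "adjusted_initial": {"K": 230305033.7788595, "r": 0.036182814238104},
  "census_2022": {"initial": 165158616, "adjusted": 170000000},
  "sri_lanka_2020": 21413249,
  "census_years_bangladesh": [1974, 1981, 1991, 2001, 2011, 2022],
  "table2_flagged": {
    "initial": {"epsilon": 0.1, "delta": 0.2, "Delta": 0.002120635, "ambiguous": false},
    "adjusted": {
      "raw": "0.70.00160095945",
      "epsilon_candidate": 0.7,
      "delta_candidate": 0.0016009594,
      "ambiguous": true,
      "note": "row typographically garbled in the source; delta scale (absolute vs fraction of K0) undecidable"
    }
  },
  "scheme_table_values": {
    "bangladesh_initial_2022": {
      "census": 165158616.0,
      "logistic": 164250406.1566,
      "pece": 164250406.1568,
      "fractional": 164082545.7138,
      "multiscale": 165158616.0541,
      "percent_error": {"logistic": 0.55, "pece": 0.55, "fractional": 0.65, "multiscale": 3e-08}
    },
    "bangladesh_adjusted_2022": {
      "census": 170000000.0,
      "logistic": 170145565.0601,
      "pece": 170145565.0603,
      "fractional": 169990102.5184,
      "multiscale": 170000000.0009,
      "percent_error": {"logistic": 0.09, "pece": 0.09, "fractional": 0.006, "multiscale": 5e-10}
    },
    "sri_lanka_2020": {
      "census": 21413249.0,
      "logistic": 21438307.51789,
      "pece": 21438307.51789,
      "fractional": 21426601.72682,
      "multiscale": 21413249.35605,
      "percent_error": {"logistic": 0.12, "pece": 0.12, "fractional": 0.06, "multiscale": 2e-06}
    }
  },
  "fps_table": {
    "r0=0.0374286": 216.887,
    "r0=0.03": 212.776,
    "r0=0.02": 204.131,
    "r0=0.01": 190.396
  },
  "stability_constants": {"psi": 0.06283730012, "hyers_ulam": 0.17494684266, "alpha": 0.5, "b": 10, "normalization": 1}
}
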