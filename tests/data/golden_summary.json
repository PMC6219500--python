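{
  "annotation": {
    "enrichment": [
      {
        "K": 20,
        "N": 889,
        "fold": 0.0,
        "k": 0,
        "label": "D",
        "n": 10,
        "p_value": 0.7955555903,
        "track": "DHS"
      },
      {
        "K": 18,
        "N": 889,
        "fold": 4.938888889,
        "k": 1,
        "label": "E",
        "n": 10,
        "p_value": 0.1858464202,
        "track": "TFBS"
      },
      {
        "K": 75,
        "N": 889,
        "fold": 3.556,
        "k": 3,
        "label": "E",
        "n": 10,
        "p_value": 0.04492628552,
        "track": "repeat"
      },
      {
        "K": 13,
        "N": 889,
        "fold": 0.0,
        "k": 0,
        "label": "D",
        "n": 10,
        "p_value": 0.8623724102,
        "track": "SINE"
      },
      {
        "K": 46,
        "N": 889,
        "fold": 1.932608696,
        "k": 1,
        "label": "E",
        "n": 10,
        "p_value": 0.4137947339,
        "track": "LINE"
      },
      {
        "K": 16,
        "N": 889,
        "fold": 11.1125,
        "k": 2,
        "label": "E",
        "n": 10,
        "p_value": 0.01257250041,
        "track": "LTR"
      }
    ],
    "island_context_counts": {
      "island": 19,
      "open_sea": 759,
      "shelf": 55,
      "shore": 56
    },
    "n_proximal": 156
  },
  "binning": {
    "n_bins_universe": 889,
    "n_cpgs_covered": 2595,
    "n_samples": 16
  },
  "clustering": {
    "chi_square": 80.0,
    "p_value": 3.744097384e-19,
    "tnr": 1.0,
    "tpr": 1.0
  },
  "config_hash": "16933dfb98ba",
  "conservation_bootstrap_p": 0.5572139303,
  "derived_sets": {
    "cancer_shared": 6,
    "cl_specific": 6,
    "cl_specific_in_nl_nb": 0,
    "phenotype_shared": 10
  },
  "dmr_counts": {
    "CB-NB": {
      "hyper": 4,
      "hypo": 2,
      "n_dmrs": 6
    },
    "CL-CB": {
      "hyper": 12,
      "hypo": 4,
      "n_dmrs": 16
    },
    "CL-NB": {
      "hyper": 16,
      "hypo": 7,
      "n_dmrs": 23
    },
    "CL-NL": {
      "hyper": 9,
      "hypo": 4,
      "n_dmrs": 13
    },
    "NL-CB": {
      "hyper": 9,
      "hypo": 7,
      "n_dmrs": 16
    },
    "NL-NB": {
      "hyper": 7,
      "hypo": 3,
      "n_dmrs": 10
    }
  },
  "overlaps": {
    "CL-CB_vs_CL-NL": {
      "direction_concordant_overlap": 6,
      "fisher_p": 1.903624665e-08,
      "n_a": 16,
      "n_b": 13,
      "n_overlap": 6,
      "n_union": 23,
      "odds_ratio": 74.22857143,
      "percent_overlap": 0.2608695652,
      "set_a": "CL-CB",
      "set_b": "CL-NL",
      "universe": 889
    },
    "CL-NL_vs_CB-NB": {
      "direction_concordant_overlap": 6,
      "fisher_p": 2.545553188e-12,
      "n_a": 13,
      "n_b": 6,
      "n_overlap": 6,
      "n_union": 13,
      "odds_ratio": 1e+300,
      "percent_overlap": 0.4615384615,
      "set_a": "CL-NL",
      "set_b": "CB-NB",
      "universe": 889
    },
    "NL-NB_vs_CL-CB": {
      "direction_concordant_overlap": 10,
      "fisher_p": 9.915888254e-20,
      "n_a": 10,
      "n_b": 16,
      "n_overlap": 10,
      "n_union": 16,
      "odds_ratio": 1e+300,
      "percent_overlap": 0.625,
      "set_a": "NL-NB",
      "set_b": "CL-CB",
      "universe": 889
    }
  },
  "seed": 5,
  "signature": {
    "auc": 1.0,
    "chosen_lambda": 0.0009118819656,
    "fisher_p": 7.396023011e-07,
    "n_probes_selected": 8,
    "tnr": 1.0,
    "tpr": 1.0
  },
  "simulated": {
    "n_regions_planted": 22,
    "n_samples": 16
  },
  "version": "0.1.0"
}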