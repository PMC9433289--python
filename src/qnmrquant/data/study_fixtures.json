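{
  "description": "Published worked-example data for the furanone/vanillin internal-standard quantitation: analyte descriptions, accuracy and precision tables, and the extract quantitation inputs.",
  "analytes": {
    "furanone": {
      "name": "5-hydroxymethyl-2(5H)-furanone",
      "molecular_weight": 114.10,
      "purity": 0.98,
      "enantiomer_ratio": [0.9690, 0.0310],
      "signals": [
        {"label": "H2", "center_shift": 6.16, "couplings": [5.7, 1.5], "n_protons": 1, "linewidth": 1.0, "t1": 0.5},
        {"label": "H3", "center_shift": 7.50, "couplings": [5.7, 1.5], "n_protons": 1, "linewidth": 1.0, "t1": 0.5},
        {"label": "H4", "center_shift": 5.17, "couplings": [1.5, 3.8, 5.1], "n_protons": 1, "linewidth": 1.0, "t1": 0.5},
        {"label": "H5a", "center_shift": 4.01, "couplings": [12.3, 3.8], "n_protons": 1, "linewidth": 1.0, "t1": 0.5},
        {"label": "H5b", "center_shift": 3.80, "couplings": [12.3, 5.1], "n_protons": 1, "linewidth": 1.0, "t1": 0.5}
      ]
    },
    "vanillin": {
      "name": "vanillin",
      "molecular_weight": 152.15,
      "purity": 0.99,
      "signals": [
        {"label": "CHO", "center_shift": 9.77, "couplings": [], "n_protons": 1, "linewidth": 1.0, "t1": 0.9}
      ]
    }
  },
  "acquisition": {
    "spectrometer_frequency": 400.132,
    "spectral_width": 6410.0,
    "flip_angle": 30.0,
    "acquisition_time": 2.56,
    "relaxation_delay": 1.0
  },
  "accuracy_table": {
    "vanillin_mass_mg": 12.60,
    "H2": [
      {"area": 0.22, "weighted_mass": 2.03, "calculated_mass": 2.03, "printed_re": 0.00},
      {"area": 0.44, "weighted_mass": 4.07, "calculated_mass": 4.05, "printed_re": -0.49},
      {"area": 0.87, "weighted_mass": 8.14, "calculated_mass": 8.01, "printed_re": -1.62},
      {"area": 1.32, "weighted_mass": 12.20, "calculated_mass": 12.16, "printed_re": -0.33},
      {"area": 1.76, "weighted_mass": 16.27, "calculated_mass": 16.21, "printed_re": -0.37},
      {"area": 2.21, "weighted_mass": 20.34, "calculated_mass": 20.36, "printed_re": 0.10},
      {"area": 3.31, "weighted_mass": 30.51, "calculated_mass": 30.49, "printed_re": -0.07}
    ],
    "H3": [
      {"area": 0.23, "weighted_mass": 2.03, "calculated_mass": 2.12, "printed_re": 4.25},
      {"area": 0.44, "weighted_mass": 4.07, "calculated_mass": 4.05, "printed_re": -0.49},
      {"area": 0.88, "weighted_mass": 8.14, "calculated_mass": 8.01, "printed_re": -1.62},
      {"area": 1.32, "weighted_mass": 12.20, "calculated_mass": 12.16, "printed_re": -0.33},
      {"area": 1.76, "weighted_mass": 16.27, "calculated_mass": 16.21, "printed_re": -0.37},
      {"area": 2.21, "weighted_mass": 20.34, "calculated_mass": 20.36, "printed_re": 0.10},
      {"area": 3.31, "weighted_mass": 30.51, "calculated_mass": 30.49, "printed_re": -0.07}
    ]
  },
  "precision_table": {
    "weighted_mass_mg": 30.51,
    "vanillin_mass_mg": 12.60,
    "H2": {
      "areas": [3.32, 3.31, 3.31, 3.32, 3.31],
      "calculated_masses": [30.58, 30.49, 30.49, 30.58, 30.49]
    },
    "H3": {
      "areas": [3.32, 3.31, 3.31, 3.32, 3.32],
      "calculated_masses": [30.58, 30.49, 30.49, 30.58, 30.49]
    }
  },
  "extract_quantitation": {
    "vanillin_mass_mg": 11.84,
    "extract_mass_mg": 29.9,
    "areas": {"H2": 2.84, "H3": 2.86},
    "printed_mass_mg": {"H2": 25.22, "H3": 25.39},
    "printed_content_pct": {"H2": 84.35, "H3": 84.93}
  },
  "extraction": {
    "fresh_leaves_g": 143.4,
    "dichloromethane_extract_g": 2.888,
    "hexane_extract_g": 0.8432,
    "printed_dcm_yield_pct": 2.01,
    "printed_hexane_yield_pct": 0.58,
    "printed_leaf_content_pct": 1.7
  },
  "relaxation": {
    "furanone_t1_s": 0.5,
    "vanillin_t1_s": 0.9,
    "inversion_recovery_d1_s": 5.0
  },
  "lod_loq": {
    "printed_lod_mg": 0.14,
    "printed_loq_mg": 0.59,
    "lod_sn_threshold": 10.0,
    "loq_sn_threshold": 150.0
  }
}
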