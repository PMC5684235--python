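{
  "description": "Published reference values for the IF2-30S initiation complex smFRET study: kinetic table (mean +/- SE over three replicate data sets), bound-state FRET peak decompositions, Forster-distance conversions, and depletion-model occupancy examples.",
  "r0_angstrom": 55.0,
  "conditions": {
    "wT": {
      "label": "30S IC_wT", "if2": "wtIF2", "nucleotide": "GTP",
      "k_a": 2.0, "k_a_se": 0.13, "k_d": 0.041, "k_d_se": 0.01,
      "K_d_nM": 21.0, "K_d_se_nM": 6.0,
      "corrections": ["cy5"],
      "peaks": [{"mean": 0.87, "mean_se": 0.02, "weight": 1.0}]
    },
    "mT": {
      "label": "30S IC_mT", "if2": "mutIF2", "nucleotide": "GTP",
      "k_a": 2.2, "k_a_se": 0.4, "k_d": 0.013, "k_d_se": 0.001,
      "K_d_nM": 6.4, "K_d_se_nM": 1.3,
      "corrections": ["cy5"],
      "peaks": [{"mean": 0.85, "mean_se": 0.01, "weight": 1.0}]
    },
    "wD": {
      "label": "30S IC_wD", "if2": "wtIF2", "nucleotide": "GDP",
      "k_a": 2.1, "k_a_se": 0.12, "k_d": 1.32, "k_d_se": 0.09,
      "K_d_nM": 622.0, "K_d_se_nM": 28.0,
      "corrections": [],
      "peaks": [
        {"mean": 0.89, "mean_se": 0.01, "weight": 0.18, "weight_se": 0.015},
        {"mean": 0.67, "mean_se": 0.01, "weight": 0.82, "weight_se": 0.015}
      ]
    },
    "mD": {
      "label": "30S IC_mD", "if2": "mutIF2", "nucleotide": "GDP",
      "k_a": 1.2, "k_a_se": 0.10, "k_d": 0.13, "k_d_se": 0.01,
      "K_d_nM": 102.0, "K_d_se_nM": 9.0,
      "corrections": [],
      "peaks": [{"mean": 0.86, "mean_se": 0.03, "weight": 1.0}]
    },
    "wT_Met": {
      "label": "30S IC_wT,Met", "if2": "wtIF2", "nucleotide": "GTP",
      "k_a": 0.52, "k_a_se": 0.02, "k_d": 1.2, "k_d_se": 0.2,
      "K_d_nM": 2328.0, "K_d_se_nM": 294.0,
      "corrections": ["cy3"], "reference": "wT",
      "peaks": [
        {"mean": 0.81, "mean_se": 0.01, "weight": 0.56, "weight_se": 0.12},
        {"mean": 0.55, "mean_se": 0.01, "weight": 0.44, "weight_se": 0.12}
      ]
    },
    "mT_Met": {
      "label": "30S IC_mT,Met", "if2": "mutIF2", "nucleotide": "GTP",
      "k_a": 0.77, "k_a_se": 0.05, "k_d": 0.11, "k_d_se": 0.01,
      "K_d_nM": 136.0, "K_d_se_nM": 7.0,
      "corrections": [],
      "peaks": [
        {"mean": 0.83, "mean_se": 0.04, "weight": 0.42, "weight_se": 0.057},
        {"mean": 0.57, "mean_se": 0.02, "weight": 0.58, "weight_se": 0.057}
      ]
    },
    "wT_OH": {
      "label": "30S IC_wT,OH", "if2": "wtIF2", "nucleotide": "GTP",
      "k_a": 0.38, "k_a_se": 0.02, "k_d": 2.2, "k_d_se": 0.5,
      "K_d_nM": 5842.0, "K_d_se_nM": 1469.0,
      "corrections": ["cy3"], "reference": "wT",
      "peaks": [{"mean": 0.53, "mean_se": 0.02, "weight": 1.0}]
    },
    "mT_OH": {
      "label": "30S IC_mT,OH", "if2": "mutIF2", "nucleotide": "GTP",
      "k_a": 0.74, "k_a_se": 0.02, "k_d": 0.14, "k_d_se": 0.02,
      "K_d_nM": 185.0, "K_d_se_nM": 18.0,
      "corrections": [],
      "peaks": [{"mean": 0.57, "mean_se": 0.01, "weight": 1.0}]
    }
  },
  "distances_angstrom": {
    "0.87": 40, "0.81": 43, "0.67": 49, "0.55": 53, "0.3": 63,
    "difference_0.67_minus_0.87": 9
  },
  "occupancy": {
    "if2_total_nM": 600.0, "ic_total_nM": 360.0,
    "percent_by_kd_nM": {"2328": 19, "5842": 9},
    "twofold_kd_pair_nM": [21.0, 622.0]
  }
}
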