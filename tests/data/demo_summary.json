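{
  "editing": {
    "enrichment_median": 1.39736,
    "f_ex_hat": 0.00440529,
    "f_ex_median_excluded": 0.219183,
    "f_ex_median_infiltrated": 0.205645,
    "f_nonex_hat": 0.00474834,
    "p_value_f_ex_infiltrated_lt_excluded": 0.639857,
    "p_value_ri_smoker_lt_nonsmoker": 0.30543,
    "ri_mean_nonsmoker": 0.00468889,
    "ri_mean_smoker": 0.00468494
  },
  "enrichment": {
    "n_terms_retained": 6,
    "n_terms_scored": 6
  },
  "peptidome": {
    "binder_fraction_hla1": 0.851667,
    "median_density_hla1": 0.020339,
    "median_density_hla2": 0.0211765,
    "n_peptides_hla1": 6000,
    "n_peptides_hla2": 6000
  },
  "schema_version": 1,
  "seed": 17,
  "stages": [
    "peptidome",
    "tme",
    "taa",
    "editing",
    "enrichment"
  ],
  "taa": {
    "mean_p_eff_excluded": 0.000379734,
    "mean_p_eff_infiltrated": 0.00081056,
    "n_taas": 10
  },
  "thresholds": {
    "binder_rank": 2.0,
    "distance": 0.2,
    "q": 0.2,
    "r": 0.5,
    "taa_tpm": 1.0,
    "weight_mode": "literal",
    "z": 2.0
  },
  "tme": {
    "fov_first_component": 0.306113,
    "inflammation_mean_high": 3.94214,
    "inflammation_mean_low": 1.94323,
    "s_c": {
      "B_cells": 0.917183,
      "CD4_T": 0.917183,
      "CD8_T": 0.917183,
      "Dendritic": 0.917183,
      "Macrophages": 0.917183,
      "NK": 0.917183
    }
  }
}
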