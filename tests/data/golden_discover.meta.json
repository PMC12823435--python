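{
  "alpha": 0.005555555555555556,
  "config": null,
  "config_hash": null,
  "meta_weights": [
    1.0,
    1.0
  ],
  "n_calibrated_genes": 5,
  "n_calibration_excluded": 0,
  "n_class_II_genes": 3,
  "n_class_I_genes": 4,
  "n_dual_genes": 2,
  "n_input_genes": 6,
  "n_masked_out": 1,
  "n_tests": 9,
  "n_unmatched_regions": 0,
  "p_side": "one-sided after enforced enrichment direction (meta); two-tailed Fisher otherwise",
  "seed": null,
  "unit": "alleles",
  "version": "0.1.0"
}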