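# Demo pipeline configuration: a small 8-patient multi-region cohort.
# Run with:  immunoedit run --config examples/demo.yaml --out results/demo
seed: 17
cohort:
  n_patients: 8
  regions_per_patient: 4
  n_proteins: 100
  protein_length_range: [80, 250]
  mutations_per_region: 40
  peptides_per_sample: 150
  taa_log2_boost_excluded: 1.0
  seed: 17
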