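# Example configuration for `tftscreen screen run --config examples/run.yaml`.
# Exactly one of `synthetic` or `inputs` may be present.
seed: 1
synthetic:
  n_genes: 384
  n_hits: 4
  n_confounders: 1
  hit_multiplier: 0.1
normalization:
  min_size_fraction: 0.5
  span: 0.3
  degree: 2
scoring:
  scale_mad: false
  reference: pooled
thresholds:
  z_threshold: 3.0
  fdr_level: 0.05
  control_z_max: 3.0
# To analyse measured data instead, replace `synthetic:` with
# inputs:
#   layout: path/to/layout.tsv
#   query: path/to/query.tsv
#   control: path/to/control.tsv
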