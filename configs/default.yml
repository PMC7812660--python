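# Packaged synthetic study configuration: ~200-species log-series pool,
# 60 fixed-effort survey plots (caps: 10 records/species/plot, 150/plot),
# plus a casual-collection stream of ~600 records.
synthetic:
  S: 200
  theta: 0.995
  specialist_fraction: 0.2
  n_plots: 60
  casual_effort: 600.0
  seed: 7
params:
  chao_variant: classic
  permutations: 999
  n_starts: 10
  current_year: 2019
  seed: 7
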