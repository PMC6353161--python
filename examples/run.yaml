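# Full-pipeline config for the synthetic six-breed panel produced by
#   divscan simulate --out data --seed 2019
plink_prefix: data/panel
breeds_tsv: data/panel.breeds.tsv
out_dir: report
breed_types:
  light: [AR, MLP]
  primitive: [HC, KN]
  draft: [SOK, SZTUM]
window_size: 10
quantile: 0.999
extension_bp: 25000
ld_max_span_bp: 500000
log_level: INFO
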