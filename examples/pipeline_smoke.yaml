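# Small end-to-end pipeline config: simulate two groups, impute, fit
# with short chains, compare, upscale.  Intended as a quick smoke run:
#   aquacarb run --config examples/pipeline_smoke.yaml
output_dir: scratch/smoke_run
seed: 42
simulate:
  groups:
    - {label: lake, mu: 15.6, tau: 8.0, n: 40}
    - {label: mangrove, mu: 73.2, tau: 45.0, n: 40,
       salinity_class: saline, inundation_class: tidal}
  sd_missing_prob: 0.58
model:
  n_chains: 3
  n_iter: 20000
  n_burnin: 5000
groupings: [ecosystem_category]
overlap:
  metric: jaccard
ratios:
  - {a: mangrove, b: lake, mode: median_ratio}
upscale:
  areas:
    lake:
      area_m2: 5.0e12
      citation: "example extent"
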