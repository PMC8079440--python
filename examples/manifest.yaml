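# Example run manifest for `cortexeval run-all`.
# Every key is optional; omitted keys take the defaults shown in
# cortexeval.manifest._DEFAULTS. Sizes here are small for a quick demo.
seed: 0
output_dir: results
stages:
  - simulate
  - pipelines
  - age-predict
  - lifespan-radar
  - icc
  - variance-ratio
  - longitudinal-eval
pipelines: [A, B]
cohort:                      # longitudinal / rescan cohort overrides
  group_sizes: {CN: 20, LMCI: 25, AD: 15}
  n_sites: 4
cross_cohort: {}             # cross-sectional cohort overrides
cross_sectional_n: 120
rescan_n: 40
age_prediction:
  n_permutations: 25
  n_trees: 100
mcmc:
  n_chains: 2
  n_iterations: 600
  n_warmup: 250
visit_coding: continuous     # or categorical
fdr_family: contrast         # or global
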