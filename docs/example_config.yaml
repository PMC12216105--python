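model: IM
seed: 42
output_dir: runs/im_demo
n_sims: 200
split:
- 120
- 40
- 40
design:
  n_diploid_per_pop: 4
  n_loci: 2
  locus_length: 100000
  recombination_rate: 1.0e-08
  mutation_rate: 1.25e-08
priors: null
stats:
  window_size: 50000.0
  n_ld_bins: 19
  ld_mean_min: 282.0
  ld_mean_max: 1400000.0
  ld_pair_cap: 10000
  ibs_n_subsets: 20
  n_deciles: 9
  sampling_seed: 2027
  include_pop_fixed_sfs: true
  jsfs_full_grid: true
  include_pooled_ibs: true
  include_pooled_afibs: true
methods:
- RF
- XGB
- MLP
regressor_overrides: {}
abc_algorithms:
- rejection
- loclinear
- neuralnet
abc_tolerance: 0.05
abc_point: mean
abc_max_stats: 300
abc_n_targets: 8
interpret_method: XGB
interpret_target: split_time
n_background: 100
n_explain: 20
n_jobs: 1
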