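# Example config for `gbscore pipeline --config examples/pipeline_config.toml`.
# Any omitted key keeps the library default (the survey-scale settings:
# threshold 3, burnin 10000, 20000 reps, 5 runs, K 1-3, min avg depth 10,
# 77-cycle reads).

seed = 11
out_dir = "scratch/pipeline_demo"

[simulate]
n_accessions = 30
n_snp = 100
n_pav = 10
n_fragments = 130
clone_sizes = [2, 3]
n_replicate_pairs = 2
mean_depth = 20.0
error_rate = 0.002
somatic_rate = 0.001

[diversity]
n_boot = 100

[structure]
k_min = 1
k_max = 4
n_runs = 3
burnin = 1000
reps = 3000
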