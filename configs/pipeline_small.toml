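# Small end-to-end run on synthetic data: full factorial design
# (3 hosts x {seaweed, proxy biofilm} + controls + seawater, 2 timepoints),
# with analysis thresholds at their standard defaults.

seed = 42
outdir = "scratch/pipeline_small"

[simulate]
n_features = 40
n_replicates = 6
effect_size = 1.0
topology = "cluster"
graph_density = 0.04

[filter]
min_depth = 2000

[core]
min_reads = 3
min_prevalence = 0.9
min_abundance_fraction = 1e-5

[stats]
factors = ["substrate", "treatment"]
n_perm = 999

[network]
min_total_reads = 3
min_mean_rel_abund = 0.0025
n_lambda = 20
n_subsamples = 20
beta_threshold = 0.05
rule = "or"

[metrics]
z_thresh = 2.5
p_thresh = 0.62

[netcompare]
standardize = "zscore"
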