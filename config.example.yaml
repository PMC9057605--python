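# Example run configuration for `epimast --config config.example.yaml all`.
# Omitted keys keep their defaults (see epimast.pipeline.RunConfig).
seed: 1
outdir: results/pipeline
simulate: true
# Synthetic-design overrides (epimast.simulate.SimulationDesign fields):
design: {}
# To run on your own files instead, set simulate: false and point `inputs`
# at: cpg, meth_conditions, bedgraph, rna_counts, rna_conditions, tss,
# curated.
inputs: {}
# Methylation caller
tile_bp: 400
min_cov_per_cpg: 10
min_cpg: 3
min_delta: 0.10      # 0.20 is the stringent preset
q_max: 0.01
# H3K27ac ranking
half_window_bp: 2500
low_threshold: 0.5
alpha: 0.05
# Expression
min_count: 10
min_samples: 2
q_max_de: 0.05
min_abs_log2fc: 1.0
n_top: 500
# Integration
window_bp: 1000
max_dist_bp: 50000
delta_threshold: 0.20
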