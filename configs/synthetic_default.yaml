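# Default synthetic run: study-condition thresholds and design sizes.
# All thresholds mirror the analysis defaults (top 10% specificity score,
# log2FC > 1 / FDR < 0.05 upregulation, 50 kb proximity, 100 permutations,
# dating window 10 with > 3 present, 25 nt junction tolerance, >= 2
# skipping reads, Jaccard 0.5, 0.5% detection).
seed: 0
output_dir: ervregnet_run
top_fraction: 0.10
fc_thresh: 1.0
fdr_thresh: 0.05
window_distance: 50000
n_perm: 100
dating_window: 10
dating_min_present: 4
tolerance: 25
min_reads: 2
jaccard: 0.5
detection_fraction: 0.005
n_cells_per_type: 200
n_genes_per_class:
  both_up: 100
  pgclc_only: 100
  naive_only: 100
  "null": 1700
effect_size: 4.0
conserved_fraction: 0.5
n_history_missing_rate: 0.2
n_samples: 10
n_absent_loci: 5
de_method: wald
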