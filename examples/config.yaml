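# Demonstration pipeline configuration: a small synthetic cohort that runs
# end to end in a few minutes on one CPU.  All sizes scale up freely; for
# real-data runs replace the `synthgen` block with an `input` block pointing
# at MTX/TSV files.
seed: 0

synthgen:
  cohort:
    n_genes: 600
    n_celltypes: 5
    n_cells_per_type_per_donor: 20
    n_module_genes: 40
    n_identity_genes: 30
    module_batch_overlap: 0.8
  bulk:
    n_samples_per_group: 50
    module_shift: 1.0
  annotations:
    tf_fraction: 0.1
    tf_odds_ratio: 5.0
    n_lr_pairs: 20

discovery:
  n_top_genes: 300
  n_replicates: 30        # demo scale; raise for production runs
  k_range: [6]            # demo scale; the conventional scan is 7..14
  max_iter: 150

consensus:
  top_n: 60
  n_grid: [20, 40, 60, 80, 100]

scoring:
  rmax: 500

cohortstats:
  n_random: 200
  permutation:
    n_cells: 100
    n_perm: 500

classify:
  k_folds: 5
  repeats: 3
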