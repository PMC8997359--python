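# Synthetic WT-versus-knockdown demonstration run.
#
# One 4-Mb chromosome; TAD borders called at 5-kb bins with the 0.04/0.08
# delta tiers and 20% down-sampling robustness; loops at 2-kb bins, FDR
# 0.05; compartments at 10-kb bins with a planted checkerboard; DEG
# association tested with 1000 region permutations.
name: demo
genome:
  chrS: 4000000
resolution: 5000
depth: 1500000.0
n_borders: 12
border_depth: 3.0
n_loops: 6
loop_enrichment: 5.0
loop_resolution: 2000
loop_depth: 6000000.0
compartment_blocks: 20
checkerboard_factor: 3.0
compartment_resolution: 10000
compartment_depth: 2000000.0
knockdowns:
  beaf32_kd: {delete: 3, shift: 3, shift_bp: 10000}
  cp190_chro_kd: {delete: 4, shift: 2, shift_bp: 10000}
downsample_fraction: 0.8
genes_per_tad: 25
deg_odds: 5.0
n_perm: 1000
seeds:
  simulation: 11
  downsample: 12
  permutation: 13
  expression: 14
outdir: demo_run
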