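# Desk-scale analogue of the F2 heart-rate mapping study:
# 2 chromosomes x 25 Mb, 300 individuals, 0.78x coverage, 1 marker/kb,
# one planted additive QTL explaining ~15% of phenotypic variance.
chromosomes:
  - [chr1, 25000000]
  - [chr2, 25000000]
n_individuals: 300
out_dir: results/study
marker_density: 0.001
coverage: 0.78
read_error: 0.01
ref_bias: 0.0
crossover_rate: 1.5
qtls:
  - chrom: chr1
    pos: 12500000
    additive: [5.94, 5.94, 5.94]   # sqrt(0.15/0.85 * 10^2 / 0.5) bpm per A allele
baselines: [120.0, 160.0, 210.0]
noise_sd: 10.0
arrhythmia_rate: 0.02
window_size: 5000
hmm_error: 0.02
grid: 10000
n_perm: 100
fdr_levels: [0.01, 0.05]
fdr_level: 0.05
r2_threshold: 0.5
merge_distance: 500000
min_log10p: 3.0
seed: 7
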