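# Full synthetic pipeline configuration for `glorimap run`.
# Every threshold of every stage is settable here; CLI flags override.
sim:
  seed: 42          # mandatory
  n_genes: 100
  length_range: [800, 2000]
  gc_content: 0.32
  exon_count_range: [1, 4]
  depth_mean: 300
  read_length: 150
  conversion_efficiency: 0.99
  site_rate: 0.04
  eij_exclusion_nt: 100
  three_prime_bias: 2.0
  n_replicates: 3

# scoring
min_reads_per_transcript: 10
max_read_span: 700
min_count: 10
min_score: 0.1
alpha: 0.05
replicate_support: 1

# linkage
max_gap: 40
score_lo: 0.4
score_hi: 0.7
min_spanning: 10

# motif model
model_min_cov: 40.0
test_frac: 0.2
top_frac: 0.01
coherent_cut: 0.8
low_cut: 0.1

# conservation
max_hamming: 3
homolog_sub_rate_AT: 0.05
homolog_sub_rate_CG: 0.15
n_species: 2

# enrichment
min_basemean: 200.0
n_bins: 10
bootstrap_frac: 0.8
n_iter: 1000
de_frac_m6a: 0.3
de_effect: 0.15
de_n_genes: 4000
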