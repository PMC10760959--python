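cohort:
  allele_pool:
  - HLA-A*01:01
  - HLA-A*02:01
  - HLA-A*03:01
  - HLA-A*11:01
  - HLA-A*24:01
  - HLA-A*26:01
  - HLA-A*30:01
  - HLA-A*68:01
  - HLA-B*01:01
  - HLA-B*02:01
  - HLA-B*03:01
  - HLA-B*11:01
  - HLA-B*24:01
  - HLA-B*26:01
  - HLA-B*30:01
  - HLA-B*68:01
  - HLA-C*01:01
  - HLA-C*02:01
  - HLA-C*03:01
  - HLA-C*11:01
  - HLA-C*24:01
  - HLA-C*26:01
  - HLA-C*30:01
  - HLA-C*68:01
  alleles_per_sample: 6
  baseline_hazard: 0.0006666666666666666
  censor_time: 3000.0
  expr_cutoff: 2.0
  expressed_fraction: 0.7
  hazard_ratio: 0.3
  log_mean: 3.0
  log_sigma: 1.0
  n_samples: 200
  presenting_alleles_per_antigen: 1
  rank_cutoff: 2.0
genome:
  ere_len:
  - 300
  - 600
  hypervariable_len:
  - 300
  - 600
  intergenic_tx_len:
  - 300
  - 600
  intron_len:
  - 300
  - 700
  length: 50000
  n_ere: 3
  n_exons: 8
  n_hypervariable: 1
  n_intergenic_tx: 2
  n_introns: 4
  orf_codons:
  - 60
  - 160
  tumor_only_fraction:
    ERE: 1.0
    exon: 0.25
    hypervariable: 1.0
    intergenic: 1.0
    intron: 0.5
identifications:
  length_range:
  - 8
  - 11
  mu_null: 0.0
  mu_true: 3.0
  n_decoy: 75
  n_false: 25
  n_true: 150
  sample_id: tumor_1
  sigma_null: 1.0
  sigma_true: 1.0
panel:
  depth: 30.0
  n_blood: 2
  n_marrow: 2
  n_mtec: 3
  n_per_normal: 3
  n_testis: 2
  n_tumor: 2
seed: 1
stages:
  build_db: true
  classify: true
  filter: true
  present: true
  profile: true
  simulate: true
  survive: true
thresholds:
  cohort_expr_cutoff: 2.0
  fdr: 0.01
  max_len: 11
  min_len: 8
  prevalence: 0.05
  rank_cutoff: 2.0
  rphm_threshold: 8.55
  taa_fold: 3.0
  tissue_fraction: 0.1
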