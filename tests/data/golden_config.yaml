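# packaged golden fixture: small but exercises every stage
seed: 5
n_lambda: 30
n_boot: 200
sim:
  n_cpgs: 3000
  chrom_length: 120000
  mean_coverage: 18.0
  donor_sigma: 0.3
  meth_overdispersion: 0.0
  effects:
    phenotype_shared: {n_regions: 10, delta: 0.5}
    cancer_luminal: {n_regions: 6, delta: 0.5}
    cancer_shared: {n_regions: 6, delta: 0.5}
sim_array:
  n_normal: 40
  n_cancer: 40
  n_probes: 60
  n_informative: 8
  delta_beta: 0.3
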