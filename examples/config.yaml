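# Full-pipeline demo config: simulate a small dataset, RY-recode it,
# infer the ML tree, run the AU test, reconstruct the trait, date the
# tree and tabulate diversification rates.
seed: 5
outdir: mitophylo_demo
variant: 12n3rRTn
simulate:
  n_taxa: 8
  lengths: {codon1: 300, codon2: 300, codon3: 300, rRNA: 200, tRNA: 100}
model:
  alpha: 0.5
  n_categories: 4
search: nni          # "none" skips the NNI climb (NJ + branch lengths only)
autest:
  replicates: 2000
ancrec:
  states: 4
date:
  enabled: true
  burnin: 400
  n_samples: 300
  sample_every: 1
divrate:
  epsilons: [0.0, 0.95]
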