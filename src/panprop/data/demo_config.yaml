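# Demo pipeline configuration: every stage on small synthetic inputs.
seed: 1
outdir: panprop_demo
simulate:
  enabled: true
derep:
  enabled: true
  n_species: 3
  genome_length: 20000
traits:
  enabled: true
markers:
  enabled: true
thermo:
  enabled: true
network:
  enabled: true
  n_permutations: 2000
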