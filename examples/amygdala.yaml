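# Two-region demo study: amygdala vs hypothalamus, 6 animals,
# 4 measurements per animal (2 sections x 2 hemispheres).
schema_version: 1
seed: 11
simulation:
  phantom: {layout: pair, dims: [16, 13], labels: [amygdala, hypothalamus]}
  regions:
    amygdala: {true_ratio: 8.15}
    hypothalamus: {true_ratio: 6.40}
  mz_range: [1520.0, 1600.0]
  n_animals: 6
  sections_per_animal: 2
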