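# Desk-scale configuration: 12 Å box, compact element channel map,
# small trunk, short episodes. Matches the scaled-down learning
# experiment in the test suite.
ligand_elements: [CU]
channel_map: element
box:
  edge_length: 12.0
  margin: 2.0
  min_protein_atoms: 8
env:
  T_MAX: 80
  step_translation: 0.25
train:
  episodes: 300
  t_max: 10
  gamma: 0.0
  lr_actor: 0.003
  lr_critic: 0.003
  entropy_coef: 0.01
  optimizer: adam
network:
  filter_counts: [2, 3, 3]
  hidden: 32
infer:
  T_MAX: 80
  T_MIN: 20
  delta: 10
  threshold: 0.3
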