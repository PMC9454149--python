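# Full-scale single-atom (copper) configuration: defaults as printed in
# the reference setting. Requires a real PDB-derived dataset and ~20k
# episodes; provided for completeness.
ligand_elements: [CU]
channel_map: default
box:
  edge_length: 18.0
  voxel_size: 1.0
  margin: 2.0
  min_protein_atoms: 30
env:
  T_MAX: 600
  step_translation: 0.1
train:
  episodes: 20000
  t_max: 10
  gamma: 1.0
  lr_actor: 0.00005
  lr_critic: 0.0000001
  optimizer: sgd
network:
  filter_counts: [4, 8, 8]
  hidden: 256
infer:
  T_MAX: 600
  T_MIN: 300
  delta: 50
  threshold: 0.3
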