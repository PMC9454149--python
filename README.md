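# dockrl

Reinforcement-learning rigid docking of small ligands (single atoms such as
Cu²⁺, small multi-atom ligands such as SO₄²⁻) on voxelized protein grids.

A protein–ligand complex is cut into an 18 Å cubic box gridded at 1 Å. Each
atom deposits unit mass as a normalized Gaussian (width = its van der Waals
radius) over its voxel and the 26 neighbours; per-atom-type channels (21
protein classes + one per ligand element) stack into an `18×18×18×N` input
grid. An actor network (three parallel same-extent 3-D convolutions →
3×3×3 max-pool → dense 256 → softmax head(s)) moves the ligand in ±0.1 Å
translations (and ±1° rotations for multi-atom ligands); a critic with a
single tanh unit scores states. Rewards are differences of
`exp(−RMSD(s₀, s)/18)`, doubled when negative. Training is asynchronous
advantage actor-critic (n-step rollouts, `t_max = 10`, γ = 1); at test time
the search stops once the range of the last δ = 50 critic outputs falls
below 0.3 (after at least 300 steps).

The networks are implemented in pure NumPy (float64) with hand-written
backward passes, validated against finite differences in the test suite —
no autodiff framework is required.

## Layout

| module | contents |
|---|---|
| `dockrl.structures` | PDB parsing (biotite-backed), channel maps, vdW radii, dataset filters (X-ray, < 2.0 Å, no DNA/RNA/UNK) |
| `dockrl.voxel` | box placement, Gaussian splatting, grid rendering |
| `dockrl.env` | episodic docking environment (reset/step, reward, termination) |
| `dockrl.metrics` | RMSD, 24-matching permutation-distance, center-distance, improvement rate, long-term reward, critic distance, DCC success rate |
| `dockrl.networks` | actor/critic with manual backprop, checkpoints |
| `dockrl.training` | n-step returns, A3C losses, SGD/Adam, multi-worker training loop |
| `dockrl.inference` | greedy docking, critic-convergence stopping, evaluation tables |
| `dockrl.fixtures` | deterministic synthetic complexes (shell/cleft/empty pockets) |
| `dockrl.cli` | `dockrl` command-line entry point |

## CLI

```bash
# 1. generate a toy dataset (writes PDBs + manifest.csv + config.json)
dockrl make-fixtures --out runs/fx --n 20 --pocket shell --seed 0 \
    --box-edge 12 --config examples/desk.yaml

# 2. (real data) parse + filter a directory of PDB files into a manifest
dockrl build-dataset --pdb-dir pdbs/ --ligand-code CU --out manifest.csv

# 3. train (checkpoints + training_log.csv under --out)
dockrl train --manifest runs/fx/manifest.csv --out runs/train \
    --config examples/desk.yaml --seed 0

# 4. dock one complex (pose.pdb + trace.csv)
dockrl dock --pdb runs/fx/fixture_0000.pdb --ligand-code CU \
    --actor runs/train/actor_ep*.npz --critic runs/train/critic_ep*.npz \
    --out runs/dock --config examples/desk.yaml

# 5. evaluate a manifest (results.csv + summary.json with mean/median
#    distances, improvement rates and the DCC success rate at 4 Å)
dockrl evaluate --manifest runs/fx/manifest.csv \
    --actor runs/train/actor_ep*.npz --critic runs/train/critic_ep*.npz \
    --out runs/eval --config examples/desk.yaml
```

Configuration is YAML (`box:`, `env:`, `train:`, `infer:`, `network:`
sections mirroring the dataclass fields, plus `ligand_elements` and
`channel_map: default|element`); every output directory receives the
resolved config and seed for provenance, and checkpoints refuse to load
against a different channel map.

## Notes on scale

Full-scale results in the reference setting require tens of thousands of
PDB-derived boxes and ~20k training episodes. The test suite instead runs
a scaled-down learning experiment (20 synthetic shell fixtures, 12 Å box,
compact channel map, 300 episodes) in which training reduces the median
final RMSD from ~6.9 Å to ~2.4 Å and beats both an untrained policy and a
uniform-random-walk baseline under identical seeds. For such short runs
the optimizer is Adam with γ = 0 (per-action credit); the defaults
(`optimizer="sgd"`, γ = 1, actor 5e-5 / critic 1e-7) match the reference
full-scale configuration.
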