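"""The maze-like docking environment.

The protein density is frozen; the agent rigidly translates (and, for
multi-atom ligands, rotates) the ligand inside the box. Each step earns
``exp(-RMSD(s0, s_{t+1})/18) - exp(-RMSD(s0, s_t)/18)``, doubled when
negative. Episodes end at ``T_MAX`` steps or when any ligand atom leaves
the box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from . import metrics
from .structures import ChannelMap, ComplexRecord
from .voxel import BoxSpec, GridBox, LigandPose, make_box, random_start_pose

__all__ = [
    "ActionSpace",
    "DockingEnv",
    "EnvConfig",
    "EpisodeDoneError",
    "StepOutcome",
    "apply_action",
    "immediate_reward",
]

# Translation directions, in action-index order: +x, -x, +y, -y, +z, -z.
_TRANSLATIONS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=float,
)
# Rotation axes/signs in the same ordering convention.
_ROTATIONS = [("x", 1.0), ("x", -1.0), ("y", 1.0), ("y", -1.0), ("z", 1.0), ("z", -1.0)]


class EpisodeDoneError(RuntimeError):
    """step() called on a finished episode."""


@dataclass(frozen=True)
class EnvConfig:
    """Step sizes, episode limit and reward shaping constants."""

    T_MAX: int = 600
    step_translation: float = 0.1
    step_rotation: float = 1.0  # degrees
    reward_scale: float = metrics.REWARD_SCALE
    penalty_factor: float = 2.0
    reward_distance: str = "rmsd"  # or "permutation"

    def __post_init__(self):
        for name in ("T_MAX", "step_translation", "step_rotation", "reward_scale", "penalty_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ActionSpace:
    """Six unit translations; six unit rotations for multi-atom ligands.

    Single-atom actions are integers in [0, 6). Multi-atom actions are
    ``(translation_index, rotation_index)`` pairs — every step is one
    translation *and* one rotation.
    """

    n_atoms: int

    @property
    def joint(self) -> bool:
        return self.n_atoms > 1

    @property
    def n_translations(self) -> int:
        return 6

    @property
    def n_rotations(self) -> int:
        return 6 if self.joint else 0

    def normalize(self, action):
        if self.joint:
            t, r = action
            if not (0 <= t < 6 and 0 <= r < 6):
                raise ValueError(f"action out of range: {action}")
            return int(t), int(r)
        a = int(action)
        if not 0 <= a < 6:
            raise ValueError(f"action out of range: {action}")
        return a


@dataclass(frozen=True)
class StepOutcome:
    next_pose: LigandPose
    reward: float
    done: bool
    reason: str  # max_steps | out_of_box | running

    def __post_init__(self):
        if self.done != (self.reason != "running"):
            raise ValueError("done must hold iff reason != running")


def apply_action(pose: LigandPose, action, config: EnvConfig) -> LigandPose:
    """Apply one rigid action: a ±step translation along an axis and, for
    multi-atom ligands, a ±step rotation about that axis through the ligand
    centroid. Interatomic distances are preserved exactly (rigid)."""
    space = ActionSpace(pose.n_atoms)
    action = space.normalize(action)
    if space.joint:
        t_idx, r_idx = action
    else:
        t_idx, r_idx = action, None
    shift = _TRANSLATIONS[t_idx] * config.step_translation
    coords = pose.coords + shift
    orientation = pose.orientation
    if r_idx is not None:
        axis, sign = _ROTATIONS[r_idx]
        R = Rotation.from_euler(axis, sign * config.step_rotation, degrees=True).as_matrix()
        centroid = coords.mean(axis=0)
        coords = (coords - centroid) @ R.T + centroid
        orientation = R @ orientation
    return LigandPose(coords=coords, elements=pose.elements, orientation=orientation)


def immediate_reward(
    s_t: LigandPose, s_next: LigandPose, s_0: LigandPose, config: EnvConfig = EnvConfig()
) -> float:
    """Exponential-RMSD reward with a doubling penalty for worsening moves.

    ``raw = exp(-D(s0, s_next)/scale) - exp(-D(s0, s_t)/scale)``; negative
    raw rewards are multiplied by ``penalty_factor`` (2) to push the agent
    toward the true position.
    """
    if not (s_t.n_atoms == s_next.n_atoms == s_0.n_atoms):
        raise ValueError("atom count mismatch between poses")
    dist = metrics.permutation_rmsd if config.reward_distance == "permutation" else metrics.rmsd
    scale = config.reward_scale
    raw = float(np.exp(-dist(s_0, s_next) / scale) - np.exp(-dist(s_0, s_t) / scale))
    return raw * config.penalty_factor if raw < 0.0 else raw


class DockingEnv:
    """Episodic simulator with a conventional reset/step interface.

    ``reset`` builds a fresh box around the record's true site and drops
    the ligand at a random start; ``step`` applies an action and returns
    ``(grid, reward, done, info)``. The rendered protein channels are
    cached across steps — only ligand channels change.
    """

    def __init__(
        self,
        record: ComplexRecord,
        channel_map: ChannelMap,
        box_spec: BoxSpec | None = None,
        config: EnvConfig | None = None,
        seed: int | np.random.Generator | None = None,
    ):
        self.record = record
        self.channel_map = channel_map
        self.box_spec = box_spec or BoxSpec()
        self.config = config or EnvConfig()
        self._rng = np.random.default_rng(seed)
        self.box: GridBox | None = None
        self.pose: LigandPose | None = None
        self.true_pose: LigandPose | None = None
        self.step_count = 0
        self.done = True
        self.action_space = ActionSpace(len(record.ligand_atoms))

    def reset(self, seed: int | None = None) -> np.ndarray:
        """Build a new box and random start pose; returns the rendered grid."""
        if seed is not None:
            self._rng = np.random.default_rng(seed)
        self.box, self.true_pose = make_box(
            self.record, self.box_spec, self.channel_map, self._rng
        )
        self.pose = random_start_pose(self.true_pose, self.box, self._rng)
        self.step_count = 0
        self.done = False
        return self.box.render(self.pose)

    def _distance(self, pose: LigandPose) -> float:
        if self.config.reward_distance == "permutation":
            return metrics.permutation_rmsd(self.true_pose, pose)
        return metrics.rmsd(self.true_pose, pose)

    def step(self, action) -> tuple[np.ndarray | None, float, bool, dict]:
        """Apply an action. Returns ``(grid, reward, done, info)``.

        A move that takes any ligand atom out of the box terminates the
        episode with the attempted move's reward; the environment's pose
        stays at the last in-box placement (which is the episode's s_end).
        """
        if self.done:
            raise EpisodeDoneError("step() on a finished episode")
        attempted = apply_action(self.pose, action, self.config)
        reward = immediate_reward(self.pose, attempted, self.true_pose, self.config)
        self.step_count += 1
        info = {"action": self.action_space.normalize(action)}
        if not self.box.contains(attempted.coords):
            self.done = True
            info["reason"] = "out_of_box"
            info["rmsd"] = self._distance(self.pose)
            return None, reward, True, info
        self.pose = attempted
        info["rmsd"] = self._distance(self.pose)
        if self.step_count >= self.config.T_MAX:
            self.done = True
            info["reason"] = "max_steps"
            return self.box.render(self.pose), reward, True, info
        info["reason"] = "running"
        return self.box.render(self.pose), reward, False, info

    def outcome(self, action) -> StepOutcome:
        """step(), packaged as a :class:`StepOutcome` (next_pose is the
        committed pose: the last in-box placement)."""
        _, reward, done, info = self.step(action)
        return StepOutcome(next_pose=self.pose, reward=reward, done=done, reason=info["reason"])
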