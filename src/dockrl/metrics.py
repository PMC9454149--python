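"""Distances and scores used to evaluate docking episodes.

Includes plain index-matched RMSD, the symmetry-corrected
permutation-distance for sulfate (minimum RMSD over the 24 oxygen
matchings), the sulfur center-distance, the improvement rate, the long-term
reward ``G_t``, the critic-distance inversion and the DCC success rate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .voxel import LigandPose

__all__ = [
    "EpisodeTrace",
    "REWARD_SCALE",
    "center_distance",
    "critic_distance",
    "dcc_success_rate",
    "improvement_rate",
    "long_term_reward",
    "oxygen_matchings",
    "permutation_rmsd",
    "rmsd",
    "score_traces",
]

#: Denominator of the exponential reward / long-term-reward formulas, in Å.
REWARD_SCALE = 18.0


def rmsd(a: LigandPose | np.ndarray, b: LigandPose | np.ndarray) -> float:
    """Index-matched root-mean-square deviation in Å.

    ``sqrt(mean_i |a_i - b_i|²)`` over matched atom indices; symmetric and
    zero iff the coordinate sets are identical.
    """
    xa = a.coords if isinstance(a, LigandPose) else np.asarray(a, dtype=float)
    xb = b.coords if isinstance(b, LigandPose) else np.asarray(b, dtype=float)
    xa = xa.reshape(-1, 3)
    xb = xb.reshape(-1, 3)
    if xa.shape != xb.shape:
        raise ValueError(f"atom count mismatch: {xa.shape[0]} vs {xb.shape[0]}")
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def _sulfate_split(pose: LigandPose) -> tuple[int, list[int]]:
    elements = [e.strip().upper() for e in pose.elements]
    s_idx = [i for i, e in enumerate(elements) if e == "S"]
    o_idx = [i for i, e in enumerate(elements) if e == "O"]
    if len(s_idx) != 1 or len(o_idx) != 4 or pose.n_atoms != 5:
        raise ValueError("pose is not a sulfate (1 S + 4 O expected)")
    return s_idx[0], o_idx


def oxygen_matchings(a: LigandPose, b: LigandPose):
    """Yield the index correspondences between two sulfates: sulfur fixed to
    sulfur, the four symmetric oxygens permuted — 4! = 24 matchings.

    Each yielded pair ``(idx_a, idx_b)`` is an equal-length index array into
    the two poses.
    """
    sa, oa = _sulfate_split(a)
    sb, ob = _sulfate_split(b)
    idx_a = np.array([sa] + oa, dtype=int)
    for perm in itertools.permutations(ob):
        yield idx_a, np.array([sb] + list(perm), dtype=int)


def permutation_rmsd(a: LigandPose, b: LigandPose) -> float:
    """Symmetry-corrected distance between two sulfate poses: the minimum
    RMSD over all 24 S-fixed oxygen matchings (enumerated exhaustively)."""
    best = np.inf
    for idx_a, idx_b in oxygen_matchings(a, b):
        best = min(best, rmsd(a.coords[idx_a], b.coords[idx_b]))
    return float(best)


def center_distance(a: LigandPose, s0: LigandPose) -> float:
    """Euclidean distance in Å between the sulfur atoms of two sulfates."""
    sa, _ = _sulfate_split(a)
    sb, _ = _sulfate_split(s0)
    return float(np.linalg.norm(a.coords[sa] - s0.coords[sb]))


@dataclass
class EpisodeTrace:
    """One docking attempt: the visited poses (s_start … s_end), per-step
    rewards, the critic outputs O_t and the true pose s0."""

    poses: list[LigandPose]
    rewards: list[float]
    true_pose: LigandPose
    critic_outputs: list[float] = field(default_factory=list)
    actions: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.rewards) != len(self.poses) - 1:
            raise ValueError("need |rewards| = |poses| - 1")
        if self.critic_outputs and len(self.critic_outputs) != len(self.poses):
            raise ValueError("need |critic_outputs| = |poses| (or empty)")

    @property
    def start_pose(self) -> LigandPose:
        return self.poses[0]

    @property
    def end_pose(self) -> LigandPose:
        return self.poses[-1]

    @property
    def n_steps(self) -> int:
        return len(self.poses) - 1


def improvement_rate(trace: EpisodeTrace, distance=rmsd) -> float:
    """Fractional reduction of the start-to-truth distance:
    ``(D(s0, s_start) - D(s0, s_end)) / D(s0, s_start)``.

    1.0 means the search ended exactly on the true pose; negative values
    mean the ligand drifted away. Undefined (raises) when the start pose
    coincides with the truth.
    """
    d_start = distance(trace.true_pose, trace.start_pose)
    if d_start == 0.0:
        raise ZeroDivisionError("improvement rate undefined: start distance is zero")
    d_end = distance(trace.true_pose, trace.end_pose)
    return (d_start - d_end) / d_start


def long_term_reward(trace: EpisodeTrace, t: int, scale: float = REWARD_SCALE) -> float:
    """The Monte-Carlo return of state s_t under the exponential reward:
    ``exp(-RMSD(s0, s_end)/scale) - exp(-RMSD(s0, s_t)/scale)``."""
    d_end = rmsd(trace.true_pose, trace.end_pose)
    d_t = rmsd(trace.true_pose, trace.poses[t])
    return float(np.exp(-d_end / scale) - np.exp(-d_t / scale))


def critic_distance(o_t: float, rmsd_end: float, scale: float = REWARD_SCALE) -> float:
    """Invert the long-term-reward formula at a critic output O_t:
    ``-scale · log(exp(-rmsd_end/scale) - O_t)``.

    With O_t = 0 this returns ``rmsd_end`` exactly; with O_t equal to the
    true G_t it recovers RMSD(s0, s_t). Raises when the log argument is not
    positive (critic output out of range).
    """
    arg = np.exp(-rmsd_end / scale) - o_t
    if arg <= 0.0:
        raise ValueError(f"critic output {o_t} out of range for rmsd_end={rmsd_end}")
    return float(-scale * np.log(arg))


def dcc_success_rate(final_distances, threshold: float = 4.0) -> float:
    """Fraction of final center distances strictly below ``threshold`` Å."""
    d = np.asarray(list(final_distances), dtype=float)
    if d.size == 0:
        raise ValueError("empty distance list")
    return float(np.mean(d < threshold))


def score_traces(traces: list[EpisodeTrace], sulfate: bool = False):
    """Score a batch of traces into a results table.

    Returns a pandas DataFrame with one row per episode (final distances
    and improvement rates) followed by aggregate ``mean`` / ``median``
    rows, mirroring the layout of per-dataset summary tables.
    """
    import pandas as pd

    rows = []
    for i, tr in enumerate(traces):
        row = {"episode": i, "steps": tr.n_steps}
        row["rmsd"] = rmsd(tr.true_pose, tr.end_pose)
        row["improvement_rate"] = improvement_rate(tr)
        if sulfate:
            row["permutation_distance"] = permutation_rmsd(tr.end_pose, tr.true_pose)
            row["center_distance"] = center_distance(tr.end_pose, tr.true_pose)
            row["improvement_rate_permutation"] = improvement_rate(tr, distance=permutation_rmsd)
            row["improvement_rate_center"] = improvement_rate(tr, distance=center_distance)
        rows.append(row)
    df = pd.DataFrame(rows)
    numeric = df.drop(columns=["episode"])
    agg = pd.DataFrame([numeric.mean(), numeric.median()])
    agg.insert(0, "episode", ["mean", "median"])
    return pd.concat([df, agg], ignore_index=True)
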