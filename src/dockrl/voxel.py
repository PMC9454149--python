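"""Gridded cubic boxes: geometry, Gaussian density splatting and rendering.

A box is an ``edge × edge × edge`` Å cube gridded at ``voxel_size`` Å
(default 18 Å / 1 Å → an 18³ grid). Voxel ``(i, j, k)`` covers the
half-open cell ``origin + [i, i+1) · voxel_size`` per axis; its center sits
at ``origin + (i + 0.5) · voxel_size``. Each atom deposits unit mass as a
normalized Gaussian over its own voxel and the 26 surrounding voxels;
per-channel densities are the sums of those splats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import ChannelMap, ComplexRecord

__all__ = [
    "BoxSpec",
    "BoxPlacementError",
    "GridBox",
    "LigandPose",
    "OutOfGridError",
    "gaussian_splat",
    "make_box",
    "random_rotation",
    "random_start_pose",
]

# Offsets of a voxel and its 26 neighbours.
_OFFSETS = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)],
    dtype=int,
)


class OutOfGridError(ValueError):
    """An atom's own voxel lies outside the grid."""


class BoxPlacementError(RuntimeError):
    """No valid box center found within the attempt budget."""


@dataclass(frozen=True)
class BoxSpec:
    """Geometry and validity constraints of the cubic box.

    ``margin`` is the minimum distance from every true-pose ligand atom to
    each box face; ``min_protein_atoms`` is the least protein content that
    makes a sampled box acceptable.
    """

    edge_length: float = 18.0
    voxel_size: float = 1.0
    margin: float = 2.0
    min_protein_atoms: int = 30
    max_attempts: int = 500

    def __post_init__(self):
        n = self.edge_length / self.voxel_size
        if abs(n - round(n)) > 1e-9:
            raise ValueError("edge_length must be divisible by voxel_size")

    @property
    def n_voxels(self) -> int:
        return int(round(self.edge_length / self.voxel_size))


@dataclass(frozen=True)
class LigandPose:
    """Rigid placement of the ligand: atom coordinates (n, 3) in Å plus a
    bookkeeping orientation matrix (identity for single atoms)."""

    coords: np.ndarray
    elements: tuple[str, ...]
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "orientation", np.asarray(self.orientation, dtype=float))
        if len(self.elements) != len(coords):
            raise ValueError("elements / coords length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


def gaussian_splat(
    center: np.ndarray,
    radius: float,
    origin: np.ndarray,
    voxel_size: float,
    grid_shape: tuple[int, int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Distribute an atom's unit mass over its voxel and the 26 neighbours.

    The raw weight at a voxel center ``c`` is
    ``(2πr²)^{-3/2} · exp(-|c - x|² / (2r²))`` with ``x`` the atom position
    and ``r`` its vdW radius; the 27 weights are normalized to sum to 1 and
    *then* voxels outside the grid are dropped (mass is lost at borders).

    Returns ``(indices, weights)`` with ``indices`` of shape (m, 3),
    ``m ≤ 27``. Raises :class:`OutOfGridError` if the atom's own voxel is
    outside the grid.
    """
    center = np.asarray(center, dtype=float)
    origin = np.asarray(origin, dtype=float)
    shape = np.asarray(grid_shape, dtype=int)
    home = np.floor((center - origin) / voxel_size).astype(int)
    if np.any(home < 0) or np.any(home >= shape):
        raise OutOfGridError(f"atom at {center} outside grid")
    vox = home + _OFFSETS
    centers = origin + (vox + 0.5) * voxel_size
    d2 = np.sum((centers - center) ** 2, axis=1)
    w = (2.0 * np.pi * radius**2) ** (-1.5) * np.exp(-d2 / (2.0 * radius**2))
    w = w / w.sum()
    keep = np.all((vox >= 0) & (vox < shape), axis=1)
    return vox[keep], w[keep]


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform SO(3) rotation matrix via a unit quaternion drawn from the
    seeded generator (all box randomness flows through ``rng``)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_matrix()


@dataclass
class GridBox:
    """A placed box: geometry plus the protein atoms retained inside it.

    Protein-channel densities are rendered once and cached; ligand channels
    are re-rendered per pose, so moving the ligand never touches the cached
    protein part.
    """

    spec: BoxSpec
    origin: np.ndarray
    rotation: np.ndarray
    channel_map: ChannelMap
    protein_coords: np.ndarray
    protein_channels: np.ndarray
    protein_radii: np.ndarray
    ligand_elements: tuple[str, ...]
    ligand_radii: np.ndarray
    true_pose: LigandPose
    _protein_density: np.ndarray | None = None

    @property
    def n_voxels(self) -> int:
        return self.spec.n_voxels

    @property
    def n_channels(self) -> int:
        return self.channel_map.n_channels

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        n = self.n_voxels
        return (n, n, n)

    def contains(self, coords: np.ndarray) -> bool:
        """True iff every point lies strictly inside the box."""
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        hi = self.origin + self.spec.edge_length
        return bool(np.all(coords > self.origin) and np.all(coords < hi))

    def _render_atoms(
        self, coords: np.ndarray, radii: np.ndarray, channels: np.ndarray, n_channels: int
    ) -> np.ndarray:
        n = self.n_voxels
        out = np.zeros((n, n, n, n_channels), dtype=float)
        for xyz, r, ch in zip(coords, radii, channels):
            vox, w = gaussian_splat(xyz, r, self.origin, self.spec.voxel_size, self.grid_shape)
            np.add.at(out, (vox[:, 0], vox[:, 1], vox[:, 2], np.full(len(w), ch)), w)
        return out

    def protein_density(self) -> np.ndarray:
        """Cached (n, n, n, N) density with only protein channels filled."""
        if self._protein_density is None:
            self._protein_density = self._render_atoms(
                self.protein_coords,
                self.protein_radii,
                self.protein_channels,
                self.n_channels,
            )
            self._protein_density.setflags(write=False)
        return self._protein_density

    def ligand_density(self, pose: LigandPose) -> np.ndarray:
        if not self.contains(pose.coords):
            raise OutOfGridError("ligand pose outside box")
        channels = np.array(
            [self.channel_map.ligand_channel(e) for e in pose.elements], dtype=int
        )
        return self._render_atoms(pose.coords, self.ligand_radii, channels, self.n_channels)

    def render(self, pose: LigandPose) -> np.ndarray:
        """Full (n, n, n, N) grid: cached protein channels + this pose."""
        return self.protein_density() + self.ligand_density(pose)

    def to_hdf5(self, path, pose: LigandPose | None = None) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["edge_length"] = self.spec.edge_length
            f.attrs["voxel_size"] = self.spec.voxel_size
            f.attrs["channel_map_hash"] = self.channel_map.content_hash()
            f.create_dataset("origin", data=self.origin)
            f.create_dataset("rotation", data=self.rotation)
            f.create_dataset("true_pose", data=self.true_pose.coords)
            if pose is not None:
                f.create_dataset("densities", data=self.render(pose))


def make_box(
    record: ComplexRecord,
    spec: BoxSpec,
    channel_map: ChannelMap,
    rng: np.random.Generator | int,
) -> tuple[GridBox, LigandPose]:
    """Rotate the complex uniformly at random and cut a valid cubic box.

    The sampled box center keeps every true-pose ligand atom at least
    ``spec.margin`` from all faces and must enclose at least
    ``spec.min_protein_atoms`` protein atoms; protein atoms outside the box
    are discarded. Returns the box and the true pose (s0) in box-frame
    (world) coordinates. Raises :class:`BoxPlacementError` after
    ``spec.max_attempts`` failed draws.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    lig0 = record.ligand_coords
    prot0 = record.protein_coords
    pivot = lig0.mean(axis=0)
    half = spec.edge_length / 2.0

    lo_extent = spec.edge_length - 2.0 * spec.margin
    if np.any(lig0.max(axis=0) - lig0.min(axis=0) > lo_extent):
        raise BoxPlacementError("ligand larger than box minus margins")

    for _ in range(spec.max_attempts):
        R = random_rotation(rng)
        lig = (lig0 - pivot) @ R.T + pivot
        prot = (prot0 - pivot) @ R.T + pivot
        c_lo = lig.max(axis=0) + spec.margin - half
        c_hi = lig.min(axis=0) - spec.margin + half
        center = rng.uniform(c_lo, c_hi)
        origin = center - half
        if prot.size:
            inside = np.all((prot >= origin) & (prot < origin + spec.edge_length), axis=1)
        else:
            inside = np.zeros(0, dtype=bool)
        if inside.sum() < spec.min_protein_atoms:
            continue
        elements = tuple(a.element.strip().upper() for a in record.ligand_atoms)
        box = GridBox(
            spec=spec,
            origin=origin,
            rotation=R,
            channel_map=channel_map,
            protein_coords=prot[inside],
            protein_channels=np.array(
                [a.channel for a in record.protein_atoms], dtype=int
            )[inside],
            protein_radii=np.array(
                [a.vdw_radius for a in record.protein_atoms], dtype=float
            )[inside],
            ligand_elements=elements,
            ligand_radii=np.array([a.vdw_radius for a in record.ligand_atoms], dtype=float),
            true_pose=LigandPose(coords=lig, elements=elements, orientation=R),
        )
        return box, box.true_pose
    raise BoxPlacementError(
        f"box placement failed after {spec.max_attempts} attempts "
        f"(min_protein_atoms={spec.min_protein_atoms})"
    )


def random_start_pose(
    true_pose: LigandPose,
    box: GridBox,
    rng: np.random.Generator | int,
    max_attempts: int = 10_000,
) -> LigandPose:
    """Randomly rotate the ligand and place it uniformly inside the box.

    Single-atom ligands get a uniform position in the box interior;
    multi-atom ligands additionally get a uniform SO(3) orientation about
    their centroid, rejection-sampled until all atoms are strictly inside.
    Rigid: interatomic distances match the true pose's.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    base = true_pose.coords - true_pose.centroid
    multi = true_pose.n_atoms > 1
    hi = box.origin + box.spec.edge_length
    for _ in range(max_attempts):
        R = random_rotation(rng) if multi else np.eye(3)
        centroid = rng.uniform(box.origin, hi)
        coords = base @ R.T + centroid
        if np.all(coords > box.origin) and np.all(coords < hi):
            return LigandPose(
                coords=coords,
                elements=true_pose.elements,
                orientation=R @ true_pose.orientation,
            )
    raise BoxPlacementError("could not place a random start pose")
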