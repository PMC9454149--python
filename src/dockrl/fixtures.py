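"""Deterministic toy protein–ligand complexes for desk-scale runs.

Fixtures are protein-like heavy-atom clouds (C/N/O/S) surrounding a
designated true ligand pose, written as standard PDB text that the parser
round-trips. Geometries: ``shell`` places atoms on a sphere around the
site, ``cleft`` carves an approach cone out of the shell, ``empty``
scatters atoms away from the site. Metadata is synthetic (X-ray, 1.5 Å)
so the standard dataset filters pass.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .structures import Atom, ChannelMap, ComplexMetadata, ComplexRecord, vdw_radius, write_pdb
from .voxel import random_rotation

__all__ = ["FixtureSpec", "make_fixture", "make_suite"]

_PROTEIN_ELEMENTS = ("C", "N", "O", "S")
_ELEMENT_WEIGHTS = (0.55, 0.2, 0.2, 0.05)

#: O–S bond length used for the near-regular tetrahedral sulfate, Å.
_SO_BOND = 1.49
_TETRAHEDRON = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / np.sqrt(3.0)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic complex."""

    n_protein_atoms: int = 40
    pocket_geometry: str = "shell"  # empty | shell | cleft
    ligand_kind: str = "single_atom"  # single_atom | sulfate_like
    box_edge: float = 18.0
    shell_radius: float = 4.0
    min_spacing: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.pocket_geometry not in ("empty", "shell", "cleft"):
            raise ValueError(f"unknown pocket geometry: {self.pocket_geometry!r}")
        if self.ligand_kind not in ("single_atom", "sulfate_like"):
            raise ValueError(f"unknown ligand kind: {self.ligand_kind!r}")


def _sample_protein_coords(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample atom positions respecting the pocket geometry and a
    minimum inter-atom spacing (mimics heavy-atom packing: most voxels hold
    at most one heavy atom)."""
    coords: list[np.ndarray] = []
    half = spec.box_edge / 2.0
    attempts = 0
    max_attempts = 20_000
    while len(coords) < spec.n_protein_atoms:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("infeasible fixture geometry: packing failed")
        if spec.pocket_geometry == "shell":
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r = spec.shell_radius + rng.uniform(-0.5, 0.5)
            p = u * r
        elif spec.pocket_geometry == "cleft":
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            if u[0] > 0.5:  # carve an approach channel along +x
                continue
            r = spec.shell_radius + rng.uniform(-0.5, 0.5)
            p = u * r
        else:  # empty: keep a clearing of 3 Å around the site
            p = rng.uniform(-half + 1.0, half - 1.0, size=3)
            if np.linalg.norm(p) < 3.0:
                continue
        if np.abs(p).max() > half - 0.5:
            continue
        if coords and np.min(np.linalg.norm(np.array(coords) - p, axis=1)) < spec.min_spacing:
            continue
        coords.append(p)
    return np.array(coords)


def _ligand_atoms(spec: FixtureSpec, channel_map: ChannelMap, rng: np.random.Generator) -> list[Atom]:
    if spec.ligand_kind == "single_atom":
        return [
            Atom(
                element="CU",
                coords=np.zeros(3),
                vdw_radius=vdw_radius("CU"),
                channel=channel_map.ligand_channel("CU"),
                name="CU",
                res_name="CU",
                res_id=900,
                chain="B",
            )
        ]
    R = random_rotation(rng)
    vertices = (_TETRAHEDRON * _SO_BOND) @ R.T
    atoms = [
        Atom(
            element="S",
            coords=np.zeros(3),
            vdw_radius=vdw_radius("S"),
            channel=channel_map.ligand_channel("S"),
            name="S",
            res_name="SO4",
            res_id=900,
            chain="B",
        )
    ]
    for i, v in enumerate(vertices):
        atoms.append(
            Atom(
                element="O",
                coords=v,
                vdw_radius=vdw_radius("O"),
                channel=channel_map.ligand_channel("O"),
                name=f"O{i + 1}",
                res_name="SO4",
                res_id=900,
                chain="B",
            )
        )
    return atoms


def make_fixture(spec: FixtureSpec, channel_map: ChannelMap) -> tuple[ComplexRecord, str]:
    """Generate one toy complex; returns the record and its PDB text.

    Deterministic: the same spec (including seed) yields byte-identical
    PDB text. The true ligand pose sits at the fixture origin.
    """
    rng = np.random.default_rng(spec.seed)
    prot_coords = _sample_protein_coords(spec, rng)
    elements = rng.choice(_PROTEIN_ELEMENTS, size=len(prot_coords), p=_ELEMENT_WEIGHTS)
    protein_atoms = []
    for i, (el, xyz) in enumerate(zip(elements, prot_coords)):
        protein_atoms.append(
            Atom(
                element=str(el),
                coords=np.round(xyz, 3),  # match PDB precision exactly
                vdw_radius=vdw_radius(str(el)),
                channel=channel_map.protein_channel(str(el), str(el)),
                name=str(el),
                res_name="GLY",
                res_id=i + 1,
                chain="A",
            )
        )
    ligand_atoms = _ligand_atoms(spec, channel_map, rng)
    ligand_atoms = [replace(a, coords=np.round(a.coords, 3)) for a in ligand_atoms]
    code = "CU" if spec.ligand_kind == "single_atom" else "SO4"
    record = ComplexRecord(
        protein_atoms=protein_atoms,
        ligand_atoms=ligand_atoms,
        metadata=ComplexMetadata(
            pdb_id=f"sy{spec.seed % 100:02d}",
            resolution=1.5,
            method="X-RAY DIFFRACTION",
            has_nucleic_or_unk=False,
            ligand_code=code,
        ),
    )
    return record, write_pdb(record)


def make_suite(
    n: int,
    template: FixtureSpec,
    channel_map: ChannelMap,
    base_seed: int = 0,
    out_dir=None,
) -> tuple[list[ComplexRecord], pd.DataFrame]:
    """Generate ``n`` fixtures with distinct seeds plus a manifest.

    The manifest schema matches the real-data dataset manifest
    (pdb_id, path, ligand_code, eligible, reasons) so it feeds the
    training and evaluation CLIs directly. If ``out_dir`` is given, PDB
    files are written there.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    records, rows = [], []
    for i in range(n):
        spec = replace(template, seed=base_seed + i)
        record, text = make_fixture(spec, channel_map)
        path = ""
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            path = str(out / f"fixture_{spec.seed:04d}.pdb")
            Path(path).write_text(text)
        records.append(record)
        rows.append(
            {
                "pdb_id": record.metadata.pdb_id,
                "path": path,
                "ligand_code": record.metadata.ligand_code,
                "eligible": True,
                "reasons": "",
                "seed": spec.seed,
            }
        )
    return records, pd.DataFrame(rows)
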