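"""Protein–ligand complex I/O: PDB parsing, atom typing and dataset filters.

Complexes are read from standard PDB text. Protein heavy atoms are assigned
to the channels of a :class:`ChannelMap`; ligand atoms (matched by a 3-letter
het code) become the movable ligand with its crystallographic placement kept
as the true pose. Hydrogens and waters are always discarded.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from biotite.structure.io import pdb as _pdb

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "ChannelMap",
    "ComplexMetadata",
    "ComplexRecord",
    "FilterCriteria",
    "LigandNotFoundError",
    "default_channel_map",
    "element_channel_map",
    "filter_record",
    "parse_all_complexes",
    "parse_complex",
    "write_pdb",
]

#: Van der Waals radii in Å (Bondi 1964 / common extensions); used as the
#: Gaussian width of each atom's density splat.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "P": 1.80,
    "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90, "B": 1.92,
    "CU": 1.40, "ZN": 1.39, "FE": 1.40, "MG": 1.73, "MN": 1.40, "NA": 2.27,
    "K": 2.75, "CA": 2.31, "NI": 1.63, "CO": 1.40, "CD": 1.58, "HG": 1.55,
}
DEFAULT_VDW_RADIUS = 1.70

#: Residue names that flag a structure as containing nucleic acids or
#: unknown polymer residues.
NUCLEIC_OR_UNK = {
    "A", "C", "G", "U", "I", "N",
    "DA", "DC", "DG", "DT", "DI", "DU",
    "UNK",
}

WATER_NAMES = {"HOH", "WAT", "DOD"}


class LigandNotFoundError(ValueError):
    """Raised when the requested het code has no atoms in the PDB text."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom with its splat radius and channel assignment.

    ``coords`` are Cartesian, in Å. ``vdw_radius`` is the ``r`` of the
    Gaussian smoothing formula. ``channel`` indexes into the active
    channel map, ``0 <= channel < n_channels``.
    """

    element: str
    coords: np.ndarray
    vdw_radius: float
    channel: int
    name: str = ""
    res_name: str = ""
    res_id: int = 1
    chain: str = "A"

    def __post_init__(self):
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if self.coords.shape != (3,):
            raise ValueError("coords must be a 3-vector")
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")


# Protein atom-name families of the default 21-class map. Atom names are
# matched against these sets in order; anything unmatched falls through to
# the element-level classes and finally the catch-all class 20.
_DEFAULT_PROTEIN_CLASSES: list[tuple[str, frozenset[str]]] = [
    ("N_backbone", frozenset({"N"})),
    ("CA", frozenset({"CA"})),
    ("C_backbone", frozenset({"C"})),
    ("O_backbone", frozenset({"O", "OXT"})),
    ("CB", frozenset({"CB"})),
    ("CG_family", frozenset({"CG", "CG1", "CG2"})),
    ("CD_family", frozenset({"CD", "CD1", "CD2"})),
    ("CE_family", frozenset({"CE", "CE1", "CE2", "CE3"})),
    ("CZ_family", frozenset({"CZ", "CZ2", "CZ3", "CH2"})),
    ("ND_family", frozenset({"ND1", "ND2"})),
    ("NE_family", frozenset({"NE", "NE1", "NE2"})),
    ("NZ_NH_family", frozenset({"NZ", "NH1", "NH2"})),
    ("OG_family", frozenset({"OG", "OG1"})),
    ("OD_family", frozenset({"OD1", "OD2"})),
    ("OE_family", frozenset({"OE1", "OE2"})),
    ("OH", frozenset({"OH"})),
    ("SD", frozenset({"SD"})),
    ("SG", frozenset({"SG"})),
    ("O_other", frozenset()),
    ("N_other", frozenset()),
    ("other", frozenset()),
]


@dataclass(frozen=True)
class ChannelMap:
    """Assignment of protein atoms and ligand atoms to grid channels.

    ``protein_classes`` is an ordered list of ``(name, atom-name set)``
    pairs; an atom is assigned to the first class whose set contains its
    (stripped, upper-cased) atom name.  Atoms matching no named class fall
    back to per-element classes named ``"<EL>_other"`` if present and
    finally to the last class, which acts as the catch-all.
    ``ligand_channels`` lists the ligand element symbols, one channel per
    distinct element, appended after the protein channels.
    """

    protein_classes: tuple[tuple[str, frozenset[str]], ...]
    ligand_channels: tuple[str, ...]

    @property
    def n_protein_channels(self) -> int:
        return len(self.protein_classes)

    @property
    def n_channels(self) -> int:
        return len(self.protein_classes) + len(self.ligand_channels)

    def protein_channel(self, atom_name: str, element: str) -> int:
        name = atom_name.strip().upper()
        elem = element.strip().upper()
        for i, (_, names) in enumerate(self.protein_classes):
            if name in names:
                return i
        class_names = [cname for cname, _ in self.protein_classes]
        fallback = f"{elem}_other"
        if fallback in class_names:
            return class_names.index(fallback)
        if elem not in VDW_RADII:
            logger.warning("unknown element %r (atom %r): using fallback channel", element, atom_name)
        return len(self.protein_classes) - 1

    def ligand_channel(self, element: str) -> int:
        elem = element.strip().upper()
        try:
            idx = self.ligand_channels.index(elem)
        except ValueError:
            raise ValueError(f"ligand element {element!r} has no channel in this map") from None
        return self.n_protein_channels + idx

    def content_hash(self) -> str:
        """Stable hash of the map, recorded in checkpoints and manifests."""
        payload = json.dumps(
            {
                "protein": [[n, sorted(s)] for n, s in self.protein_classes],
                "ligand": list(self.ligand_channels),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_channel_map(ligand_elements: tuple[str, ...]) -> ChannelMap:
    """The default 21-class protein map plus one channel per ligand element.

    For the copper configuration (``("CU",)``) the total channel count is
    22; for sulfate (``("S", "O")``) it is 23.
    """
    cmap = ChannelMap(
        protein_classes=tuple(_DEFAULT_PROTEIN_CLASSES),
        ligand_channels=tuple(e.strip().upper() for e in ligand_elements),
    )
    assert cmap.n_protein_channels == 21
    return cmap


def element_channel_map(
    ligand_elements: tuple[str, ...],
    protein_elements: tuple[str, ...] = ("C", "N", "O", "S"),
) -> ChannelMap:
    """A compact per-element map (used for desk-scale experiments)."""
    classes = [(f"{e.upper()}_other", frozenset()) for e in protein_elements]
    classes.append(("other", frozenset()))
    return ChannelMap(
        protein_classes=tuple(classes),
        ligand_channels=tuple(e.strip().upper() for e in ligand_elements),
    )


@dataclass(frozen=True)
class ComplexMetadata:
    pdb_id: str = ""
    resolution: float | None = None
    method: str = ""
    has_nucleic_or_unk: bool = False
    ligand_code: str = ""
    ligand_instance: int = 0


@dataclass
class ComplexRecord:
    """A parsed complex: fixed protein environment plus one ligand instance.

    ``ligand_atoms`` carry the crystallographic (true) pose, s0.
    """

    protein_atoms: list[Atom]
    ligand_atoms: list[Atom]
    metadata: ComplexMetadata = field(default_factory=ComplexMetadata)

    def __post_init__(self):
        if not self.ligand_atoms:
            raise ValueError("ligand_atoms must be non-empty")

    @property
    def protein_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.protein_atoms], dtype=float).reshape(-1, 3)

    @property
    def ligand_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.ligand_atoms], dtype=float).reshape(-1, 3)


def vdw_radius(element: str) -> float:
    elem = element.strip().upper()
    if elem not in VDW_RADII:
        logger.warning("no vdW radius for element %r: using %.2f Å", element, DEFAULT_VDW_RADIUS)
        return DEFAULT_VDW_RADIUS
    return VDW_RADII[elem]


def _scan_header(pdb_text: str) -> tuple[str, float | None, str]:
    pdb_id, resolution, method = "", None, ""
    for line in pdb_text.splitlines():
        rec = line[:6]
        if rec == "HEADER":
            pdb_id = line[62:66].strip().lower()
        elif rec == "EXPDTA":
            method = line[10:].strip()
        elif line.startswith("REMARK   2 RESOLUTION"):
            for tok in line[22:].split():
                try:
                    resolution = float(tok)
                    break
                except ValueError:
                    continue
    return pdb_id, resolution, method


def parse_all_complexes(pdb_text: str, ligand_code: str, channel_map: ChannelMap) -> list[ComplexRecord]:
    """Parse PDB text into one :class:`ComplexRecord` per ligand instance.

    Hydrogens (H/D) and waters are excluded; alternate locations are
    resolved to the highest-occupancy conformer; every retained atom gets a
    channel and a vdW radius. Raises :class:`LigandNotFoundError` when no
    HETATM group matches ``ligand_code``.
    """
    code = ligand_code.strip().upper()
    pdb_file = _pdb.PDBFile.read(io.StringIO(pdb_text))
    arr = pdb_file.get_structure(model=1, altloc="occupancy")

    pdb_id, resolution, method = _scan_header(pdb_text)

    elements = np.char.upper(arr.element)
    res_names = np.char.upper(np.char.strip(arr.res_name))
    heavy = (elements != "H") & (elements != "D")
    not_water = ~np.isin(res_names, sorted(WATER_NAMES))
    keep = heavy & not_water

    polymer_res = res_names[keep & ~arr.hetero]
    has_nucleic = bool(np.isin(polymer_res, sorted(NUCLEIC_OR_UNK)).any()) or bool(
        (res_names[keep] == "UNK").any()
    )

    is_ligand = keep & arr.hetero & (res_names == code)
    if not is_ligand.any():
        raise LigandNotFoundError(f"ligand not found: {ligand_code!r}")

    protein_atoms: list[Atom] = []
    protein_mask = keep & ~is_ligand
    for i in np.flatnonzero(protein_mask):
        elem = str(elements[i])
        protein_atoms.append(
            Atom(
                element=elem,
                coords=arr.coord[i],
                vdw_radius=vdw_radius(elem),
                channel=channel_map.protein_channel(str(arr.atom_name[i]), elem),
                name=str(arr.atom_name[i]),
                res_name=str(arr.res_name[i]),
                res_id=int(arr.res_id[i]),
                chain=str(arr.chain_id[i]),
            )
        )

    # Group ligand atoms by (chain, residue id): one record per instance.
    instances: dict[tuple[str, int], list[int]] = {}
    for i in np.flatnonzero(is_ligand):
        instances.setdefault((str(arr.chain_id[i]), int(arr.res_id[i])), []).append(int(i))

    records = []
    for n_inst, (key, idxs) in enumerate(sorted(instances.items())):
        ligand_atoms = []
        for i in idxs:
            elem = str(elements[i])
            ligand_atoms.append(
                Atom(
                    element=elem,
                    coords=arr.coord[i],
                    vdw_radius=vdw_radius(elem),
                    channel=channel_map.ligand_channel(elem),
                    name=str(arr.atom_name[i]),
                    res_name=str(arr.res_name[i]),
                    res_id=int(arr.res_id[i]),
                    chain=str(arr.chain_id[i]),
                )
            )
        meta = ComplexMetadata(
            pdb_id=pdb_id,
            resolution=resolution,
            method=method,
            has_nucleic_or_unk=has_nucleic,
            ligand_code=code,
            ligand_instance=n_inst,
        )
        records.append(ComplexRecord(protein_atoms, ligand_atoms, meta))
    return records


def parse_complex(
    pdb_text: str, ligand_code: str, channel_map: ChannelMap, instance: int = 0
) -> ComplexRecord:
    """Parse one ligand instance (default: the first) out of PDB text."""
    records = parse_all_complexes(pdb_text, ligand_code, channel_map)
    return records[instance]


@dataclass(frozen=True)
class FilterCriteria:
    """Dataset eligibility: X-ray, resolution < ``max_resolution`` Å, no
    DNA/RNA/UNK residues."""

    max_resolution: float = 2.0
    require_xray: bool = True
    exclude_nucleic_or_unk: bool = True


def filter_record(
    record: ComplexRecord, criteria: FilterCriteria | None = None
) -> tuple[bool, list[str]]:
    """Check a record against the dataset filters.

    Returns ``(eligible, reasons)`` where ``reasons`` names every failed
    criterion (empty when eligible).
    """
    criteria = criteria or FilterCriteria()
    meta = record.metadata
    reasons: list[str] = []
    if criteria.require_xray and "X-RAY" not in meta.method.upper():
        reasons.append(f"method is not X-ray: {meta.method!r}")
    if meta.resolution is None:
        reasons.append("no resolution")
    elif meta.resolution >= criteria.max_resolution:
        reasons.append(
            f"resolution {meta.resolution:.2f} Å not better than {criteria.max_resolution:.1f} Å"
        )
    if criteria.exclude_nucleic_or_unk and meta.has_nucleic_or_unk:
        reasons.append("contains DNA/RNA/UNK residues")
    return (not reasons), reasons


def _pdb_atom_line(record_name: str, serial: int, atom: Atom) -> str:
    name = atom.name.strip() or atom.element.strip()
    elem = atom.element.strip().upper()
    # Standard alignment: 1-char element names start in column 14,
    # 2-char elements in column 13.
    if len(name) >= 4:
        fmt_name = name[:4]
    elif len(elem) == 2:
        fmt_name = f"{name:<4s}"
    else:
        fmt_name = f" {name:<3s}"
    x, y, z = atom.coords
    return (
        f"{record_name:<6s}{serial:>5d} {fmt_name:<4.4s} {atom.res_name:>3.3s} "
        f"{atom.chain:1.1s}{atom.res_id:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{atom.element.strip().upper():>2.2s}"
    )


def write_pdb(record: ComplexRecord, ligand_pose: np.ndarray | None = None) -> str:
    """Serialize a record to PDB text (optionally with a replacement ligand
    pose), suitable for re-parsing by :func:`parse_complex`."""
    meta = record.metadata
    lines = []
    if meta.pdb_id:
        lines.append(f"HEADER    COMPLEX                                 01-JAN-00   {meta.pdb_id.upper():<4s}")
    if meta.method:
        lines.append(f"EXPDTA    {meta.method}")
    if meta.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {meta.resolution:6.2f} ANGSTROMS.")
    serial = 0
    for atom in record.protein_atoms:
        serial += 1
        lines.append(_pdb_atom_line("ATOM", serial, atom))
    lig = record.ligand_atoms
    if ligand_pose is not None:
        pose = np.asarray(ligand_pose, dtype=float).reshape(-1, 3)
        if len(pose) != len(lig):
            raise ValueError("pose atom count mismatch")
        lig = [replace(a, coords=c) for a, c in zip(lig, pose)]
    for atom in lig:
        serial += 1
        lines.append(_pdb_atom_line("HETATM", serial, atom))
    lines.append("END")
    return "\n".join(lines) + "\n"
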