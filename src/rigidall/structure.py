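"""Structure and ensemble I/O, polar-hydrogen placement and site selection.

Structures are held in a light-weight :class:`StructureModel` (an ordered
list of :class:`AtomRecord` plus cached numpy views).  Reading and writing
of PDB / mmCIF files is delegated to :mod:`biotite`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from functools import total_ordering
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import chemdata
from .geometry import place_atom

logger = logging.getLogger(__name__)

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class FormatError(ValueError):
    """Raised when an input file cannot be parsed."""


class TopologyError(ValueError):
    """Raised when ensemble frames disagree on atom topology."""


class ResidueKey(NamedTuple):
    """Hashable, orderable residue identifier (chain, seq number, icode)."""

    chain: str
    res_seq: int
    icode: str = ""

    def __str__(self) -> str:  # e.g. "A:376" or "A:52A"
        return f"{self.chain}:{self.res_seq}{self.icode}"


@total_ordering
@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    res_name: str
    chain: str
    res_seq: int
    icode: str
    xyz: tuple[float, float, float]
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self):
        if not self.element:
            raise ValueError(f"atom {self.name} has empty element")
        if not all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name} has non-finite coordinates")

    @property
    def residue_key(self) -> ResidueKey:
        return ResidueKey(self.chain, self.res_seq, self.icode)

    def _sort_key(self):
        return (self.chain, self.res_seq, self.icode, self.name)

    def __lt__(self, other):
        return self._sort_key() < other._sort_key()


class StructureModel:
    """One conformer: an ordered collection of atoms with residue indexing."""

    def __init__(self, atoms: Sequence[AtomRecord], model_id: int = 1,
                 label: str = ""):
        self.atoms: list[AtomRecord] = list(atoms)
        self.model_id = model_id
        self.label = label
        self._index()

    def _index(self) -> None:
        self._coords = np.array(
            [a.xyz for a in self.atoms], dtype=float
        ).reshape(-1, 3)
        self._by_residue: dict[ResidueKey, list[int]] = {}
        self._by_atom: dict[tuple[ResidueKey, str], int] = {}
        for i, a in enumerate(self.atoms):
            key = a.residue_key
            self._by_residue.setdefault(key, []).append(i)
            self._by_atom.setdefault((key, a.name), i)

    # -- basic access ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array (do not mutate in place)."""
        return self._coords

    def residues(self) -> list[ResidueKey]:
        """Residue keys ordered by chain, then number, then icode."""
        return sorted(self._by_residue)

    def residue_atoms(self, key: ResidueKey) -> list[int]:
        try:
            return self._by_residue[key]
        except KeyError:
            raise KeyError(f"no residue {key} in model") from None

    def residue_name(self, key: ResidueKey) -> str:
        return self.atoms[self._by_residue[key][0]].res_name

    def atom_index(self, key: ResidueKey, name: str) -> int | None:
        return self._by_atom.get((key, name))

    def atom_coord(self, key: ResidueKey, name: str) -> np.ndarray | None:
        i = self.atom_index(key, name)
        return None if i is None else self._coords[i]

    @property
    def ligands(self) -> set[ResidueKey]:
        """Hetero groups that are not water."""
        out = set()
        for key, idx in self._by_residue.items():
            a = self.atoms[idx[0]]
            if a.is_hetero and a.res_name.upper() not in _WATER_NAMES:
                out.add(key)
        return out

    def find_ligand(self, name: str) -> list[ResidueKey]:
        """All hetero groups matching a ligand name or its synonyms."""
        name = name.upper()
        codes = chemdata.LIGAND_SYNONYMS.get(name, {name})
        return sorted(
            k for k in self.ligands
            if self.residue_name(k).upper() in codes
        )

    def transformed(self, rotation: np.ndarray,
                    translation: np.ndarray) -> "StructureModel":
        """Copy with coordinates mapped through x -> R x + t."""
        new_xyz = self._coords @ np.asarray(rotation, float).T + translation
        atoms = [
            replace(a, xyz=tuple(new_xyz[i])) for i, a in enumerate(self.atoms)
        ]
        return StructureModel(atoms, self.model_id, self.label)

    def protein_mask(self) -> np.ndarray:
        return np.array([not a.is_hetero for a in self.atoms], dtype=bool)


@dataclass
class Ensemble:
    """Ordered frames sharing one atom topology."""

    frames: list[StructureModel]
    frame_times: list[float] | None = None

    def __post_init__(self):
        if not self.frames:
            raise ValueError("ensemble needs at least one frame")
        ref = _topology_keys(self.frames[0])
        for i, fr in enumerate(self.frames[1:], start=2):
            keys = _topology_keys(fr)
            if keys != ref:
                mism = _first_mismatch(ref, keys)
                raise TopologyError(
                    f"frame {i} topology differs from frame 1 "
                    f"(first mismatch: {mism})"
                )

    def __len__(self) -> int:
        return len(self.frames)


def _topology_keys(model: StructureModel) -> list[tuple[str, int, str, str]]:
    return [(a.chain, a.res_seq, a.icode, a.name) for a in model.atoms]


def _first_mismatch(ref, other) -> str:
    for i, (a, b) in enumerate(zip(ref, other)):
        if a != b:
            return f"position {i}: {a} vs {b}"
    return f"atom count {len(ref)} vs {len(other)}"


# --------------------------------------------------------------------------
# reading / writing
# --------------------------------------------------------------------------


def _atoms_from_atom_array(array) -> list[AtomRecord]:
    records = []
    n = array.array_length()
    serials = (
        array.get_annotation("atom_id")
        if "atom_id" in array.get_annotation_categories()
        else np.arange(1, n + 1)
    )
    occ = (
        array.get_annotation("occupancy")
        if "occupancy" in array.get_annotation_categories()
        else np.ones(n)
    )
    bfac = (
        array.get_annotation("b_factor")
        if "b_factor" in array.get_annotation_categories()
        else np.zeros(n)
    )
    for i in range(n):
        records.append(
            AtomRecord(
                serial=int(serials[i]),
                name=str(array.atom_name[i]),
                element=str(array.element[i]),
                res_name=str(array.res_name[i]),
                chain=str(array.chain_id[i]),
                res_seq=int(array.res_id[i]),
                icode=str(array.ins_code[i]).strip(),
                # file coordinates carry 3 decimals; rounding recovers the
                # exact text values from biotite's float32 storage
                xyz=tuple(round(float(x), 3) for x in array.coord[i]),
                occupancy=float(occ[i]),
                b_factor=float(bfac[i]),
                is_hetero=bool(array.hetero[i]),
            )
        )
    return records


def _load_file(path: str | Path):
    from biotite.structure.io import pdb as bt_pdb

    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix in (".cif", ".mmcif", ".pdbx"):
            from biotite.structure.io import pdbx as bt_pdbx

            return bt_pdbx.CIFFile.read(str(path)), "cif"
        return bt_pdb.PDBFile.read(str(path)), "pdb"
    except Exception as exc:  # noqa: BLE001 - re-raise as format error
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def _get_model(handle, kind: str, model_index: int):
    from biotite.structure.io import pdb as bt_pdb

    try:
        if kind == "pdb":
            return handle.get_structure(
                model=model_index,
                altloc="occupancy",
                extra_fields=["atom_id", "occupancy", "b_factor"],
            )
        from biotite.structure.io import pdbx as bt_pdbx

        return bt_pdbx.get_structure(
            handle,
            model=model_index,
            altloc="occupancy",
            extra_fields=["atom_id", "occupancy", "b_factor"],
        )
    except Exception as exc:  # noqa: BLE001
        msg = str(exc)
        if "model" in msg.lower():
            raise IndexError(
                f"model {model_index} not present: {msg}"
            ) from exc
        raise FormatError(f"cannot read coordinates: {msg}") from exc


def read_structure(path: str | Path, model_index: int = 1,
                   label: str = "") -> StructureModel:
    """Read one model of a PDB or mmCIF file.

    Altloc groups are resolved to the highest-occupancy conformer; hetero
    groups (ligands) are retained and flagged.
    """
    handle, kind = _load_file(path)
    array = _get_model(handle, kind, model_index)
    atoms = _atoms_from_atom_array(array)
    if not atoms:
        raise FormatError(f"{path}: no atoms in model {model_index}")
    return StructureModel(atoms, model_id=model_index,
                          label=label or Path(path).stem)


def read_ensemble(path: str | Path) -> Ensemble:
    """Read a multi-model PDB file as an ensemble with a shared topology."""
    from biotite.structure.io import pdb as bt_pdb

    path = Path(path)
    try:
        handle = bt_pdb.PDBFile.read(str(path))
        n_models = handle.get_model_count()
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    frames = []
    for m in range(1, n_models + 1):
        array = _get_model(handle, "pdb", m)
        frames.append(
            StructureModel(_atoms_from_atom_array(array), model_id=m,
                           label=f"{path.stem}#{m}")
        )
    return Ensemble(frames)


def _to_atom_array(model: StructureModel):
    import biotite.structure as bt_struct

    n = len(model)
    array = bt_struct.AtomArray(n)
    array.coord = np.asarray(model.coords, dtype=np.float32)
    array.chain_id = np.array([a.chain for a in model.atoms])
    array.res_id = np.array([a.res_seq for a in model.atoms])
    array.ins_code = np.array([a.icode for a in model.atoms])
    array.res_name = np.array([a.res_name for a in model.atoms])
    array.atom_name = np.array([a.name for a in model.atoms])
    array.element = np.array([a.element.upper() for a in model.atoms])
    array.hetero = np.array([a.is_hetero for a in model.atoms])
    array.set_annotation(
        "b_factor", np.array([a.b_factor for a in model.atoms])
    )
    array.set_annotation(
        "occupancy", np.array([a.occupancy for a in model.atoms])
    )
    array.set_annotation(
        "atom_id", np.array([a.serial for a in model.atoms], dtype=int)
    )
    return array


def write_structure(model_or_ensemble, path: str | Path) -> None:
    """Write a model (or every frame of an ensemble) as a PDB file."""
    import biotite.structure as bt_struct
    from biotite.structure.io import pdb as bt_pdb

    handle = bt_pdb.PDBFile()
    if isinstance(model_or_ensemble, Ensemble):
        arrays = [_to_atom_array(fr) for fr in model_or_ensemble.frames]
        stack = bt_struct.stack(arrays)
        handle.set_structure(stack)
    else:
        handle.set_structure(_to_atom_array(model_or_ensemble))
    handle.write(str(path))


# --------------------------------------------------------------------------
# polar hydrogen placement
# --------------------------------------------------------------------------

_BOND_H = {"N": 1.01, "O": 0.96, "S": 1.34}

#: conventional hydrogen names per (residue, donor) -> tuple of names
_H_NAMES = {
    ("SER", "OG"): ("HG",), ("THR", "OG1"): ("HG1",),
    ("TYR", "OH"): ("HH",), ("CYS", "SG"): ("HG",),
    ("LYS", "NZ"): ("HZ1", "HZ2", "HZ3"),
    ("ARG", "NE"): ("HE",), ("ARG", "NH1"): ("HH11", "HH12"),
    ("ARG", "NH2"): ("HH21", "HH22"),
    ("HIS", "ND1"): ("HD1",), ("HIS", "NE2"): ("HE2",),
    ("TRP", "NE1"): ("HE1",),
    ("ASN", "ND2"): ("HD21", "HD22"), ("GLN", "NE2"): ("HE21", "HE22"),
}

# donor -> (base atom, reference atom bonded to base) for torsional placement
_DONOR_FRAME = {
    ("SER", "OG"): ("CB", "CA"), ("THR", "OG1"): ("CB", "CA"),
    ("TYR", "OH"): ("CZ", "CE1"), ("CYS", "SG"): ("CB", "CA"),
    ("LYS", "NZ"): ("CE", "CD"),
    ("ARG", "NH1"): ("CZ", "NE"), ("ARG", "NH2"): ("CZ", "NE"),
    ("ASN", "ND2"): ("CG", "OD1"), ("GLN", "NE2"): ("CD", "OE1"),
}

# donors placed on the external bisector of two heavy neighbours
_DONOR_BISECTOR = {
    ("ARG", "NE"): ("CD", "CZ"),
    ("HIS", "ND1"): ("CG", "CE1"), ("HIS", "NE2"): ("CD2", "CE1"),
    ("TRP", "NE1"): ("CD1", "CE2"),
}


def _existing_h_count(model: StructureModel, key: ResidueKey,
                      donor_xyz: np.ndarray) -> int:
    count = 0
    for i in model.residue_atoms(key):
        a = model.atoms[i]
        if a.element.upper() == "H":
            if np.linalg.norm(np.array(a.xyz) - donor_xyz) < 1.45:
                count += 1
    return count


def _bisector_h(donor: np.ndarray, nb1: np.ndarray, nb2: np.ndarray,
                bond: float) -> np.ndarray:
    u = (nb1 - donor) / np.linalg.norm(nb1 - donor)
    w = (nb2 - donor) / np.linalg.norm(nb2 - donor)
    d = -(u + w)
    return donor + bond * d / np.linalg.norm(d)


def add_polar_hydrogens(model: StructureModel) -> StructureModel:
    """Return a copy with ideal-geometry polar hydrogens added.

    Backbone amide H sits 1.01 A from N on the external bisector of the
    C(-1)-N-CA angle; side-chain donor hydrogens use ideal internal
    coordinates.  Existing hydrogens are preserved and the operation is
    idempotent.  N-terminal amines and prolines gain no backbone H.
    """
    new_atoms = list(model.atoms)
    serial = max((a.serial for a in model.atoms), default=0)
    residues = model.residues()

    def _add(name: str, xyz: np.ndarray, template: AtomRecord):
        nonlocal serial
        serial += 1
        new_atoms.append(
            AtomRecord(
                serial=serial, name=name, element="H",
                res_name=template.res_name, chain=template.chain,
                res_seq=template.res_seq, icode=template.icode,
                xyz=tuple(float(x) for x in xyz),
                occupancy=1.0, b_factor=0.0, is_hetero=template.is_hetero,
            )
        )

    # backbone amide hydrogens
    prev_by_chain: dict[str, ResidueKey] = {}
    for key in residues:
        res_name = model.residue_name(key).upper()
        if res_name not in chemdata.STANDARD_RESIDUES:
            continue
        prev = prev_by_chain.get(key.chain)
        prev_by_chain[key.chain] = key
        if res_name == "PRO" or prev is None:
            continue
        n_xyz = model.atom_coord(key, "N")
        ca_xyz = model.atom_coord(key, "CA")
        c_prev = model.atom_coord(prev, "C")
        if n_xyz is None or ca_xyz is None or c_prev is None:
            logger.warning("backbone donor incomplete at %s; skipped", key)
            continue
        if np.linalg.norm(c_prev - n_xyz) > 1.8:  # chain break
            continue
        if model.atom_index(key, "H") is not None or _existing_h_count(
            model, key, n_xyz
        ):
            continue
        template = model.atoms[model.residue_atoms(key)[0]]
        _add("H", _bisector_h(n_xyz, c_prev, ca_xyz, _BOND_H["N"]), template)

    # side-chain donors
    for key in residues:
        res_name = model.residue_name(key).upper()
        if res_name not in chemdata.STANDARD_RESIDUES:
            continue
        for donor_name, (hyb, n_h) in chemdata._SIDECHAIN_DONORS.get(
            res_name, {}
        ).items():
            d_xyz = model.atom_coord(key, donor_name)
            if d_xyz is None:
                logger.warning("donor %s missing at %s; skipped",
                               donor_name, key)
                continue
            have = _existing_h_count(model, key, d_xyz)
            if have >= n_h:
                continue
            template = model.atoms[model.residue_atoms(key)[0]]
            names = _H_NAMES.get(
                (res_name, donor_name),
                tuple(f"H{donor_name[1:]}{i+1}" for i in range(n_h)),
            )
            frame = _DONOR_FRAME.get((res_name, donor_name))
            bis = _DONOR_BISECTOR.get((res_name, donor_name))
            bond = _BOND_H.get(donor_name[0], 1.0)
            placed: list[np.ndarray] = []
            if bis is not None:
                nb1 = model.atom_coord(key, bis[0])
                nb2 = model.atom_coord(key, bis[1])
                if nb1 is None or nb2 is None:
                    logger.warning("frame atoms missing for donor %s at %s",
                                   donor_name, key)
                    continue
                placed.append(_bisector_h(d_xyz, nb1, nb2, bond))
            elif frame is not None:
                base = model.atom_coord(key, frame[0])
                ref = model.atom_coord(key, frame[1])
                if base is None or ref is None:
                    logger.warning("frame atoms missing for donor %s at %s",
                                   donor_name, key)
                    continue
                if hyb == "sp3":
                    angles = [109.5] * n_h
                    torsions = [180.0, 60.0, -60.0][:n_h]
                else:
                    angles = [120.0] * n_h
                    torsions = [0.0, 180.0][:n_h]
                for ang_, tors in zip(angles, torsions):
                    placed.append(
                        place_atom(ref, base, d_xyz, bond, ang_, tors)
                    )
            else:
                continue
            for h_name, h_xyz in zip(names[have:], placed[have:] or placed):
                _add(h_name, h_xyz, template)

    out = StructureModel(new_atoms, model.model_id, model.label)
    return out


# --------------------------------------------------------------------------
# neighbourhood selection
# --------------------------------------------------------------------------


@dataclass
class NeighborhoodSelection:
    """Atoms (and their residues) within a radius of a ligand."""

    ligand: ResidueKey
    radius: float
    atom_ids: list[int] = field(default_factory=list)
    residues: set[ResidueKey] = field(default_factory=set)

    def to_json(self) -> str:
        return json.dumps(
            {
                "ligand": str(self.ligand),
                "radius": self.radius,
                "atom_ids": self.atom_ids,
                "residues": sorted(str(r) for r in self.residues),
            },
            indent=2,
        )


def select_neighborhood(model: StructureModel, ligand: ResidueKey,
                        radius: float) -> NeighborhoodSelection:
    """All non-ligand atoms within ``radius`` (closed interval) of the ligand.

    Distances are measured to any ligand atom.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    try:
        lig_idx = model.residue_atoms(ligand)
    except KeyError:
        raise KeyError(f"unknown ligand {ligand}") from None
    lig_set = set(lig_idx)
    coords = model.coords
    tree = cKDTree(coords[lig_idx])
    dist, _ = tree.query(coords, k=1)
    sel = NeighborhoodSelection(ligand=ligand, radius=radius)
    for i in np.nonzero(dist <= radius)[0]:
        if int(i) in lig_set:
            continue
        sel.atom_ids.append(int(i))
        sel.residues.add(model.atoms[int(i)].residue_key)
    return sel
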