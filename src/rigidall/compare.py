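"""Conformer comparison: superposition, per-residue RMSD, distance tables,
backbone dihedrals, helix rotations, buried interface areas and residue
interaction network diffs."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import chemdata
from .geometry import dihedral, fibonacci_sphere, fit_line, twist_about_axis
from .network import find_hydrogen_bonds
from .structure import ResidueKey, StructureModel

logger = logging.getLogger(__name__)


class DegeneracyError(ValueError):
    """Raised when a geometric fit is underdetermined."""


# --------------------------------------------------------------------------
# superposition
# --------------------------------------------------------------------------


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper rotation
    translation: np.ndarray
    rmsd: float
    selection_size: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _paired_coords(ref: StructureModel, mobile: StructureModel,
                   selection: Iterable[ResidueKey] | None,
                   atom_names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    wanted = None if selection is None else set(selection)
    names = set(atom_names)
    a, b = [], []
    for key in ref.residues():
        if wanted is not None and key not in wanted:
            continue
        for name in sorted(names):
            i = ref.atom_index(key, name)
            j = mobile.atom_index(key, name)
            if i is not None and j is not None:
                a.append(ref.coords[i])
                b.append(mobile.coords[j])
    return np.asarray(a, float), np.asarray(b, float)


def superpose(ref: StructureModel, mobile: StructureModel,
              selection: Iterable[ResidueKey] | None = None,
              atom_names: Sequence[str] = ("CA",)) -> SuperpositionResult:
    """Kabsch least-squares superposition of paired atoms.

    Pairs are matched by (residue key, atom name); the returned transform
    maps mobile coordinates onto the reference frame.  The rotation is
    always proper (reflections are absorbed as residual RMSD).
    """
    p_ref, p_mob = _paired_coords(ref, mobile, selection, atom_names)
    if len(p_ref) < 3:
        raise DegeneracyError(f"only {len(p_ref)} paired atoms (need >= 3)")
    c_ref = p_ref.mean(axis=0)
    c_mob = p_mob.mean(axis=0)
    x = p_mob - c_mob
    y = p_ref - c_ref
    if np.linalg.matrix_rank(y, tol=1e-8) < 2:
        raise DegeneracyError("collinear selection")
    u, _, vt = np.linalg.svd(x.T @ y)
    d = np.sign(np.linalg.det(u @ vt))
    D = np.diag([1.0, 1.0, d])
    rotation = (u @ D @ vt).T
    translation = c_ref - rotation @ c_mob
    moved = x @ rotation.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - y) ** 2, axis=1))))
    return SuperpositionResult(rotation=rotation, translation=translation,
                               rmsd=rmsd, selection_size=len(p_ref))


@dataclass
class RMSDProfile:
    per_residue: dict[ResidueKey, float]
    reference_label: str
    target_label: str

    def to_frame(self) -> pd.DataFrame:
        keys = sorted(self.per_residue)
        return pd.DataFrame({
            "chain": [k.chain for k in keys],
            "res_seq": [k.res_seq for k in keys],
            "icode": [k.icode for k in keys],
            "ca_rmsd": [self.per_residue[k] for k in keys],
        })

    def mean_over(self, residues: Iterable[ResidueKey]) -> float:
        vals = [self.per_residue[k] for k in residues
                if k in self.per_residue]
        return float(np.mean(vals)) if vals else float("nan")


def per_residue_ca_rmsd(ref: StructureModel, mobile: StructureModel,
                        frame: SuperpositionResult) -> RMSDProfile:
    """|CA_ref - T(CA_mobile)| over the residues common to both models."""
    out = {}
    for key in ref.residues():
        i = ref.atom_index(key, "CA")
        j = mobile.atom_index(key, "CA")
        if i is None or j is None:
            if (i is None) != (j is None):
                logger.warning("residue %s lacks CA in one model; omitted",
                               key)
            continue
        moved = frame.apply(mobile.coords[j][None, :])[0]
        out[key] = float(np.linalg.norm(ref.coords[i] - moved))
    return RMSDProfile(per_residue=out, reference_label=ref.label,
                       target_label=mobile.label)


# --------------------------------------------------------------------------
# residue pair distances
# --------------------------------------------------------------------------


def _residue_distance(model: StructureModel, key_a: ResidueKey,
                      key_b: ResidueKey, metric: str) -> float:
    try:
        ia = model.residue_atoms(key_a)
        ib = model.residue_atoms(key_b)
    except KeyError as exc:
        raise KeyError(f"pair ({key_a}, {key_b}): {exc}") from None
    if metric == "ca":
        pa = model.atom_coord(key_a, "CA")
        pb = model.atom_coord(key_b, "CA")
        if pa is None or pb is None:
            raise KeyError(f"pair ({key_a}, {key_b}): missing CA")
        return float(np.linalg.norm(pa - pb))
    # minimum heavy-atom distance
    ca = np.array([model.coords[i] for i in ia
                   if model.atoms[i].element.upper() != "H"])
    cb = np.array([model.coords[i] for i in ib
                   if model.atoms[i].element.upper() != "H"])
    diff = ca[:, None, :] - cb[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).min())


def residue_pair_distances(models: Mapping[str, StructureModel],
                           pairs: Sequence[tuple[ResidueKey, ResidueKey]],
                           metric: str = "min_heavy") -> pd.DataFrame:
    """Distance table with one row per pair and one column per model.

    With exactly two models a ``ratio`` column (first / second) is added.
    """
    if metric not in ("min_heavy", "ca"):
        raise ValueError("metric must be 'min_heavy' or 'ca'")
    labels = list(models)
    rows = []
    for key_a, key_b in pairs:
        row: dict = {"residue_a": str(key_a), "residue_b": str(key_b),
                     "metric": metric}
        for label in labels:
            row[label] = _residue_distance(models[label], key_a, key_b,
                                           metric)
        if len(labels) == 2:
            row["ratio"] = row[labels[0]] / row[labels[1]]
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# backbone dihedrals
# --------------------------------------------------------------------------


def backbone_dihedrals(model: StructureModel, residue: ResidueKey
                       ) -> tuple[float | None, float | None, float | None]:
    """(phi, psi, omega) in degrees, IUPAC convention, range (-180, 180].

    An angle whose flanking atoms are absent is returned as None.
    """
    chain_residues = [k for k in model.residues() if k.chain == residue.chain]
    try:
        pos = chain_residues.index(residue)
    except ValueError:
        raise KeyError(f"no residue {residue}") from None
    prev = chain_residues[pos - 1] if pos > 0 else None
    nxt = chain_residues[pos + 1] if pos + 1 < len(chain_residues) else None

    n = model.atom_coord(residue, "N")
    ca = model.atom_coord(residue, "CA")
    c = model.atom_coord(residue, "C")
    def _all(*arrays) -> bool:
        return all(x is not None for x in arrays)

    phi = psi = omega = None
    if prev is not None:
        c_prev = model.atom_coord(prev, "C")
        ca_prev = model.atom_coord(prev, "CA")
        if _all(c_prev, n, ca, c):
            phi = dihedral(c_prev, n, ca, c)
        if _all(c_prev, ca_prev, n, ca):
            omega = dihedral(ca_prev, c_prev, n, ca)
    if nxt is not None:
        n_next = model.atom_coord(nxt, "N")
        if _all(n, ca, c, n_next):
            psi = dihedral(n, ca, c, n_next)
    return phi, psi, omega


# --------------------------------------------------------------------------
# helix rotation
# --------------------------------------------------------------------------


@dataclass
class HelixRotation:
    helix_id: str
    angle: float  # degrees in [0, 180]
    sense: str  # clockwise | anticlockwise, viewed from the N-term end
    axis: np.ndarray

    def __post_init__(self):
        if not 0.0 <= self.angle <= 180.0:
            raise ValueError("angle out of range")


def helix_rotation_angle(apo: StructureModel, other: StructureModel,
                         helix: tuple[str, int, int],
                         core: Iterable[ResidueKey] | None = None,
                         helix_id: str = "") -> HelixRotation:
    """Rotation of a helix about its own (apo) axis between two conformers.

    After core superposition the apo-helix axis is fitted by a principal
    component line through the CA atoms; the optimal helix-to-helix rigid
    transform is decomposed and its twist about the apo axis reported.
    The sense is judged looking down the axis from the N-terminal end: a
    right-handed rotation about the N->C axis direction appears clockwise.
    """
    chain, start, end = helix
    helix_keys = [k for k in apo.residues()
                  if k.chain == chain and start <= k.res_seq <= end]
    if len(helix_keys) < 6:
        raise DegeneracyError("helix shorter than 6 residues")
    if core is not None:
        frame = superpose(apo, other, selection=core)
    else:
        frame = SuperpositionResult(np.eye(3), np.zeros(3), 0.0, 0)
    p_apo, p_other = _paired_coords(apo, other, helix_keys, ("CA",))
    if len(p_apo) < 6:
        raise DegeneracyError("fewer than 6 paired helix CA atoms")
    p_other = frame.apply(p_other)
    _, axis = fit_line(p_apo)
    # optimal rigid transform apo-helix -> other-helix
    ca_a = p_apo.mean(axis=0)
    ca_b = p_other.mean(axis=0)
    u, _, vt = np.linalg.svd((p_apo - ca_a).T @ (p_other - ca_b))
    d = np.sign(np.linalg.det(u @ vt))
    rot = (u @ np.diag([1.0, 1.0, d]) @ vt).T
    twist = twist_about_axis(rot, axis)
    sense = "clockwise" if twist > 0 else "anticlockwise"
    return HelixRotation(helix_id=helix_id or f"{chain}:{start}-{end}",
                         angle=abs(twist), sense=sense, axis=axis)


# --------------------------------------------------------------------------
# buried interface area (Shrake-Rupley)
# --------------------------------------------------------------------------


@dataclass
class InterfaceArea:
    bsa: float  # full buried surface area, A^2
    half_bsa: float
    sasa_protein: float
    sasa_ligand: float
    sasa_complex: float


def shrake_rupley_sasa(coords: np.ndarray, radii: np.ndarray,
                       probe: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area by sphere-point sampling."""
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float) + probe
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    areas = np.zeros(len(coords))
    max_r = radii.max()
    for i in range(len(coords)):
        pts = coords[i] + radii[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i],
                                                      radii[i] + max_r)
                     if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d >= radii[j]
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return areas


def buried_interface_area(model: StructureModel, ligand: ResidueKey,
                          probe: float = 1.4,
                          n_points: int = 960) -> InterfaceArea:
    """Buried surface area between a ligand and the protein.

    BSA = SASA(protein) + SASA(ligand) - SASA(complex), Shrake-Rupley
    sampling with Bondi radii; the conventional half-BSA is reported too.
    Other hetero groups are excluded from the calculation.
    """
    lig_idx = model.residue_atoms(ligand)
    prot_idx = [i for i, a in enumerate(model.atoms) if not a.is_hetero]
    if not prot_idx:
        raise ValueError("no protein atoms")
    radii = np.array([chemdata.vdw_radius(a.element) for a in model.atoms])

    def _sasa(indices):
        idx = np.asarray(indices)
        return shrake_rupley_sasa(model.coords[idx], radii[idx], probe,
                                  n_points).sum()

    s_prot = _sasa(prot_idx)
    s_lig = _sasa(lig_idx)
    s_complex = _sasa(prot_idx + list(lig_idx))
    bsa = float(s_prot + s_lig - s_complex)
    return InterfaceArea(bsa=bsa, half_bsa=bsa / 2.0,
                         sasa_protein=float(s_prot),
                         sasa_ligand=float(s_lig),
                         sasa_complex=float(s_complex))


# --------------------------------------------------------------------------
# residue interaction networks
# --------------------------------------------------------------------------

VDW_SLACK = 0.5
PIPI_CENTROID_CUTOFF = 5.5


@dataclass(frozen=True)
class InteractionEdge:
    kind: str  # hbond | vdw | pipi
    residue_a: ResidueKey
    residue_b: ResidueKey
    atom_a: str
    atom_b: str
    distance: float
    energy: float | None = None

    @property
    def pair_key(self) -> tuple[str, ResidueKey, ResidueKey]:
        a, b = sorted((self.residue_a, self.residue_b))
        return (self.kind, a, b)


def _ring_geometry(model: StructureModel, key: ResidueKey,
                   names: Sequence[str]):
    pts = []
    for name in names:
        xyz = model.atom_coord(key, name)
        if xyz is None:
            return None
        pts.append(xyz)
    pts = np.array(pts)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[2]


def interaction_network(model: StructureModel,
                        selection: Iterable[ResidueKey] | None = None
                        ) -> list[InteractionEdge]:
    """Residue interaction edges (hbond / vdw / pipi), one per residue pair
    per kind (closest atom pair kept).  Polar hydrogens must be present
    for hydrogen-bond typing."""
    wanted = None if selection is None else set(selection)

    def _keep(key_a: ResidueKey, key_b: ResidueKey) -> bool:
        if wanted is None:
            return True
        return key_a in wanted and key_b in wanted

    best: dict[tuple, InteractionEdge] = {}

    def _offer(edge: InteractionEdge):
        key = edge.pair_key
        if key not in best or edge.distance < best[key].distance:
            best[key] = edge

    # hydrogen bonds (geometric acceptance via the Mayo potential)
    hbond_pairs: set[frozenset[int]] = set()
    for e in find_hydrogen_bonds(model):
        a = model.atoms[e.body_i]
        b = model.atoms[e.body_j]
        hbond_pairs.add(frozenset((e.body_i, e.body_j)))
        if not _keep(a.residue_key, b.residue_key):
            continue
        d = float(np.linalg.norm(model.coords[e.body_i]
                                 - model.coords[e.body_j]))
        _offer(InteractionEdge("hbond", a.residue_key, b.residue_key,
                               a.name, b.name, d, e.energy))

    # van der Waals contacts
    heavy = [i for i, a in enumerate(model.atoms)
             if a.element.upper() != "H"]
    radii = {i: chemdata.vdw_radius(model.atoms[i].element) for i in heavy}
    tree = cKDTree(model.coords[heavy])
    pairs = tree.query_pairs(2 * max(radii.values()) + VDW_SLACK)
    from .network import detect_covalent_bonds

    cov_pairs = {frozenset((e.body_i, e.body_j))
                 for e in detect_covalent_bonds(model)}
    for p, q in pairs:
        i, j = heavy[p], heavy[q]
        a, b = model.atoms[i], model.atoms[j]
        if a.residue_key == b.residue_key:
            continue
        fs = frozenset((i, j))
        if fs in cov_pairs or fs in hbond_pairs:
            continue
        if not _keep(a.residue_key, b.residue_key):
            continue
        d = float(np.linalg.norm(model.coords[i] - model.coords[j]))
        if d <= radii[i] + radii[j] + VDW_SLACK:
            _offer(InteractionEdge("vdw", a.residue_key, b.residue_key,
                                   a.name, b.name, d))

    # pi-pi ring interactions
    rings = []
    for key in model.residues():
        res_name = model.residue_name(key).upper()
        for names in chemdata.AROMATIC_RINGS.get(res_name, ()):  # type: ignore
            geom = _ring_geometry(model, key, names)
            if geom is not None:
                rings.append((key, names, geom[0], geom[1]))
    for x in range(len(rings)):
        for y in range(x + 1, len(rings)):
            key_a, names_a, cen_a, norm_a = rings[x]
            key_b, names_b, cen_b, norm_b = rings[y]
            if key_a == key_b or not _keep(key_a, key_b):
                continue
            d = float(np.linalg.norm(cen_a - cen_b))
            if d > PIPI_CENTROID_CUTOFF:
                continue
            cosang = abs(float(norm_a @ norm_b))
            ang = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
            if ang <= 30.0 or ang >= 60.0:  # stacked or T-shaped
                _offer(InteractionEdge("pipi", key_a, key_b,
                                       names_a[0], names_b[0], d))

    return sorted(best.values(),
                  key=lambda e: (e.kind, e.residue_a, e.residue_b))


@dataclass
class InteractionDiff:
    only_in_a: list[InteractionEdge]
    only_in_b: list[InteractionEdge]

    @property
    def is_empty(self) -> bool:
        return not self.only_in_a and not self.only_in_b


def diff_interactions(edges_a: Sequence[InteractionEdge],
                      edges_b: Sequence[InteractionEdge]) -> InteractionDiff:
    """Edges keyed by (kind, residue pair) present in one list only."""
    keys_a = {e.pair_key: e for e in edges_a}
    keys_b = {e.pair_key: e for e in edges_b}
    return InteractionDiff(
        only_in_a=[e for k, e in sorted(keys_a.items()) if k not in keys_b],
        only_in_b=[e for k, e in sorted(keys_b.items()) if k not in keys_a],
    )
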