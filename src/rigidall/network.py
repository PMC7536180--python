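"""Molecular constraint networks: covalent bonds, Mayo-ranked hydrogen
bonds and hydrophobic tethers, with bar multiplicities for the body-bar
pebble game (rotatable covalent = 5, locked = 6, hbond = 5, tether = 2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import chemdata
from .geometry import angle
from .structure import ResidueKey, StructureModel

logger = logging.getLogger(__name__)

VALID_BARS = (2, 5, 6)

BARS_ROTATABLE = 5
BARS_LOCKED = 6
BARS_HBOND = 5
BARS_TETHER = 2

#: Mayo potential parameters (kcal/mol, Angstrom).
MAYO_V0 = 8.0
MAYO_D0 = 2.8
HBOND_DIST_CUTOFF = 3.6
SALT_BRIDGE_ENERGY = -10.0
TETHER_SURFACE_CUTOFF = 0.25


@dataclass(frozen=True)
class BarEdge:
    body_i: int
    body_j: int
    bars: int
    kind: str  # covalent_rotatable | covalent_locked | hbond | hydrophobic
    energy: float | None = None  # kcal/mol, hbond edges only

    def __post_init__(self):
        if self.body_i == self.body_j:
            raise ValueError("self-edge")
        if self.bars not in VALID_BARS:
            raise ValueError(f"bars must be one of {VALID_BARS}")


@dataclass
class ConstraintNetwork:
    """Bodies (atoms) joined by bar-weighted edges."""

    n_bodies: int
    edges: list[BarEdge]
    body_residues: list[ResidueKey] | None = None
    coords: np.ndarray | None = None  # used by tests' rank oracle
    hbond_cutoff: float = 0.0
    source_label: str = ""

    def __post_init__(self):
        seen: set[tuple[int, int, str]] = set()
        for e in self.edges:
            if not (0 <= e.body_i < self.n_bodies
                    and 0 <= e.body_j < self.n_bodies):
                raise ValueError(f"edge {e} out of range")
            key = (min(e.body_i, e.body_j), max(e.body_i, e.body_j), e.kind)
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)

    # -- array views for the pebble game ----------------------------------

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        eu = np.array([e.body_i for e in self.edges], dtype=np.int64)
        ev = np.array([e.body_j for e in self.edges], dtype=np.int64)
        eb = np.array([e.bars for e in self.edges], dtype=np.int64)
        return eu, ev, eb

    def undirected_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR adjacency (indptr, indices) of the underlying simple graph."""
        pairs = {(min(e.body_i, e.body_j), max(e.body_i, e.body_j))
                 for e in self.edges}
        counts = np.zeros(self.n_bodies + 1, dtype=np.int64)
        for i, j in pairs:
            counts[i + 1] += 1
            counts[j + 1] += 1
        indptr = np.cumsum(counts)
        indices = np.zeros(indptr[-1], dtype=np.int64)
        cursor = indptr[:-1].copy()
        for i, j in pairs:
            indices[cursor[i]] = j
            cursor[i] += 1
            indices[cursor[j]] = i
            cursor[j] += 1
        return indptr, indices

    def residues_to_bodies(self, residues: Iterable[ResidueKey]) -> np.ndarray:
        if self.body_residues is None:
            raise ValueError("network has no residue back-map")
        wanted = set(residues)
        return np.array(
            [i for i, r in enumerate(self.body_residues) if r in wanted],
            dtype=np.int64,
        )

    # -- serialization (also the pebble-game fixture format) ---------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_bodies={self.n_bodies}\n")
            fh.write("body_i\tbody_j\tkind\tbars\tenergy\n")
            for e in self.edges:
                energy = "" if e.energy is None else f"{e.energy:.6f}"
                fh.write(
                    f"{e.body_i}\t{e.body_j}\t{e.kind}\t{e.bars}\t{energy}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConstraintNetwork":
        edges = []
        n_bodies = 0
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# n_bodies="):
                    n_bodies = int(line.split("=", 1)[1])
                    continue
                if not line.strip() or line.startswith(("#", "body_i")):
                    continue
                bi, bj, kind, bars, energy = line.split("\t")
                edges.append(
                    BarEdge(int(bi), int(bj), int(bars), kind,
                            float(energy) if energy else None)
                )
        if n_bodies == 0:
            n_bodies = 1 + max(
                max(e.body_i, e.body_j) for e in edges
            ) if edges else 0
        return cls(n_bodies=n_bodies, edges=edges)


# --------------------------------------------------------------------------
# Mayo hydrogen-bond energy
# --------------------------------------------------------------------------


def mayo_hbond_energy(donor_xyz, hydrogen_xyz, acceptor_xyz, base_xyz,
                      donor_hyb: str = "sp3",
                      acceptor_hyb: str = "sp3") -> float:
    """Hydrogen-bond energy (kcal/mol) of the Mayo distance/angular potential.

    ``E = V0 * (5 (d0/d)^12 - 6 (d0/d)^10) * F`` with ``d`` the
    donor-acceptor distance, V0 = 8 kcal/mol, d0 = 2.8 A.  F depends on the
    donor/acceptor hybridization (Dahiyat-Gordon-Mayo-style angular
    weights; the sp2-sp2 out-of-plane term is folded into the in-plane
    deviation, see package notes).  Returns 0.0 outside the geometric gates
    (donor-acceptor distance <= 3.6 A, D-H...A angle strictly > 90 deg).
    """
    d_xyz = np.asarray(donor_xyz, float)
    h_xyz = np.asarray(hydrogen_xyz, float)
    a_xyz = np.asarray(acceptor_xyz, float)
    b_xyz = np.asarray(base_xyz, float)

    d = float(np.linalg.norm(a_xyz - d_xyz))
    if d > HBOND_DIST_CUTOFF or d < 1.5:
        return 0.0
    theta = angle(d_xyz, h_xyz, a_xyz)
    if theta <= 90.0:
        return 0.0
    phi = angle(h_xyz, a_xyz, b_xyz)

    cos2_theta = math.cos(math.radians(theta)) ** 2

    def _cos2_dev(value: float, ideal: float) -> float:
        return math.cos(math.radians(value - ideal)) ** 2

    donor_hyb = donor_hyb.lower()
    acceptor_hyb = acceptor_hyb.lower()
    if donor_hyb == "sp3" and acceptor_hyb == "sp3":
        f = cos2_theta * _cos2_dev(phi, 109.5)
    elif donor_hyb == "sp3" and acceptor_hyb == "sp2":
        f = cos2_theta * _cos2_dev(phi, 120.0)
    elif donor_hyb == "sp2" and acceptor_hyb == "sp3":
        f = cos2_theta ** 2
    else:  # sp2 donor, sp2 acceptor
        f = cos2_theta * _cos2_dev(phi, 120.0)

    ratio = MAYO_D0 / d
    radial = MAYO_V0 * (5.0 * ratio**12 - 6.0 * ratio**10)
    return float(radial * f)


# --------------------------------------------------------------------------
# covalent bond detection
# --------------------------------------------------------------------------


def detect_covalent_bonds(model: StructureModel) -> list[BarEdge]:
    """Covalent edges with 5/6 bar multiplicities.

    Standard residues use name templates; anything else falls back to
    distance-based detection (d <= r_cov(i) + r_cov(j) + 0.4 A).  Peptide
    bonds, template double/partial-double bonds and bonds to single-neighbor
    atoms are locked (6 bars); everything else is rotatable (5 bars).
    """
    bonds: dict[tuple[int, int], bool] = {}  # pair -> locked flag

    def _put(i: int, j: int, locked: bool):
        key = (min(i, j), max(i, j))
        bonds[key] = bonds.get(key, False) or locked

    residues = model.residues()
    # template bonds
    for key in residues:
        res_name = model.residue_name(key).upper()
        template = chemdata.residue_bonds(res_name)
        if template is None:
            continue
        for name_a, name_b in template:
            ia = model.atom_index(key, name_a)
            ib = model.atom_index(key, name_b)
            if ia is None or ib is None:
                continue
            _put(ia, ib, chemdata.is_locked_bond(res_name, name_a, name_b))

    # inter-residue peptide bonds (locked)
    prev_by_chain: dict[str, ResidueKey] = {}
    for key in residues:
        res_name = model.residue_name(key).upper()
        if res_name not in chemdata.STANDARD_RESIDUES:
            continue
        prev = prev_by_chain.get(key.chain)
        prev_by_chain[key.chain] = key
        if prev is None:
            continue
        ic = model.atom_index(prev, "C")
        jn = model.atom_index(key, "N")
        if ic is None or jn is None:
            continue
        if np.linalg.norm(model.coords[ic] - model.coords[jn]) <= 1.8:
            _put(ic, jn, True)

    # disulfides (rotatable)
    sg = [model.atom_index(k, "SG") for k in residues
          if model.residue_name(k).upper() == "CYS"]
    sg = [i for i in sg if i is not None]
    for a in range(len(sg)):
        for b in range(a + 1, len(sg)):
            if np.linalg.norm(
                model.coords[sg[a]] - model.coords[sg[b]]
            ) <= 2.3:
                _put(sg[a], sg[b], False)

    # hydrogens: bond each H to its nearest heavy atom
    heavy_idx = [i for i, a in enumerate(model.atoms)
                 if a.element.upper() != "H"]
    h_idx = [i for i, a in enumerate(model.atoms) if a.element.upper() == "H"]
    if h_idx and heavy_idx:
        tree = cKDTree(model.coords[heavy_idx])
        dist, nearest = tree.query(model.coords[h_idx], k=1)
        for pos, ih in enumerate(h_idx):
            if dist[pos] <= 1.6:
                _put(ih, heavy_idx[nearest[pos]], True)

    # distance fallback for heavy atoms of non-template residues
    fallback_res = [k for k in residues
                    if chemdata.residue_bonds(model.residue_name(k)) is None]
    if fallback_res:
        seen_warn = set()
        for key in fallback_res:
            name = model.residue_name(key)
            if name not in seen_warn:
                seen_warn.add(name)
                logger.warning(
                    "no bond template for residue %s; using distance "
                    "fallback", name,
                )
        fb_atoms = [i for k in fallback_res for i in model.residue_atoms(k)
                    if model.atoms[i].element.upper() != "H"]
        if fb_atoms:
            all_heavy = np.array(heavy_idx, dtype=int)
            tree_all = cKDTree(model.coords[all_heavy])
            tree_fb = cKDTree(model.coords[fb_atoms])
            pairs = tree_fb.query_ball_tree(tree_all, r=2.6)
            for pos, neighbors in enumerate(pairs):
                i = fb_atoms[pos]
                ri = chemdata.covalent_radius(model.atoms[i].element)
                for q in neighbors:
                    j = int(all_heavy[q])
                    if j == i:
                        continue
                    rj = chemdata.covalent_radius(model.atoms[j].element)
                    d = np.linalg.norm(model.coords[i] - model.coords[j])
                    if d <= ri + rj + 0.4:
                        _put(i, j, False)

    # lock bonds to single-neighbor atoms
    degree = np.zeros(len(model), dtype=int)
    for (i, j) in bonds:
        degree[i] += 1
        degree[j] += 1
    edges = []
    for (i, j), locked in sorted(bonds.items()):
        terminal = degree[i] == 1 or degree[j] == 1
        bars = BARS_LOCKED if (locked or terminal) else BARS_ROTATABLE
        kind = "covalent_locked" if bars == BARS_LOCKED \
            else "covalent_rotatable"
        edges.append(BarEdge(i, j, bars, kind))
    return edges


# --------------------------------------------------------------------------
# hydrogen bonds and tethers
# --------------------------------------------------------------------------


def _covalent_neighbor_map(model: StructureModel,
                           edges: Sequence[BarEdge]) -> dict[int, set[int]]:
    nb: dict[int, set[int]] = {}
    for e in edges:
        nb.setdefault(e.body_i, set()).add(e.body_j)
        nb.setdefault(e.body_j, set()).add(e.body_i)
    return nb


def find_hydrogen_bonds(model: StructureModel,
                        covalent: Sequence[BarEdge] | None = None,
                        salt_bridge_energy: float = SALT_BRIDGE_ENERGY
                        ) -> list[BarEdge]:
    """All geometrically acceptable hydrogen bonds with Mayo energies.

    One edge per donor/acceptor heavy-atom pair (strongest hydrogen);
    salt bridges between charged groups get a fixed energy and are always
    retained by any cutoff in the dilution range.
    """
    if covalent is None:
        covalent = detect_covalent_bonds(model)
    neighbors = _covalent_neighbor_map(model, covalent)
    coords = model.coords

    donors = []  # (heavy idx, [h idx...], hyb, charged)
    acceptors = []  # (idx, hyb, base idx, charged)
    any_h = any(a.element.upper() == "H" for a in model.atoms)
    for key in model.residues():
        res_name = model.residue_name(key).upper()
        for i in model.residue_atoms(key):
            a = model.atoms[i]
            if a.element.upper() == "H":
                continue
            dinfo = chemdata.donor_info(res_name, a.name)
            if dinfo is not None:
                h_ids = [j for j in neighbors.get(i, ())
                         if model.atoms[j].element.upper() == "H"]
                if h_ids:
                    charged = (res_name, a.name.upper()) in \
                        chemdata.CHARGED_DONOR_ATOMS
                    donors.append((i, h_ids, dinfo[0], charged))
            ainfo = chemdata.acceptor_info(res_name, a.name)
            if ainfo is not None:
                base = model.atom_index(key, ainfo[1])
                if base is None:
                    base_nb = [j for j in neighbors.get(i, ())
                               if model.atoms[j].element.upper() != "H"]
                    base = base_nb[0] if base_nb else None
                if base is not None:
                    charged = (res_name, a.name.upper()) in \
                        chemdata.CHARGED_ACCEPTOR_ATOMS
                    acceptors.append((i, ainfo[0], base, charged))

    if not donors:
        if not any_h:
            logger.warning("no hydrogens in model: no hydrogen bonds found")
        return []
    if not acceptors:
        return []

    acc_idx = np.array([a[0] for a in acceptors])
    tree = cKDTree(coords[acc_idx])
    best: dict[tuple[int, int], float] = {}
    for d_i, h_ids, d_hyb, d_charged in donors:
        near = tree.query_ball_point(coords[d_i], HBOND_DIST_CUTOFF)
        for q in near:
            a_i, a_hyb, base_i, a_charged = acceptors[q]
            if a_i == d_i:
                continue
            if model.atoms[a_i].residue_key == model.atoms[d_i].residue_key:
                continue
            if a_i in neighbors.get(d_i, ()):
                continue
            energy = 0.0
            for h_i in h_ids:
                e = mayo_hbond_energy(coords[d_i], coords[h_i], coords[a_i],
                                      coords[base_i], d_hyb, a_hyb)
                energy = min(energy, e)
            if energy >= 0.0:
                continue
            if d_charged and a_charged:
                energy = salt_bridge_energy
            key = (min(d_i, a_i), max(d_i, a_i))
            best[key] = min(best.get(key, 0.0), energy)

    return [BarEdge(i, j, BARS_HBOND, "hbond", energy)
            for (i, j), energy in sorted(best.items())]


def find_hydrophobic_tethers(model: StructureModel,
                             covalent: Sequence[BarEdge]) -> list[BarEdge]:
    """2-bar tethers between apolar C/S atoms of different residues whose
    van der Waals surfaces come within 0.25 A."""
    neighbors = _covalent_neighbor_map(model, covalent)
    apolar = []
    for i, a in enumerate(model.atoms):
        if a.element.upper() not in ("C", "S"):
            continue
        polar_bonded = any(
            model.atoms[j].element.upper() in ("N", "O")
            for j in neighbors.get(i, ())
        )
        if not polar_bonded:
            apolar.append(i)
    if len(apolar) < 2:
        return []
    coords = model.coords[apolar]
    radii = np.array(
        [chemdata.vdw_radius(model.atoms[i].element) for i in apolar]
    )
    max_reach = 2 * radii.max() + TETHER_SURFACE_CUTOFF
    tree = cKDTree(coords)
    pairs = tree.query_pairs(max_reach)
    edges = []
    for p, q in sorted(pairs):
        i, j = apolar[p], apolar[q]
        if model.atoms[i].residue_key == model.atoms[j].residue_key:
            continue
        if j in neighbors.get(i, ()):
            continue
        d = np.linalg.norm(model.coords[i] - model.coords[j])
        if d <= radii[p] + radii[q] + TETHER_SURFACE_CUTOFF:
            edges.append(
                BarEdge(min(i, j), max(i, j), BARS_TETHER, "hydrophobic")
            )
    return edges


def build_constraint_network(model: StructureModel,
                             hbond_cutoff: float = -0.5,
                             hydrophobic: bool = True,
                             salt_bridge_energy: float = SALT_BRIDGE_ENERGY
                             ) -> ConstraintNetwork:
    """FIRST-style constraint network of a (hydrogenated) structure.

    Hydrogen bonds are retained iff their Mayo energy is <= ``hbond_cutoff``
    (weaker bonds are ignored).  Ligand atoms are included as bodies.
    """
    covalent = detect_covalent_bonds(model)
    hbonds = [e for e in find_hydrogen_bonds(model, covalent,
                                             salt_bridge_energy)
              if e.energy is not None and e.energy <= hbond_cutoff]
    tethers = find_hydrophobic_tethers(model, covalent) if hydrophobic else []
    # covalent/hbond duplicates: drop tether or hbond when covalent exists
    cov_pairs = {(min(e.body_i, e.body_j), max(e.body_i, e.body_j))
                 for e in covalent}
    hbonds = [e for e in hbonds
              if (e.body_i, e.body_j) not in cov_pairs]
    tethers = [e for e in tethers
               if (e.body_i, e.body_j) not in cov_pairs]
    return ConstraintNetwork(
        n_bodies=len(model),
        edges=covalent + hbonds + tethers,
        body_residues=[a.residue_key for a in model.atoms],
        coords=model.coords.copy(),
        hbond_cutoff=hbond_cutoff,
        source_label=model.label,
    )


# --------------------------------------------------------------------------
# dilution series
# --------------------------------------------------------------------------


@dataclass
class DilutionSeries:
    cutoffs: np.ndarray
    retained_hbonds: np.ndarray
    lrc_size: np.ndarray
    n_clusters: np.ndarray
    source_label: str = ""

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "retained_hbonds": self.retained_hbonds,
                "lrc_size": self.lrc_size,
                "n_clusters": self.n_clusters,
            }
        )


def dilution_series(model: StructureModel, start: float = 0.0,
                    stop: float = -2.0, step: float = 0.01,
                    hydrophobic: bool = True) -> DilutionSeries:
    """Rigid-cluster statistics along a descending H-bond cutoff grid."""
    from .rigidity import rigid_clusters

    if step <= 0:
        raise ValueError("step must be positive")
    n_steps = int(round((start - stop) / step)) + 1
    cutoffs = start - step * np.arange(n_steps)
    covalent = detect_covalent_bonds(model)
    hbonds = find_hydrogen_bonds(model, covalent)
    tethers = find_hydrophobic_tethers(model, covalent) if hydrophobic else []
    cov_pairs = {(min(e.body_i, e.body_j), max(e.body_i, e.body_j))
                 for e in covalent}
    hbonds = [e for e in hbonds if (e.body_i, e.body_j) not in cov_pairs]
    tethers = [e for e in tethers if (e.body_i, e.body_j) not in cov_pairs]

    retained = np.zeros(n_steps, dtype=int)
    lrc = np.zeros(n_steps, dtype=int)
    n_clusters = np.zeros(n_steps, dtype=int)
    for s, cutoff in enumerate(cutoffs):
        kept = [e for e in hbonds if e.energy <= cutoff]
        net = ConstraintNetwork(
            n_bodies=len(model),
            edges=covalent + kept + tethers,
            body_residues=[a.residue_key for a in model.atoms],
            hbond_cutoff=cutoff,
            source_label=model.label,
        )
        decomp = rigid_clusters(net)
        retained[s] = len(kept)
        lrc[s] = decomp.lrc_size
        n_clusters[s] = decomp.n_clusters
    return DilutionSeries(cutoffs, retained, lrc, n_clusters, model.label)
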