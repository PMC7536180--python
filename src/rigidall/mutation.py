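"""In silico point mutations with idealized side-chain placement, and
rigidity / allostery difference reports between wild type and mutant.

Side chains are rebuilt from ideal residue geometry (bond lengths, angles
and torsions taken from the chemical component dictionary shipped with
biotite) on the existing backbone; chi angles are chosen from a coarse
built-in rotamer set by minimizing heavy-atom clashes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np

from . import chemdata
from .geometry import dihedral, place_atom
from .structure import AtomRecord, ResidueKey, StructureModel

logger = logging.getLogger(__name__)

CLASH_DISTANCE = 2.5
ROTAMER_CHI_VALUES = (-60.0, 60.0, 180.0)

#: chi-angle atom quadruples per residue type (heavy-atom naming).
CHI_ATOMS = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3"}


@dataclass(frozen=True)
class MutationSpec:
    site: ResidueKey
    from_aa: str
    to_aa: str

    def __post_init__(self):
        for aa in (self.from_aa, self.to_aa):
            if aa.upper() not in chemdata.STANDARD_RESIDUES:
                raise ValueError(f"unknown residue type {aa!r}")

    def __str__(self) -> str:
        return f"{self.from_aa}{self.site.res_seq}{self.to_aa}"


def _ideal_geometry(res_name: str):
    """Heavy-atom ideal coordinates of a residue type, by atom name."""
    from biotite.structure.info import residue as ccd_residue

    ideal = ccd_residue(res_name.upper())
    return {
        str(ideal.atom_name[i]): np.array(ideal.coord[i], dtype=float)
        for i in range(ideal.array_length())
        if str(ideal.element[i]).upper() != "H"
    }


def _sidechain_build_order(res_name: str) -> list[tuple[str, str, str, str]]:
    """(atom, parent, grandparent, great-grandparent) in BFS order from CA.

    The predecessor chain follows the side-chain bond tree, so that the
    torsion reference of every atom placed about a chi bond matches the
    chi quadruple definition.
    """
    template = chemdata.residue_bonds(res_name)
    adjacency: dict[str, list[str]] = {}
    for a, b in template:
        adjacency.setdefault(a, []).append(b)
        adjacency.setdefault(b, []).append(a)
    pred = {"CA": "N", "N": "C"}  # virtual chain for the CB improper
    order = []
    queue = ["CA"]
    seen = {"N", "CA", "C", "O", "OXT"}
    while queue:
        parent = queue.pop(0)
        for child in sorted(adjacency.get(parent, [])):
            if child in seen:
                continue
            seen.add(child)
            grand = pred[parent]
            great = pred[grand]
            order.append((child, parent, grand, great))
            pred[child] = parent
            queue.append(child)
    return order


def _build_sidechain(res_name: str, backbone: dict[str, np.ndarray],
                     chi_values: Sequence[float]) -> dict[str, np.ndarray]:
    """Place ideal-geometry side-chain heavy atoms on an actual backbone."""
    ideal = _ideal_geometry(res_name)
    order = _sidechain_build_order(res_name)
    chi_defs = CHI_ATOMS.get(res_name.upper(), [])
    chi_bonds = {(q[1], q[2]): (k, q) for k, q in enumerate(chi_defs)}

    placed = dict(backbone)
    for atom, parent, grand, great in order:
        if atom not in ideal:
            raise ValueError(f"ideal geometry lacks atom {atom} "
                             f"for {res_name}")
        bond = float(np.linalg.norm(ideal[atom] - ideal[parent]))
        from .geometry import angle as _angle

        ang = _angle(ideal[grand], ideal[parent], ideal[atom])
        tors = dihedral(ideal[great], ideal[grand], ideal[parent],
                        ideal[atom])
        chi_hit = chi_bonds.get((grand, parent))
        if chi_hit is not None:
            k, quad = chi_hit
            if k < len(chi_values):
                ref_tors = dihedral(ideal[quad[0]], ideal[quad[1]],
                                    ideal[quad[2]], ideal[quad[3]])
                tors = chi_values[k] + (tors - ref_tors)
        placed[atom] = place_atom(placed[great], placed[grand],
                                  placed[parent], bond, ang, tors)
    return {name: xyz for name, xyz in placed.items()
            if name not in backbone}


def apply_point_mutation(model: StructureModel,
                         spec: MutationSpec) -> StructureModel:
    """Replace the side chain at ``spec.site``, keeping the backbone fixed.

    Rotamers (coarse chi grid over the first two chi angles, at most nine
    per residue type) are ranked by the number of heavy-atom contacts
    below 2.5 A with the rest of the structure; ties break by enumeration
    order.  Side-chain hydrogens are not rebuilt.
    """
    site = spec.site
    current = model.residue_name(site).upper()
    if current != spec.from_aa.upper():
        raise ValueError(
            f"site {site} is {current}, not {spec.from_aa.upper()}"
        )
    to_aa = spec.to_aa.upper()

    backbone = {}
    for name in ("N", "CA", "C"):
        xyz = model.atom_coord(site, name)
        if xyz is None:
            raise ValueError(f"site {site} lacks backbone atom {name}")
        backbone[name] = xyz

    site_atoms = set(model.residue_atoms(site))
    other_coords = np.array([
        model.coords[i] for i in range(len(model))
        if i not in site_atoms
        and model.atoms[i].element.upper() != "H"
    ]).reshape(-1, 3)

    if to_aa == "GLY":
        candidates = [{}]
    else:
        n_chi = len(CHI_ATOMS.get(to_aa, []))
        if n_chi == 0:  # ALA
            chi_sets = [()]
        elif n_chi == 1:
            chi_sets = [(v,) for v in ROTAMER_CHI_VALUES]
        else:
            chi_sets = list(product(ROTAMER_CHI_VALUES,
                                    ROTAMER_CHI_VALUES))
        candidates = [_build_sidechain(to_aa, backbone, chis)
                      for chis in chi_sets]

    def _clashes(sidechain: dict[str, np.ndarray]) -> int:
        if not sidechain or other_coords.size == 0:
            return 0
        pts = np.array(list(sidechain.values()))
        d = np.linalg.norm(
            pts[:, None, :] - other_coords[None, :, :], axis=2
        )
        return int(np.sum(d < CLASH_DISTANCE))

    scores = [_clashes(c) for c in candidates]
    best = int(np.argmin(scores))
    if scores[best] > 0:
        logger.warning("mutation %s: no clash-free rotamer "
                       "(best has %d clashes)", spec, scores[best])
    sidechain = candidates[best]

    keep_names = _BACKBONE_NAMES
    new_atoms: list[AtomRecord] = []
    serial = 0
    for i, a in enumerate(model.atoms):
        if a.residue_key == site:
            if a.name not in keep_names:
                continue
            serial += 1
            new_atoms.append(AtomRecord(
                serial=serial, name=a.name, element=a.element,
                res_name=to_aa, chain=a.chain, res_seq=a.res_seq,
                icode=a.icode, xyz=a.xyz, occupancy=a.occupancy,
                b_factor=a.b_factor, is_hetero=a.is_hetero,
            ))
            if a.name == "O":  # append the new side chain after O
                for name in sorted(sidechain):
                    serial += 1
                    new_atoms.append(AtomRecord(
                        serial=serial, name=name,
                        element=name[0] if name[0] != "H" else "H",
                        res_name=to_aa, chain=a.chain, res_seq=a.res_seq,
                        icode=a.icode,
                        xyz=tuple(float(x) for x in sidechain[name]),
                    ))
        else:
            serial += 1
            new_atoms.append(AtomRecord(
                serial=serial, name=a.name, element=a.element,
                res_name=a.res_name, chain=a.chain, res_seq=a.res_seq,
                icode=a.icode, xyz=a.xyz, occupancy=a.occupancy,
                b_factor=a.b_factor, is_hetero=a.is_hetero,
            ))
    label = f"{model.label}_{spec}" if model.label else str(spec)
    return StructureModel(new_atoms, model.model_id, label)


# --------------------------------------------------------------------------
# rigidity diff
# --------------------------------------------------------------------------


@dataclass
class RigidityDiff:
    delta_lrc_size: int
    split_clusters: list[dict]
    lost_hbonds: list[str]
    gained_hbonds: list[str]
    delta_transmission: dict[ResidueKey, float] = field(default_factory=dict)
    wild_lrc_size: int = 0
    mutant_lrc_size: int = 0

    @property
    def is_empty(self) -> bool:
        return (self.delta_lrc_size == 0 and not self.split_clusters
                and not self.lost_hbonds and not self.gained_hbonds)

    def to_json(self) -> str:
        return json.dumps({
            "delta_lrc_size": self.delta_lrc_size,
            "wild_lrc_size": self.wild_lrc_size,
            "mutant_lrc_size": self.mutant_lrc_size,
            "split_clusters": self.split_clusters,
            "lost_hbonds": self.lost_hbonds,
            "gained_hbonds": self.gained_hbonds,
            "delta_transmission": {
                str(k): v for k, v in self.delta_transmission.items()
            },
        }, indent=2)

    def report(self) -> str:
        lines = [
            f"LRC size: wild {self.wild_lrc_size} -> mutant "
            f"{self.mutant_lrc_size} (delta {self.delta_lrc_size:+d})",
            f"lost H-bonds ({len(self.lost_hbonds)}): "
            + ", ".join(self.lost_hbonds[:20]),
            f"gained H-bonds ({len(self.gained_hbonds)}): "
            + ", ".join(self.gained_hbonds[:20]),
        ]
        for split in self.split_clusters:
            lines.append(
                f"cluster {split['wild_cluster']} "
                f"({split['residue_range']}) splits into "
                f"{split['n_fragments']} fragments"
            )
        return "\n".join(lines)


def _hbond_labels(model: StructureModel, edges) -> dict[str, float]:
    out = {}
    for e in edges:
        if e.kind != "hbond":
            continue
        a, b = model.atoms[e.body_i], model.atoms[e.body_j]
        key = (f"{a.residue_key}.{a.name}-{b.residue_key}.{b.name}")
        out[key] = e.energy
    return out


def rigidity_diff(wild: StructureModel, mutant: StructureModel,
                  cutoff: float = -1.0,
                  target_site_residues=None,
                  mutated_site: ResidueKey | None = None) -> RigidityDiff:
    """Rigidity and H-bond network differences between wild type and mutant.

    Both structures are hydrogenated, their constraint networks rebuilt at
    the given H-bond cutoff and decomposed into rigid clusters.  Reports
    the LRC size change, wild clusters split into several mutant clusters,
    lost/gained hydrogen bonds, and (when a target site is given)
    per-residue transmission-intensity deltas at that cutoff.
    """
    from .network import build_constraint_network
    from .rigidity import rigid_clusters
    from .structure import add_polar_hydrogens

    wild_keys = {(a.chain, a.res_seq, a.icode) for a in wild.atoms}
    mut_keys = {(a.chain, a.res_seq, a.icode) for a in mutant.atoms}
    if wild_keys != mut_keys:
        raise ValueError("wild/mutant residue numbering differs beyond "
                         "the mutated site")

    wild_h = add_polar_hydrogens(wild)
    mut_h = add_polar_hydrogens(mutant)
    net_w = build_constraint_network(wild_h, hbond_cutoff=cutoff)
    net_m = build_constraint_network(mut_h, hbond_cutoff=cutoff)
    dec_w = rigid_clusters(net_w)
    dec_m = rigid_clusters(net_m)

    hb_w = _hbond_labels(wild_h, net_w.edges)
    hb_m = _hbond_labels(mut_h, net_m.edges)
    lost = sorted(k for k in hb_w if k not in hb_m)
    gained = sorted(k for k in hb_m if k not in hb_w)

    # map wild bodies to mutant bodies by (residue, atom name)
    mut_index = {
        (a.residue_key, a.name): i for i, a in enumerate(mut_h.atoms)
    }
    splits = []
    for cluster in dec_w.clusters:
        if len(cluster) < 2:
            continue
        mapped = [mut_index.get((wild_h.atoms[b].residue_key,
                                 wild_h.atoms[b].name))
                  for b in cluster]
        mapped = [m for m in mapped if m is not None]
        frag_labels = {int(dec_m.labels[m]) for m in mapped}
        if len(frag_labels) >= 2:
            res_seqs = [wild_h.atoms[b].res_seq for b in cluster]
            splits.append({
                "wild_cluster": int(dec_w.labels[cluster[0]]),
                "size": int(len(cluster)),
                "residue_range": f"{min(res_seqs)}-{max(res_seqs)}",
                "n_fragments": len(frag_labels),
            })

    delta_tx: dict[ResidueKey, float] = {}
    if target_site_residues is not None:
        from .rta import SiteDefinition, rta_scan_profile

        site_w = SiteDefinition.from_residues("target", net_w,
                                              target_site_residues)
        site_m = SiteDefinition.from_residues("target", net_m,
                                              target_site_residues)
        prof_w = rta_scan_profile(net_w, site_w, cutoffs=[cutoff])
        prof_m = rta_scan_profile(net_m, site_m, cutoffs=[cutoff])
        for key, v in prof_w.intensity.items():
            delta_tx[key] = prof_m.intensity.get(key, 0.0) - v

    return RigidityDiff(
        delta_lrc_size=dec_m.lrc_size - dec_w.lrc_size,
        split_clusters=splits,
        lost_hbonds=lost,
        gained_hbonds=gained,
        delta_transmission=delta_tx,
        wild_lrc_size=dec_w.lrc_size,
        mutant_lrc_size=dec_m.lrc_size,
    )
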