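"""Headline measurements of the apo/open/closed glutamate-dehydrogenase
reproduction, computed from locally supplied structure files.

Each function takes already-loaded models and returns a plain number; the
:func:`compute_targets` driver maps the published target ids onto them and
silently skips targets whose inputs are unavailable.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import chemdata
from .compare import backbone_dihedrals, helix_rotation_angle
from .enm import gnm_modes, mode_stats
from .network import build_constraint_network
from .pipeline import classify_nadh
from .rigidity import rigid_clusters
from .structure import (ResidueKey, StructureModel, add_polar_hydrogens,
                        read_structure, select_neighborhood)

logger = logging.getLogger(__name__)

DEFAULT_DATA_DIR = Path("data/pdb")
ACCESSIONS = {"apo": "3jcz", "open": "3jd3", "closed": "3jd4"}


def _min_heavy_distance(model: StructureModel, idx_a, idx_b) -> float:
    ca = np.array([model.coords[i] for i in idx_a
                   if model.atoms[i].element.upper() != "H"])
    cb = np.array([model.coords[i] for i in idx_b
                   if model.atoms[i].element.upper() != "H"])
    diff = ca[:, None, :] - cb[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).min())


def gly376_phi(apo: StructureModel, chain: str = "A") -> float:
    """t1: backbone phi of Gly376 in the apo structure (degrees)."""
    phi, _, _ = backbone_dihedrals(apo, ResidueKey(chain, 376))
    if phi is None:
        raise ValueError("phi undefined for residue 376")
    return phi


def his209_alpha_phosphate_distance(model: StructureModel,
                                    nadh_code: str = "NAI",
                                    chain: str = "A") -> float:
    """t4/t5: min distance from His209 heavy atoms to the alpha-phosphate
    P of the regulatory NADH (Angstrom)."""
    sites = classify_nadh(model, nadh_code, "GTP", chain)
    reg = sites["regulatory"]
    p_atoms = [i for i in model.residue_atoms(reg)
               if model.atoms[i].name.upper() in ("PA", "P")]
    if not p_atoms:
        p_atoms = [i for i in model.residue_atoms(reg)
                   if model.atoms[i].element.upper() == "P"]
    his = model.residue_atoms(ResidueKey(chain, 209))
    return _min_heavy_distance(model, his, p_atoms)


def asn349_catalytic_nadh_distance(closed: StructureModel,
                                   nadh_code: str = "NAI",
                                   chain: str = "A") -> float:
    """t6: closest heavy-atom contact Asn349 -> catalytic NADH."""
    sites = classify_nadh(closed, nadh_code, "GTP", chain)
    asn = closed.residue_atoms(ResidueKey(chain, 349))
    cat = closed.residue_atoms(sites["catalytic"])
    return _min_heavy_distance(closed, asn, cat)


def glu292_gtp_contact(closed: StructureModel,
                       chain: str = "A") -> float:
    """t7: min distance from Glu292 side-chain oxygens to GTP polar
    atoms."""
    key = ResidueKey(chain, 292)
    glu_o = [i for i in closed.residue_atoms(key)
             if closed.atoms[i].name.upper() in ("OE1", "OE2")]
    gtp_keys = [k for k in closed.ligands
                if closed.residue_name(k).upper() == "GTP"
                and k.chain == chain] or \
        [k for k in closed.ligands
         if closed.residue_name(k).upper() == "GTP"]
    gtp_polar = [i for k in gtp_keys[:1] for i in closed.residue_atoms(k)
                 if closed.atoms[i].element.upper() in ("N", "O")]
    return _min_heavy_distance(closed, glu_o, gtp_polar)


def gnm_second_mode_collectivity(closed: StructureModel,
                                 cutoffs=(7.0, 7.5, 8.0, 8.5, 9.0, 9.5,
                                          10.0)) -> float:
    """t9: collectivity of the 2nd global GNM mode; the ENM
    parameterization of the published analysis is unknown, so the value is
    summarized as the median over a cutoff sweep."""
    values = []
    for cutoff in cutoffs:
        modes = gnm_modes(closed, cutoff=float(cutoff), n_modes=10)
        values.append(mode_stats(modes, 2).collectivity)
    return float(np.median(values))


def lrc_ratio(open_m: StructureModel, closed: StructureModel,
              cutoff: float = -0.5) -> float:
    """t10: LRC(closed) / LRC(open) at the analysis H-bond cutoff."""
    sizes = {}
    for label, model in (("open", open_m), ("closed", closed)):
        net = build_constraint_network(add_polar_hydrogens(model),
                                       hbond_cutoff=cutoff)
        sizes[label] = rigid_clusters(net).lrc_size
    return sizes["closed"] / sizes["open"]


def helix_x_rotation(apo: StructureModel, closed: StructureModel,
                     apo_path: str | Path | None = None,
                     chain: str = "A") -> float:
    """t11: rotation of helix X (closed vs apo) about its own axis after
    superposition on the helix I-V core."""
    table = {}
    if apo_path is not None:
        table = chemdata.helices_from_pdb_header(apo_path, chain)
    if len(table) < 10:
        table = dict(chemdata.GDH_HELIX_RANGES)
    start, end = table["X"]
    core = set()
    for hid in ("I", "II", "III", "IV", "V"):
        s, e = table[hid]
        core.update(ResidueKey(chain, q) for q in range(s, e + 1))
    core &= set(apo.residues()) & set(closed.residues())
    hr = helix_rotation_angle(apo, closed, (chain, start, end), core=core,
                              helix_id="X")
    return hr.angle


def ser441_catalytic_site_distance(closed: StructureModel,
                                   nadh_code: str = "NAI",
                                   chain: str = "A",
                                   radius: float = 3.0) -> float:
    """t12: min heavy-atom distance from Ser441 to the catalytic site
    (3 A neighborhood of the catalytic NADH)."""
    sites = classify_nadh(closed, nadh_code, "GTP", chain)
    sel = select_neighborhood(closed, sites["catalytic"], radius)
    ser = closed.residue_atoms(ResidueKey(chain, 441))
    return _min_heavy_distance(closed, ser, sel.atom_ids)


def locate_inputs(data_dir: str | Path = DEFAULT_DATA_DIR
                  ) -> dict[str, Path]:
    """Paths of locally cached apo/open/closed entries (if present)."""
    data_dir = Path(data_dir)
    found = {}
    for label, acc in ACCESSIONS.items():
        for suffix in (".pdb", ".ent", ".cif"):
            path = data_dir / f"{acc}{suffix}"
            if path.exists():
                found[label] = path
                break
    return found


def compute_targets(data_dir: str | Path = DEFAULT_DATA_DIR,
                    nadh_code: str = "NAI",
                    chain: str = "A") -> dict[str, dict]:
    """All recomputable published targets from locally cached structures.

    Returns ``{target_id: {"value": number, "n": problem size}}``; targets
    whose inputs or measurements fail are omitted (logged).
    """
    paths = locate_inputs(data_dir)
    models: dict[str, StructureModel] = {}
    for label, path in paths.items():
        try:
            models[label] = read_structure(path, label=label)
        except Exception as exc:  # noqa: BLE001
            logger.warning("cannot read %s: %s", path, exc)

    apo = models.get("apo")
    open_m = models.get("open")
    closed = models.get("closed")
    out: dict[str, dict] = {}

    def _try(tid, fn, n):
        try:
            out[tid] = {"value": float(fn()), "n": int(n)}
        except Exception as exc:  # noqa: BLE001
            logger.warning("target %s not computed: %s", tid, exc)

    if apo is not None:
        _try("t1", lambda: gly376_phi(apo, chain), len(apo))
    if open_m is not None:
        _try("t4", lambda: his209_alpha_phosphate_distance(
            open_m, nadh_code, chain), len(open_m))
    if closed is not None:
        _try("t5", lambda: his209_alpha_phosphate_distance(
            closed, nadh_code, chain), len(closed))
        _try("t6", lambda: asn349_catalytic_nadh_distance(
            closed, nadh_code, chain), len(closed))
        _try("t7", lambda: glu292_gtp_contact(closed, chain), len(closed))
        _try("t9", lambda: gnm_second_mode_collectivity(closed),
             len(closed))
        _try("t12", lambda: ser441_catalytic_site_distance(
            closed, nadh_code, chain), len(closed))
    if open_m is not None and closed is not None:
        _try("t10", lambda: lrc_ratio(open_m, closed),
             len(open_m) + len(closed))
    if apo is not None and closed is not None:
        _try("t11", lambda: helix_x_rotation(apo, closed,
                                             paths.get("apo"), chain),
             len(apo))
    return out
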