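"""Synthetic inputs with known ground truth for every pipeline stage.

Every generator is deterministic given its seed.  Frameworks come with
analytic DOF/redundancy labels; helices with a known applied rotation;
allosteric toys with a planted DOF-transmission count; backbone ensembles
with planted phi trajectories and peptide-geometry distortions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import place_atom, rotation_about_axis
from .network import BarEdge, ConstraintNetwork
from .rta import SiteDefinition
from .structure import AtomRecord, Ensemble, ResidueKey, StructureModel

# --------------------------------------------------------------------------
# body-bar frameworks
# --------------------------------------------------------------------------


@dataclass
class FrameworkSpec:
    topology: str  # chain | ring | tree | custom
    n_bodies: int
    bars: int = 5
    seed: int = 0
    edges: list[tuple[int, int, int]] | None = None  # custom topology

    def __post_init__(self):
        if self.topology not in ("chain", "ring", "tree", "custom"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.topology == "custom" and not self.edges:
            raise ValueError("custom topology needs an edge list")
        if self.n_bodies < 1:
            raise ValueError("need at least one body")


def _generic_coords(n: int, rng: np.random.Generator,
                    min_dist: float = 1.0) -> np.ndarray:
    """Random coordinates in a box with a minimum pairwise distance."""
    box = max(4.0, 2.0 * n ** (1 / 3) * min_dist * 2)
    coords = np.empty((n, 3))
    placed = 0
    while placed < n:
        cand = rng.uniform(-box, box, 3)
        if placed == 0 or np.min(
            np.linalg.norm(coords[:placed] - cand, axis=1)
        ) >= min_dist:
            coords[placed] = cand
            placed += 1
    return coords


def gen_body_bar_framework(spec: FrameworkSpec
                           ) -> tuple[ConstraintNetwork, dict]:
    """Framework with generic coordinates plus analytic ground truth.

    For trees/chains with b-bar edges the generic count gives
    ``dof = 6n - 6 - b(n-1)`` with no redundancy; rings additionally
    saturate at rank ``6n - 6``.
    """
    rng = np.random.default_rng(spec.seed)
    n, b = spec.n_bodies, spec.bars
    if spec.topology == "chain":
        pairs = [(i, i + 1) for i in range(n - 1)]
    elif spec.topology == "ring":
        if n < 3:
            raise ValueError("ring needs >= 3 bodies")
        pairs = [(i, (i + 1) % n) for i in range(n)]
    elif spec.topology == "tree":
        pairs = [(int(rng.integers(0, i)), i) for i in range(1, n)]
    else:
        pairs = None

    if pairs is not None:
        edges = [(i, j, b) for i, j in pairs]
    else:
        edges = list(spec.edges)

    total_bars = sum(e[2] for e in edges)
    if spec.topology in ("chain", "tree"):
        rank = total_bars  # every subtree satisfies b(|S|-1) <= 6|S|-6
        dof = 6 * n - 6 - rank
        redundant = 0
    elif spec.topology == "ring":
        rank = min(total_bars, 6 * n - 6)
        dof = 6 * n - 6 - rank
        redundant = total_bars - rank
    else:
        rank = dof = redundant = None  # caller supplies/validates

    kind = {2: "hydrophobic", 5: "covalent_rotatable",
            6: "covalent_locked"}
    net = ConstraintNetwork(
        n_bodies=n,
        edges=[BarEdge(i, j, bars, kind[bars]) for i, j, bars in edges],
        coords=_generic_coords(n, rng),
        source_label=f"{spec.topology}(n={n},b={b},seed={spec.seed})",
    )
    truth = {
        "expected_internal_dof": dof,
        "expected_redundant": redundant,
        "total_bars": total_bars,
    }
    return net, truth


# --------------------------------------------------------------------------
# ideal helices
# --------------------------------------------------------------------------

ALPHA_PHI = -57.8
ALPHA_PSI = -47.0


def _screw_axis(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact helix axis (unit direction, point on axis) of a backbone whose
    residues are related by a constant screw motion.

    The rotation of the one-residue screw is recovered by Kabsch
    superposition of CA[:-1] onto CA[1:]; the axis point is the
    least-squares centre of the CA circle projected along the axis.
    """
    from scipy.spatial.transform import Rotation

    p = ca[:-1] - ca[:-1].mean(axis=0)
    q = ca[1:] - ca[1:].mean(axis=0)
    u_m, _, vt = np.linalg.svd(p.T @ q)
    d = np.sign(np.linalg.det(u_m @ vt))
    rot = (u_m @ np.diag([1.0, 1.0, d]) @ vt).T
    rotvec = Rotation.from_matrix(rot).as_rotvec()
    axis = rotvec / np.linalg.norm(rotvec)
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    # in-plane circle centre: 2 q_i . c - k = |q_i|^2
    e1 = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(axis, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    proj = ca - np.outer(ca @ axis, axis)
    q2d = np.column_stack([proj @ e1, proj @ e2])
    design = np.column_stack([2.0 * q2d, -np.ones(len(q2d))])
    rhs = (q2d**2).sum(axis=1)
    (cx, cy, _k), *_ = np.linalg.lstsq(design, rhs, rcond=None)
    point = cx * e1 + cy * e2
    return axis, point


def gen_ideal_helix(n_res: int, phi: float = ALPHA_PHI,
                    psi: float = ALPHA_PSI,
                    rotation_about_axis_deg: float = 0.0,
                    chain: str = "A",
                    ) -> tuple[StructureModel, StructureModel]:
    """Poly-alanine backbone of an ideal alpha helix, built from standard
    internal coordinates (textbook rise 1.5 A / twist 100 deg emerge from
    the default phi/psi).

    Returns (reference, transformed); the transformed copy is rotated by
    the requested angle about the exact helix (screw) axis, right-handed
    about the N- to C-terminal axis direction.  Both models carry the
    construction axis as a ``helix_axis`` attribute.
    """
    if n_res < 6:
        raise ValueError("need >= 6 residues for a helix")
    phis = np.full(n_res, float(phi))
    psis = np.full(n_res, float(psi))
    angs = np.full(n_res, ANGLE_C_N_CA)
    # carbonyl O takes its ideal position (planted distance = ideal)
    pos = {}
    pos[(1, "N")] = np.array([0.0, 0.0, 0.0])
    pos[(1, "CA")] = np.array([BOND_N_CA, 0.0, 0.0])
    ang0 = np.radians(180.0 - ANGLE_N_CA_C)
    pos[(1, "C")] = pos[(1, "CA")] + BOND_CA_C * np.array(
        [np.cos(ang0), np.sin(ang0), 0.0])
    for i in range(2, n_res + 1):
        pos[(i, "N")] = place_atom(pos[(i - 1, "N")], pos[(i - 1, "CA")],
                                   pos[(i - 1, "C")], BOND_C_N,
                                   ANGLE_CA_C_N, psis[i - 2])
        pos[(i, "CA")] = place_atom(pos[(i - 1, "CA")], pos[(i - 1, "C")],
                                    pos[(i, "N")], BOND_N_CA,
                                    angs[i - 1], 180.0)
        pos[(i, "C")] = place_atom(pos[(i - 1, "C")], pos[(i, "N")],
                                   pos[(i, "CA")], BOND_CA_C,
                                   ANGLE_N_CA_C, phis[i - 1])
    for i in range(1, n_res + 1):
        pos[(i, "O")] = place_atom(pos[(i, "N")], pos[(i, "CA")],
                                   pos[(i, "C")], BOND_C_O, ANGLE_CA_C_O,
                                   psis[i - 1] + 180.0)
    atoms = []
    serial = 0
    for i in range(1, n_res + 1):
        for name, element in (("N", "N"), ("CA", "C"), ("C", "C"),
                              ("O", "O")):
            serial += 1
            atoms.append(AtomRecord(
                serial=serial, name=name, element=element, res_name="ALA",
                chain=chain, res_seq=i, icode="",
                xyz=tuple(float(x) for x in pos[(i, name)]),
            ))
    ref = StructureModel(atoms, label="ideal_helix")
    ca = np.array([pos[(i, "CA")] for i in range(1, n_res + 1)])
    axis, point = _screw_axis(ca)
    R = rotation_about_axis(axis, rotation_about_axis_deg)
    rotated = ref.transformed(R, point - R @ point)
    rotated.label = f"ideal_helix_rot{rotation_about_axis_deg:g}"
    ref.helix_axis = axis
    rotated.helix_axis = axis
    return ref, rotated


# --------------------------------------------------------------------------
# allosteric toys
# --------------------------------------------------------------------------


@dataclass
class AllostericToy:
    network: ConstraintNetwork
    site_a: SiteDefinition
    site_b: SiteDefinition
    severed: ConstraintNetwork
    planted_transmission: int


def gen_allosteric_toy(transmission_dof: int,
                       pathway_length: int = 3) -> AllostericToy:
    """Two sites joined by ``transmission_dof`` rigidity-transmitting loops.

    Each loop carries exactly 7 hinges (one internal DOF); rigidifying
    site A locks one hinge per loop, freezing the loop and removing one
    DOF at site B.  Loops are joined into one framework by a rigid spine
    on the A side.  The severed variant cuts every loop, which leaves the
    two sites without any transmission pathway.
    """
    t = int(transmission_dof)
    if t < 0:
        raise ValueError("transmission_dof must be >= 0")
    L = max(int(pathway_length), 3)

    def _build(severed: bool):
        edges: list[tuple[int, int, int]] = []
        nid = 0
        a_bodies: list[int] = []
        b_bodies: list[int] = []
        if t == 0:
            # two disjoint flexible pairs: nothing can be transmitted
            edges += [(0, 1, 5), (2, 3, 5)]
            return ConstraintNetwork(
                4,
                [BarEdge(i, j, b, "covalent_rotatable")
                 for i, j, b in edges],
                body_residues=[ResidueKey("X", i + 1) for i in range(4)],
            ), [0, 1], [2, 3]
        for _k in range(t):
            a1, a2, b1, b2 = nid, nid + 1, nid + 2, nid + 3
            nid += 4
            a_bodies += [a1, a2]
            b_bodies += [b1, b2]
            edges.append((a1, a2, 5))
            edges.append((b1, b2, 5))
            # path P: a2 -> b1 (3 hinges, then locked edges)
            chain = [a2] + list(range(nid, nid + L)) + [b1]
            nid += L
            for i in range(len(chain) - 1):
                if severed and i == len(chain) - 2:
                    continue
                edges.append((chain[i], chain[i + 1], 5 if i < 3 else 6))
            # path Q: b2 -> a1 (2 hinges, then locked edges)
            chain = [b2] + list(range(nid, nid + L)) + [a1]
            nid += L
            for i in range(len(chain) - 1):
                if severed and i == len(chain) - 2:
                    continue
                edges.append((chain[i], chain[i + 1], 5 if i < 2 else 6))
        if t > 1:  # rigid spine joining the loops on the A side
            hub = nid
            nid += 1
            a_bodies.append(hub)
            for k in range(t):
                edges.append((hub, a_bodies[2 * k], 6))
        net = ConstraintNetwork(
            nid,
            [BarEdge(i, j, b,
                     "covalent_rotatable" if b == 5 else "covalent_locked")
             for i, j, b in edges],
            body_residues=[ResidueKey("X", i + 1) for i in range(nid)],
        )
        return net, a_bodies, b_bodies

    net, a_bodies, b_bodies = _build(False)
    severed_net, _, _ = _build(True)
    return AllostericToy(
        network=net,
        site_a=SiteDefinition("site_a", np.array(a_bodies)),
        site_b=SiteDefinition("site_b", np.array(b_bodies)),
        severed=severed_net,
        planted_transmission=t,
    )


# --------------------------------------------------------------------------
# dihedral ensembles
# --------------------------------------------------------------------------

# Engh-Huber-style reference backbone geometry
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6   # the CA(-1)-C(-1)-N angle
ANGLE_C_N_CA = 121.7   # the C(-1)-N-CA angle
ANGLE_CA_C_O = 120.8
DEFAULT_PHI = -65.0
DEFAULT_PSI = -90.0


@dataclass
class DihedralEnsembleTruth:
    """Planted ground truth emitted alongside a generated ensemble."""

    table: pd.DataFrame  # residue, frame, phi, psi, d_O1_C, ang_C1_N_CA
    quad_coeffs: tuple[float, float, float]
    cosine_amplitude: float
    zone: tuple[float, float] = (-35.0, 35.0)

    def zone_counts(self) -> dict[int, int]:
        lo, hi = self.zone
        t = self.table
        inside = t[(t.phi > lo) & (t.phi < hi)]
        return inside.groupby("res_seq").size().to_dict()


def _sphere_sphere_point(center_a: np.ndarray, radius_a: float,
                         center_b: np.ndarray, radius_b: float,
                         near: np.ndarray) -> np.ndarray:
    """Point at ``radius_a`` from A and ``radius_b`` from B, closest to
    ``near``; distances are clamped to the reachable band if the spheres
    do not intersect."""
    u = center_b - center_a
    dist = float(np.linalg.norm(u))
    u = u / dist
    x = (dist**2 + radius_a**2 - radius_b**2) / (2.0 * dist)
    if abs(x) >= radius_a:  # no intersection: nearest pole
        return center_a + radius_a * np.sign(x) * u
    r_circ = np.sqrt(radius_a**2 - x**2)
    center = center_a + x * u
    w = near - center
    w = w - (w @ u) * u
    norm = np.linalg.norm(w)
    if norm < 1e-9:  # arbitrary perpendicular
        w = np.cross(u, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(w) < 1e-9:
            w = np.cross(u, np.array([0.0, 1.0, 0.0]))
        norm = np.linalg.norm(w)
    return center + r_circ * w / norm


def _build_backbone_frame(n_res: int, phi: np.ndarray, psi: np.ndarray,
                          ang_c_n_ca: np.ndarray,
                          d_target: np.ndarray) -> dict:
    """One frame of backbone coordinates realizing the planted internal
    coordinates; O(-1) is positioned so that its distance to the next C
    matches ``d_target`` where geometrically reachable."""
    pos = {}
    pos[(1, "N")] = np.array([0.0, 0.0, 0.0])
    pos[(1, "CA")] = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - ANGLE_N_CA_C)
    pos[(1, "C")] = pos[(1, "CA")] + BOND_CA_C * np.array(
        [np.cos(ang), np.sin(ang), 0.0]
    )
    for i in range(2, n_res + 1):
        pos[(i, "N")] = place_atom(
            pos[(i - 1, "N")], pos[(i - 1, "CA")], pos[(i - 1, "C")],
            BOND_C_N, ANGLE_CA_C_N, psi[i - 2],
        )
        pos[(i, "CA")] = place_atom(
            pos[(i - 1, "CA")], pos[(i - 1, "C")], pos[(i, "N")],
            BOND_N_CA, ang_c_n_ca[i - 1], 180.0,
        )
        pos[(i, "C")] = place_atom(
            pos[(i - 1, "C")], pos[(i, "N")], pos[(i, "CA")],
            BOND_CA_C, ANGLE_N_CA_C, phi[i - 1],
        )
        # place O on residue i-1 hitting the planted O(-1)...C(i) distance:
        # O lies on the sphere |O - C(-1)| = 1.231; intersecting it with the
        # sphere of radius d around C(i) gives a circle, and the point on
        # that circle closest to the ideal carbonyl position is taken
        # (least geometric distortion realizing the planted distance).
        c_prev = pos[(i - 1, "C")]
        ca_prev = pos[(i - 1, "CA")]
        n_prev = pos[(i - 1, "N")]
        ideal_o = place_atom(n_prev, ca_prev, c_prev,
                             BOND_C_O, ANGLE_CA_C_O, psi[i - 2] + 180.0)
        pos[(i - 1, "O")] = _sphere_sphere_point(
            c_prev, BOND_C_O, pos[(i, "C")], d_target[i - 1], ideal_o
        )
    # terminal carbonyl O (no distance constraint)
    pos[(n_res, "O")] = place_atom(
        pos[(n_res, "N")], pos[(n_res, "CA")], pos[(n_res, "C")],
        BOND_C_O, ANGLE_CA_C_O, psi[n_res - 1] + 180.0,
    )
    return pos


def gen_dihedral_ensemble(
    n_frames: int,
    n_res: int,
    phi_trajectories: Mapping[int, Sequence[float]] | None = None,
    quad_coeffs: tuple[float, float, float] = (5e-5, 1e-4, 3.04),
    cosine_amplitude: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    chain: str = "A",
) -> tuple[Ensemble, DihedralEnsembleTruth]:
    """Glycine-backbone ensemble with planted phi values and distortions.

    ``phi_trajectories`` maps 1-based residue numbers to per-frame phi
    values (residues not listed sit at a constant helical phi).  The
    O(-1)...C distance follows the planted quadratic in phi and the
    C(-1)-N-CA bond angle follows the planted cosine distortion
    ``I * cos(phi * pi / 120)``, both plus Gaussian noise.
    """
    if n_res < 5:
        raise ValueError("need >= 5 residues (two flanking on both sides)")
    rng = np.random.default_rng(seed)
    phi_trajectories = phi_trajectories or {}
    qa, qb, qc = quad_coeffs

    frames = []
    rows = []
    for f in range(n_frames):
        phi = np.full(n_res, DEFAULT_PHI)
        psi = np.full(n_res, DEFAULT_PSI)
        for res, series in phi_trajectories.items():
            phi[res - 1] = series[f]
        d_target = np.zeros(n_res)
        ang = np.full(n_res, ANGLE_C_N_CA)
        for i in range(1, n_res):
            p = phi[i]
            d_target[i] = (qa * p * p + qb * p + qc
                           + rng.normal(0.0, noise_sd))
            ang[i] = (ANGLE_C_N_CA
                      + cosine_amplitude * np.cos(p * np.pi / 120.0)
                      + rng.normal(0.0, noise_sd))
        pos = _build_backbone_frame(n_res, phi, psi, ang, d_target)
        atoms = []
        serial = 0
        for i in range(1, n_res + 1):
            for name, element in (("N", "N"), ("CA", "C"), ("C", "C"),
                                  ("O", "O")):
                serial += 1
                atoms.append(AtomRecord(
                    serial=serial, name=name, element=element,
                    res_name="GLY", chain=chain, res_seq=i, icode="",
                    xyz=tuple(float(x) for x in pos[(i, name)]),
                ))
        frames.append(StructureModel(atoms, model_id=f + 1,
                                     label=f"synthetic#{f+1}"))
        for i in range(2, n_res + 1):
            rows.append({
                "res_seq": i, "frame": f, "phi": phi[i - 1],
                "psi": psi[i - 1], "d_O1_C": d_target[i - 1],
                "ang_C1_N_CA": ang[i - 1],
            })
    truth = DihedralEnsembleTruth(
        table=pd.DataFrame(rows),
        quad_coeffs=quad_coeffs,
        cosine_amplitude=cosine_amplitude,
    )
    times = [10.0 * (f + 1) for f in range(n_frames)]
    return Ensemble(frames, frame_times=times), truth
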