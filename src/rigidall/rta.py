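"""Rigidity-transmission allostery: how rigidifying one site removes
conformational degrees of freedom at a distant site.

The DOF available at a site is the number of free pebbles gatherable onto
its bodies beyond the 6 trivial rigid-body motions.  Perturbing a site
means inserting 6-bar edges along a spanning star of its bodies until the
site is internally rigid.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._pebble import PebbleState
from .network import BarEdge, ConstraintNetwork
from .rigidity import play_network
from .structure import ResidueKey

logger = logging.getLogger(__name__)


@dataclass
class SiteDefinition:
    """A perturbation or readout site: a set of bodies (atoms)."""

    label: str
    bodies: np.ndarray
    residues: set[ResidueKey] = field(default_factory=set)

    def __post_init__(self):
        self.bodies = np.unique(np.asarray(self.bodies, dtype=np.int64))
        if self.bodies.size == 0:
            raise ValueError(f"site {self.label!r} is empty")

    @classmethod
    def from_selection(cls, label, selection) -> "SiteDefinition":
        return cls(label=label, bodies=np.array(selection.atom_ids),
                   residues=set(selection.residues))

    @classmethod
    def from_residues(cls, label, network: ConstraintNetwork,
                      residues: Iterable[ResidueKey]) -> "SiteDefinition":
        residues = set(residues)
        return cls(label=label,
                   bodies=network.residues_to_bodies(residues),
                   residues=residues)

    def to_json(self) -> str:
        return json.dumps({
            "label": self.label,
            "bodies": [int(b) for b in self.bodies],
            "residues": sorted(str(r) for r in self.residues),
        })


@dataclass
class TransmissionResult:
    dof_B_before: int
    dof_B_after: int
    cutoff: float | None = None

    @property
    def transmitted(self) -> int:
        return self.dof_B_before - self.dof_B_after


def _site_dof(state: PebbleState, bodies: np.ndarray) -> int:
    """Free DOF at a body set beyond its 6 trivial motions (mutates state)."""
    return max(state.collect_on(bodies) - 6, 0)


def _rigidify(state: PebbleState, bodies: np.ndarray) -> None:
    """Insert 6-bar edges along a star over ``bodies`` (in place)."""
    bodies = np.sort(np.asarray(bodies, dtype=np.int64))
    if bodies.size < 2:
        return
    hub = bodies[0]
    eu = np.full(bodies.size - 1, hub, dtype=np.int64)
    ev = bodies[1:]
    state.insert_edges(eu, ev, np.full(ev.size, 6, dtype=np.int64))


def rta_transmission(network: ConstraintNetwork, site_a: SiteDefinition,
                     site_b: SiteDefinition,
                     base_state: PebbleState | None = None
                     ) -> TransmissionResult:
    """Degrees of freedom transmitted from site A to site B.

    Measures the DOF available at B, rigidifies A, and measures again;
    the drop is the transmitted DOF.  Sites must be disjoint.
    """
    if np.intersect1d(site_a.bodies, site_b.bodies).size:
        raise ValueError("sites A and B overlap")
    if base_state is None:
        base_state, _ = play_network(network)
    before_state = base_state.copy()
    dof_before = _site_dof(before_state, site_b.bodies)
    after_state = base_state.copy()
    _rigidify(after_state, site_a.bodies)
    dof_after = _site_dof(after_state, site_b.bodies)
    return TransmissionResult(dof_before, dof_after,
                              cutoff=network.hbond_cutoff)


# --------------------------------------------------------------------------
# windowed scan
# --------------------------------------------------------------------------


@dataclass
class RTAProfile:
    """Per-residue transmission intensity toward a target site."""

    intensity: dict[ResidueKey, float]
    persistence: dict[ResidueKey, float]
    window: int
    cutoffs: np.ndarray
    target_label: str

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("residue\tintensity\tpersistence\n")
            for key in sorted(self.intensity):
                fh.write(f"{key}\t{self.intensity[key]:.6f}\t"
                         f"{self.persistence[key]:.6f}\n")


def _filtered_edges(network: ConstraintNetwork,
                    cutoff: float) -> list[BarEdge]:
    return [e for e in network.edges
            if e.kind != "hbond"
            or (e.energy is not None and e.energy <= cutoff)]


def rta_scan_profile(network: ConstraintNetwork, target: SiteDefinition,
                     window: int = 3,
                     cutoffs: Sequence[float] | None = None) -> RTAProfile:
    """Sliding-window perturbation scan toward ``target``.

    For every H-bond cutoff the network is re-filtered and every window of
    ``window`` consecutive residues (per chain, from the N-terminus) is
    rigidified; the per-residue intensity is the transmitted DOF averaged
    over the windows containing the residue and over the cutoff grid.
    Windows overlapping the target are skipped.
    """
    if network.body_residues is None:
        raise ValueError("network has no residue back-map")
    if target.bodies.size == 0:
        raise ValueError("target site has no atoms")
    if cutoffs is None:
        cutoffs = [network.hbond_cutoff]
    cutoffs = np.asarray(sorted(cutoffs, reverse=True), dtype=float)

    # residue -> bodies, in chain/sequence order
    res_bodies: dict[ResidueKey, list[int]] = {}
    for i, key in enumerate(network.body_residues):
        res_bodies.setdefault(key, []).append(i)
    ordered = sorted(res_bodies)
    chains: dict[str, list[ResidueKey]] = {}
    for key in ordered:
        chains.setdefault(key.chain, []).append(key)

    target_set = set(int(b) for b in target.bodies)
    windows: list[tuple[ResidueKey, ...]] = []
    for chain_residues in chains.values():
        if len(chain_residues) < window:
            continue
        for s in range(len(chain_residues) - window + 1):
            windows.append(tuple(chain_residues[s:s + window]))

    sums: dict[ResidueKey, float] = {k: 0.0 for k in ordered}
    counts: dict[ResidueKey, int] = {k: 0 for k in ordered}
    nonzero_cutoffs: dict[ResidueKey, set[int]] = {k: set() for k in ordered}

    for ic, cutoff in enumerate(cutoffs):
        sub = ConstraintNetwork(
            n_bodies=network.n_bodies,
            edges=_filtered_edges(network, cutoff),
            body_residues=network.body_residues,
            hbond_cutoff=cutoff,
            source_label=network.source_label,
        )
        base_state, _ = play_network(sub)
        probe = base_state.copy()
        dof_before = _site_dof(probe, target.bodies)
        for win in windows:
            bodies = np.array(
                [b for key in win for b in res_bodies[key]], dtype=np.int64
            )
            if target_set.intersection(int(b) for b in bodies):
                continue
            state = base_state.copy()
            _rigidify(state, bodies)
            transmitted = dof_before - _site_dof(state, target.bodies)
            for key in win:
                sums[key] += transmitted
                counts[key] += 1
                if transmitted > 0:
                    nonzero_cutoffs[key].add(ic)

    intensity = {k: (sums[k] / counts[k] if counts[k] else 0.0)
                 for k in ordered}
    persistence = {k: len(nonzero_cutoffs[k]) / len(cutoffs)
                   for k in ordered}
    return RTAProfile(intensity=intensity, persistence=persistence,
                      window=window, cutoffs=cutoffs,
                      target_label=target.label)


# --------------------------------------------------------------------------
# AUC and hotspot calls
# --------------------------------------------------------------------------


@dataclass
class AUCResult:
    value: float
    x_label: str = ""
    region: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {"auc": self.value, "x_label": self.x_label,
             "region": self.region}
        )


def allosteric_auc(x: Sequence[float], y: Sequence[float],
                   x_label: str = "", region: str = "") -> AUCResult:
    """Area under an intensity curve.

    ``AUC = sum (x_i - x_{i-1}) y_{i-1} + 1/2 (x_i - x_{i-1})(y_i - y_{i-1})``
    (a rectangle plus a triangle per interval, i.e. the trapezoid rule).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly ascending")
    dx = np.diff(x)
    value = float(np.sum(dx * y[:-1] + 0.5 * dx * np.diff(y)))
    return AUCResult(value=value, x_label=x_label, region=region)


def call_hotspots(profile: RTAProfile, percentile: float = 90.0,
                  exclude: Iterable[ResidueKey] = ()) -> set[ResidueKey]:
    """Residues whose intensity strictly exceeds the given percentile of
    the nonzero intensities (an optional mask, e.g. the antenna, is
    excluded first)."""
    exclude = set(exclude)
    items = {k: v for k, v in profile.intensity.items() if k not in exclude}
    nonzero = np.array([v for v in items.values() if v > 0.0])
    if nonzero.size == 0:
        warnings.warn("all-zero transmission profile; no hotspots",
                      stacklevel=2)
        return set()
    threshold = float(np.percentile(nonzero, percentile))
    return {k for k, v in items.items() if v > threshold}


def remove_bodies(network: ConstraintNetwork,
                  bodies: Iterable[int]) -> ConstraintNetwork:
    """Copy of the network with the given bodies (e.g. a ligand) deleted."""
    drop = set(int(b) for b in bodies)
    keep = [i for i in range(network.n_bodies) if i not in drop]
    remap = {old: new for new, old in enumerate(keep)}
    edges = [
        BarEdge(remap[e.body_i], remap[e.body_j], e.bars, e.kind, e.energy)
        for e in network.edges
        if e.body_i not in drop and e.body_j not in drop
    ]
    residues = None
    if network.body_residues is not None:
        residues = [network.body_residues[i] for i in keep]
    coords = None
    if network.coords is not None:
        coords = network.coords[keep]
    return ConstraintNetwork(
        n_bodies=len(keep), edges=edges, body_residues=residues,
        coords=coords, hbond_cutoff=network.hbond_cutoff,
        source_label=network.source_label,
    )
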