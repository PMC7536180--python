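"""Rigid-cluster decomposition and DOF counting via the (6,6) body-bar
pebble game."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from ._pebble import PebbleState
from .network import VALID_BARS, ConstraintNetwork
from .structure import ResidueKey


def _validate(network: ConstraintNetwork) -> None:
    for e in network.edges:
        if e.bars not in VALID_BARS:
            raise ValueError(f"invalid bar count {e.bars} on edge "
                             f"({e.body_i}, {e.body_j})")


def _connected_component_count(network: ConstraintNetwork) -> int:
    n = network.n_bodies
    if not network.edges:
        return n
    eu, ev, _ = network.edge_arrays()
    graph = coo_matrix(
        (np.ones(eu.size), (eu, ev)), shape=(n, n)
    )
    n_comp, _ = connected_components(graph, directed=False)
    return int(n_comp)


def play_network(network: ConstraintNetwork) -> tuple[PebbleState, np.ndarray]:
    """Run the pebble game over all edges; returns (state, accepted bars)."""
    _validate(network)
    state = PebbleState(network.n_bodies)
    eu, ev, eb = network.edge_arrays()
    accepted = state.insert_edges(eu, ev, eb) if eu.size else np.zeros(0, int)
    return state, accepted


def pebble_game_dof(network: ConstraintNetwork
                    ) -> tuple[int, PebbleState, int]:
    """(internal DOF, final pebble state, redundant bar count).

    Internal DOF = total free pebbles minus 6 per connected component;
    bars rejected by the game are redundant.
    """
    state, accepted = play_network(network)
    _, _, eb = network.edge_arrays()
    redundant = int(eb.sum() - accepted.sum()) if eb.size else 0
    n_comp = _connected_component_count(network)
    internal = state.free_pebbles() - 6 * n_comp
    return internal, state, redundant


@dataclass
class RigidClusterDecomposition:
    """Partition of bodies into maximal mutually-rigid clusters."""

    labels: np.ndarray  # cluster representative (smallest body id) per body
    clusters: list[np.ndarray]  # sorted by size descending, then min id
    lrc_id: int
    lrc_size: int
    n_clusters: int
    internal_dof: int
    redundant_bars: int
    body_residues: list[ResidueKey] | None = None

    def cluster_of(self, body: int) -> int:
        return int(self.labels[body])

    def lrc_bodies(self) -> np.ndarray:
        return np.nonzero(self.labels == self.lrc_id)[0]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("body\tcluster\tresidue\n")
            for i, lab in enumerate(self.labels):
                res = ""
                if self.body_residues is not None:
                    res = str(self.body_residues[i])
                fh.write(f"{i}\t{int(lab)}\t{res}\n")

    def to_pymol_script(self, path: str | Path, top: int = 10) -> None:
        """Text coloring script for the `top` largest clusters."""
        palette = ["cyan", "orange", "magenta", "yellow", "green",
                   "salmon", "purple", "olive", "teal", "wheat"]
        with open(path, "w") as fh:
            fh.write("# rigid-cluster coloring script\n")
            for c, bodies in enumerate(self.clusters[:top]):
                ids = "+".join(str(b + 1) for b in bodies[:2000])
                fh.write(f"select cluster_{c}, id {ids}\n")
                fh.write(f"color {palette[c % len(palette)]}, cluster_{c}\n")


def rigid_clusters(network: ConstraintNetwork) -> RigidClusterDecomposition:
    """Pebble-game rigid-cluster decomposition of a constraint network."""
    internal, state, redundant = pebble_game_dof(network)
    indptr, indices = network.undirected_csr()
    labels = state.decompose(indptr, indices)
    reps, inverse, counts = np.unique(labels, return_inverse=True,
                                      return_counts=True)
    order = sorted(range(reps.size), key=lambda r: (-counts[r], reps[r]))
    clusters = [np.nonzero(labels == reps[r])[0] for r in order]
    lrc_id = int(reps[order[0]]) if reps.size else -1
    return RigidClusterDecomposition(
        labels=labels,
        clusters=clusters,
        lrc_id=lrc_id,
        lrc_size=int(counts[order[0]]) if reps.size else 0,
        n_clusters=int(reps.size),
        internal_dof=internal,
        redundant_bars=redundant,
        body_residues=network.body_residues,
    )


def mutually_rigid(network: ConstraintNetwork, body_i: int,
                   body_j: int) -> bool:
    """Probe-edge test: a rejected extra bar means the pair is rigid."""
    state, _ = play_network(network)
    probe = state.copy()
    accepted = probe.insert_edges(
        np.array([body_i]), np.array([body_j]), np.array([1])
    )
    return accepted[0] == 0


def cluster_membership_stats(decomp: RigidClusterDecomposition,
                             residues: Iterable[ResidueKey] | None = None,
                             bodies: Sequence[int] | None = None) -> float:
    """Atom-weighted fraction of a residue range inside the LRC."""
    if bodies is None:
        if residues is None or decomp.body_residues is None:
            raise ValueError("need residues (with back-map) or bodies")
        wanted = set(residues)
        bodies = [i for i, r in enumerate(decomp.body_residues)
                  if r in wanted]
    bodies = np.asarray(list(bodies), dtype=int)
    if bodies.size == 0:
        raise ValueError("empty residue range")
    return float(np.mean(decomp.labels[bodies] == decomp.lrc_id))
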