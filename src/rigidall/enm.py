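"""Gaussian and anisotropic elastic network models over C-alpha nodes:
global modes, frequency dispersion, collectivity, sign-based domain
splitting, hinge prediction and mode overlap."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure import AtomRecord, ResidueKey, StructureModel

GNM_CUTOFF = 7.3
ANM_CUTOFF = 15.0
_ZERO_TOL = 1e-8


@dataclass
class ModeSet:
    eigenvalues: np.ndarray  # ascending
    eigenvectors: np.ndarray  # columns, orthonormal
    n_zero_modes: int
    model_kind: str  # GNM | ANM
    cutoff: float
    node_keys: list[ResidueKey]
    ca_coords: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.node_keys)

    def nontrivial_index(self, mode_index: int) -> int:
        """Column index of the ``mode_index``-th nontrivial mode (1-based)."""
        if mode_index < 1:
            raise ValueError("mode_index is 1-based")
        col = self.n_zero_modes + mode_index - 1
        if col >= self.eigenvectors.shape[1]:
            raise IndexError(f"mode {mode_index} not computed")
        return col

    def mode_vector(self, mode_index: int) -> np.ndarray:
        return self.eigenvectors[:, self.nontrivial_index(mode_index)]

    def to_nmd(self, path: str | Path, n_modes: int = 5) -> None:
        """Plain-text NMD export for external mode viewers."""
        with open(path, "w") as fh:
            fh.write(f"name {self.model_kind.lower()}_modes\n")
            fh.write("resids " + " ".join(
                str(k.res_seq) for k in self.node_keys) + "\n")
            if self.ca_coords is not None:
                fh.write("coordinates " + " ".join(
                    f"{x:.3f}" for x in self.ca_coords.ravel()) + "\n")
            for m in range(1, n_modes + 1):
                try:
                    vec = self.mode_vector(m)
                except IndexError:
                    break
                fh.write(f"mode {m} " + " ".join(
                    f"{x:.5f}" for x in vec) + "\n")


def _ca_nodes(model: StructureModel) -> tuple[list[ResidueKey], np.ndarray]:
    keys, coords = [], []
    for key in model.residues():
        i = model.atom_index(key, "CA")
        if i is not None and not model.atoms[i].is_hetero:
            keys.append(key)
            coords.append(model.coords[i])
    return keys, np.asarray(coords, float)


def gnm_modes(model: StructureModel, cutoff: float = GNM_CUTOFF,
              n_modes: int | None = None) -> ModeSet:
    """Gaussian network model: eigendecomposition of the Kirchhoff matrix
    (unit spring constant) over CA nodes within ``cutoff``."""
    keys, coords = _ca_nodes(model)
    n = len(keys)
    if n < 2:
        raise ValueError("need at least 2 CA nodes")
    tree = cKDTree(coords)
    gamma = np.zeros((n, n))
    for i, j in tree.query_pairs(cutoff):
        gamma[i, j] = gamma[j, i] = -1.0
    np.fill_diagonal(gamma, -gamma.sum(axis=1))
    if n_modes is None or n_modes >= n:
        evals, evecs = np.linalg.eigh(gamma)
    else:
        from scipy.linalg import eigh

        evals, evecs = eigh(gamma, subset_by_index=(0, n_modes - 1))
    n_zero = int(np.sum(evals < _ZERO_TOL * max(1.0, abs(evals[-1]))))
    return ModeSet(evals, evecs, n_zero, "GNM", cutoff, keys, coords)


def _anm_hessian(coords: np.ndarray, cutoff: float) -> np.ndarray:
    n = len(coords)
    hess = np.zeros((3 * n, 3 * n))
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(cutoff):
        d = coords[j] - coords[i]
        d2 = d @ d
        block = -np.outer(d, d) / d2
        hess[3 * i:3 * i + 3, 3 * j:3 * j + 3] += block
        hess[3 * j:3 * j + 3, 3 * i:3 * i + 3] += block
        hess[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        hess[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    return hess


def anm_modes(model: StructureModel, cutoff: float = ANM_CUTOFF,
              n_modes: int | None = None) -> ModeSet:
    """Anisotropic network model (3N Hessian, unit spring constant).

    A connected, non-degenerate structure has exactly 6 zero modes; large
    systems are solved sparsely for the lowest modes only.
    """
    keys, coords = _ca_nodes(model)
    n = len(keys)
    if n < 3:
        raise ValueError("need at least 3 CA nodes")
    if n_modes is not None and 3 * n > 1200:
        import scipy.sparse as sp
        from scipy.sparse.linalg import eigsh

        hess = sp.csc_matrix(_anm_hessian(coords, cutoff))
        shift = -1e-4
        evals, evecs = eigsh(hess, k=min(n_modes, 3 * n - 2), sigma=shift,
                             which="LM")
        order = np.argsort(evals)
        evals, evecs = evals[order], evecs[:, order]
    else:
        evals, evecs = np.linalg.eigh(_anm_hessian(coords, cutoff))
    evals = np.where(np.abs(evals) < _ZERO_TOL, 0.0, evals)
    n_zero = int(np.sum(evals < _ZERO_TOL * max(1.0, abs(evals[-1]))))
    return ModeSet(evals, evecs, n_zero, "ANM", cutoff, keys, coords)


def mode_displaced_conformer(modes: ModeSet, mode_index: int,
                             amplitude: float) -> StructureModel:
    """CA-trace conformer displaced along an ANM mode so that its CA RMSD
    from the input equals ``amplitude`` (in Angstrom)."""
    if modes.model_kind != "ANM":
        raise ValueError("conformer generation needs ANM modes")
    vec = modes.mode_vector(mode_index)
    n = modes.n_nodes
    u = vec / np.linalg.norm(vec)
    scale = amplitude * np.sqrt(n)
    displaced = modes.ca_coords + scale * u.reshape(n, 3)
    atoms = [
        AtomRecord(serial=i + 1, name="CA", element="C", res_name="ALA",
                   chain=key.chain, res_seq=key.res_seq, icode=key.icode,
                   xyz=tuple(displaced[i]))
        for i, key in enumerate(modes.node_keys)
    ]
    return StructureModel(atoms, label=f"anm_mode{mode_index}")


def gnm_mean_square_fluctuations(modes: ModeSet) -> np.ndarray:
    """Per-node mean-square fluctuations from the Kirchhoff pseudo-inverse
    diagonal (sum of u_i^2 / lambda over nontrivial modes)."""
    if modes.model_kind != "GNM":
        raise ValueError("MSF profile defined for GNM modes")
    vecs = modes.eigenvectors[:, modes.n_zero_modes:]
    vals = modes.eigenvalues[modes.n_zero_modes:]
    return np.sum(vecs**2 / vals[None, :], axis=1)


@dataclass
class ModeStats:
    mode_index: int
    eigenvalue: float
    frequency_dispersion: float  # 1 / eigenvalue
    collectivity: float


def mode_stats(modes: ModeSet, mode_index: int = 2) -> ModeStats:
    """Frequency dispersion (1/eigenvalue) and entropy-based collectivity
    of a nontrivial mode (per-residue squared amplitudes)."""
    col = modes.nontrivial_index(mode_index)
    lam = float(modes.eigenvalues[col])
    if lam < _ZERO_TOL:
        raise ValueError("requested mode is a zero mode")
    vec = modes.eigenvectors[:, col]
    if modes.model_kind == "ANM":
        amp2 = np.sum(vec.reshape(-1, 3) ** 2, axis=1)
    else:
        amp2 = vec ** 2
    p = amp2 / amp2.sum()
    p_nonzero = p[p > 0]
    entropy = -np.sum(p_nonzero * np.log(p_nonzero))
    kappa = float(np.exp(entropy) / p.size)
    return ModeStats(mode_index=mode_index, eigenvalue=lam,
                     frequency_dispersion=1.0 / lam, collectivity=kappa)


@dataclass
class DomainSplit:
    signs: np.ndarray  # +1 / -1 per node
    domains: list[tuple[int, int]]  # contiguous node-index runs
    hinges: list[ResidueKey]

    @property
    def n_domains(self) -> int:
        return len(self.domains)


def domain_split_hinges(modes: ModeSet, mode_index: int = 1,
                        hinge_tol: float = 1e-3) -> DomainSplit:
    """Split nodes into +/- domains along a GNM mode; hinges flank the
    sign crossings (nodes with near-zero amplitude join the hinge band)."""
    if modes.model_kind != "GNM":
        raise ValueError("domain splitting uses GNM modes")
    vec = modes.mode_vector(mode_index)
    signs = np.where(vec >= 0.0, 1, -1)
    domains = []
    start = 0
    for i in range(1, len(signs)):
        if signs[i] != signs[i - 1]:
            domains.append((start, i - 1))
            start = i
    domains.append((start, len(signs) - 1))
    hinges: list[ResidueKey] = []
    for i in range(1, len(signs)):
        if signs[i] != signs[i - 1]:
            hinges.append(modes.node_keys[i - 1])
            hinges.append(modes.node_keys[i])
    for i, v in enumerate(vec):
        if abs(v) < hinge_tol and modes.node_keys[i] not in hinges:
            hinges.append(modes.node_keys[i])
    return DomainSplit(signs=signs, domains=domains, hinges=sorted(hinges))


@dataclass
class OverlapResult:
    per_mode: np.ndarray
    cumulative: np.ndarray  # sqrt of the running sum of squares

    def best_mode(self) -> int:
        return int(np.argmax(self.per_mode)) + 1


def mode_overlap(modes: ModeSet, displacement: np.ndarray) -> OverlapResult:
    """Normalized overlap of each nontrivial mode with a displacement
    vector (3N for ANM, N for GNM); conformers must be superposed first."""
    delta = np.asarray(displacement, float).ravel()
    norm = np.linalg.norm(delta)
    if norm < 1e-12:
        raise ValueError("zero displacement")
    vecs = modes.eigenvectors[:, modes.n_zero_modes:]
    if vecs.shape[0] != delta.size:
        raise ValueError("displacement length does not match modes")
    overlaps = np.abs(vecs.T @ delta) / (
        np.linalg.norm(vecs, axis=0) * norm
    )
    cumulative = np.sqrt(np.cumsum(overlaps ** 2))
    return OverlapResult(per_mode=overlaps, cumulative=cumulative)
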