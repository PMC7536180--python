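"""Ensemble analysis of backbone dihedrals and peptide-bond geometry:
transition-zone occupancy, distortion fits and Ramachandran densities.

Records are held in a pandas DataFrame with one row per (residue, frame);
see :func:`peptide_geometry` for the column schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import angle, dihedral
from .structure import Ensemble, ResidueKey

logger = logging.getLogger(__name__)

TRANSITION_ZONE = (-35.0, 35.0)

#: Reference backbone bond angles (degrees) for distortion measures.
STANDARD_ANGLES = {
    "ang_C1_N_CA": 121.7,
    "ang_O1_C1_N": 123.0,
    "ang_CA1_C1_N": 116.6,
    "ang_N_CA_C": 111.0,
    "ang_CA_C_O": 120.8,
    "ang_CA_C_N1": 116.6,
}

_COLUMNS = ["chain", "res_seq", "icode", "res_name", "frame",
            "phi", "psi", "omega",
            "ang_C1_N_CA", "ang_O1_C1_N", "ang_CA1_C1_N",
            "ang_N_CA_C", "ang_CA_C_O", "ang_CA_C_N1", "d_O1_C"]


def peptide_geometry(ensemble: Ensemble,
                     residues: Sequence[ResidueKey] | None = None
                     ) -> pd.DataFrame:
    """Backbone torsions, bond angles and the O(-1)...C distance per
    (residue, frame).

    Residues without two flanking residues on both sides are excluded;
    rows with missing backbone atoms are omitted (and logged).
    """
    wanted = None if residues is None else set(residues)
    rows = []
    ref = ensemble.frames[0]
    by_chain: dict[str, list[ResidueKey]] = {}
    for key in ref.residues():
        by_chain.setdefault(key.chain, []).append(key)

    for f, frame in enumerate(ensemble.frames):
        for chain, keys in by_chain.items():
            for pos in range(2, len(keys) - 2):
                key = keys[pos]
                if wanted is not None and key not in wanted:
                    continue
                prev = keys[pos - 1]
                nxt = keys[pos + 1]
                needed = {
                    "N": frame.atom_coord(key, "N"),
                    "CA": frame.atom_coord(key, "CA"),
                    "C": frame.atom_coord(key, "C"),
                    "O": frame.atom_coord(key, "O"),
                    "N+1": frame.atom_coord(nxt, "N"),
                    "C-1": frame.atom_coord(prev, "C"),
                    "CA-1": frame.atom_coord(prev, "CA"),
                    "O-1": frame.atom_coord(prev, "O"),
                }
                if any(v is None for v in needed.values()):
                    missing = [k for k, v in needed.items() if v is None]
                    logger.warning("frame %d residue %s: missing %s; "
                                   "record omitted", f, key, missing)
                    continue
                n, ca, c = needed["N"], needed["CA"], needed["C"]
                o = needed["O"]
                n_next = needed["N+1"]
                c_prev, ca_prev = needed["C-1"], needed["CA-1"]
                o_prev = needed["O-1"]
                rows.append({
                    "chain": chain, "res_seq": key.res_seq,
                    "icode": key.icode,
                    "res_name": frame.residue_name(key), "frame": f,
                    "phi": dihedral(c_prev, n, ca, c),
                    "psi": dihedral(n, ca, c, n_next),
                    "omega": dihedral(ca_prev, c_prev, n, ca),
                    "ang_C1_N_CA": angle(c_prev, n, ca),
                    "ang_O1_C1_N": angle(o_prev, c_prev, n),
                    "ang_CA1_C1_N": angle(ca_prev, c_prev, n),
                    "ang_N_CA_C": angle(n, ca, c),
                    "ang_CA_C_O": angle(ca, c, o),
                    "ang_CA_C_N1": angle(ca, c, n_next),
                    "d_O1_C": float(np.linalg.norm(o_prev - c)),
                })
    return pd.DataFrame(rows, columns=_COLUMNS)


@dataclass
class TransitionZoneReport:
    zone: tuple[float, float]
    counts: dict[tuple[str, int, str], int]  # (chain, res_seq, icode)
    n_frames: int

    def ranked(self) -> list[tuple[tuple[str, int, str], int]]:
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))


def transition_zone_scan(records: pd.DataFrame,
                         zone: tuple[float, float] = TRANSITION_ZONE
                         ) -> TransitionZoneReport:
    """Per-residue counts of frames with phi strictly inside the open
    high-energy interval (default -35 < phi < +35 degrees)."""
    if records.empty:
        raise ValueError("no records")
    lo, hi = zone
    inside = records[(records.phi > lo) & (records.phi < hi)]
    counts = {
        (chain, int(res_seq), icode): int(n)
        for (chain, res_seq, icode), n in
        inside.groupby(["chain", "res_seq", "icode"]).size().items()
    }
    n_frames = int(records.frame.nunique())
    return TransitionZoneReport(zone=zone, counts=counts, n_frames=n_frames)


@dataclass
class FitResult:
    model: str  # quadratic_in_phi | cosine_in_phi
    coefficients: tuple[float, ...]  # (a, b, c) or (amplitude,)
    r_squared: float
    n: int

    def predict(self, phi: np.ndarray) -> np.ndarray:
        phi = np.asarray(phi, float)
        if self.model == "quadratic_in_phi":
            a, b, c = self.coefficients
            return a * phi**2 + b * phi + c
        (amp,) = self.coefficients
        return amp * np.cos(phi * np.pi / 120.0)


def fit_distortion_models(records: pd.DataFrame, response: str = "d_O1_C",
                          model: str = "quadratic",
                          reference: float | None = None) -> FitResult:
    """Least-squares fits of peptide-geometry distortion against phi.

    quadratic: ``y = a phi^2 + b phi + c`` on the raw response.
    cosine: ``y = I cos(phi pi / 120)`` (fixed 240-degree period) on the
    response minus its reference value (standard backbone geometry for
    angles; override with ``reference``).
    """
    if response not in records.columns:
        raise KeyError(f"no column {response!r}")
    data = records[["phi", response]].dropna()
    if len(data) < 5:
        raise ValueError("need at least 5 records")
    phi = data.phi.to_numpy(float)
    y = data[response].to_numpy(float)

    if model == "quadratic":
        design = np.column_stack([phi**2, phi, np.ones_like(phi)])
        if np.linalg.matrix_rank(design) < 3:
            raise ValueError("rank-deficient design (constant phi?)")
        coeffs, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        pred = design @ coeffs
        kind = "quadratic_in_phi"
        out = tuple(float(v) for v in coeffs)
    elif model == "cosine":
        if reference is None:
            reference = STANDARD_ANGLES.get(response, 0.0)
        yc = y - reference
        basis = np.cos(phi * np.pi / 120.0)
        denom = float(basis @ basis)
        if denom < 1e-12:
            raise ValueError("rank-deficient design")
        amp = float(basis @ yc) / denom
        pred = amp * basis + reference
        kind = "cosine_in_phi"
        out = (amp,)
    else:
        raise ValueError("model must be 'quadratic' or 'cosine'")

    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return FitResult(model=kind, coefficients=out, r_squared=r2,
                     n=len(data))


@dataclass
class RamachandranDensity:
    histogram: np.ndarray  # normalized to sum 1
    phi_edges: np.ndarray
    psi_edges: np.ndarray

    def neg_log_density(self, floor: float = 1e-12) -> np.ndarray:
        return -np.log(np.maximum(self.histogram, floor))


def ramachandran_density(records: pd.DataFrame,
                         bins: int = 36) -> RamachandranDensity:
    """Normalized 2-D phi/psi histogram with periodic binning on
    (-180, 180] (so phi = -180 and phi = +180 share a bin)."""
    if records.empty:
        raise ValueError("no records")

    def _wrap(x):
        x = np.asarray(x, float)
        wrapped = ((x - 180.0) % 360.0) + 180.0  # maps to (-180, 180]
        return np.where(wrapped > 180.0, wrapped - 360.0, wrapped)

    phi = _wrap(records.phi.to_numpy())
    psi = _wrap(records.psi.to_numpy())
    edges = np.linspace(-180.0, 180.0, bins + 1)
    hist, pe, se = np.histogram2d(phi, psi, bins=[edges, edges])
    hist = hist / hist.sum()
    return RamachandranDensity(histogram=hist, phi_edges=pe, psi_edges=se)
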