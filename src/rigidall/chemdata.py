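"""Chemical reference data: radii, residue bond templates, donor/acceptor
typing, aromatic rings, hydrophobic typing and helix annotations.

Bond templates cover the 20 standard amino acids; anything else (ligands,
modified residues) falls back to distance-based bond detection.
"""

from __future__ import annotations

# --- element data ---------------------------------------------------------

#: Covalent radii in Angstrom (Cordero et al. consensus values).
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "SE": 1.20,
    "MG": 1.41, "ZN": 1.22, "FE": 1.32, "CA": 1.76, "NA": 1.66, "K": 2.03,
}

#: Bondi van der Waals radii in Angstrom.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "MG": 1.73, "ZN": 1.39, "NA": 2.27, "K": 2.75,
}

DEFAULT_COVALENT_RADIUS = 1.0
DEFAULT_VDW_RADIUS = 1.70


def covalent_radius(element: str) -> float:
    return COVALENT_RADII.get(element.upper(), DEFAULT_COVALENT_RADIUS)


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)


# --- residue bond templates ----------------------------------------------

_BACKBONE_BONDS = [("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT")]

_SIDECHAIN_BONDS = {
    "ALA": [("CA", "CB")],
    "ARG": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
            ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")],
    "ASN": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "ASP": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "CYS": [("CA", "CB"), ("CB", "SG")],
    "GLN": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "NE2")],
    "GLU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "OE2")],
    "GLY": [],
    "HIS": [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
            ("ND1", "CE1"), ("CD2", "NE2"), ("CE1", "NE2")],
    "ILE": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "LEU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "LYS": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"),
            ("CE", "NZ")],
    "MET": [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PHE": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "PRO": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "SER": [("CA", "CB"), ("CB", "OG")],
    "THR": [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
    "TRP": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "NE1"), ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"),
            ("CE2", "CZ2"), ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2")],
    "TYR": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
            ("CZ", "OH")],
    "VAL": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
}

STANDARD_RESIDUES = frozenset(_SIDECHAIN_BONDS)


def residue_bonds(res_name: str) -> list[tuple[str, str]] | None:
    """Heavy-atom bond template for a standard residue, else None."""
    sc = _SIDECHAIN_BONDS.get(res_name.upper())
    if sc is None:
        return None
    return _BACKBONE_BONDS + sc


#: Intra-residue bonds with double / partial-double character (locked, i.e.
#: no free torsion).  Peptide C-N bonds are locked by the network builder.
_LOCKED_BONDS = {
    "ARG": {("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")},
    "ASN": {("CG", "OD1"), ("CG", "ND2")},
    "ASP": {("CG", "OD1"), ("CG", "OD2")},
    "GLN": {("CD", "OE1"), ("CD", "NE2")},
    "GLU": {("CD", "OE1"), ("CD", "OE2")},
    "HIS": {("CG", "ND1"), ("CG", "CD2"), ("ND1", "CE1"), ("CD2", "NE2"),
            ("CE1", "NE2")},
    "PHE": {("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"), ("CD2", "CE2"),
            ("CE1", "CZ"), ("CE2", "CZ")},
    "TRP": {("CG", "CD1"), ("CG", "CD2"), ("CD1", "NE1"), ("NE1", "CE2"),
            ("CD2", "CE2"), ("CD2", "CE3"), ("CE2", "CZ2"), ("CE3", "CZ3"),
            ("CZ2", "CH2"), ("CZ3", "CH2")},
    "TYR": {("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"), ("CD2", "CE2"),
            ("CE1", "CZ"), ("CE2", "CZ")},
}


def is_locked_bond(res_name: str, name_a: str, name_b: str) -> bool:
    """True for intra-residue bonds with no rotational freedom.

    Carbonyl C=O (and C-OXT) bonds are locked for every residue.
    """
    pair = {name_a.upper(), name_b.upper()}
    if pair in ({"C", "O"}, {"C", "OXT"}):
        return True
    locked = _LOCKED_BONDS.get(res_name.upper(), set())
    a, b = sorted(pair)
    return (a, b) in locked or (b, a) in locked


# --- hydrogen-bond donors / acceptors -------------------------------------

# donor heavy atom -> (hybridization, number of polar hydrogens to build)
_SIDECHAIN_DONORS = {
    "SER": {"OG": ("sp3", 1)},
    "THR": {"OG1": ("sp3", 1)},
    "TYR": {"OH": ("sp2", 1)},
    "LYS": {"NZ": ("sp3", 3)},
    "ARG": {"NE": ("sp2", 1), "NH1": ("sp2", 2), "NH2": ("sp2", 2)},
    "HIS": {"ND1": ("sp2", 1), "NE2": ("sp2", 1)},
    "TRP": {"NE1": ("sp2", 1)},
    "ASN": {"ND2": ("sp2", 2)},
    "GLN": {"NE2": ("sp2", 2)},
    "CYS": {"SG": ("sp3", 1)},
}

# acceptor heavy atom -> (hybridization, base atom name)
_SIDECHAIN_ACCEPTORS = {
    "ASN": {"OD1": ("sp2", "CG")},
    "GLN": {"OE1": ("sp2", "CD")},
    "ASP": {"OD1": ("sp2", "CG"), "OD2": ("sp2", "CG")},
    "GLU": {"OE1": ("sp2", "CD"), "OE2": ("sp2", "CD")},
    "SER": {"OG": ("sp3", "CB")},
    "THR": {"OG1": ("sp3", "CB")},
    "TYR": {"OH": ("sp2", "CZ")},
    "MET": {"SD": ("sp3", "CG")},
    "CYS": {"SG": ("sp3", "CB")},
}


def donor_info(res_name: str, atom_name: str):
    """(hybridization, n_hydrogens) for a donor heavy atom, else None."""
    res_name, atom_name = res_name.upper(), atom_name.upper()
    if atom_name == "N" and res_name != "PRO":
        return ("sp2", 1)
    return _SIDECHAIN_DONORS.get(res_name, {}).get(atom_name)


def acceptor_info(res_name: str, atom_name: str):
    """(hybridization, base-atom name) for an acceptor heavy atom, else None."""
    res_name, atom_name = res_name.upper(), atom_name.upper()
    if atom_name in ("O", "OXT"):
        return ("sp2", "C")
    return _SIDECHAIN_ACCEPTORS.get(res_name, {}).get(atom_name)


#: Charged groups used for salt-bridge typing.
CHARGED_DONOR_ATOMS = {
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
}
CHARGED_ACCEPTOR_ATOMS = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
}

# --- aromatic rings -------------------------------------------------------

AROMATIC_RINGS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "TRP": [("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")],
}

# --- ligand naming --------------------------------------------------------

#: Hetero residue-name synonyms for the ligands handled by the pipeline.
LIGAND_SYNONYMS = {
    "NADH": {"NAI", "NAD", "NDH"},
    "GTP": {"GTP"},
}

# --- GDH helix annotation -------------------------------------------------

#: PROVISIONAL helix ranges (roman numeral -> inclusive residue range) for
#: mammalian glutamate dehydrogenase, mature-chain numbering.  The primary
#: source never prints this table; prefer ``helices_from_pdb_header`` on an
#: actual deposited file, which overrides these estimates.
GDH_HELIX_RANGES = {
    "I": (10, 25), "II": (61, 76), "III": (105, 124), "IV": (141, 153),
    "V": (161, 165), "VI": (187, 207), "VII": (217, 227), "VIII": (254, 260),
    "IX": (280, 292), "X": (327, 339), "XI": (376, 394), "XII": (410, 421),
    "XIII": (423, 442), "XIV": (444, 470),
}


def helices_from_pdb_header(path, chain: str = "A",
                            min_length: int = 5) -> dict[str, tuple[int, int]]:
    """Helix ranges parsed from HELIX records of a PDB file.

    Returns a roman-numbered table (I, II, ...) of helices on ``chain`` with
    at least ``min_length`` residues, in sequence order.  Falls back to an
    empty dict when the file carries no HELIX records.
    """
    romans = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
              "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII",
              "XIX", "XX"]
    ranges = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("HELIX"):
                continue
            try:
                init_chain = line[19].strip()
                start = int(line[21:25])
                end = int(line[33:37])
            except (ValueError, IndexError):
                continue
            if init_chain == chain and end - start + 1 >= min_length:
                ranges.append((start, end))
    ranges.sort()
    return {romans[i]: r for i, r in enumerate(ranges[: len(romans)])}
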