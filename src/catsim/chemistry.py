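"""Amino-acid nomenclature tables and idealized side-chain geometry.

Heavy-atom names follow PDB v3 conventions. The idealized templates are
built from internal coordinates (standard bond lengths and tetrahedral /
trigonal angles) and are used only by the synthetic generator; RMSD
behaviour, not rotamer realism, is what they need to capture.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

CANONICAL_AA: frozenset[str] = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

BACKBONE_ATOMS: tuple[str, ...] = ("N", "CA", "C", "O")

# Side-chain heavy atoms in canonical PDB order.
SIDE_CHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}


def heavy_atom_order(aa: str) -> tuple[str, ...]:
    """Canonical heavy-atom name order: backbone N, CA, C, O then side chain."""
    return BACKBONE_ATOMS + SIDE_CHAIN_ATOMS.get(aa, ())


# Chemically indistinguishable atom pairs: swapping the members of every pair
# listed for a residue type yields an equivalent labeling (carboxylate oxygens,
# guanidinium nitrogens, two-fold symmetric rings).
SYMMETRIC_SWAPS: dict[str, tuple[tuple[str, str], ...]] = {
    "ASP": (("OD1", "OD2"),),
    "GLU": (("OE1", "OE2"),),
    "ARG": (("NH1", "NH2"),),
    "PHE": (("CD1", "CD2"), ("CE1", "CE2")),
    "TYR": (("CD1", "CD2"), ("CE1", "CE2")),
}

# Residues most often seen as catalytic: the 11 polar / charged side chains.
CATALYTIC_POOL: tuple[str, ...] = (
    "HIS", "ASP", "GLU", "LYS", "ARG", "SER", "THR", "TYR", "CYS", "ASN", "GLN",
)
HYDROPHOBIC_EXTRAS: tuple[str, ...] = ("PHE", "ILE", "LEU", "VAL", "ALA")

_ELEMENT_BY_INITIAL = {"C": "C", "N": "N", "O": "O", "S": "S"}


def element_of(atom_name: str) -> str:
    """Element symbol from a heavy-atom PDB name (first letter suffices here)."""
    return _ELEMENT_BY_INITIAL.get(atom_name[0], atom_name[0])


# ---------------------------------------------------------------------------
# Idealized residue templates from internal coordinates
# ---------------------------------------------------------------------------

# (atom, parent, grandparent, bond length A, bond angle deg, dihedral deg)
# relative to great-grandparent; chains are built by NeRF placement.
_SIDE_TOPOLOGY: dict[str, tuple[tuple[str, str, str, str, float, float, float], ...]] = {
    # atom       parent  gparent ggparent length  angle  dihedral
    "ALA": (),
    "SER": (("OG", "CB", "CA", "N", 1.42, 109.5, 180.0),),
    "CYS": (("SG", "CB", "CA", "N", 1.81, 109.5, 180.0),),
    "THR": (("OG1", "CB", "CA", "N", 1.42, 109.5, 180.0),
            ("CG2", "CB", "CA", "N", 1.53, 109.5, -60.0)),
    "VAL": (("CG1", "CB", "CA", "N", 1.53, 109.5, 180.0),
            ("CG2", "CB", "CA", "N", 1.53, 109.5, -60.0)),
    "ILE": (("CG1", "CB", "CA", "N", 1.53, 109.5, 180.0),
            ("CG2", "CB", "CA", "N", 1.53, 109.5, -60.0),
            ("CD1", "CG1", "CB", "CA", 1.53, 109.5, 180.0)),
    "LEU": (("CG", "CB", "CA", "N", 1.53, 109.5, 180.0),
            ("CD1", "CG", "CB", "CA", 1.53, 109.5, 60.0),
            ("CD2", "CG", "CB", "CA", 1.53, 109.5, 180.0)),
    "ASP": (("CG", "CB", "CA", "N", 1.52, 109.5, 180.0),
            ("OD1", "CG", "CB", "CA", 1.25, 120.0, 0.0),
            ("OD2", "CG", "CB", "CA", 1.25, 120.0, 180.0)),
    "ASN": (("CG", "CB", "CA", "N", 1.52, 109.5, 180.0),
            ("OD1", "CG", "CB", "CA", 1.23, 120.0, 0.0),
            ("ND2", "CG", "CB", "CA", 1.33, 120.0, 180.0)),
    "GLU": (("CG", "CB", "CA", "N", 1.53, 109.5, 180.0),
            ("CD", "CG", "CB", "CA", 1.52, 109.5, 180.0),
            ("OE1", "CD", "CG", "CB", 1.25, 120.0, 0.0),
            ("OE2", "CD", "CG", "CB", 1.25, 120.0, 180.0)),
    "GLN": (("CG", "CB", "CA", "N", 1.53, 109.5, 180.0),
            ("CD", "CG", "CB", "CA", 1.52, 109.5, 180.0),
            ("OE1", "CD", "CG", "CB", 1.23, 120.0, 0.0),
            ("NE2", "CD", "CG", "CB", 1.33, 120.0, 180.0)),
    "LYS": (("CG", "CB", "CA", "N", 1.53, 109.5, 180.0),
            ("CD", "CG", "CB", "CA", 1.53, 109.5, 180.0),
            ("CE", "CD", "CG", "CB", 1.53, 109.5, 180.0),
            ("NZ", "CE", "CD", "CG", 1.49, 109.5, 180.0)),
    "ARG": (("CG", "CB", "CA", "N", 1.53, 109.5, 180.0),
            ("CD", "CG", "CB", "CA", 1.53, 109.5, 180.0),
            ("NE", "CD", "CG", "CB", 1.46, 109.5, 180.0),
            ("CZ", "NE", "CD", "CG", 1.33, 120.0, 180.0),
            ("NH1", "CZ", "NE", "CD", 1.33, 120.0, 0.0),
            ("NH2", "CZ", "NE", "CD", 1.33, 120.0, 180.0)),
    "MET": (("CG", "CB", "CA", "N", 1.53, 109.5, 180.0),
            ("SD", "CG", "CB", "CA", 1.81, 109.5, 180.0),
            ("CE", "SD", "CG", "CB", 1.79, 100.0, 180.0)),
    "HIS": (("CG", "CB", "CA", "N", 1.50, 109.5, 180.0),
            ("ND1", "CG", "CB", "CA", 1.38, 122.0, 0.0),
            ("CD2", "CG", "CB", "CA", 1.36, 131.0, 180.0),
            ("CE1", "ND1", "CG", "CB", 1.32, 109.0, 180.0),
            ("NE2", "CD2", "CG", "CB", 1.37, 107.0, 180.0)),
    "PHE": (("CG", "CB", "CA", "N", 1.50, 109.5, 180.0),
            ("CD1", "CG", "CB", "CA", 1.39, 120.0, 0.0),
            ("CD2", "CG", "CB", "CA", 1.39, 120.0, 180.0),
            ("CE1", "CD1", "CG", "CB", 1.39, 120.0, 180.0),
            ("CE2", "CD2", "CG", "CB", 1.39, 120.0, 180.0),
            ("CZ", "CE1", "CD1", "CG", 1.39, 120.0, 0.0)),
    "TYR": (("CG", "CB", "CA", "N", 1.50, 109.5, 180.0),
            ("CD1", "CG", "CB", "CA", 1.39, 120.0, 0.0),
            ("CD2", "CG", "CB", "CA", 1.39, 120.0, 180.0),
            ("CE1", "CD1", "CG", "CB", 1.39, 120.0, 180.0),
            ("CE2", "CD2", "CG", "CB", 1.39, 120.0, 180.0),
            ("CZ", "CE1", "CD1", "CG", 1.39, 120.0, 0.0),
            ("OH", "CZ", "CE1", "CD1", 1.38, 120.0, 180.0)),
    "GLY": (),
    "PRO": (("CG", "CB", "CA", "N", 1.50, 104.0, 30.0),
            ("CD", "CG", "CB", "CA", 1.50, 104.0, -30.0)),
    "TRP": (("CG", "CB", "CA", "N", 1.50, 109.5, 180.0),
            ("CD1", "CG", "CB", "CA", 1.37, 127.0, 0.0),
            ("CD2", "CG", "CB", "CA", 1.43, 126.0, 180.0),
            ("NE1", "CD1", "CG", "CB", 1.38, 110.0, 180.0),
            ("CE2", "CD2", "CG", "CB", 1.41, 107.0, 180.0),
            ("CE3", "CD2", "CG", "CB", 1.40, 133.5, 0.0),
            ("CZ2", "CE2", "CD2", "CG", 1.40, 122.0, 180.0),
            ("CZ3", "CE3", "CD2", "CG", 1.39, 118.8, 180.0),
            ("CH2", "CZ2", "CE2", "CD2", 1.37, 117.5, 180.0)),
}


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           length: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF: position of atom D given chain A-B-C and internal coordinates."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -length * math.cos(angle),
        length * math.sin(angle) * math.cos(dihedral),
        length * math.sin(angle) * math.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@lru_cache(maxsize=None)
def residue_template(aa: str) -> dict[str, tuple[float, float, float]]:
    """Idealized heavy-atom coordinates for one residue, CA at origin.

    Backbone is placed at standard geometry (N-CA 1.46 A, CA-C 1.52 A,
    C=O 1.23 A, tetrahedral CA); side chain follows the internal-coordinate
    topology table.
    """
    if aa not in CANONICAL_AA:
        raise KeyError(f"no template for residue type {aa!r}")
    coords: dict[str, np.ndarray] = {}
    coords["CA"] = np.zeros(3)
    coords["N"] = np.array([1.46, 0.0, 0.0])
    ang = math.radians(110.5)
    coords["C"] = 1.52 * np.array([math.cos(ang), math.sin(ang), 0.0])
    coords["O"] = _place(coords["N"], coords["CA"], coords["C"], 1.23, 121.0, 0.0)
    if aa != "GLY":
        coords["CB"] = _place(coords["N"], coords["C"], coords["CA"], 1.53, 110.5, 122.5)
    for atom, parent, gparent, ggparent, length, angle, dihedral in _SIDE_TOPOLOGY[aa]:
        coords[atom] = _place(coords[ggparent], coords[gparent], coords[parent],
                              length, angle, dihedral)
    return {name: tuple(map(float, xyz)) for name, xyz in coords.items()}
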