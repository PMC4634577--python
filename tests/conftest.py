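"""Shared fixtures: in-memory residues/sites and tiny on-disk format fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from catsim.chemistry import residue_template, element_of
from catsim.io_model import Atom, CatalyticSite, Residue


def build_residue(
    aa: str,
    chain: str = "A",
    seq_pos: int = 1,
    rotation: np.ndarray | None = None,
    ca: np.ndarray | tuple = (0.0, 0.0, 0.0),
) -> Residue:
    """A full heavy-atom residue from the idealized template."""
    R = np.eye(3) if rotation is None else rotation
    ca = np.asarray(ca, dtype=float)
    atoms = tuple(
        Atom(name, element_of(name), tuple(R @ np.asarray(xyz) + ca))
        for name, xyz in residue_template(aa).items()
    )
    return Residue(aa=aa, chain_id=chain, seq_pos=seq_pos, atoms=atoms)


def build_site(
    types: list[str],
    site_id: str = "S1",
    ec: str | None = "1.1.1.1",
    superfamily: str | None = "a.1.1",
    rng: np.random.Generator | None = None,
    spread: float = 7.0,
) -> CatalyticSite:
    """A site with the given residue types at spread-out random positions."""
    rng = rng or np.random.default_rng(0)
    residues = []
    for k, aa in enumerate(types):
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        ca = rng.normal(scale=spread, size=3)
        residues.append(build_residue(aa, seq_pos=10 + k, rotation=q, ca=ca))
    return CatalyticSite(site_id=site_id, struct_id=site_id, residues=residues,
                         ec=ec, superfamily=superfamily)


def random_rigid_motion(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.uniform(-15, 15, size=3)


def transform_site(site: CatalyticSite, R: np.ndarray, t: np.ndarray,
                   site_id: str | None = None) -> CatalyticSite:
    residues = []
    for res in site.residues:
        atoms = tuple(
            Atom(a.name, a.element, tuple(R @ np.asarray(a.position) + t))
            for a in res.atoms
        )
        residues.append(Residue(aa=res.aa, chain_id=res.chain_id,
                                seq_pos=res.seq_pos, icode=res.icode,
                                atoms=atoms, canonical=res.canonical))
    return CatalyticSite(site_id=site_id or site.site_id + "_moved",
                         struct_id=site.struct_id, residues=residues,
                         ec=site.ec, superfamily=site.superfamily, go=site.go)


@pytest.fixture
def two_residue_pdb(tmp_path):
    """Minimal two-residue PDB file with known coordinates."""
    text = """\
ATOM      1  N   SER A  10       1.000   2.000   3.000  1.00 10.00           N
ATOM      2  CA  SER A  10       2.000   2.500   3.500  1.00 10.00           C
ATOM      3  C   SER A  10       3.000   2.000   4.000  1.00 10.00           C
ATOM      4  O   SER A  10       3.500   1.000   4.000  1.00 10.00           O
ATOM      5  CB  SER A  10       2.200   4.000   3.700  1.00 10.00           C
ATOM      6  OG  SER A  10       2.500   4.500   5.000  1.00 10.00           O
ATOM      7  N   HIS A  11       5.000   5.000   5.000  1.00 10.00           N
ATOM      8  CA  HIS A  11       6.000   5.500   5.500  1.00 10.00           C
ATOM      9  C   HIS A  11       7.000   5.000   6.000  1.00 10.00           C
ATOM     10  O   HIS A  11       7.500   4.000   6.000  1.00 10.00           O
ATOM     11  CB  HIS A  11       6.200   7.000   5.700  1.00 10.00           C
END
"""
    path = tmp_path / "mini.pdb"
    path.write_text(text)
    return path
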