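"""Domain model for catalytic sites and readers for the standard formats.

A catalytic site is the small set of residues (typically 2-10) of one enzyme
directly engaged in catalysis; its 3D arrangement is the *pose*. Sites carry
the labels the downstream analysis needs: an EC number, a SCOP superfamily
(the homology criterion) and optionally GO term sets.

Coordinates are read from PDB-format files (first model only) via gemmi;
site definitions, SCOP assignments and EC numbers come from plain TSV
tables, and curated site collections round-trip through a JSON interchange.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import gemmi
import numpy as np

from .chemistry import CANONICAL_AA, element_of

__all__ = [
    "Atom",
    "Residue",
    "CatalyticSite",
    "EnzymeFunctionRecord",
    "Inconsistency",
    "read_structure",
    "load_site_definitions",
    "load_scop_table",
    "load_ec_table",
    "sites_to_json",
    "sites_from_json",
    "superfamily_from_sccs",
    "is_full_ec",
]


@dataclass(frozen=True)
class Atom:
    """One heavy atom: PDB atom name, element symbol and position in A."""

    name: str
    element: str
    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")


@dataclass(frozen=True)
class Residue:
    """An amino-acid residue with its heavy atoms.

    ``seq_pos`` is the author residue number as printed in the coordinate
    file; an insertion code, if any, is kept in ``icode`` and forms part of
    the residue's identity. ``canonical`` is False for non-standard residues
    (e.g. selenomethionine), which are retained by the reader but excluded
    during curation.
    """

    aa: str
    chain_id: str
    seq_pos: int
    atoms: tuple[Atom, ...]
    icode: str = ""
    canonical: bool = True

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate atom names in residue {self.label}")

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.seq_pos}{self.icode}"

    @property
    def atom_map(self) -> dict[str, Atom]:
        return {a.name: a for a in self.atoms}

    def coord(self, atom_name: str) -> np.ndarray:
        return np.asarray(self.atom_map[atom_name].position, dtype=float)

    def has_atom(self, atom_name: str) -> bool:
        return any(a.name == atom_name for a in self.atoms)


@dataclass
class CatalyticSite:
    """A catalytic site: residues with coordinates plus function labels.

    ``go`` maps a namespace abbreviation (``MF``, ``BP``, ``CC``) to a set
    of GO term identifiers.
    """

    site_id: str
    struct_id: str
    residues: list[Residue]
    ec: str | None = None
    superfamily: str | None = None
    go: dict[str, set[str]] | None = None

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def chain_ids(self) -> set[str]:
        return {r.chain_id for r in self.residues}

    @property
    def ec_class(self) -> str | None:
        """First EC field (reaction class 1-6), or None without an EC."""
        return self.ec.split(".")[0] if self.ec else None

    def ca_coords(self) -> np.ndarray:
        return np.stack([r.coord("CA") for r in self.residues])


@dataclass(frozen=True)
class EnzymeFunctionRecord:
    """Census input: one enzyme with its domain count, ECs and superfamily."""

    enzyme_id: str
    domain_count: int
    ec_numbers: tuple[str, ...]
    superfamily: str

    def __post_init__(self) -> None:
        if self.domain_count < 1:
            raise ValueError("domain_count must be >= 1")


@dataclass(frozen=True)
class Inconsistency:
    """A disagreement between a site table row and the coordinate file."""

    site_id: str
    chain_id: str
    seq_pos: str
    expected_aa: str
    found_aa: str | None
    reason: str


def is_full_ec(ec: str) -> bool:
    """True for a syntactically full four-field EC number (digits only)."""
    fields = ec.split(".")
    return len(fields) == 4 and all(f.isdigit() for f in fields)


def superfamily_from_sccs(sccs: str) -> str:
    """SCOP superfamily = first three dot-fields of an sccs code.

    >>> superfamily_from_sccs("c.1.8.1")
    'c.1.8'
    """
    fields = sccs.split(".")
    if len(fields) < 3 or not fields[0].isalpha() or not all(
        f.isdigit() for f in fields[1:3]
    ):
        raise ValueError(f"malformed sccs identifier: {sccs!r}")
    return ".".join(fields[:3])


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def read_structure(path: str | Path) -> dict[tuple[str, str], Residue]:
    """Read a PDB file into residues keyed by ``(chain_id, seq_label)``.

    ``seq_label`` is the author residue number with any insertion code
    appended (CSA-style author numbering). Only the first model is used;
    hydrogens are dropped; of multiple alternate locations only the
    highest-occupancy one is kept, ties breaking toward altloc 'A'.
    Waters are skipped; non-standard residues are kept but flagged
    ``canonical=False``.
    """
    try:
        structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, OSError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(structure) == 0:
        raise ValueError(f"no models in {path}")
    model = structure[0]
    out: dict[tuple[str, str], Residue] = {}
    for chain in model:
        for res in chain:
            if res.is_water():
                continue
            atoms: dict[str, Atom] = {}
            best_occ: dict[str, tuple[float, str]] = {}
            for at in res:
                if at.is_hydrogen():
                    continue
                # keep highest occupancy; ties toward the earlier altloc
                # so that 'A' beats 'B' and a blank altloc beats both
                key = (at.occ, "" if at.altloc == "\0" else at.altloc)
                prev = best_occ.get(at.name)
                if prev is None or key[0] > prev[0] or (
                    key[0] == prev[0] and key[1] < prev[1]
                ):
                    best_occ[at.name] = key
                    atoms[at.name] = Atom(
                        name=at.name,
                        element=at.element.name or element_of(at.name),
                        position=(at.pos.x, at.pos.y, at.pos.z),
                    )
            if not atoms:
                continue
            name = res.name.upper()
            seqid = res.seqid
            icode = seqid.icode.strip()
            out[(chain.name, f"{seqid.num}{icode}")] = Residue(
                aa=name,
                chain_id=chain.name,
                seq_pos=seqid.num,
                icode=icode,
                atoms=tuple(atoms.values()),
                canonical=name in CANONICAL_AA,
            )
    return out


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def load_site_definitions(
    table_path: str | Path,
    structures: Mapping[str, Mapping[tuple[str, str], Residue]],
) -> tuple[list[CatalyticSite], list[Inconsistency]]:
    """Resolve a CSA-style site table against loaded structures.

    The table is tab-separated with columns
    ``site_id  struct_id  chain  seq_pos  residue_type``.
    Returns the assembled sites plus an inconsistency record for every row
    whose residue cannot be found or whose residue type disagrees with the
    structure; inconsistent sites are still returned (with the residues that
    did resolve) so the curation stage can exclude and log them.
    """
    rows: list[tuple[str, str, str, str, str]] = []
    with open(table_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "site_id":
                continue
            if len(parts) != 5:
                raise ValueError(f"bad site-table row: {line!r}")
            rows.append(tuple(parts))  # type: ignore[arg-type]

    sites: dict[str, CatalyticSite] = {}
    problems: list[Inconsistency] = []
    for site_id, struct_id, chain, seq_pos, aa in rows:
        site = sites.setdefault(site_id, CatalyticSite(site_id, struct_id, []))
        aa = aa.upper()
        residue = structures.get(struct_id, {}).get((chain, seq_pos))
        if residue is None:
            problems.append(Inconsistency(site_id, chain, seq_pos, aa, None,
                                          "residue not found in structure"))
            continue
        if residue.aa != aa:
            problems.append(Inconsistency(site_id, chain, seq_pos, aa, residue.aa,
                                          "residue type disagrees with structure"))
            continue
        if not residue.has_atom("CA"):
            problems.append(Inconsistency(site_id, chain, seq_pos, aa, residue.aa,
                                          "missing CA atom"))
            continue
        site.residues.append(residue)
    return list(sites.values()), problems


def load_scop_table(path: str | Path) -> dict[tuple[str, str], str]:
    """Read a SCOP-style TSV ``struct_id  chain  sccs`` into superfamilies.

    The superfamily is the three-field sccs prefix (e.g. ``c.1.8``);
    malformed sccs codes are skipped.
    """
    out: dict[tuple[str, str], str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "struct_id":
                continue
            struct_id, chain, sccs = parts[:3]
            try:
                out[(struct_id, chain)] = superfamily_from_sccs(sccs)
            except ValueError:
                continue
    return out


def load_ec_table(path: str | Path) -> dict[str, list[str]]:
    """Read an EC assignment TSV ``struct_id  ec`` (one row per EC)."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "struct_id":
                continue
            struct_id, ec = parts[:2]
            out.setdefault(struct_id, []).append(ec)
    return out


# ---------------------------------------------------------------------------
# JSON interchange
# ---------------------------------------------------------------------------

def _site_to_dict(site: CatalyticSite) -> dict:
    d = {
        "site_id": site.site_id,
        "struct_id": site.struct_id,
        "ec": site.ec,
        "superfamily": site.superfamily,
        "go": {ns: sorted(terms) for ns, terms in site.go.items()} if site.go else None,
        "residues": [
            {
                "aa": r.aa,
                "chain_id": r.chain_id,
                "seq_pos": r.seq_pos,
                "icode": r.icode,
                "canonical": r.canonical,
                "atoms": [
                    {"name": a.name, "element": a.element, "position": list(a.position)}
                    for a in r.atoms
                ],
            }
            for r in site.residues
        ],
    }
    return d


def _site_from_dict(d: dict) -> CatalyticSite:
    residues = [
        Residue(
            aa=r["aa"],
            chain_id=r["chain_id"],
            seq_pos=r["seq_pos"],
            icode=r.get("icode", ""),
            canonical=r.get("canonical", True),
            atoms=tuple(
                Atom(a["name"], a["element"], tuple(a["position"])) for a in r["atoms"]
            ),
        )
        for r in d["residues"]
    ]
    go = d.get("go")
    return CatalyticSite(
        site_id=d["site_id"],
        struct_id=d["struct_id"],
        residues=residues,
        ec=d.get("ec"),
        superfamily=d.get("superfamily"),
        go={ns: set(terms) for ns, terms in go.items()} if go else None,
    )


def sites_to_json(sites: Iterable[CatalyticSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([_site_to_dict(s) for s in sites], fh, indent=1)


def sites_from_json(path: str | Path) -> list[CatalyticSite]:
    with open(path) as fh:
        return [_site_from_dict(d) for d in json.load(fh)]
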