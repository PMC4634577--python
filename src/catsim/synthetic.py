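"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates a curated catalytic-site collection: families of
isofunctional sites derived from a template pose by rigid motion plus
isotropic Gaussian coordinate noise, residue types drawn from the 11 polar
and charged amino acids that dominate real catalytic sites (with occasional
hydrophobics), site sizes between 2 and 10 residues with a small-site-heavy
distribution (mean ~3.4), SCOP-style superfamily labels with a configurable
fraction of functions planted in two superfamilies (synthetic NISE), EC
numbers per family, and GO term sets drawn from small synthetic DAGs where
molecular-function and biological-process terms track function while
cellular-component terms are assigned at random (so including CC must
dilute a GO-based classification).

Everything derives from a single integer seed; a fixed seed gives
byte-identical output. The same structures can be written out in the file
formats the real pipeline reads (PDB, TSV tables, OBO, GAF).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import gemmi
import networkx as nx
import numpy as np

from .chemistry import (
    HYDROPHOBIC_EXTRAS,
    element_of,
    residue_template,
)
from .go_sim import NAMESPACES, OntologyGraph
from .io_model import Atom, CatalyticSite, EnzymeFunctionRecord, Residue

__all__ = [
    "SyntheticConfig",
    "make_sites",
    "make_ontology",
    "make_census_table",
    "write_fixture_files",
]

# Site-size distribution over 2..10 residues, small-site-heavy (mean ~3.4,
# ~30 % of sites at the two-residue minimum).
_SIZE_WEIGHTS = {2: 0.30, 3: 0.34, 4: 0.20, 5: 0.08, 6: 0.04,
                 7: 0.016, 8: 0.010, 9: 0.008, 10: 0.006}

# Catalytic propensities for the polar/charged pool: His, Asp, Glu and Ser
# dominate real catalytic sites, and the residue combinations in use across
# unrelated enzymes are strictly limited, so types repeat across families.
_TYPE_WEIGHTS = {"HIS": 0.24, "ASP": 0.18, "GLU": 0.15, "SER": 0.12,
                 "ARG": 0.08, "LYS": 0.08, "THR": 0.05, "TYR": 0.04,
                 "CYS": 0.03, "ASN": 0.02, "GLN": 0.01}

_SUBSTITUTIONS = {"TYR": "PHE", "PHE": "TYR", "ILE": "VAL", "VAL": "ILE"}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator; one seed drives all sampling."""

    seed: int = 0
    n_families: int = 10
    sites_per_family: int = 5
    site_size_range: tuple[int, int] = (2, 10)
    noise_sigma: float = 0.3           # A, isotropic per-coordinate
    multi_superfamily_fraction: float = 0.11  # functions planted in >= 2 SFs
    substitution_rate: float = 0.05    # Y<->F / I<->V swaps per residue
    hydrophobic_rate: float = 0.1      # non-polar residues in the type pool
    annotation_depth: int = 3          # levels below each namespace root
    n_census_functions: int = 500
    census_one_superfamily_fraction: float = 0.89

    def __post_init__(self) -> None:
        lo, hi = self.site_size_range
        if not (2 <= lo <= hi <= 10):
            raise ValueError("site_size_range must lie within [2, 10]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for name in ("multi_superfamily_fraction", "substitution_rate",
                     "hydrophobic_rate", "census_one_superfamily_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be within [0, 1]")
        if self.multi_superfamily_fraction > 0 and self.sites_per_family < 2:
            raise ValueError(
                "planting a function in two superfamilies needs at least "
                "two sites per family")


def _rand_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _sample_sizes(rng: np.random.Generator, n: int, lo: int, hi: int) -> np.ndarray:
    sizes = np.array([k for k in _SIZE_WEIGHTS if lo <= k <= hi])
    w = np.array([_SIZE_WEIGHTS[k] for k in sizes])
    return rng.choice(sizes, size=n, p=w / w.sum())


def _sample_ca_positions(rng: np.random.Generator, k: int) -> np.ndarray:
    """k C-alpha positions in a 6 A sphere, pairwise 3-12 A apart."""
    for _ in range(1000):
        pts: list[np.ndarray] = []
        tries = 0
        while len(pts) < k and tries < 2000:
            tries += 1
            p = rng.normal(size=3)
            p *= 6.0 * rng.random() ** (1 / 3) / np.linalg.norm(p)
            if all(3.0 <= np.linalg.norm(p - q) for q in pts):
                pts.append(p)
        if len(pts) == k:
            return np.stack(pts)
    raise RuntimeError(f"could not place {k} C-alpha positions")


def _build_residue(aa: str, chain: str, seq_pos: int,
                   frame: np.ndarray, ca: np.ndarray) -> Residue:
    tmpl = residue_template(aa)
    atoms = tuple(
        Atom(name=name, element=element_of(name),
             position=tuple(frame @ np.asarray(xyz) + ca))
        for name, xyz in tmpl.items()
    )
    return Residue(aa=aa, chain_id=chain, seq_pos=seq_pos, atoms=atoms)


@dataclass
class _FamilyTemplate:
    types: list[str]
    frames: list[np.ndarray]   # per-residue orientation
    ca: np.ndarray             # (k, 3)


def make_sites(
    config: SyntheticConfig,
    ontology_bundle: tuple[OntologyGraph, dict[int, dict[str, set[str]]]] | None = None,
) -> tuple[list[CatalyticSite], dict[str, int]]:
    """Generate site families; returns the sites and site_id -> family truth.

    Each family shares one full EC number (families cycle through the six
    EC classes) and, unless planted as a synthetic NISE case, one
    superfamily. If an ontology bundle from :func:`make_ontology` is given,
    GO annotations are attached (MF/BP per function, CC per enzyme).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.site_size_range
    sizes = _sample_sizes(rng, config.n_families, lo, hi)
    n_multi = int(round(config.multi_superfamily_fraction * config.n_families))
    multi_sf = set(rng.choice(config.n_families, size=n_multi, replace=False).tolist())

    graph_and_annos = ontology_bundle
    sites: list[CatalyticSite] = []
    truth: dict[str, int] = {}
    for fam in range(config.n_families):
        k = int(sizes[fam])
        pool = list(_TYPE_WEIGHTS)
        weights = np.array([_TYPE_WEIGHTS[a] for a in pool])
        weights /= weights.sum()
        is_extra = rng.random(k) < config.hydrophobic_rate
        types = [
            str(rng.choice(HYDROPHOBIC_EXTRAS)) if extra
            else str(rng.choice(pool, p=weights))
            for extra in is_extra
        ]
        template = _FamilyTemplate(
            types=types,
            frames=[_rand_rotation(rng) for _ in range(k)],
            ca=_sample_ca_positions(rng, k),
        )
        ec_class = fam % 6 + 1
        ec = f"{ec_class}.{fam // 6 + 1}.1.{fam + 1}"
        superfamilies = [f"a.{fam + 1}.1"]
        if fam in multi_sf:
            superfamilies.append(f"b.{fam + 1}.1")
        for member in range(config.sites_per_family):
            site_id = f"F{fam:03d}S{member:02d}"
            member_types = []
            for aa in template.types:
                if aa in _SUBSTITUTIONS and rng.random() < config.substitution_rate:
                    member_types.append(_SUBSTITUTIONS[aa])
                else:
                    member_types.append(aa)
            Rg = _rand_rotation(rng)
            tg = rng.uniform(-20.0, 20.0, size=3)
            residues = []
            for r in range(k):
                res = _build_residue(member_types[r], "A", 10 + r,
                                     template.frames[r], template.ca[r])
                coords = np.array([a.position for a in res.atoms])
                coords = coords @ Rg.T + tg
                if config.noise_sigma > 0:
                    coords = coords + rng.normal(
                        scale=config.noise_sigma, size=coords.shape)
                residues.append(Residue(
                    aa=res.aa, chain_id=res.chain_id, seq_pos=res.seq_pos,
                    atoms=tuple(
                        Atom(a.name, a.element, tuple(xyz))
                        for a, xyz in zip(res.atoms, coords)
                    ),
                ))
            sf = superfamilies[member % len(superfamilies)]
            go = None
            if graph_and_annos is not None:
                _, per_function = graph_and_annos
                anno = {ns: set(terms) for ns, terms
                        in per_function[fam % len(per_function)].items()}
                site_go = {ns: set(t) for ns, t in anno.items() if ns != "CC"}
                cc_pool = sorted(anno.get("CC", set()))
                if cc_pool:
                    site_go["CC"] = {cc_pool[int(rng.integers(len(cc_pool)))]}
                go = site_go
            site = CatalyticSite(
                site_id=site_id, struct_id=site_id, residues=residues,
                ec=ec, superfamily=sf, go=go,
            )
            sites.append(site)
            truth[site_id] = fam
    return sites, truth


def make_ontology(
    config: SyntheticConfig,
) -> tuple[OntologyGraph, dict[int, dict[str, set[str]]]]:
    """Small rooted DAGs for MF/BP/CC plus per-function annotations.

    Each namespace is a binary is_a tree of the configured depth (CC also
    carries a few part_of edges), with at least one leaf per function.
    Function f is annotated with one MF and one BP leaf (shared by all
    enzymes of that function); the CC annotation offers the whole leaf pool
    and is sampled per enzyme by :func:`make_sites`, independent of
    function.
    """
    depth = max(config.annotation_depth,
                math.ceil(math.log2(max(config.n_families, 2))))
    graph = nx.MultiDiGraph()
    leaves: dict[str, list[str]] = {}
    for idx, (abbrev, namespace) in enumerate(sorted(NAMESPACES.items())):
        n_nodes = 2 ** (depth + 1) - 1

        def term_id(i: int) -> str:
            return f"GO:{idx + 1:02d}{i:05d}"

        for i in range(n_nodes):
            graph.add_node(term_id(i), namespace=namespace,
                           name=f"{abbrev.lower()} term {i}")
        for i in range(1, n_nodes):
            rel = "part_of" if abbrev == "CC" and i % 5 == 0 else "is_a"
            graph.add_edge(term_id(i), term_id((i - 1) // 2), key=rel)
        first_leaf = 2 ** depth - 1
        leaves[abbrev] = [term_id(i) for i in range(first_leaf, n_nodes)]

    per_function: dict[int, dict[str, set[str]]] = {}
    for fam in range(config.n_families):
        per_function[fam] = {
            "MF": {leaves["MF"][fam % len(leaves["MF"])]},
            "BP": {leaves["BP"][fam % len(leaves["BP"])]},
            "CC": set(leaves["CC"]),  # pool; one is drawn per enzyme
        }
    return OntologyGraph(graph), per_function


def make_census_table(config: SyntheticConfig) -> tuple[list[EnzymeFunctionRecord], float]:
    """Enzyme records with a planted one-superfamily fraction.

    Returns the records and the exact planted fraction of functions whose
    enzymes all share one superfamily (the quantity the census recovers).
    """
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_census_functions
    n_multi = int(round((1.0 - config.census_one_superfamily_fraction) * n))
    multi = set(rng.choice(n, size=n_multi, replace=False).tolist())
    records: list[EnzymeFunctionRecord] = []
    for f in range(n):
        ec = f"{f % 6 + 1}.{f % 9 + 1}.{f % 7 + 1}.{f + 1}"
        n_sf = int(rng.integers(2, 7)) if f in multi else 1
        n_enzymes = max(n_sf, int(rng.integers(1, 20)))
        sfs = [f"c.{f + 1}.{s + 1}" for s in range(n_sf)]
        for e in range(n_enzymes):
            records.append(EnzymeFunctionRecord(
                enzyme_id=f"ENZ{f:04d}_{e:02d}",
                domain_count=1,
                ec_numbers=(ec,),
                superfamily=sfs[e % n_sf],
            ))
    planted_one = 1.0 - len(multi) / n
    return records, planted_one


# ---------------------------------------------------------------------------
# Fixture file emission (same formats the real pipeline reads)
# ---------------------------------------------------------------------------

def _site_to_pdb(site: CatalyticSite, path: Path) -> None:
    structure = gemmi.Structure()
    structure.name = site.struct_id
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for res in site.residues:
        g_res = gemmi.Residue()
        g_res.name = res.aa
        g_res.seqid = gemmi.SeqId(res.seq_pos, res.icode or " ")
        for atom in res.atoms:
            g_at = gemmi.Atom()
            g_at.name = atom.name
            g_at.element = gemmi.Element(atom.element)
            g_at.pos = gemmi.Position(*atom.position)
            g_at.occ = 1.0
            g_res.add_atom(g_at)
        chain.add_residue(g_res)
    model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))


def write_fixture_files(
    sites: list[CatalyticSite],
    outdir: str | Path,
    ontology: OntologyGraph | None = None,
) -> dict[str, Path]:
    """Emit PDB / site TSV / SCOP TSV / EC TSV (and OBO + GAF) fixtures."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pdb_dir = outdir / "pdb"
    pdb_dir.mkdir(exist_ok=True)
    paths: dict[str, Path] = {}
    for site in sites:
        _site_to_pdb(site, pdb_dir / f"{site.struct_id}.pdb")
    paths["pdb_dir"] = pdb_dir

    site_tsv = outdir / "sites.tsv"
    with open(site_tsv, "w") as fh:
        fh.write("site_id\tstruct_id\tchain\tseq_pos\tresidue_type\n")
        for site in sites:
            for res in site.residues:
                fh.write(f"{site.site_id}\t{site.struct_id}\t{res.chain_id}"
                         f"\t{res.seq_pos}{res.icode}\t{res.aa}\n")
    paths["sites"] = site_tsv

    scop_tsv = outdir / "scop.tsv"
    with open(scop_tsv, "w") as fh:
        fh.write("struct_id\tchain\tsccs\n")
        for site in sites:
            if site.superfamily:
                for chain in sorted(site.chain_ids):
                    fh.write(f"{site.struct_id}\t{chain}\t{site.superfamily}.1\n")
    paths["scop"] = scop_tsv

    ec_tsv = outdir / "ec.tsv"
    with open(ec_tsv, "w") as fh:
        fh.write("struct_id\tec\n")
        for site in sites:
            if site.ec:
                fh.write(f"{site.struct_id}\t{site.ec}\n")
    paths["ec"] = ec_tsv

    if ontology is not None:
        obo = outdir / "ontology.obo"
        _write_obo(ontology, obo)
        paths["obo"] = obo
        gaf = outdir / "annotations.gaf"
        _write_gaf(sites, gaf)
        paths["gaf"] = gaf
    return paths


def _write_obo(ontology: OntologyGraph, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n\n")
        for node in sorted(ontology.graph.nodes):
            data = ontology.graph.nodes[node]
            fh.write("[Term]\n")
            fh.write(f"id: {node}\n")
            fh.write(f"name: {data.get('name', node)}\n")
            fh.write(f"namespace: {data['namespace']}\n")
            for _, parent, rel in sorted(ontology.graph.out_edges(node, keys=True)):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")
            fh.write("\n")


def _write_gaf(sites: list[CatalyticSite], path: Path) -> None:
    aspect = {"MF": "F", "BP": "P", "CC": "C"}
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for site in sites:
            if not site.go:
                continue
            for ns, terms in sorted(site.go.items()):
                for term in sorted(terms):
                    cols = ["SYN", site.struct_id, site.struct_id, "",
                            term, "SYN:0000", "IEA", "", aspect[ns],
                            "", "", "protein", "taxon:0", "20140101",
                            "SYN", "", ""]
                    fh.write("\t".join(cols) + "\n")
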