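"""Normalized GO term-set similarity between two enzymes.

The score S_GO(G_i, G_j) in [0, 1] compares the sets of GO terms annotated
to two enzymes, restricted to a chosen subset of the three annotation
domains (molecular function MF, biological process BP, cellular component
CC). It is topology-only: term-term similarity depends solely on the
ontology graph, never on term frequencies in a corpus, so the score is
independent of the data set under study.

Term-term similarity follows the Wang graph-based measure: each term t
induces S-values over its ancestor DAG (S_t(t) = 1, and walking an edge
multiplies by a relation weight: 0.8 for is_a, 0.6 for part_of, taking the
maximum over paths); the similarity of two terms is the summed S-values of
their common ancestors normalized by their total semantic values. Term sets
are aggregated by the symmetric best-match average per namespace, and the
per-namespace scores of the selected domains are averaged.
"""

from __future__ import annotations

from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

__all__ = [
    "NAMESPACES",
    "OntologyGraph",
    "load_obo",
    "load_gaf",
    "term_similarity",
    "set_similarity",
    "EDGE_WEIGHTS",
]

#: namespace abbreviation -> OBO namespace name
NAMESPACES: dict[str, str] = {
    "MF": "molecular_function",
    "BP": "biological_process",
    "CC": "cellular_component",
}
_ABBREV = {v: k for k, v in NAMESPACES.items()}

EDGE_WEIGHTS: dict[str, float] = {"is_a": 0.8, "part_of": 0.6}


class OntologyGraph:
    """A GO-style ontology: DAG with is_a / part_of edges toward the roots."""

    def __init__(self, graph: nx.MultiDiGraph):
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("ontology graph must be acyclic")
        self.graph = graph
        self.alt_ids: dict[str, str] = {}
        for node, data in graph.nodes(data=True):
            for alt in data.get("alt_id", []):
                self.alt_ids[alt] = node
        self._svalues_cached = lru_cache(maxsize=None)(self._svalues)

    def resolve(self, term: str) -> str:
        """Map an alt_id to its primary id; error for unknown terms."""
        if term in self.graph:
            return term
        if term in self.alt_ids:
            return self.alt_ids[term]
        raise KeyError(f"unknown ontology term {term!r}")

    def namespace(self, term: str) -> str:
        ns = self.graph.nodes[self.resolve(term)].get("namespace")
        return _ABBREV.get(ns, ns)

    def _svalues(self, term: str) -> Mapping[str, float]:
        """Wang S-values of ``term`` over its ancestor DAG."""
        sv: dict[str, float] = {term: 1.0}
        # obonet edges run child -> parent keyed by relation
        frontier = [term]
        while frontier:
            nxt: list[str] = []
            for node in frontier:
                for _, parent, rel in self.graph.out_edges(node, keys=True):
                    w = EDGE_WEIGHTS.get(rel)
                    if w is None:
                        continue
                    cand = sv[node] * w
                    if cand > sv.get(parent, 0.0):
                        sv[parent] = cand
                        nxt.append(parent)
            frontier = nxt
        return sv

    def svalues(self, term: str) -> Mapping[str, float]:
        return self._svalues_cached(self.resolve(term))


def load_obo(path: str | Path) -> OntologyGraph:
    """Read an OBO 1.2 ontology; obsolete terms are dropped by the reader."""
    graph = obonet.read_obo(str(path))
    return OntologyGraph(graph)


def load_gaf(path: str | Path, ontology: OntologyGraph) -> dict[str, dict[str, set[str]]]:
    """Read a GAF 2.x annotation file into per-object, per-namespace term sets.

    Unknown terms raise; alt_ids resolve to their primary term.
    """
    out: dict[str, dict[str, set[str]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            obj_id, term = cols[1], cols[4]
            term = ontology.resolve(term)
            ns = ontology.namespace(term)
            out.setdefault(obj_id, {}).setdefault(ns, set()).add(term)
    return out


def term_similarity(t1: str, t2: str, ontology: OntologyGraph) -> float:
    """Wang similarity of two terms; 1 iff identical, 0 across namespaces."""
    t1, t2 = ontology.resolve(t1), ontology.resolve(t2)
    if ontology.namespace(t1) != ontology.namespace(t2):
        return 0.0
    if t1 == t2:
        return 1.0
    sv1, sv2 = ontology.svalues(t1), ontology.svalues(t2)
    common = set(sv1) & set(sv2)
    if not common:
        return 0.0
    num = sum(sv1[a] + sv2[a] for a in common)
    den = sum(sv1.values()) + sum(sv2.values())
    return num / den


def _best_match_average(
    terms_i: Iterable[str], terms_j: Iterable[str], ontology: OntologyGraph
) -> float:
    ti, tj = list(terms_i), list(terms_j)
    sim = [[term_similarity(a, b, ontology) for b in tj] for a in ti]
    row_best = sum(max(row) for row in sim)
    col_best = sum(max(sim[r][c] for r in range(len(ti))) for c in range(len(tj)))
    return (row_best + col_best) / (len(ti) + len(tj))


def set_similarity(
    gi: Mapping[str, set[str]],
    gj: Mapping[str, set[str]],
    domains: Iterable[str],
    ontology: OntologyGraph,
) -> float | None:
    """S_GO between two annotation sets over selected domains, or None.

    ``gi``/``gj`` map namespace abbreviations (MF/BP/CC) to term sets;
    ``domains`` restricts which namespaces are compared. Namespaces with
    terms in both annotations contribute a best-match-average score; these
    are averaged. Returns None (undefined) when no selected namespace has
    terms on both sides — such pairs are excluded from evaluation.
    """
    selected = sorted(set(domains))
    bad = [d for d in selected if d not in NAMESPACES]
    if bad:
        raise ValueError(f"unknown GO domains: {bad}")
    parts: list[float] = []
    for ns in selected:
        ti, tj = gi.get(ns) or set(), gj.get(ns) or set()
        if ti and tj:
            parts.append(_best_match_average(ti, tj, ontology))
    if not parts:
        return None
    return sum(parts) / len(parts)
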