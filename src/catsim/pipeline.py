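"""Glue: run all-vs-all site comparisons and feed the evaluation protocols."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .evaluation import ScoredCandidate
from .go_sim import OntologyGraph, set_similarity
from .io_model import CatalyticSite
from .superposer import (
    EQUI_NONE,
    EquivalenceRules,
    MatchBudgetExceeded,
    Representation,
    compare_sites,
)

__all__ = ["all_vs_all", "sgo_matrix"]


def sgo_matrix(
    sites: Sequence[CatalyticSite],
    ontology: OntologyGraph,
    domains: Iterable[str],
) -> dict[tuple[str, str], float | None]:
    """Pairwise S_GO for every unordered site pair with annotations."""
    domains = sorted(set(domains))
    out: dict[tuple[str, str], float | None] = {}
    for i, a in enumerate(sites):
        for b in sites[i + 1:]:
            if a.go is None or b.go is None:
                value = None
            else:
                value = set_similarity(a.go, b.go, domains, ontology)
            out[(a.site_id, b.site_id)] = value
            out[(b.site_id, a.site_id)] = value
    return out


def all_vs_all(
    sites: Sequence[CatalyticSite],
    rep: Representation = Representation.ALL_ATOM,
    rules: EquivalenceRules = EQUI_NONE,
    rmsd_cutoff: float = 1.0,
    score_name: str = "rmsd_n2",
    sgo: Mapping[tuple[str, str], float | None] | None = None,
    skip_budget_exceeded: bool = False,
) -> dict[str, list[ScoredCandidate]]:
    """Compare every site with every other; queries map to scored candidates.

    Pairs without any match under the cutoff contribute no candidate. The
    optional ``sgo`` matrix (from :func:`sgo_matrix`) attaches GO term-set
    similarities for GO-based agreement and best-of-k selection. With
    ``skip_budget_exceeded`` a pair whose match enumeration exceeds the
    combinatorial budget is treated as matchless instead of fatal.
    """
    comparisons: dict[str, list[ScoredCandidate]] = {s.site_id: [] for s in sites}
    for i, a in enumerate(sites):
        for b in sites[i + 1:]:
            try:
                cmp_ab = compare_sites(a, b, rep, rules, rmsd_cutoff, score_name)
            except MatchBudgetExceeded:
                if skip_budget_exceeded:
                    continue
                raise
            if cmp_ab.best_match is None:
                continue
            same_sf = (a.superfamily is not None and b.superfamily is not None
                       and a.superfamily == b.superfamily)
            go_value = sgo.get((a.site_id, b.site_id)) if sgo is not None else None
            ec_match = (a.ec_class is not None and a.ec_class == b.ec_class)
            score = float(cmp_ab.score_value)  # symmetric: reuse for both
            comparisons[a.site_id].append(ScoredCandidate(
                target_id=b.site_id, score=score, same_superfamily=same_sf,
                ec_class_match=ec_match, s_go=go_value))
            comparisons[b.site_id].append(ScoredCandidate(
                target_id=a.site_id, score=score, same_superfamily=same_sf,
                ec_class_match=ec_match, s_go=go_value))
    return comparisons
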