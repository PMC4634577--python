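"""Build an analysis-ready, redundancy-controlled catalytic-site set.

Raw site collections mix entries a pose comparison cannot use: one-residue
sites (any two single side chains superpose almost perfectly), sites with
non-canonical residues, sites spread over several chains, enzymes without a
(unique) EC number, sites without a SCOP superfamily (no homology call
possible) and sites whose annotation disagrees with the coordinates. The
exclusion cascade removes these in a fixed order, logging each dropped site
under the first rule it violates so the audit is disjoint and conserving.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_model import CatalyticSite, is_full_ec

__all__ = ["ExclusionLog", "Annotations", "curate", "site_statistics", "EXCLUSION_REASONS"]

# Order matters: a site is logged under the first rule it violates.
EXCLUSION_REASONS: tuple[str, ...] = (
    "single_residue",
    "non_canonical",
    "multi_chain",
    "no_ec",
    "multifunctional",
    "no_scop",
    "inconsistent",
)


@dataclass
class ExclusionLog:
    """Per-reason tallies of excluded sites; reasons are disjoint."""

    excluded: dict[str, list[str]] = field(
        default_factory=lambda: {r: [] for r in EXCLUSION_REASONS}
    )

    def add(self, reason: str, site_id: str) -> None:
        self.excluded[reason].append(site_id)

    @property
    def counts(self) -> dict[str, int]:
        return {r: len(ids) for r, ids in self.excluded.items()}

    @property
    def total_excluded(self) -> int:
        return sum(len(ids) for ids in self.excluded.values())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("reason\tcount\tsite_ids\n")
            for reason in EXCLUSION_REASONS:
                ids = self.excluded[reason]
                fh.write(f"{reason}\t{len(ids)}\t{','.join(ids)}\n")


@dataclass
class Annotations:
    """Side information consumed by :func:`curate`.

    ``ec`` maps struct_id to the list of EC numbers assigned to that enzyme
    (multiple entries mean a multifunctional enzyme); ``scop`` maps
    ``(struct_id, chain)`` to a superfamily identifier; ``inconsistent``
    holds site_ids flagged during structure resolution.
    """

    ec: Mapping[str, Sequence[str]] = field(default_factory=dict)
    scop: Mapping[tuple[str, str], str] = field(default_factory=dict)
    inconsistent: frozenset[str] = frozenset()


def _first_violation(site: CatalyticSite, ann: Annotations) -> str | None:
    if len(site.residues) <= 1:
        return "single_residue"
    if any(not r.canonical for r in site.residues):
        return "non_canonical"
    if len(site.chain_ids) > 1:
        return "multi_chain"
    ecs = [e for e in ann.ec.get(site.struct_id, []) if is_full_ec(e)]
    if site.ec and is_full_ec(site.ec) and not ecs:
        ecs = [site.ec]
    if not ecs:
        return "no_ec"
    if len(set(ecs)) > 1:
        return "multifunctional"
    chain = next(iter(site.chain_ids))
    sf = ann.scop.get((site.struct_id, chain), site.superfamily)
    if not sf:
        return "no_scop"
    if site.site_id in ann.inconsistent:
        return "inconsistent"
    return None


def curate(
    sites: Iterable[CatalyticSite],
    annotations: Annotations | None = None,
) -> tuple[list[CatalyticSite], ExclusionLog]:
    """Apply the exclusion cascade; annotate and return the retained sites.

    Filters, in order: (1) single-residue site, (2) any non-canonical
    residue, (3) residues on more than one chain, (4) no full EC number,
    (5) more than one EC number, (6) no SCOP superfamily, (7) flagged
    inconsistency. Each excluded site is logged once, under the first rule
    it violates; retained sites come back with their EC and superfamily
    labels filled in. Retained + excluded counts always sum to the input.
    """
    ann = annotations or Annotations()
    log = ExclusionLog()
    retained: list[CatalyticSite] = []
    for site in sites:
        reason = _first_violation(site, ann)
        if reason is not None:
            log.add(reason, site.site_id)
            continue
        ecs = [e for e in ann.ec.get(site.struct_id, []) if is_full_ec(e)]
        if ecs:
            site.ec = ecs[0]
        chain = next(iter(site.chain_ids))
        sf = ann.scop.get((site.struct_id, chain))
        if sf:
            site.superfamily = sf
        retained.append(site)
    return retained, log


def site_statistics(sites: Sequence[CatalyticSite]) -> dict:
    """Summary statistics of residue counts per site.

    Returns the mean (1 decimal), min, max, a residue-count histogram and
    the percentage of sites at the minimum count (1 decimal).
    """
    if not sites:
        raise ValueError("site statistics are undefined for an empty collection")
    counts = np.array([len(s) for s in sites])
    hist: dict[int, int] = {}
    for c in counts:
        hist[int(c)] = hist.get(int(c), 0) + 1
    cmin = int(counts.min())
    at_min = int((counts == cmin).sum())
    return {
        "n_sites": len(sites),
        "mean_residues": round(float(counts.mean()), 1),
        "min_residues": cmin,
        "max_residues": int(counts.max()),
        "histogram": dict(sorted(hist.items())),
        "fraction_at_min_pct": round(100.0 * at_min / len(sites), 1),
    }
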