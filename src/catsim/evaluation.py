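"""From all-vs-all pose comparisons to classification performance.

Two protocols are implemented. The *best-hit* protocol transfers function
from the single most similar site and scores TP (same EC class, first
digit) or FN (different class) — no threshold. The *thresholded* protocol
additionally applies a score cutoff cu_RMSD: a best hit below the cutoff is
a positive prediction (TP when the functions agree, else FP) and a hit at
or above it is a negative one (FN when the functions agree, else TN).
Function agreement is either identical first EC digits or a GO term-set
similarity S_GO at or above a cutoff cu_S_GO.

Performance is summarized by sensitivity TP/(TP+FN) and the Matthews
correlation coefficient; the optimal (cu_RMSD, cu_S_GO) pair is found by an
exhaustive grid search maximizing the MCC.

In DIFF_SF mode only candidates from a different SCOP superfamily than the
query are considered (likely non-homologs); in ALL mode every other site
competes. The best-of-k variant picks, among the k lowest-score hits, the
candidate with the highest S_GO to the query.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .io_model import CatalyticSite

__all__ = [
    "ConfusionCounts",
    "GridSearchResult",
    "EvaluationConfig",
    "Mode",
    "Agreement",
    "ident_supfam",
    "best_hit",
    "classify_best_hit",
    "classify_thresholded",
    "sensitivity",
    "mcc",
    "round_half_up",
    "grid_search",
    "best_hit_evaluation",
    "default_rmsd_grid",
    "default_sgo_grid",
]


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round half away from zero at the printed precision (report style)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionCounts:
    """TP/FP/TN/FN tallies; the total equals the classified query count."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def add(self, outcome: str) -> None:
        setattr(self, outcome.lower(), getattr(self, outcome.lower()) + 1)


def sensitivity(counts: ConfusionCounts) -> float | None:
    """TP / (TP + FN); None when no positives exist."""
    denom = counts.tp + counts.fn
    if denom == 0:
        return None
    return counts.tp / denom


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when a denominator factor is 0."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom = math.sqrt(
        float(tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    )
    if denom == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / denom


class Mode(str, Enum):
    DIFF_SF = "diff_sf"  # candidates restricted to other superfamilies
    ALL = "all"          # homologous candidates included


class Agreement(str, Enum):
    EC_CLASS = "ec_class"  # identical first EC digit
    GO = "go"              # S_GO >= cu_sgo


@dataclass
class EvaluationConfig:
    mode: Mode = Mode.DIFF_SF
    agreement: Agreement = Agreement.EC_CLASS
    score_name: str = "rmsd_n2"
    k: int = 1  # best-of-k: among k best poses, take the highest-S_GO one

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class GridSearchResult:
    cu_rmsd: float
    cu_sgo: float | None
    mcc: float
    counts: ConfusionCounts


def ident_supfam(a: CatalyticSite, b: CatalyticSite) -> bool:
    """True iff both sites' enzymes share a SCOP superfamily (homologs)."""
    if a.superfamily is None or b.superfamily is None:
        raise ValueError("both sites need superfamily labels")
    return a.superfamily == b.superfamily


# ---------------------------------------------------------------------------
# Best-hit selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoredCandidate:
    """One query->candidate comparison result feeding the protocols."""

    target_id: str
    score: float
    same_superfamily: bool
    ec_class_match: bool
    s_go: float | None  # None = undefined similarity


def best_hit(
    candidates: Sequence[ScoredCandidate],
    config: EvaluationConfig,
) -> ScoredCandidate | None:
    """The most similar admissible candidate, or None.

    DIFF_SF mode drops same-superfamily candidates first. With k > 1 the k
    lowest-score candidates are shortlisted and the one with the highest
    S_GO wins (undefined S_GO ranks lowest); ties break toward the better
    score, then the lexicographically smaller target id.
    """
    pool = [c for c in candidates
            if config.mode is Mode.ALL or not c.same_superfamily]
    if not pool:
        return None
    pool.sort(key=lambda c: (c.score, c.target_id))
    if config.k <= 1:
        return pool[0]
    shortlist = pool[: config.k]
    shortlist.sort(key=lambda c: (-(c.s_go if c.s_go is not None else -1.0),
                                  c.score, c.target_id))
    return shortlist[0]


def classify_best_hit(hit: ScoredCandidate) -> str:
    """Unthresholded protocol: TP iff the EC classes agree, else FN."""
    return "TP" if hit.ec_class_match else "FN"


def classify_thresholded(
    hit: ScoredCandidate,
    cu_rmsd: float,
    cu_sgo: float | None,
    agreement: Agreement,
) -> str | None:
    """Thresholded protocol: one of TP/FP/TN/FN, or None (query excluded).

    score < cu_rmsd is a positive prediction; agreement decides TP vs FP
    (and FN vs TN on the negative side). Under GO agreement a query whose
    S_GO to the hit is undefined cannot be judged and is excluded.
    """
    if agreement is Agreement.GO:
        if cu_sgo is None:
            raise ValueError("GO agreement requires cu_sgo")
        if hit.s_go is None:
            return None
        agree = hit.s_go >= cu_sgo
    else:
        agree = hit.ec_class_match
    if hit.score < cu_rmsd:
        return "TP" if agree else "FP"
    return "FN" if agree else "TN"


# ---------------------------------------------------------------------------
# Whole-collection protocols
# ---------------------------------------------------------------------------

def best_hit_evaluation(
    comparisons: Mapping[str, Sequence[ScoredCandidate]],
    config: EvaluationConfig,
) -> tuple[ConfusionCounts, int]:
    """Best-hit (unthresholded) protocol over all queries.

    Returns the TP/FN counts and the number of queries dropped for lack of
    an admissible candidate.
    """
    counts = ConfusionCounts()
    dropped = 0
    for query_id in sorted(comparisons):
        hit = best_hit(comparisons[query_id], config)
        if hit is None:
            dropped += 1
            continue
        counts.add(classify_best_hit(hit))
    return counts, dropped


def default_rmsd_grid() -> np.ndarray:
    """cu_RMSD grid 0.01..1.50 A, step 0.01 (spans all reported cutoffs)."""
    return np.round(np.arange(1, 151) * 0.01, 2)


def default_sgo_grid() -> np.ndarray:
    """cu_S_GO grid 0.50..1.00, step 0.01."""
    return np.round(np.arange(50, 101) * 0.01, 2)


def grid_search(
    comparisons: Mapping[str, Sequence[ScoredCandidate]],
    config: EvaluationConfig,
    rmsd_grid: Sequence[float] | None = None,
    sgo_grid: Sequence[float] | None = None,
) -> GridSearchResult:
    """MCC-maximizing exhaustive search over (cu_RMSD, cu_S_GO).

    Every query's best hit is fixed first (it does not depend on the
    cutoffs), then the confusion counts are tallied at every grid point.
    Ties break toward the smaller cu_RMSD, then the larger cu_S_GO.
    """
    rmsd_grid = np.asarray(
        default_rmsd_grid() if rmsd_grid is None else rmsd_grid, dtype=float)
    if rmsd_grid.size == 0:
        raise ValueError("empty cu_RMSD grid")
    use_go = config.agreement is Agreement.GO
    if use_go:
        sgo_grid = np.asarray(
            default_sgo_grid() if sgo_grid is None else sgo_grid, dtype=float)
        if sgo_grid.size == 0:
            raise ValueError("empty cu_S_GO grid")
    else:
        sgo_grid = np.asarray([np.nan])

    hits = []
    for query_id in sorted(comparisons):
        h = best_hit(comparisons[query_id], config)
        if h is None:
            continue
        if use_go and h.s_go is None:
            continue
        hits.append(h)
    scores = np.array([h.score for h in hits])
    if use_go:
        sgo = np.array([h.s_go for h in hits])
    else:
        agree_fixed = np.array([h.ec_class_match for h in hits])

    best: GridSearchResult | None = None
    for cu_sgo in sgo_grid:
        agree = (sgo >= cu_sgo) if use_go else agree_fixed
        for cu_rmsd in rmsd_grid:
            positive = scores < cu_rmsd
            tp = int(np.sum(positive & agree))
            fp = int(np.sum(positive & ~agree))
            fn = int(np.sum(~positive & agree))
            tn = int(np.sum(~positive & ~agree))
            counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
            val = mcc(counts)
            if best is None or val > best.mcc + 1e-12 or (
                abs(val - best.mcc) <= 1e-12
                and (cu_rmsd < best.cu_rmsd - 1e-12
                     or (abs(cu_rmsd - best.cu_rmsd) <= 1e-12 and use_go
                         and cu_sgo > (best.cu_sgo or -1) + 1e-12))
            ):
                best = GridSearchResult(
                    cu_rmsd=float(cu_rmsd),
                    cu_sgo=float(cu_sgo) if use_go else None,
                    mcc=val,
                    counts=counts,
                )
    assert best is not None
    return best
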