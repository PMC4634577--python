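"""Rigid-body comparison of catalytic-site poses.

Two sites are compared by enumerating residue correspondences (injective,
type-compatible mappings), optimally superposing the represented atoms of
every mapping with a proper rotation (Kabsch, via SVD) and keeping all
mappings whose residual RMSD falls below a cutoff. Four residue
representations are supported: the C-alpha atom alone, C-alpha plus C-beta,
C-alpha plus the side-chain centroid, and all heavy atoms.

Enumeration is exhaustive but pruned: two residue pairs can only belong to
the same rigid match if their intra-site C-alpha distances agree to within
``2 * cutoff * sqrt(n_points)`` (a triangle-inequality bound that never
discards a valid match), and a hard budget caps the number of candidate
mappings considered for one site pair. The superposition of each candidate
is evaluated in closed form from running Kabsch accumulators (point sums,
squared norms and the 3x3 cross-covariance), so each candidate costs one
3x3 SVD.

Chemically indistinguishable side-chain atoms (Asp OD1/OD2, Glu OE1/OE2,
Arg NH1/NH2, Phe/Tyr ring carbons) are handled by trying both labelings
per mapped residue, keeping the lower RMSD; a Lipschitz bound on how much a
relabeling can lower the RMSD skips the search when no labeling can reach
the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .chemistry import SIDE_CHAIN_ATOMS, SYMMETRIC_SWAPS, heavy_atom_order
from .io_model import CatalyticSite, Residue
from . import scoring

__all__ = [
    "Representation",
    "EquivalenceRules",
    "EQUI_NONE",
    "EQUI_YF_IL",
    "EQUI_YF_IV",
    "Match",
    "SiteComparison",
    "MatchBudgetExceeded",
    "MissingAtomError",
    "represent",
    "superpose_points",
    "enumerate_matches",
    "compare_sites",
]

DEFAULT_BUDGET = 10**6


class MissingAtomError(ValueError):
    """A residue lacks an atom required by the chosen representation."""


class MatchBudgetExceeded(RuntimeError):
    """Raised when a site pair exceeds the candidate-mapping budget."""


class Representation(str, Enum):
    """Per-residue point representation used for superposition."""

    CA = "ca"
    CA_CB = "ca_cb"
    CA_CENTROID = "ca_centroid"
    ALL_ATOM = "all_atom"


@dataclass(frozen=True)
class EquivalenceRules:
    """Unordered amino-acid pairs treated as interchangeable.

    The default (no pairs) is strict identity. Pairs use three-letter codes.
    """

    pairs: frozenset[frozenset[str]] = frozenset()

    @classmethod
    def from_pairs(cls, *pairs: tuple[str, str]) -> "EquivalenceRules":
        return cls(frozenset(frozenset(p) for p in pairs))

    def compatible(self, aa1: str, aa2: str) -> bool:
        return aa1 == aa2 or frozenset((aa1, aa2)) in self.pairs


EQUI_NONE = EquivalenceRules()
#: Table-legend preset: Tyr/Phe and Ile/Leu interchangeable.
EQUI_YF_IL = EquivalenceRules.from_pairs(("TYR", "PHE"), ("ILE", "LEU"))
#: Text preset: Tyr/Phe and Ile/Val interchangeable.
EQUI_YF_IV = EquivalenceRules.from_pairs(("TYR", "PHE"), ("ILE", "VAL"))


@dataclass
class Match:
    """One residue correspondence with its optimal rigid transform.

    ``mapping`` lists (index in A, index in B) pairs; the transform maps
    B's points onto A's frame: ``p ~ R q + t``.
    """

    mapping: tuple[tuple[int, int], ...]
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    @property
    def size(self) -> int:
        return len(self.mapping)

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("a match needs at least one residue pair")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det +1)")


@dataclass
class SiteComparison:
    """Best-scoring match between an ordered site pair, if any."""

    query_id: str
    target_id: str
    score_name: str
    best_match: Match | None = None
    score_value: float | None = None


# ---------------------------------------------------------------------------
# Representation
# ---------------------------------------------------------------------------

def represent(residue: Residue, rep: Representation) -> list[tuple[str, np.ndarray]]:
    """Ordered labelled point list for one residue under a representation.

    Glycine contributes no C-beta / centroid point (it has no side chain).
    Raises :class:`MissingAtomError` if a required atom is absent.
    """
    amap = residue.atom_map
    if "CA" not in amap:
        raise MissingAtomError(f"residue {residue.label} has no CA atom")
    ca = residue.coord("CA")
    if rep is Representation.CA:
        return [("CA", ca)]
    if rep is Representation.CA_CB:
        if residue.aa == "GLY":
            return [("CA", ca)]
        if "CB" not in amap:
            raise MissingAtomError(f"residue {residue.label} has no CB atom")
        return [("CA", ca), ("CB", residue.coord("CB"))]
    if rep is Representation.CA_CENTROID:
        if residue.aa == "GLY":
            return [("CA", ca)]
        side = [residue.coord(n) for n in SIDE_CHAIN_ATOMS.get(residue.aa, ())
                if n in amap]
        if not side:
            raise MissingAtomError(f"residue {residue.label} has no side-chain atoms")
        return [("CA", ca), ("CENTROID", np.mean(side, axis=0))]
    if rep is Representation.ALL_ATOM:
        names = [n for n in heavy_atom_order(residue.aa) if n in amap]
        return [(n, residue.coord(n)) for n in names]
    raise ValueError(f"unknown representation {rep!r}")


# ---------------------------------------------------------------------------
# Superposition (Kabsch)
# ---------------------------------------------------------------------------

def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    n = P.shape[0]
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    H = Qc.T @ Pc
    U, S, Vt = np.linalg.svd(H)
    d = 1.0 if np.linalg.det(U) * np.linalg.det(Vt) >= 0 else -1.0
    R = (Vt.T * np.array([1.0, 1.0, d])) @ U.T
    t = cp - R @ cq
    # explicit residual: the closed form e0 - 2*trace suffers cancellation
    # for near-perfect superpositions
    resid = P - (Q @ R.T + t)
    rmsd = float(np.sqrt((resid * resid).sum() / n))
    if rmsd < 1e-9:  # below any coordinate precision: an exact superposition
        rmsd = 0.0
    return R, t, rmsd


def superpose_points(
    P: np.ndarray, Q: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-RMSD proper rigid transform mapping points Q onto points P.

    Returns ``(R, t, rmsd)`` with ``rmsd = sqrt(mean ||p - (R q + t)||^2)``.
    Reflections are never returned; degenerate (collinear or coincident)
    point sets still yield a minimizer.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be equal-shape (n, 3) arrays")
    if not (np.isfinite(P).all() and np.isfinite(Q).all()):
        raise ValueError("points must be finite")
    if P.shape[0] == 1:
        return np.eye(3), P[0] - Q[0], 0.0
    return _kabsch(P, Q)


# ---------------------------------------------------------------------------
# Pairing of residue points
# ---------------------------------------------------------------------------

@dataclass
class _PairBlock:
    """Kabsch accumulator contributions of one residue correspondence."""

    n: int
    sum_p: np.ndarray        # (3,)
    sum_q: np.ndarray        # (3,)
    sum_pp: float
    sum_qq: float
    h: np.ndarray            # (3,3)  sum over points of q p^T
    P: np.ndarray            # (n,3)
    Q: np.ndarray            # (n,3) default labeling
    Q_alt: np.ndarray | None  # alternative symmetric labeling, if any
    delta2: float            # squared perturbation norm |Q_alt - Q|^2

    @classmethod
    def build(cls, P: np.ndarray, Q: np.ndarray, Q_alt: np.ndarray | None) -> "_PairBlock":
        delta2 = float(((Q_alt - Q) ** 2).sum()) if Q_alt is not None else 0.0
        return cls(
            n=P.shape[0],
            sum_p=P.sum(axis=0), sum_q=Q.sum(axis=0),
            sum_pp=float((P * P).sum()), sum_qq=float((Q * Q).sum()),
            h=Q.T @ P, P=P, Q=Q, Q_alt=Q_alt, delta2=delta2,
        )


def _paired_blocks(
    res_a: Residue, res_b: Residue, rep: Representation
) -> _PairBlock:
    """Paired coordinate blocks for one residue correspondence.

    Points are paired by label on the intersection of labels present in
    both residues (for equivalence-paired residue types under ALL_ATOM this
    is the shared subset of atom names, in A's canonical order). An
    alternative B block encodes the symmetric side-chain relabeling
    (carboxylate oxygens, ring flip, guanidinium nitrogens) where one
    applies.
    """
    pa = represent(res_a, rep)
    pb = dict(represent(res_b, rep))
    labels = [lab for lab, _ in pa if lab in pb]
    if not labels:
        raise MissingAtomError(
            f"no shared points between {res_a.label} and {res_b.label}")
    P = np.stack([xyz for lab, xyz in pa if lab in pb])
    Q = np.stack([pb[lab] for lab in labels])
    Q_alt = None
    if rep is Representation.ALL_ATOM:
        swaps = SYMMETRIC_SWAPS.get(res_b.aa) or SYMMETRIC_SWAPS.get(res_a.aa)
        if swaps:
            swap_map: dict[str, str] = {}
            for x, y in swaps:
                swap_map[x], swap_map[y] = y, x
            alt = [swap_map.get(lab, lab) for lab in labels]
            if alt != labels and all(lab in pb for lab in alt):
                Q_alt = np.stack([pb[lab] for lab in alt])
    return _PairBlock.build(P, Q, Q_alt)


# ---------------------------------------------------------------------------
# Match enumeration
# ---------------------------------------------------------------------------

class _Accumulator:
    """Running Kabsch sums over the residue blocks of a partial mapping."""

    def __init__(self) -> None:
        self.n = 0
        self.sum_p = np.zeros(3)
        self.sum_q = np.zeros(3)
        self.sum_pp = 0.0
        self.sum_qq = 0.0
        self.h = np.zeros((3, 3))
        self.delta2 = 0.0

    def push(self, b: _PairBlock) -> None:
        self.n += b.n
        self.sum_p += b.sum_p
        self.sum_q += b.sum_q
        self.sum_pp += b.sum_pp
        self.sum_qq += b.sum_qq
        self.h += b.h
        self.delta2 += b.delta2

    def pop(self, b: _PairBlock) -> None:
        self.n -= b.n
        self.sum_p -= b.sum_p
        self.sum_q -= b.sum_q
        self.sum_pp -= b.sum_pp
        self.sum_qq -= b.sum_qq
        self.h -= b.h
        self.delta2 -= b.delta2

    def solve(self) -> tuple[np.ndarray, np.ndarray, float]:
        n = self.n
        cp, cq = self.sum_p / n, self.sum_q / n
        M = self.h - n * np.outer(cq, cp)
        U, S, Vt = np.linalg.svd(M)
        d = 1.0 if np.linalg.det(U) * np.linalg.det(Vt) >= 0 else -1.0
        R = (Vt.T * np.array([1.0, 1.0, d])) @ U.T
        e0 = self.sum_pp - n * float(cp @ cp) + self.sum_qq - n * float(cq @ cq)
        msd = max(0.0, (e0 - 2.0 * (S[0] + S[1] + d * S[2])) / n)
        return R, cp - R @ cq, float(np.sqrt(msd))


# exhaustive relabeling search up to this many ambiguous residues per
# mapping; beyond it, per-residue coordinate descent
_EXACT_SWAP_LIMIT = 6


def _min_over_relabelings(
    blocks: list[_PairBlock],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lowest-RMSD symmetric labeling for one mapping.

    Up to ``_EXACT_SWAP_LIMIT`` ambiguous residues the product of labelings
    is searched exhaustively (the minimum is exact); beyond that, each
    ambiguous residue's alternative labeling is tried with the others fixed,
    keeping improvements, until a pass changes nothing.
    """
    ambiguous = [k for k, b in enumerate(blocks) if b.Q_alt is not None]
    flags = [False] * len(blocks)
    P = np.concatenate([b.P for b in blocks])

    def assemble() -> np.ndarray:
        return np.concatenate([
            b.Q_alt if (f and b.Q_alt is not None) else b.Q
            for b, f in zip(blocks, flags)
        ])

    best = _kabsch(P, assemble())
    if len(ambiguous) <= _EXACT_SWAP_LIMIT:
        for mask in range(1, 2 ** len(ambiguous)):
            for bit, k in enumerate(ambiguous):
                flags[k] = bool(mask >> bit & 1)
            cand = _kabsch(P, assemble())
            if cand[2] < best[2]:
                best = cand
        return best
    improved = True
    while improved:
        improved = False
        for k in ambiguous:
            flags[k] = not flags[k]
            cand = _kabsch(P, assemble())
            if cand[2] < best[2] - 1e-12:
                best = cand
                improved = True
            else:
                flags[k] = not flags[k]
    return best


def _ca_distance_matrix(site: CatalyticSite) -> np.ndarray:
    ca = site.ca_coords()
    diff = ca[:, None, :] - ca[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


class _PairContext:
    """Precomputed pairing data for one (site A, site B, rep, rules) tuple."""

    def __init__(self, A: CatalyticSite, B: CatalyticSite,
                 rep: Representation, rules: EquivalenceRules):
        self.nA, self.nB = len(A), len(B)
        self.blocks: dict[tuple[int, int], _PairBlock] = {}
        self.compat: list[list[int]] = []
        for i, ra in enumerate(A.residues):
            row: list[int] = []
            for j, rb in enumerate(B.residues):
                if not rules.compatible(ra.aa, rb.aa):
                    continue
                try:
                    self.blocks[(i, j)] = _paired_blocks(ra, rb, rep)
                except MissingAtomError:
                    continue
                row.append(j)
            self.compat.append(row)
        self.dA = _ca_distance_matrix(A)
        self.dB = _ca_distance_matrix(B)
        # conservative bound on the point count of any single match
        self.n_bound = (max(b.n for b in self.blocks.values())
                        * min(self.nA, self.nB)) if self.blocks else 1


def enumerate_matches(
    A: CatalyticSite,
    B: CatalyticSite,
    rep: Representation = Representation.ALL_ATOM,
    rules: EquivalenceRules = EQUI_NONE,
    rmsd_cutoff: float = 1.0,
    min_size: int = 2,
    budget: int = DEFAULT_BUDGET,
) -> list[Match]:
    """Every injective type-compatible mapping whose optimal RMSD <= cutoff.

    Sub-mappings of a passing mapping are enumerated (and reported when
    they pass) in their own right. Raises :class:`MatchBudgetExceeded` if
    the pair generates more candidate mappings than ``budget``.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if rmsd_cutoff <= 0:
        raise ValueError("rmsd_cutoff must be positive")
    ctx = _PairContext(A, B, rep, rules)
    tol = 2.0 * rmsd_cutoff * np.sqrt(ctx.n_bound)
    out: list[Match] = []
    acc = _Accumulator()
    used: set[int] = set()
    chosen: list[tuple[int, int]] = []
    counter = 0

    def emit() -> None:
        nonlocal counter
        counter += 1
        if counter > budget:
            raise MatchBudgetExceeded(
                f"pair ({A.site_id}, {B.site_id}): candidate-mapping budget "
                f"of {budget} exceeded")
        R, t, rmsd = acc.solve()
        near = rmsd <= rmsd_cutoff + 1e-6
        if acc.delta2 > 0.0:
            # a symmetric relabeling can lower the RMSD by at most
            # sqrt(delta2 / n) (Lipschitz bound); search only when it
            # could matter for the cutoff or improve an accepted match
            if near or rmsd - np.sqrt(acc.delta2 / acc.n) <= rmsd_cutoff:
                blocks = [ctx.blocks[p] for p in chosen]
                R, t, rmsd = _min_over_relabelings(blocks)
        elif near:
            # re-evaluate with the explicit residual: the accumulator
            # closed form loses precision near rmsd 0
            blocks = [ctx.blocks[p] for p in chosen]
            R, t, rmsd = _kabsch(np.concatenate([b.P for b in blocks]),
                                 np.concatenate([b.Q for b in blocks]))
        if rmsd <= rmsd_cutoff:
            out.append(Match(mapping=tuple(chosen), rotation=R,
                             translation=t, rmsd=rmsd))

    def rec(i: int) -> None:
        if i == ctx.nA:
            if len(chosen) >= min_size:
                emit()
            return
        rec(i + 1)  # skip residue i of A
        for j in ctx.compat[i]:
            if j in used:
                continue
            if any(abs(ctx.dA[i, k] - ctx.dB[j, l]) > tol for k, l in chosen):
                continue
            used.add(j)
            chosen.append((i, j))
            acc.push(ctx.blocks[(i, j)])
            rec(i + 1)
            acc.pop(ctx.blocks[(i, j)])
            chosen.pop()
            used.remove(j)

    rec(0)
    return out


def compare_sites(
    A: CatalyticSite,
    B: CatalyticSite,
    rep: Representation = Representation.ALL_ATOM,
    rules: EquivalenceRules = EQUI_NONE,
    rmsd_cutoff: float = 1.0,
    score_name: str = "rmsd_n2",
    min_size: int = 2,
    budget: int = DEFAULT_BUDGET,
) -> SiteComparison:
    """Best-scoring match between an ordered site pair.

    The best match minimizes the named score; ties break toward the larger
    match, then the lexicographically smallest mapping. ``best_match`` is
    absent when no mapping passes the cutoff.
    """
    spec = scoring.get_score(score_name)
    matches = enumerate_matches(A, B, rep, rules, rmsd_cutoff, min_size, budget)
    comparison = SiteComparison(A.site_id, B.site_id, score_name)
    best_key = None
    for m in matches:
        value = scoring.score_match(m, spec, A, B)
        key = (value, -m.size, m.mapping)
        if best_key is None or key < best_key:
            best_key = key
            comparison.best_match = m
            comparison.score_value = value
    return comparison
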