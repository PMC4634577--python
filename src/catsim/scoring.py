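"""Pose-similarity scores over matches.

All scores are lower-is-more-similar. Besides the raw RMSD, two
normalizations reward matches that superpose more residues:

    RMSD_N1 = RMSD / (|ms| - 1)
    RMSD_N2 = RMSD / max(1, 3 |ms| - 6)

where |ms| is the number of matched residue pairs. RMSD_N2 decreases faster
with match size, favouring extensive superpositions more strongly.
Additional scores (e.g. literature scores whose formulas live elsewhere)
can be registered as plugins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .io_model import CatalyticSite
    from .superposer import Match

__all__ = [
    "ScoreSpec",
    "rmsd_n1",
    "rmsd_n2",
    "score_match",
    "get_score",
    "register_plugin",
]


def rmsd_n1(rmsd: float, size: int) -> float:
    """RMSD normalized by (|ms| - 1)."""
    if size < 2:
        raise ValueError("rmsd_n1 requires a match of at least 2 residues")
    if rmsd < 0:
        raise ValueError("rmsd must be non-negative")
    return rmsd / (size - 1)


def rmsd_n2(rmsd: float, size: int) -> float:
    """RMSD normalized by max(1, 3 |ms| - 6)."""
    if size < 2:
        raise ValueError("rmsd_n2 requires a match of at least 2 residues")
    if rmsd < 0:
        raise ValueError("rmsd must be non-negative")
    return rmsd / max(1, 3 * size - 6)


@dataclass(frozen=True)
class ScoreSpec:
    """A named pose score; ``func(match, site_a, site_b) -> value``."""

    name: str
    func: Callable[["Match", "CatalyticSite | None", "CatalyticSite | None"], float]


_BUILTIN: dict[str, ScoreSpec] = {
    "rmsd": ScoreSpec("rmsd", lambda m, a, b: m.rmsd),
    "rmsd_n1": ScoreSpec("rmsd_n1", lambda m, a, b: rmsd_n1(m.rmsd, m.size)),
    "rmsd_n2": ScoreSpec("rmsd_n2", lambda m, a, b: rmsd_n2(m.rmsd, m.size)),
}
_PLUGINS: dict[str, ScoreSpec] = {}


def register_plugin(
    name: str,
    func: Callable[["Match", "CatalyticSite | None", "CatalyticSite | None"], float],
) -> None:
    """Register ``plugin:<name>`` as an additional pose score."""
    _PLUGINS[name] = ScoreSpec(f"plugin:{name}", func)


def get_score(name: str) -> ScoreSpec:
    if name in _BUILTIN:
        return _BUILTIN[name]
    if name.startswith("plugin:") and name[7:] in _PLUGINS:
        return _PLUGINS[name[7:]]
    raise KeyError(f"unknown score {name!r}; known: "
                   f"{sorted(_BUILTIN) + sorted('plugin:' + p for p in _PLUGINS)}")


def score_match(
    match: "Match",
    spec: ScoreSpec | str,
    site_a: "CatalyticSite | None" = None,
    site_b: "CatalyticSite | None" = None,
) -> float:
    """Evaluate a score on one match (plugins also see both sites)."""
    if isinstance(spec, str):
        spec = get_score(spec)
    return float(spec.func(match, site_a, site_b))
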