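"""Census of non-homologous isofunctional enzymes (NISE).

For single-domain, mono-functional enzymes, each enzymatic function (an EC
number truncated to 4 or 3 fields) is mapped to the set of SCOP
superfamilies in which it occurs. Functions found in two or more
superfamilies are candidate products of convergent evolution. The module
also compares EC-class compositions between two enzyme collections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_model import EnzymeFunctionRecord, is_full_ec

__all__ = [
    "CensusResult",
    "select_census_enzymes",
    "census",
    "ec_class_composition",
]


@dataclass
class CensusResult:
    """Superfamily counts per function at one EC truncation level."""

    ec_level: int
    superfamilies_per_function: dict[str, set[str]]
    histogram: dict[int, int]  # superfamily count -> number of functions
    fraction_one_superfamily: float
    fraction_multi_superfamily: float  # >= 2
    fraction_five_plus: float          # >= 5

    @property
    def n_functions(self) -> int:
        return len(self.superfamilies_per_function)


def select_census_enzymes(
    records: Iterable[EnzymeFunctionRecord],
) -> list[EnzymeFunctionRecord]:
    """Keep single-domain enzymes with exactly one full (4-field) EC number."""
    out = []
    for rec in records:
        if rec.domain_count != 1:
            continue
        full = {ec for ec in rec.ec_numbers if is_full_ec(ec)}
        if len(full) == 1 and len(set(rec.ec_numbers)) == 1:
            out.append(rec)
    return out


def census(records: Sequence[EnzymeFunctionRecord], ec_level: int = 4) -> CensusResult:
    """Count distinct superfamilies per function at an EC truncation level."""
    if ec_level not in (3, 4):
        raise ValueError("ec_level must be 3 or 4")
    per_function: dict[str, set[str]] = {}
    for rec in records:
        ec = rec.ec_numbers[0]
        key = ".".join(ec.split(".")[:ec_level])
        per_function.setdefault(key, set()).add(rec.superfamily)
    if not per_function:
        raise ValueError("no records to census")
    histogram: dict[int, int] = {}
    for sfs in per_function.values():
        histogram[len(sfs)] = histogram.get(len(sfs), 0) + 1
    n = len(per_function)
    one = histogram.get(1, 0)
    five_plus = sum(c for k, c in histogram.items() if k >= 5)
    return CensusResult(
        ec_level=ec_level,
        superfamilies_per_function=per_function,
        histogram=dict(sorted(histogram.items())),
        fraction_one_superfamily=one / n,
        fraction_multi_superfamily=(n - one) / n,
        fraction_five_plus=five_plus / n,
    )


def ec_class_composition(
    ecs1: Sequence[str], ecs2: Sequence[str]
) -> dict[str, dict[str, float | None]]:
    """EC class (1-6) fractions of two collections and their ratios.

    Returns per class the fraction in each set and the ratio set1/set2
    (None where the class is absent from set2).
    """
    if not ecs1 or not ecs2:
        raise ValueError("both collections must be non-empty")

    def fractions(ecs: Sequence[str]) -> dict[str, float]:
        counts = {str(c): 0 for c in range(1, 7)}
        for ec in ecs:
            cls = ec.split(".")[0]
            if cls in counts:
                counts[cls] += 1
        total = sum(counts.values())
        return {c: k / total for c, k in counts.items()}

    f1, f2 = fractions(ecs1), fractions(ecs2)
    out: dict[str, dict[str, float | None]] = {}
    for cls in f1:
        ratio = f1[cls] / f2[cls] if f2[cls] > 0 else None
        out[cls] = {"set1": f1[cls], "set2": f2[cls], "ratio": ratio}
    return out
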