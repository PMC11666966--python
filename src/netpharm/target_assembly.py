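"""Assembly of compound-target and disease-target gene universes.

Multi-source target lists (drug databases, disease-gene databases) are
merged by set union, the GeneCards source is reduced by a median filter on
its GIFTS (GeneCards Inferred Functionality Score) annotation, and the
compound-side and disease-side universes are intersected to yield the
candidate therapeutic targets.  A Venn-region report makes every
membership pattern and its member list explicit.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal, Mapping, Sequence

__all__ = [
    "TargetSet",
    "ScoredTargetSet",
    "UnionReport",
    "normalize_symbol",
    "union_sources",
    "gifts_median_filter",
    "intersect_sets",
    "venn_regions",
]


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: surrounding whitespace stripped, uppercased.

    No alias or identifier mapping is attempted; inputs are assumed to
    already be gene symbols.
    """
    return symbol.strip().upper()


@dataclass(frozen=True)
class TargetSet:
    """A labeled set of normalized gene symbols."""

    label: str
    genes: frozenset[str]

    @classmethod
    def from_symbols(cls, label: str, symbols: Iterable[str]) -> "TargetSet":
        norm = {normalize_symbol(s) for s in symbols}
        norm.discard("")
        return cls(label, frozenset(norm))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class ScoredTargetSet:
    """A labeled gene set with one nonnegative score per gene (e.g. GIFTS)."""

    label: str
    scores: Mapping[str, float]

    def to_target_set(self) -> TargetSet:
        return TargetSet(self.label, frozenset(self.scores))

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class UnionReport:
    """Union of several sources plus each source's contribution count."""

    merged: TargetSet
    contributions: dict[str, int] = field(default_factory=dict)


def union_sources(sets: Sequence[TargetSet]) -> UnionReport:
    """Merge and deduplicate per-source target sets.

    Returns the union labeled "merged" and, per source, how many of its
    genes it contributed (its own size; overlaps are visible by comparing
    the sum of contributions with the union size).
    """
    if not sets:
        raise ValueError("union_sources requires at least one set")
    genes: set[str] = set()
    contributions: dict[str, int] = {}
    for ts in sets:
        genes |= ts.genes
        contributions[ts.label] = len(ts.genes)
    return UnionReport(TargetSet("merged", frozenset(genes)), contributions)


Direction = Literal["at_or_below", "at_or_above"]


def gifts_median_filter(
    scored: ScoredTargetSet, direction: Direction = "at_or_below"
) -> TargetSet:
    """Keep genes whose score is on the requested side of the median, inclusive.

    The median of an even-sized score vector is the arithmetic mean of the
    two central order statistics.  Genes scoring exactly at the median are
    always kept ("at or ...").  The default direction keeps the lower half,
    matching the published screening procedure; the opposite direction is
    available because confidence scores are more usually filtered upward.
    """
    if not scored.scores:
        raise ValueError("cannot take the median of an empty score set")
    if direction not in ("at_or_below", "at_or_above"):
        raise ValueError(f"unknown direction {direction!r}")
    med = statistics.median(scored.scores.values())
    if direction == "at_or_below":
        kept = {g for g, s in scored.scores.items() if s <= med}
    else:
        kept = {g for g, s in scored.scores.items() if s >= med}
    return TargetSet(f"{scored.label}|gifts_{direction}", frozenset(kept))


def intersect_sets(a: TargetSet, b: TargetSet) -> TargetSet:
    """Set intersection of two labeled gene sets."""
    return TargetSet(f"{a.label}&{b.label}", a.genes & b.genes)


def venn_regions(sets: Sequence[TargetSet]) -> dict:
    """Exact Venn-region tally for 2-4 sets.

    Every nonempty membership pattern is reported under a binary-mask key
    ("10" = in the first set only, etc.), with its count and sorted member
    list.  Region counts partition the union.
    """
    if not (2 <= len(sets) <= 4):
        raise ValueError(f"venn_regions supports 2-4 sets, got {len(sets)}")
    labels = [ts.label for ts in sets]
    regions: dict[str, list[str]] = {}
    universe = set().union(*(ts.genes for ts in sets))
    for gene in universe:
        mask = "".join("1" if gene in ts.genes else "0" for ts in sets)
        regions.setdefault(mask, []).append(gene)
    report = {
        "labels": labels,
        "regions": {
            mask: {"count": len(members), "members": sorted(members)}
            for mask, members in sorted(regions.items())
        },
    }
    # pairwise intersection sizes are handy for diagram annotation
    report["pairwise"] = {
        f"{labels[i]}&{labels[j]}": len(sets[i].genes & sets[j].genes)
        for i, j in combinations(range(len(sets)), 2)
    }
    return report
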