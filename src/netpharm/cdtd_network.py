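"""Drug-compounds-targets-disease (CDTD) network and docking summaries.

The CDTD network is a typed multipartite graph: the drug node connects to
every screened compound, each compound connects to the core targets it is
predicted to hit, and every hit target connects to the disease node.
Compounds are ranked by their compound-target degree (the drug edge is
excluded, so a compound's rank equals its core-target count).

Docking results are consumed, not produced: a docking matrix holds one or
more pose energies (kcal/mol) per compound-target pair, and the summary
reports the per-pair best (minimum) energy, each target's best binder(s)
with ties kept jointly, and a "good binding" flag for best energies
strictly below the conventional -5.0 kcal/mol.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .compound_screen import CompoundRecord
from .target_assembly import TargetSet

__all__ = [
    "CDTDNetwork",
    "DockingMatrix",
    "DockingSummary",
    "CompoundRanking",
    "build_cdtd",
    "compound_degree_ranking",
    "summarize_docking",
]

REL_DRUG_COMPOUND = "drug-compound"
REL_COMPOUND_TARGET = "compound-target"
REL_TARGET_DISEASE = "target-disease"


@dataclass
class CDTDNetwork:
    """Typed multipartite network.

    ``nodes`` maps a node name to its type (drug/compound/target/disease);
    ``edges`` holds (source, target, relation) triples, stored once per
    undirected pair with the source on the drug-ward side.
    """

    nodes: dict[str, str] = field(default_factory=dict)
    edges: set[tuple[str, str, str]] = field(default_factory=set)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, node: str) -> int:
        return sum(1 for a, b, _ in self.edges if node in (a, b))

    def edges_of_type(self, relation: str) -> set[tuple[str, str, str]]:
        return {e for e in self.edges if e[2] == relation}


def build_cdtd(
    drug: str,
    compounds: Sequence[CompoundRecord],
    per_compound_targets: Mapping[str, TargetSet],
    core: TargetSet,
    disease: str,
    include_disease_edges: bool = True,
) -> CDTDNetwork:
    """Assemble the CDTD network from screened compounds and core targets.

    Compound-target edges exist only for targets inside the core set.  A
    compound with no core targets stays in the network (with a warning) so
    the panel remains complete.  Targets reached by at least one compound
    are wired to the disease node unless ``include_disease_edges`` is off.
    """
    names = {c.name for c in compounds}
    unknown = set(per_compound_targets) - names
    if unknown:
        raise ValueError(f"per_compound_targets has keys not in the panel: {sorted(unknown)[:5]}")

    net = CDTDNetwork()
    net.nodes[drug] = "drug"
    net.nodes[disease] = "disease"
    hit_targets: set[str] = set()
    for comp in compounds:
        net.nodes[comp.name] = "compound"
        net.edges.add((drug, comp.name, REL_DRUG_COMPOUND))
        targets = per_compound_targets.get(comp.name)
        core_hits = (targets.genes & core.genes) if targets is not None else frozenset()
        if not core_hits:
            warnings.warn(f"compound {comp.name!r} has no core targets", stacklevel=2)
            continue
        for t in core_hits:
            net.nodes[t] = "target"
            net.edges.add((comp.name, t, REL_COMPOUND_TARGET))
        hit_targets |= core_hits
    if include_disease_edges:
        for t in hit_targets:
            net.edges.add((t, disease, REL_TARGET_DISEASE))
    return net


@dataclass(frozen=True)
class CompoundRanking:
    """Compounds ordered by core-target degree (descending, ties by name)."""

    entries: tuple[tuple[str, int], ...]
    tied_degrees: frozenset[int]

    def top(self, k: int) -> list[str]:
        return [name for name, _ in self.entries[:k]]


def compound_degree_ranking(net: CDTDNetwork) -> CompoundRanking:
    """Rank compounds by number of compound-target edges.

    The mandatory drug edge is excluded, so the degree equals the
    compound's core-target count.  Degrees shared by more than one
    compound are flagged, since an arbitrary tie-break there would change
    the printed order.
    """
    degrees = {name: 0 for name, t in net.nodes.items() if t == "compound"}
    for a, b, rel in net.edges:
        if rel == REL_COMPOUND_TARGET:
            degrees[a] += 1
    ordered = sorted(degrees.items(), key=lambda item: (-item[1], item[0]))
    counts: dict[int, int] = {}
    for _, d in ordered:
        counts[d] = counts.get(d, 0) + 1
    tied = frozenset(d for d, c in counts.items() if c > 1)
    return CompoundRanking(tuple(ordered), tied)


@dataclass
class DockingMatrix:
    """Pose energies (kcal/mol) per (compound, target) pair; negative = favorable."""

    entries: dict[tuple[str, str], list[float]] = field(default_factory=dict)

    def add(self, compound: str, target: str, energy: float) -> None:
        if not math.isfinite(energy):
            raise ValueError(f"non-finite energy for ({compound}, {target})")
        self.entries.setdefault((compound, target), []).append(energy)

    def compounds(self) -> list[str]:
        return sorted({c for c, _ in self.entries})

    def targets(self) -> list[str]:
        return sorted({t for _, t in self.entries})

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class DockingSummary:
    best: dict[tuple[str, str], float]
    best_binders: dict[str, tuple[tuple[str, float], ...]]
    good: dict[tuple[str, str], bool]
    good_threshold: float

    def heatmap(self) -> pd.DataFrame:
        """Best energies as a compounds x targets table (NaN where undocked)."""
        compounds = sorted({c for c, _ in self.best})
        targets = sorted({t for _, t in self.best})
        frame = pd.DataFrame(index=compounds, columns=targets, dtype=float)
        for (c, t), e in self.best.items():
            frame.loc[c, t] = e
        frame.index.name = "compound"
        return frame


def summarize_docking(m: DockingMatrix, good_threshold: float = -5.0) -> DockingSummary:
    """Per-pair best (minimum) energy, per-target best binder(s), quality flags.

    The flag is strict: a best energy exactly at the threshold is not
    "good".  Ties for a target's best binder are reported jointly.
    """
    if len(m) == 0:
        raise ValueError("docking matrix is empty")
    best = {pair: min(poses) for pair, poses in m.entries.items()}
    best_binders: dict[str, tuple[tuple[str, float], ...]] = {}
    for target in m.targets():
        col = {c: e for (c, t), e in best.items() if t == target}
        lowest = min(col.values())
        winners = tuple((c, col[c]) for c in sorted(col) if col[c] == lowest)
        best_binders[target] = winners
    good = {pair: e < good_threshold for pair, e in best.items()}
    return DockingSummary(best, best_binders, good, good_threshold)
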