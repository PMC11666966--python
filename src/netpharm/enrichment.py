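"""Hypergeometric over-representation analysis against flat gene-set terms.

Terms (GO categories, pathways) are treated as plain gene sets with a
category label; no ontology structure is used.  For a query of n genes
inside a background of N genes, a term of K genes overlapping the query in
k genes is scored with the hypergeometric upper tail P(X >= k) and the
enrichment factor (k/n)/(K/N).  Benjamini-Hochberg q-values are reported
over all tested terms, but the significance flag defaults to the raw-p
screen with minimum-overlap and minimum-enrichment cutoffs, mirroring the
common web-tool defaults (p < 0.05, overlap >= 3, enrichment >= 1.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .target_assembly import TargetSet, normalize_symbol

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "EnrichmentConfig",
    "EnrichmentRow",
    "hypergeom_tail",
    "enrichment_factor",
    "run_ora",
    "rows_to_frame",
]


@dataclass(frozen=True)
class GeneSet:
    """One annotation term: identifier, description, member symbols."""

    term_id: str
    term_name: str
    members: frozenset[str]
    category: str = ""

    @classmethod
    def from_symbols(
        cls, term_id: str, term_name: str, symbols: Iterable[str], category: str = ""
    ) -> "GeneSet":
        norm = {normalize_symbol(s) for s in symbols}
        norm.discard("")
        return cls(term_id, term_name, frozenset(norm), category)


@dataclass
class GeneSetCollection:
    """An ordered collection of terms with unique identifiers."""

    terms: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate term_id in collection")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def member_union(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self.terms:
            out |= t.members
        return frozenset(out)


@dataclass(frozen=True)
class EnrichmentConfig:
    """Cutoffs for the over-representation screen.

    ``background`` overrides the default background (the union of all
    collection members) with an explicit gene universe.  ``flag_on``
    selects whether the significance flag tests the raw p or the BH q.
    """

    p_cutoff: float = 0.05
    min_overlap: int = 3
    min_enrichment: float = 1.5
    background: Optional[frozenset[str]] = None
    flag_on: Literal["p", "q"] = "p"

    def __post_init__(self) -> None:
        if not (0 < self.p_cutoff <= 1):
            raise ValueError("p_cutoff must lie in (0, 1]")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.min_enrichment <= 0:
            raise ValueError("min_enrichment must be positive")


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    term_name: str
    category: str
    k: int
    K: int
    n: int
    N: int
    p: float
    ef: float
    q: float
    members: tuple[str, ...]
    significant: bool


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P(X >= k), X ~ Hypergeometric(N, K, n).

    N is the background size, K the term size, n the query size and k the
    observed overlap.  P(X >= 0) is 1 by convention.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if K > N or n > N or K < 0 or n < 0:
        raise ValueError(f"require 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrichment_factor(k: int, K: int, n: int, N: int) -> float:
    """Fold enrichment (k/n)/(K/N); 0 when the overlap is empty."""
    if n <= 0 or K <= 0:
        raise ValueError("enrichment factor requires n > 0 and K > 0")
    if k == 0:
        return 0.0
    return (k / n) / (K / N)


def run_ora(
    query: TargetSet,
    collection: GeneSetCollection,
    config: EnrichmentConfig = EnrichmentConfig(),
) -> list[EnrichmentRow]:
    """Over-representation analysis of ``query`` against every term.

    Only terms overlapping the query (k >= 1) are tested; the BH correction
    is taken over exactly those tested terms.  Query genes outside the
    background are dropped (with a warning) and do not count toward n.
    Rows are sorted by ascending p, ties by term_id.
    """
    if not query.genes:
        raise ValueError("query gene set is empty")
    if len(collection) == 0:
        raise ValueError("gene-set collection is empty")
    background = (
        set(config.background) if config.background is not None else set(collection.member_union())
    )
    if not background:
        raise ValueError("enrichment background is empty")
    query_in = query.genes & background
    n_outside = len(query.genes) - len(query_in)
    if n_outside:
        warnings.warn(
            f"{n_outside} query gene(s) outside the background were excluded",
            stacklevel=2,
        )
    if not query_in:
        return []
    n = len(query_in)
    N = len(background)

    tested: list[tuple[GeneSet, int, int, tuple[str, ...]]] = []
    for term in collection:
        members_bg = term.members & background
        overlap = query_in & members_bg
        if overlap:
            tested.append((term, len(overlap), len(members_bg), tuple(sorted(overlap))))
    if not tested:
        return []

    ps = [hypergeom_tail(k, K, n, N) for _, k, K, _ in tested]
    qs = multipletests(ps, method="fdr_bh")[1]

    rows: list[EnrichmentRow] = []
    for (term, k, K, overlap), p, q in zip(tested, ps, qs):
        ef = enrichment_factor(k, K, n, N)
        basis = p if config.flag_on == "p" else q
        significant = (
            k >= config.min_overlap and ef >= config.min_enrichment and basis < config.p_cutoff
        )
        rows.append(
            EnrichmentRow(
                term_id=term.term_id,
                term_name=term.term_name,
                category=term.category,
                k=k,
                K=K,
                n=n,
                N=N,
                p=p,
                ef=ef,
                q=float(q),
                members=overlap,
                significant=significant,
            )
        )
    rows.sort(key=lambda r: (r.p, r.term_id))
    return rows


def rows_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    """Tabular (bubble-plot-ready) view of enrichment rows."""
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in rows],
            "term_name": [r.term_name for r in rows],
            "category": [r.category for r in rows],
            "k": [r.k for r in rows],
            "K": [r.K for r in rows],
            "n": [r.n for r in rows],
            "N": [r.N for r in rows],
            "p": [r.p for r in rows],
            "ef": [r.ef for r in rows],
            "q": [r.q for r in rows],
            "significant": [r.significant for r in rows],
            "members": [",".join(r.members) for r in rows],
        }
    )
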