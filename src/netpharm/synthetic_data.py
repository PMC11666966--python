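"""Synthetic inputs with planted, manifest-recorded structure.

Every live-database input of the screening pipeline is replaced by a
seeded generator: a compound panel whose OB/DL values straddle the
screening thresholds with a known pass count, compound-target and
disease-target universes sharing an exactly planted overlap, a PPI graph
with planted hub nodes that dominate degree, closeness, MNC and MCC
simultaneously, annotation terms with one planted enriched term, and a
docking-energy table.

Every planted quantity (pass counts, union and overlap sizes, hub
identities, the planted term's (k, K, n, N)) is written to a JSON-able
manifest so downstream tests assert against the manifest rather than
re-deriving it.  All generators are pure functions of the configuration,
seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .compound_screen import CompoundRecord
from .enrichment import GeneSet, GeneSetCollection
from .formats_io import (
    EdgeRecord,
    write_compound_table,
    write_docking_table,
    write_edge_table,
    write_gene_list,
    write_gmt,
    write_json,
)
from .cdtd_network import DockingMatrix
from .target_assembly import ScoredTargetSet, TargetSet

__all__ = [
    "SynthConfig",
    "gen_compound_panel",
    "gen_target_universes",
    "gen_ppi_with_hubs",
    "gen_gene_sets",
    "gen_docking_scores",
    "gen_bundle",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator conditions.

    Defaults mirror the scale of a published herbal-compound screen:
    830 raw phytochemicals of which 24 pass the OB/DL filter, a
    614-gene compound-target universe, disease sources of roughly
    10,031 (GIFTS-scored), 2,496, 95 and 6 genes, an exactly planted
    449-gene compound/disease overlap of which 5 genes receive no
    interactions, and six planted hub proteins.
    """

    seed: int = 0
    # compound panel
    n_compounds: int = 830
    n_compound_passers: int = 24
    n_duplicate_compounds: int = 0
    # gene universes
    n_genes: int = 12000
    overlap_size: int = 449
    compound_union_size: int = 614
    genecards_size: int = 10031
    disease_source_sizes: tuple[int, ...] = (95, 2496, 6)
    compound_targets_range: tuple[int, int] = (40, 230)
    # PPI graph
    n_hubs: int = 6
    hub_degree_boost: float = 5.0
    edge_density: float = 0.03
    edge_subthreshold_fraction: float = 0.05
    n_unmapped: int = 5
    # annotation terms
    n_terms: int = 50
    planted_term_overlap: float = 0.75
    planted_term_size: int = 30
    term_size_range: tuple[int, int] = (10, 40)
    enrichment_background_size: int = 500
    enrichment_query_size: int = 20
    # docking
    n_docking_compounds: int = 10
    docking_energy_range: tuple[float, float] = (-9.5, -5.2)

    def __post_init__(self) -> None:
        if self.n_compound_passers > self.n_compounds:
            raise ValueError("more passers than compounds")
        if self.n_hubs >= self.n_genes:
            raise ValueError("n_hubs must be smaller than n_genes")
        if not (0 <= self.planted_term_overlap <= 1):
            raise ValueError("planted_term_overlap must lie in [0, 1]")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


def _gene_symbols(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# compound panel
# ---------------------------------------------------------------------------


def gen_compound_panel(config: SynthConfig) -> tuple[list[CompoundRecord], dict]:
    """Compound panel with OB/DL straddling the 30 / 0.18 thresholds.

    Exactly ``n_compound_passers`` unique compounds pass both thresholds;
    the rest fail OB, DL, or both.  ``n_duplicate_compounds`` of the total
    are repeats of earlier records (same PubChem id), exercising the
    deduplication step.  The manifest records the planted counts.
    """
    rng = config.rng(salt=1)
    n_unique = config.n_compounds - config.n_duplicate_compounds
    if n_unique < config.n_compound_passers:
        raise ValueError("not enough unique compounds for the requested passers")
    records: list[CompoundRecord] = []
    ids = rng.choice(np.arange(10_000, 99_999_999), size=n_unique, replace=False)
    passer_names: list[str] = []
    for i in range(n_unique):
        name = f"CPD-{i + 1:04d}"
        if i < config.n_compound_passers:
            ob = float(rng.uniform(30.0, 80.0))
            dl = float(rng.uniform(0.18, 0.85))
            passer_names.append(name)
        else:
            # failer ranges stop short of the thresholds so the 2-decimal
            # rounding below cannot push a planted failer over the line
            mode = rng.integers(0, 3)
            ob = float(rng.uniform(2.0, 29.5)) if mode in (0, 2) else float(rng.uniform(30.0, 80.0))
            dl = float(rng.uniform(0.02, 0.17)) if mode in (1, 2) else float(rng.uniform(0.18, 0.85))
        records.append(CompoundRecord(pubchem_id=str(int(ids[i])), name=name, ob=round(ob, 2), dl=round(dl, 2)))
    for _ in range(config.n_duplicate_compounds):
        records.append(records[int(rng.integers(0, n_unique))])
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    manifest = {
        "n_compound_records": len(records),
        "n_unique_compounds": n_unique,
        "n_compound_passers": config.n_compound_passers,
        "n_compound_failers": n_unique - config.n_compound_passers,
        "passer_names": sorted(passer_names),
    }
    return records, manifest


# ---------------------------------------------------------------------------
# target universes
# ---------------------------------------------------------------------------


def gen_target_universes(
    config: SynthConfig, compound_names: Optional[Sequence[str]] = None
) -> tuple[dict[str, TargetSet], list[ScoredTargetSet | TargetSet], dict]:
    """Compound and disease target universes with an exactly planted overlap.

    The gene universe is partitioned into shared genes (the planted
    overlap), compound-only genes, and a disease-side pool, so the
    intersection of the two unions equals ``overlap_size`` exactly.  One
    disease source carries GIFTS-style scores (to be median-filtered); the
    planted shared genes are also placed in an unscored source so the
    filter cannot erode the overlap.
    """
    rng = config.rng(salt=2)
    if config.overlap_size > config.n_genes:
        raise ValueError("planted overlap exceeds the gene universe")
    if config.compound_union_size < config.overlap_size:
        raise ValueError("compound union smaller than the planted overlap")
    genes = _gene_symbols(config.n_genes)
    perm = rng.permutation(config.n_genes)
    shared = [genes[i] for i in perm[: config.overlap_size]]
    n_conly = config.compound_union_size - config.overlap_size
    compound_only = [genes[i] for i in perm[config.overlap_size : config.overlap_size + n_conly]]
    disease_pool = [genes[i] for i in perm[config.overlap_size + n_conly :]]
    if config.genecards_size > config.overlap_size + len(disease_pool):
        raise ValueError("gene universe too small for the GIFTS-scored source")

    if compound_names is None:
        compound_names = [f"CPD-{i + 1:04d}" for i in range(config.n_compound_passers)]
    compound_pool = shared + compound_only
    per_compound: dict[str, TargetSet] = {}
    lo, hi = config.compound_targets_range
    hi = min(hi, len(compound_pool))
    chosen: dict[str, set[str]] = {name: set() for name in compound_names}
    for name in compound_names:
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(compound_pool), size=size, replace=False)
        chosen[name] = {compound_pool[i] for i in idx}
    covered = set().union(*chosen.values()) if chosen else set()
    uncovered = [g for g in compound_pool if g not in covered]
    names_arr = list(compound_names)
    for g in uncovered:  # guarantee the union covers the planted pool
        chosen[names_arr[int(rng.integers(0, len(names_arr)))]].add(g)
    per_compound = {name: TargetSet(name, frozenset(members)) for name, members in chosen.items()}

    # scored source (GeneCards-like): sampled from shared + disease pool
    gc_pool = shared + disease_pool
    gc_idx = rng.choice(len(gc_pool), size=config.genecards_size, replace=False)
    gc_scores = {gc_pool[i]: float(round(rng.uniform(0.0, 60.0), 3)) for i in gc_idx}
    genecards = ScoredTargetSet("genecards", gc_scores)
    med = float(np.median(list(gc_scores.values())))
    gifts_kept = sum(1 for s in gc_scores.values() if s <= med)

    disease_sources: list[ScoredTargetSet | TargetSet] = [genecards]
    source_names = ["drugbank", "disgenet", "omim"]
    for name, size in zip(source_names, config.disease_source_sizes):
        if name == "disgenet":
            # the largest unscored source anchors the full planted overlap
            size = max(size, config.overlap_size)
            extra = size - config.overlap_size
            idx = rng.choice(len(disease_pool), size=extra, replace=False)
            members = set(shared) | {disease_pool[i] for i in idx}
        else:
            idx = rng.choice(len(gc_pool), size=size, replace=False)
            members = {gc_pool[i] for i in idx}
        disease_sources.append(TargetSet(name, frozenset(members)))

    compound_union = set().union(*(ts.genes for ts in per_compound.values()))
    kept_gc = {g for g, s in gc_scores.items() if s <= med}
    disease_union = kept_gc.union(
        *(ts.genes for ts in disease_sources if isinstance(ts, TargetSet))
    )
    manifest = {
        "overlap_size": config.overlap_size,
        "compound_union_size": len(compound_union),
        "disease_union_size": len(disease_union),
        "gifts_median": med,
        "gifts_kept_count": gifts_kept,
        "per_source_sizes": {
            ts.label: len(ts) for ts in disease_sources
        },
        "shared_genes": sorted(shared),
    }
    assert len(compound_union & disease_union) == config.overlap_size
    return per_compound, disease_sources, manifest


# ---------------------------------------------------------------------------
# PPI graph with planted hubs
# ---------------------------------------------------------------------------


def gen_ppi_with_hubs(
    config: SynthConfig, nodes: Optional[Sequence[str]] = None
) -> tuple[list[EdgeRecord], list[str], dict]:
    """Random interaction graph with hubs planted to dominate all hub metrics.

    A baseline Erdos-Renyi graph at ``edge_density`` is augmented, for
    boost > 1, with (i) a clique among the hubs — which drives MCC — and
    (ii) per-hub stars of (boost - 1) x mean-baseline-degree extra
    neighbors — which drive degree, closeness, betweenness and MNC.  At
    boost = 1 the hubs are ordinary nodes (negative control).  Kept edges
    score >= 0.4; a fraction of extra sub-threshold edges (score < 0.4)
    exercises the confidence filter.  ``n_unmapped`` non-hub nodes are
    withheld from all edges, mirroring targets that map to no interaction.
    """
    rng = config.rng(salt=3)
    if nodes is None:
        nodes = _gene_symbols(config.n_genes)
    nodes = list(nodes)
    n = len(nodes)
    if config.n_hubs >= n:
        raise ValueError("more hubs than nodes")
    perm = rng.permutation(n)
    hubs = sorted(nodes[i] for i in perm[: config.n_hubs])
    withheld = sorted(nodes[i] for i in perm[config.n_hubs : config.n_hubs + config.n_unmapped])
    blocked = set(withheld)

    pairs: set[tuple[str, str]] = set()
    if config.edge_density > 0 and n >= 2:
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(len(iu)) < config.edge_density
        for i, j in zip(iu[mask], ju[mask]):
            a, b = nodes[i], nodes[j]
            if a in blocked or b in blocked:
                continue
            pairs.add((a, b) if a < b else (b, a))

    mean_deg = max(1.0, config.edge_density * (n - 1))
    if config.hub_degree_boost > 1:
        for i, h in enumerate(hubs):  # shared hub clique
            for g in hubs[i + 1 :]:
                pairs.add((h, g) if h < g else (g, h))
        candidates = [v for v in nodes if v not in blocked and v not in hubs]
        extra = int(round((config.hub_degree_boost - 1) * mean_deg))
        extra = min(extra, len(candidates))
        for h in hubs:
            idx = rng.choice(len(candidates), size=extra, replace=False)
            for i in idx:
                v = candidates[i]
                pairs.add((h, v) if h < v else (v, h))

    kept_edges = [
        EdgeRecord(a, b, float(round(rng.uniform(0.4, 1.0), 3))) for a, b in sorted(pairs)
    ]
    n_sub = int(round(config.edge_subthreshold_fraction * len(kept_edges)))
    sub_edges: list[EdgeRecord] = []
    attempts = 0
    while len(sub_edges) < n_sub and attempts < 20 * max(n_sub, 1):
        attempts += 1
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        a, b = nodes[int(i)], nodes[int(j)]
        key = (a, b) if a < b else (b, a)
        if key in pairs or a in blocked or b in blocked:
            continue
        pairs.add(key)
        sub_edges.append(EdgeRecord(key[0], key[1], float(round(rng.uniform(0.15, 0.399), 3))))
    manifest = {
        "hubs": hubs,
        "withheld_nodes": withheld,
        "n_edges_kept": len(kept_edges),
        "n_edges_subthreshold": len(sub_edges),
        "n_graph_nodes": n,
    }
    edges = sorted(kept_edges + sub_edges, key=lambda e: e.key)
    return edges, hubs, manifest


# ---------------------------------------------------------------------------
# annotation terms
# ---------------------------------------------------------------------------


def gen_gene_sets(
    config: SynthConfig,
    background_genes: Optional[Sequence[str]] = None,
    seed_members: Optional[Sequence[str]] = None,
) -> tuple[GeneSetCollection, TargetSet, dict]:
    """Random flat terms plus one planted enriched term and a matching query.

    The planted term has ``planted_term_size`` members; the emitted query
    draws a fraction ``planted_term_overlap`` of its genes from that term
    and the rest from elsewhere in the background.  ``seed_members`` forces
    specific genes into the planted term (used by the bundle generator to
    anchor it on the planted hubs).
    """
    rng = config.rng(salt=4)
    if background_genes is None:
        background_genes = _gene_symbols(config.enrichment_background_size)
    bg = list(dict.fromkeys(background_genes))
    N = len(bg)
    K = min(config.planted_term_size, N)
    planted_members: set[str] = set(seed_members or ())
    remaining = [g for g in bg if g not in planted_members]
    need = K - len(planted_members)
    if need > 0:
        idx = rng.choice(len(remaining), size=need, replace=False)
        planted_members |= {remaining[i] for i in idx}
    planted = GeneSet("T0000", "planted term", frozenset(planted_members), "synthetic")

    lo, hi = config.term_size_range
    members_by_term: dict[int, set[str]] = {}
    for t in range(1, config.n_terms + 1):
        size = int(rng.integers(lo, min(hi, N) + 1))
        idx = rng.choice(N, size=size, replace=False)
        members_by_term[t] = {bg[i] for i in idx}
    # pad so the term union covers the whole background: the default ORA
    # background (union of members) then equals N as recorded here
    if members_by_term:
        covered = set(planted_members).union(*members_by_term.values())
        for g in (g for g in bg if g not in covered):
            members_by_term[int(rng.integers(1, config.n_terms + 1))].add(g)
    terms = [planted] + [
        GeneSet(f"T{t:04d}", f"random term {t}", frozenset(members_by_term[t]), "synthetic")
        for t in sorted(members_by_term)
    ]
    collection = GeneSetCollection(terms)

    n_query = min(config.enrichment_query_size, N)
    k = int(round(config.planted_term_overlap * n_query))
    k = min(k, len(planted_members))
    in_members = sorted(planted_members)
    idx = rng.choice(len(in_members), size=k, replace=False)
    query = {in_members[i] for i in idx}
    outside = [g for g in bg if g not in planted_members]
    idx = rng.choice(len(outside), size=n_query - k, replace=False)
    query |= {outside[i] for i in idx}
    query_set = TargetSet("planted_query", frozenset(query))
    manifest = {
        "planted_term_id": planted.term_id,
        "k": k,
        "K": len(planted_members),
        "n": len(query),
        "N": N,
        "n_terms": len(collection),
    }
    return collection, query_set, manifest


# ---------------------------------------------------------------------------
# docking scores
# ---------------------------------------------------------------------------


def gen_docking_scores(
    config: SynthConfig, compounds: Sequence[str], targets: Sequence[str]
) -> tuple[DockingMatrix, dict]:
    """Uniform favorable binding energies, 1-3 poses per pair."""
    rng = config.rng(salt=5)
    lo, hi = config.docking_energy_range
    matrix = DockingMatrix()
    for c in compounds:
        for t in targets:
            for _ in range(int(rng.integers(1, 4))):
                matrix.add(c, t, float(round(rng.uniform(lo, hi), 1)))
    manifest = {"n_docking_pairs": len(matrix)}
    return matrix, manifest


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------


def gen_bundle(config: SynthConfig, out_dir) -> dict:
    """Generate every pipeline input under ``out_dir`` plus manifest.json.

    Layout: compounds.tsv, compound_targets/<compound>.txt, disease_sources/
    (three plain lists plus genecards.tsv with a gifts column),
    ppi_edges.tsv (over the planted overlap genes, sub-threshold edges
    included), genesets.gmt, docking_scores.tsv, manifest.json and a ready
    pipeline.yaml.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config)}

    records, m_panel = gen_compound_panel(config)
    manifest.update(m_panel)
    write_compound_table(records, out / "compounds.tsv")

    passers = m_panel["passer_names"]
    per_compound, disease_sources, m_targets = gen_target_universes(config, passers)
    shared = m_targets.pop("shared_genes")
    manifest.update(m_targets)
    ct_dir = out / "compound_targets"
    ct_dir.mkdir(exist_ok=True)
    for name, ts in per_compound.items():
        write_gene_list(ts, ct_dir / f"{name}.txt")
    ds_dir = out / "disease_sources"
    ds_dir.mkdir(exist_ok=True)
    for ts in disease_sources:
        if isinstance(ts, ScoredTargetSet):
            path = ds_dir / f"{ts.label}.tsv"
            with open(path, "w", encoding="utf-8") as fh:
                fh.write("symbol\tgifts\n")
                for sym in sorted(ts.scores):
                    fh.write(f"{sym}\t{ts.scores[sym]!r}\n")
        else:
            write_gene_list(ts, ds_dir / f"{ts.label}.txt")

    edges, hubs, m_ppi = gen_ppi_with_hubs(config, nodes=shared)
    manifest.update(m_ppi)
    write_edge_table(edges, out / "ppi_edges.tsv")

    collection, _, m_sets = gen_gene_sets(config, background_genes=shared, seed_members=hubs)
    manifest["geneset_manifest"] = m_sets
    write_gmt(collection, out / "genesets.gmt")

    dock_compounds = passers[: config.n_docking_compounds]
    matrix, m_dock = gen_docking_scores(config, dock_compounds, hubs)
    manifest.update(m_dock)
    write_docking_table(matrix, out / "docking_scores.tsv")

    pipeline_cfg = {
        "compounds": str(out / "compounds.tsv"),
        "compound_targets_dir": str(ct_dir),
        "disease_sources_dir": str(ds_dir),
        "gifts_column": "gifts",
        "gifts_direction": "at_or_below",
        "edges": str(out / "ppi_edges.tsv"),
        "min_score": 0.4,
        "hub_k": 10,
        "hub_metrics": ["dc", "cc", "mnc", "mcc"],
        "gmt": [str(out / "genesets.gmt")],
        "docking_scores": str(out / "docking_scores.tsv"),
        "docking_threshold": -5.0,
        "drug": "HEF",
        "disease": "depression",
        "out_dir": str(out / "results"),
    }
    import yaml

    with open(out / "pipeline.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(pipeline_cfg, fh, sort_keys=True)
    write_json(manifest, out / "manifest.json")
    return manifest
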