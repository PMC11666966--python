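"""End-to-end orchestration of the screening chain.

Stages run in a fixed order — compound screen, target assembly, PPI
centrality screen, hub intersection, enrichment, CDTD network, docking
summary — each reading the previous stage's in-memory results and writing
deterministic artifacts into the output directory.  Stages whose inputs
are absent are skipped and recorded as such.  A machine-readable run
report (stage, status, counts, medians, warnings) is written alongside
the artifacts; logs never interleave with data files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import formats_io as fio
from .cdtd_network import build_cdtd, compound_degree_ranking, summarize_docking
from .compound_screen import ScreenConfig, dedup_compounds, filter_adme
from .enrichment import EnrichmentConfig, GeneSetCollection, rows_to_frame, run_ora
from .ppi_centrality import (
    build_graph,
    central_intersection,
    centrality_table,
    median_core_screen,
    top_k,
)
from .target_assembly import (
    TargetSet,
    gifts_median_filter,
    intersect_sets,
    union_sources,
    venn_regions,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run, YAML-loadable."""

    out_dir: str
    compounds: Optional[str] = None
    compound_targets_dir: Optional[str] = None
    disease_sources_dir: Optional[str] = None
    gifts_column: str = "gifts"
    gifts_direction: str = "at_or_below"
    edges: Optional[str] = None
    gmt: Sequence[str] = field(default_factory=list)
    docking_scores: Optional[str] = None
    ob_min: float = 30.0
    dl_min: float = 0.18
    min_score: float = 0.4
    hub_k: int = 10
    hub_metrics: Sequence[str] = ("dc", "cc", "mnc", "mcc")
    p_cutoff: float = 0.05
    min_overlap: int = 3
    min_enrichment: float = 1.5
    docking_threshold: float = -5.0
    drug: str = "drug"
    disease: str = "disease"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)


def _exists(path: Optional[str]) -> bool:
    return path is not None and Path(path).exists()


def _read_gene_list_dir(directory: str, gifts_column: str, gifts_direction: str):
    """Read every gene list in a directory; .tsv files with the GIFTS column
    are median-filtered, everything else is taken verbatim."""
    sets = []
    gifts_info = {}
    for path in sorted(Path(directory).iterdir()):
        if path.suffix == ".tsv":
            head = path.read_text(encoding="utf-8").splitlines()
            if head and gifts_column in head[0].split("\t"):
                scored = fio.read_gene_list(path, score_column=gifts_column)
                filtered = gifts_median_filter(scored, gifts_direction)
                gifts_info[path.stem] = {
                    "raw": len(scored),
                    "kept": len(filtered.genes),
                }
                sets.append(TargetSet(path.stem, filtered.genes))
                continue
        if path.suffix in (".txt", ".tsv", ".list", ""):
            ts = fio.read_gene_list(path)
            sets.append(TargetSet(path.stem, ts.genes))
    return sets, gifts_info


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every runnable stage and return the run report (also written
    to <out_dir>/report.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": []}
    collected_warnings: list[str] = []

    def record(name: str, status: str, **counts) -> None:
        report["stages"].append({"stage": name, "status": status, **counts})

    kept = None
    core = None
    potential = None
    table = None
    per_compound = None

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # ---- stage 1: compound screen ------------------------------------
        if _exists(config.compounds):
            records = fio.read_compound_table(config.compounds)
            deduped = dedup_compounds(records)
            kept, dropped = filter_adme(deduped, ScreenConfig(config.ob_min, config.dl_min))
            fio.write_compound_table(kept, out / "kept.tsv")
            fio.write_compound_table([d.record for d in dropped], out / "dropped.tsv")
            record(
                "screen",
                "completed",
                n_input=len(records),
                n_deduped=len(deduped),
                n_kept=len(kept),
                n_dropped=len(dropped),
            )
        else:
            record("screen", "skipped")

        # ---- stage 2: target assembly ------------------------------------
        if _exists(config.compound_targets_dir) and _exists(config.disease_sources_dir):
            ct_sets, _ = _read_gene_list_dir(config.compound_targets_dir, "", "at_or_below")
            compound_union = union_sources(ct_sets).merged
            per_compound = {ts.label: ts for ts in ct_sets}
            ds_sets, gifts_info = _read_gene_list_dir(
                config.disease_sources_dir, config.gifts_column, config.gifts_direction
            )
            disease_union = union_sources(ds_sets).merged
            potential = intersect_sets(compound_union, disease_union)
            fio.write_gene_list(TargetSet("potential", potential.genes), out / "potential.txt")
            fio.write_json(
                venn_regions([TargetSet("compound", compound_union.genes),
                              TargetSet("disease", disease_union.genes)]),
                out / "venn.json",
            )
            record(
                "targets",
                "completed",
                n_compound_sources=len(ct_sets),
                n_disease_sources=len(ds_sets),
                compound_union=len(compound_union.genes),
                disease_union=len(disease_union.genes),
                gifts=gifts_info,
                n_potential=len(potential.genes),
            )
        else:
            record("targets", "skipped")

        # ---- stage 3: PPI centrality + core screen -----------------------
        if _exists(config.edges) and potential is not None:
            edge_records = fio.read_edge_table(config.edges, config.min_score)
            graph = build_graph(edge_records, required_nodes=potential)
            table = centrality_table(graph)
            table.to_csv(out / "centrality.tsv", sep="\t", index=False)
            screen = median_core_screen(graph, table)
            core = TargetSet("core", screen.core)
            fio.write_gene_list(core, out / "core.txt")
            record(
                "ppi",
                "completed",
                n_targets=len(potential.genes),
                n_nodes=graph.n_nodes,
                n_nonisolated=graph.n_nodes - len(graph.isolated_nodes()),
                n_edges=graph.n_edges,
                medians=screen.medians,
                n_core=len(core.genes),
            )
        else:
            record("ppi", "skipped")

        # ---- stage 4: hub intersection -----------------------------------
        if table is not None:
            lists = {m: top_k(table, m, config.hub_k) for m in config.hub_metrics}
            central = central_intersection({m: tl.members for m, tl in lists.items()})
            fio.write_gene_list(TargetSet("central", central), out / "central.txt")
            record(
                "hubs",
                "completed",
                k=config.hub_k,
                metrics=list(config.hub_metrics),
                boundary_ties={m: tl.boundary_tie for m, tl in lists.items()},
                n_central=len(central),
            )
        else:
            record("hubs", "skipped")

        # ---- stage 5: enrichment -----------------------------------------
        gmt_paths = [p for p in config.gmt if Path(p).exists()]
        if gmt_paths and core is not None and core.genes:
            terms = []
            for p in gmt_paths:
                terms.extend(fio.read_gmt(p, category=Path(p).stem).terms)
            collection = GeneSetCollection(terms)
            rows = run_ora(
                core,
                collection,
                EnrichmentConfig(config.p_cutoff, config.min_overlap, config.min_enrichment),
            )
            rows_to_frame(rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)
            record(
                "enrich",
                "completed",
                n_terms=len(collection),
                n_tested=len(rows),
                n_significant=sum(r.significant for r in rows),
            )
        else:
            record("enrich", "skipped")

        # ---- stage 6: CDTD network ---------------------------------------
        if kept is not None and per_compound is not None and core is not None:
            per_kept = {c.name: per_compound[c.name] for c in kept if c.name in per_compound}
            net = build_cdtd(config.drug, kept, per_kept, core, config.disease)
            fio.write_network_export(net, out / "cdtd")
            ranking = compound_degree_ranking(net)
            with open(out / "compound_ranking.tsv", "w", encoding="utf-8") as fh:
                fh.write("compound\tdegree\n")
                for name, deg in ranking.entries:
                    fh.write(f"{name}\t{deg}\n")
            record(
                "network",
                "completed",
                n_nodes=net.n_nodes,
                n_edges=net.n_edges,
                top_compound=ranking.entries[0][0] if ranking.entries else None,
                tied_degrees=sorted(ranking.tied_degrees),
            )
        else:
            record("network", "skipped")

        # ---- stage 7: docking summary ------------------------------------
        if _exists(config.docking_scores):
            matrix = fio.read_docking_table(config.docking_scores)
            if len(matrix):
                summary = summarize_docking(matrix, config.docking_threshold)
                with open(out / "dock_summary.tsv", "w", encoding="utf-8") as fh:
                    fh.write("compound\ttarget\tbest_energy\tgood\n")
                    for (c, t) in sorted(summary.best):
                        fh.write(
                            f"{c}\t{t}\t{summary.best[(c, t)]!r}\t"
                            f"{int(summary.good[(c, t)])}\n"
                        )
                summary.heatmap().to_csv(out / "dock_heatmap.tsv", sep="\t")
                record(
                    "dock_summary",
                    "completed",
                    n_pairs=len(summary.best),
                    n_good=sum(summary.good.values()),
                )
            else:
                record("dock_summary", "skipped")
        else:
            record("dock_summary", "skipped")

        collected_warnings = [str(w.message) for w in caught]

    report["warnings"] = sorted(set(collected_warnings))
    report["n_completed"] = sum(1 for s in report["stages"] if s["status"] == "completed")
    fio.write_json(report, out / "report.json")
    return report
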