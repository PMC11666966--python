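# netpharm

Network-pharmacology target screening as a tested, reusable pipeline.

Herbal medicines act through many compounds hitting many proteins at once.
The standard way to nominate the therapeutic targets of an edible or
medicinal plant — here modeled on a screen of *Hemerocallis citrina*
(daylily) edible flower against depression — chains together half a dozen
web tools (TCMSP/HERB for compounds, SwissTargetPrediction/SEA for targets,
GeneCards/DisGeNet/OMIM/DrugBank for disease genes, STRING + Cytoscape for
network analysis, Metascape for enrichment, AutoDock Vina for docking).
That chain is hard to audit and impossible to rerun once the database
snapshots move. `netpharm` reimplements every desk-side computation of
that chain as a library with file-based inputs, so each step is exact,
deterministic and testable — and ships a seeded synthetic-data generator
that replaces the live databases with planted, manifest-recorded structure.

## What it computes

1. **ADME compound screen** — keep compounds with oral bioavailability
   OB ≥ 30 % and drug-likeness DL ≥ 0.18 (inclusive), with an auditable
   record of what was dropped and why.
2. **Target assembly** — per-source gene lists are uppercased, deduplicated
   and unioned; the GeneCards-style source is reduced to genes with GIFTS
   score at or below the median; candidate therapeutic targets are the
   intersection of the compound-target and disease-target universes, with
   an exact Venn-region report.
3. **PPI centrality screen** — from a STRING-style edge table (combined
   score ≥ 0.4), five hub metrics are computed natively on the unweighted
   simple graph:
   - degree `DC(v) = |N(v)|`;
   - betweenness `BC(v) = Σ_{s<t, s≠v≠t} σ_st(v)/σ_st` (Brandes, unordered
     pairs, unnormalized);
   - closeness `CC(v) = r(v) / Σ_{u reachable} d(v,u)`, isolated nodes 0;
   - maximal clique centrality `MCC(v) = Σ_{C ∋ v, |C|≥2} (|C|−1)!` over
     maximal cliques (Bron–Kerbosch with pivoting);
   - maximum neighborhood component `MNC(v)` = size of the largest
     connected component of the subgraph induced by `N(v)`.

   **Core targets** are the nodes strictly above the median of DC, BC and
   CC simultaneously; **central targets** are the intersection of the
   top-10 lists under DC, CC, MNC and MCC.
4. **Over-representation analysis** — hypergeometric upper tail
   `P(X ≥ k)` for a query of `n` genes against terms of size `K` in a
   background of `N`, enrichment factor `(k/n)/(K/N)`, Benjamini–Hochberg
   q-values; significance flags use the conventional screen
   (p < 0.05, overlap ≥ 3, enrichment ≥ 1.5).
5. **Drug–compounds–targets–disease network** — typed multipartite network;
   compounds ranked by core-target degree; SIF + node-attribute export.
6. **Docking summary** — per compound–target pair the best (minimum)
   binding energy over poses, per-target best binder(s) with ties kept,
   and a strict "good binding" flag below −5.0 kcal/mol.

## Worked example

The package ships the published worked-example tables: the 24-compound
screened daylily-flower panel, the four published top-10 hub lists, and
the published per-target best docking energies.

```python
from netpharm import filter_adme, dedup_compounds, central_intersection
from netpharm.cdtd_network import summarize_docking
from netpharm.reference import (
    HUB_METRIC_FILES, load_compound_panel, load_hub_top10, load_docking_energies,
)

panel = dedup_compounds(load_compound_panel())
kept, dropped = filter_adme(panel)
print(f"{len(kept)} kept, {len(dropped)} dropped "
      f"({dropped[0].record.name}: OB {dropped[0].record.ob})")

lists = {m: sorted(load_hub_top10(m).genes) for m in HUB_METRIC_FILES}
print("central:", ", ".join(sorted(central_intersection(lists))))

summary = summarize_docking(load_docking_energies())
print("AKT1 best binder:", summary.best_binders["AKT1"])
```

prints

```
23 kept, 1 dropped (3-O-Feruloylquinic acid: OB 25.51)
central: AKT1, CASP3, IL6, JUN, TNF, TP53
AKT1 best binder: (('Quercetin', -8.7),)
```

Reading: one compound of the published 24-compound panel actually sits
below the stated OB ≥ 30 threshold (the screen reports it rather than
hiding the inconsistency); the four hub lists intersect to six central
targets; and quercetin is AKT1's strongest predicted binder at
−8.7 kcal/mol (below −5.0, i.e. a good predicted binding).

## Command line

```sh
netpharm simulate --seed 11 --out bundle/    # synthetic inputs + manifest.json
netpharm run --config bundle/pipeline.yaml   # full screening chain
```

Subcommands `screen`, `ppi`, `hubs`, `enrich`, `network` and
`dock-summary` expose the individual stages; `netpharm run` chains them
and writes a machine-readable `report.json` whose stage counts are
cross-checkable against the generator's `manifest.json`.

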