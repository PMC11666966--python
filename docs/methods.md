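# Methods

## Scope and model

`netpharm` implements the desk-side computations of a network-pharmacology
target screen: compound filtering, target-set algebra, graph centrality
screening, over-representation analysis, multipartite network ranking and
docking-score summarization. It deliberately does **not** query any live
database, map identifiers through UniProt, compute OB/DL from structure,
or run a docking engine: compound tables, gene lists, interaction tables,
GMT collections and docking energies are consumed as files, and a seeded
generator produces synthetic stand-ins for all of them.

## Conventions that matter

**Gene symbols.** Normalization is trim + uppercase only. No alias or
cross-identifier mapping is attempted; two spellings of the same protein
(e.g. a hyphenated cytokine name vs its HGNC symbol) are different nodes.
The packaged reference lists therefore use HGNC symbols.

**Screening thresholds.** The OB/DL screen is inclusive (≥ 30, ≥ 0.18): a
compound exactly on a threshold passes. The STRING-style confidence
filter is likewise keep-if ≥ threshold, since the cutoff is a *minimum
required* score. Both 0–1 decimal and 0–1000 integer score dialects are
accepted; any value in (1, 1000] is divided by 1000.

**Medians.** The GIFTS filter and the core screen both use the standard
sample median (mean of the two central order statistics for even n). The
GIFTS filter is *inclusive* ("at or below"); keeping the lower-scored half
of a functionality score is unusual, so the direction is exposed as a
flag with "at_or_below" as the default. The core screen is *strict*
("higher than the median"), so any metric that is constant across the
graph — e.g. on a vertex-transitive graph — empties the core. Core-screen
medians are taken over every node of the built graph, isolated required
nodes included; this is the conservative reading when some candidate
targets receive no interaction.

**Betweenness** counts unordered pairs, excludes endpoints and is not
normalized. Conventions differ between tools by a factor of two; this one
matches the Cytoscape-plugin convention that the screening procedure
assumes, and the oracle tests pin it against networkx with
`normalized=False`.

**Closeness** uses the reachable-set form `r(v) / Σ d(v, u)`, which equals
`(n−1)/Σd` on a connected graph, degrades gracefully on disconnected
graphs, and scores isolated nodes 0. It is *not* the Wasserman–Faust
variant (no `r/(n−1)` rescaling), so values across components of different
sizes are comparable only within a component — acceptable here because
the screen only thresholds at the median and takes top-k lists.

**MCC** enumerates maximal cliques of size ≥ 2 via Bron–Kerbosch with
pivoting and sums `(|C|−1)!`. Singleton cliques are excluded so isolated
nodes score 0; when a node's neighbors are pairwise non-adjacent, every
incident edge is a maximal 2-clique and MCC reduces to degree. A budget
(default 2·10⁶ maximal cliques) turns pathological inputs into a clear
resource error instead of an unbounded run.

**Top-k lists** break ties lexicographically for determinism and raise a
`boundary_tie` flag whenever rank k and k+1 share a value — exactly the
situation where a GUI tool's arbitrary tie-break would silently change
hub membership.

**Centralities are unweighted.** Confidence scores act only in edge
filtering; the metrics are computed on the simple unweighted graph.

**Enrichment.** Terms are flat gene sets with a category label; no
ontology propagation or term-redundancy clustering. The background
defaults to the union of all term members (the common web-tool behavior)
and can be overridden by an explicit universe — the choice changes N
materially and is therefore a visible parameter. Only terms with k ≥ 1
are tested; Benjamini–Hochberg runs over exactly the tested terms. The
significance flag tests the *raw* p (p < 0.05, k ≥ 3, enrichment ≥ 1.5)
as the conventional screen does; q is reported and can be made the flag
basis instead.

**Docking.** Lower energy = stronger predicted binding. The per-pair best
is the minimum over poses; per-target best binders keep ties jointly
(the reference data itself contains a two-way tie); the "good binding"
flag is strict (< −5.0 kcal/mol).

**CDTD degrees.** A compound's degree counts compound–target edges only
(not the mandatory drug edge, not disease wiring), so the ranking equals
per-compound core-target counts. Target–disease edges are included in the
network by default and can be switched off.

## Synthetic-data generator

The generator's defaults are the study conditions of the screen it
emulates: 830 raw phytochemicals of which exactly 24 pass the OB/DL
screen; a 614-gene compound-target universe and a GIFTS-scored
10,031-gene disease source (plus unscored sources of 95, 2,496 and
6 genes) sharing an exactly planted 449-gene overlap; 5 of those genes
receive no interactions (mirroring candidates that map to no network
node, 449 → 444); six planted hubs; one planted enriched term. Baseline
interaction density defaults to 0.03 (mean degree ≈ 13 on the 449-node
graph), a typical medium-confidence subnetwork density at this scale.

Hub planting combines two devices, because no single random-graph family
makes all four hub metrics agree: a shared clique among the hubs drives
MCC, and per-hub stars of `(boost − 1) ×` mean-baseline-degree extra
neighbors drive degree, closeness, betweenness and MNC. At
`hub_degree_boost = 1` neither device is added, so hubs are statistically
ordinary nodes — the negative control. A configurable fraction of
sub-threshold edges (score < 0.4) is emitted so the confidence filter is
exercised end-to-end.

GIFTS scores are uniform on [0, 60] (continuous, so the median filter
keeps ⌈n/2⌉ genes — unlike real GIFTS, which is heavily tied); the
planted overlap genes are anchored in an *unscored* source so the median
filter cannot erode the planted intersection. Random annotation terms are
padded to cover the whole background, so the default ORA background
equals the manifest's N. Docking energies are uniform on
[−9.5, −5.2] kcal/mol with 1–3 poses per pair.

Every planted quantity is written to `manifest.json`; tests and the
pipeline report are checked against the manifest, never against a
re-derivation. All generators are pure functions of
`(configuration, seed)` and byte-deterministic.

**What the generator does not emulate:** real STRING degree
distributions and clustering, realistic OB/DL marginals, tied GIFTS
scores, correlated term memberships, or symbol aliasing. Passing tests
demonstrate that the *procedures* are implemented exactly and recover
planted structure under fair conditions — not that any particular
biological conclusion is reproducible from live databases.

## Numerical choices

- Hypergeometric tails come from `scipy.stats.hypergeom.sf(k−1, N, K, n)`;
  an exhaustive test checks every (k, K, n, N) with N ≤ 30 against exact
  rational arithmetic (`fractions.Fraction` + `math.comb`).
- BH q-values come from `statsmodels.stats.multitest.multipletests`
  (`fdr_bh`); a test re-derives the step-up by hand from the emitted
  p-values.
- Numeric fields accept the Unicode minus (U+2212), which published
  energy tables use.
- Duplicate handling is max-keep for scores and first-wins for names,
  applied uniformly across readers.
- Degenerate inputs fail loudly: empty graphs cannot be median-screened,
  empty score sets have no median, empty docking matrices cannot be
  summarized; empty *gene list files* are tolerated with a warning since
  a source legitimately may contribute nothing.

## Pipeline sizes and determinism

The end-to-end pipeline at the default (full-scale) synthetic conditions —
12,000-gene universe, 449-node PPI with ~3,200 edges, 51 terms — runs in
well under a minute on one CPU; the hub-recovery experiment (n = 300,
50 seeds, boosted and control arms) takes a few tens of seconds. Reports
and artifacts contain no timestamps, so re-running with identical inputs
is byte-identical.

## Known limitations

- One screening round only: the core screen is a single DC/BC/CC median
  pass; iterative re-screening is not performed.
- The published 24-compound panel contains one compound (OB 25.51) that
  fails the stated OB ≥ 30 screen. The package treats the panel and the
  filter as separate, honest artifacts: parsing the panel yields 24
  records, filtering yields 23 kept + 1 dropped with the reason recorded.
  No attempt is made to guess which behavior was intended upstream.
- Headline counts of any real screen (target-universe sizes, core-target
  counts, enrichment term lists, docking energies) depend on database
  snapshots and a stochastic docking engine; they are mirrored here by
  planted synthetic scale, not reproduced.
- Closeness comparisons across components of very different sizes are
  only meaningful through the median/top-k screens used here.
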