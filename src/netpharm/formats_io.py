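"""Readers and writers for every external file the pipeline touches.

All tabular inputs are UTF-8 TSV; lines starting with '#' are comments and
blank lines are skipped.  Gene sets travel as GMT, networks are exported as
SIF plus a node-attribute TSV, and all writers emit deterministic
(sorted) byte streams so identical inputs produce identical files.

Conventions applied uniformly:

* gene symbols are normalized by trimming and uppercasing, nothing more;
* duplicate scored entries keep the maximum score; duplicate names keep
  the first occurrence;
* numeric fields accept both the ASCII hyphen and the Unicode minus
  (U+2212), which shows up in published energy tables;
* STRING-style edge scores are accepted in either the 0-1 decimal or the
  0-1000 integer dialect and normalized to [0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .cdtd_network import CDTDNetwork, DockingMatrix
from .compound_screen import CompoundRecord
from .enrichment import GeneSet, GeneSetCollection
from .target_assembly import ScoredTargetSet, TargetSet, normalize_symbol

__all__ = [
    "FormatError",
    "EdgeRecord",
    "read_compound_table",
    "write_compound_table",
    "read_gene_list",
    "write_gene_list",
    "read_edge_table",
    "write_edge_table",
    "read_gmt",
    "write_gmt",
    "write_network_export",
    "read_docking_table",
    "write_docking_table",
    "write_json",
]

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A file violates the expected format."""


@dataclass(frozen=True)
class EdgeRecord:
    """One undirected interaction with a confidence score in [0, 1].

    Endpoints are stored in sorted order so an EdgeRecord is a canonical
    representation of the unordered pair.
    """

    node_a: str
    node_b: str
    score: float

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise ValueError(f"self-loop on {self.node_a!r}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.node_a > self.node_b:
            a, b = self.node_b, self.node_a
            object.__setattr__(self, "node_a", a)
            object.__setattr__(self, "node_b", b)

    @property
    def key(self) -> tuple[str, str]:
        return (self.node_a, self.node_b)


def _parse_number(text: str, path: PathLike, lineno: int, column: str) -> float:
    cleaned = text.strip().replace("−", "-")
    try:
        return float(cleaned)
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: cannot parse {column}={text!r} as a number"
        ) from None


def _data_lines(path: PathLike) -> list[tuple[int, str]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            out.append((lineno, line))
    return out


def _read_tsv(path: PathLike) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Header + rows of a TSV file; every row padded/validated later by callers."""
    lines = _data_lines(path)
    if not lines:
        return [], []
    header = [h.strip() for h in lines[0][1].split("\t")]
    if len(set(header)) != len(header):
        raise FormatError(f"{path}: duplicate column names in header")
    rows = [(lineno, line.split("\t")) for lineno, line in lines[1:]]
    for lineno, fields in rows:
        if len(fields) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
    return header, rows


# ---------------------------------------------------------------------------
# compound tables
# ---------------------------------------------------------------------------

_COMPOUND_MANDATORY = ("pubchem_id", "name", "ob", "dl")


def read_compound_table(path: PathLike) -> list[CompoundRecord]:
    """Read a compound panel (columns pubchem_id, name, ob, dl [, smiles, target_count]).

    Duplicate pubchem ids are rejected: deduplication is an explicit
    pipeline step, not a silent reader behavior.
    """
    header, rows = _read_tsv(path)
    if not header:
        return []
    for col in _COMPOUND_MANDATORY:
        if col not in header:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    idx = {col: header.index(col) for col in header}
    records: list[CompoundRecord] = []
    seen_ids: set[str] = set()
    for lineno, fields in rows:
        pid = fields[idx["pubchem_id"]].strip() or None
        if pid is not None:
            if pid in seen_ids:
                raise FormatError(f"{path}:{lineno}: duplicate pubchem_id {pid!r}")
            seen_ids.add(pid)
        target_count: Optional[int] = None
        if "target_count" in idx and fields[idx["target_count"]].strip():
            target_count = int(
                _parse_number(fields[idx["target_count"]], path, lineno, "target_count")
            )
        records.append(
            CompoundRecord(
                pubchem_id=pid,
                name=fields[idx["name"]].strip(),
                ob=_parse_number(fields[idx["ob"]], path, lineno, "ob"),
                dl=_parse_number(fields[idx["dl"]], path, lineno, "dl"),
                smiles=(fields[idx["smiles"]].strip() or None) if "smiles" in idx else None,
                target_count=target_count,
            )
        )
    return records


def write_compound_table(records: Sequence[CompoundRecord], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pubchem_id\tname\tob\tdl\tsmiles\ttarget_count\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.pubchem_id or "",
                        r.name,
                        repr(r.ob),
                        repr(r.dl),
                        r.smiles or "",
                        "" if r.target_count is None else str(r.target_count),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# gene lists
# ---------------------------------------------------------------------------


def read_gene_list(
    path: PathLike,
    score_column: Optional[str] = None,
    label: Optional[str] = None,
) -> Union[TargetSet, ScoredTargetSet]:
    """Read a gene list (one symbol per line, or TSV with a score column).

    Without ``score_column`` the first tab-field of every line is taken as
    a symbol (a leading 'symbol' header line is tolerated).  With it, the
    file must be a TSV whose header names the score column; the symbol
    column is the one named 'symbol', else the first column.  Duplicates
    collapse keeping the maximum score.  The set label defaults to the
    file stem.
    """
    label = label if label is not None else Path(path).stem
    lines = _data_lines(path)
    if not lines:
        warnings.warn(f"{path}: empty gene list", stacklevel=2)
        return (
            ScoredTargetSet(label, {}) if score_column else TargetSet(label, frozenset())
        )
    if score_column is None:
        symbols = []
        for i, (lineno, line) in enumerate(lines):
            sym = line.split("\t")[0]
            if i == 0 and sym.strip().lower() == "symbol":
                continue
            symbols.append(sym)
        return TargetSet.from_symbols(label, symbols)

    header, rows = _read_tsv(path)
    if score_column not in header:
        raise FormatError(f"{path}: missing score column {score_column!r}")
    sym_col = header.index("symbol") if "symbol" in header else 0
    score_col = header.index(score_column)
    scores: dict[str, float] = {}
    for lineno, fields in rows:
        sym = normalize_symbol(fields[sym_col])
        if not sym:
            continue
        value = _parse_number(fields[score_col], path, lineno, score_column)
        scores[sym] = max(value, scores.get(sym, float("-inf")))
    return ScoredTargetSet(label, scores)


def write_gene_list(ts: Union[TargetSet, ScoredTargetSet], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if isinstance(ts, ScoredTargetSet):
            fh.write("symbol\tscore\n")
            for sym in sorted(ts.scores):
                fh.write(f"{sym}\t{ts.scores[sym]!r}\n")
        else:
            for sym in sorted(ts.genes):
                fh.write(sym + "\n")


# ---------------------------------------------------------------------------
# interaction edge tables
# ---------------------------------------------------------------------------


def _normalize_edge_score(value: float, path: PathLike, lineno: int) -> float:
    if 0.0 <= value <= 1.0:
        return value
    if 1.0 < value <= 1000.0:
        return value / 1000.0  # STRING combined_score dialect
    raise FormatError(
        f"{path}:{lineno}: score {value} outside both the [0,1] and the 0-1000 dialect"
    )


def read_edge_table(path: PathLike, score_threshold: float = 0.4) -> list[EdgeRecord]:
    """Read a STRING-style interaction table and filter by confidence.

    The first two columns are node symbols; the score column is the one
    named 'combined_score' or 'score' when a header is present, else the
    third column.  Self-loops are dropped, duplicate undirected pairs keep
    the maximum score, and only edges with score >= threshold survive
    (the threshold is a minimum required score, hence inclusive).  The
    result is sorted, so row order never matters.
    """
    lines = _data_lines(path)
    if not lines:
        return []
    first_fields = lines[0][1].split("\t")
    if len(first_fields) < 3:
        raise FormatError(f"{path}: edge table needs at least 3 columns")

    def _is_number(text: str) -> bool:
        try:
            float(text.strip().replace("−", "-"))
            return True
        except ValueError:
            return False

    has_header = not _is_number(first_fields[2])
    if has_header:
        header = [h.strip() for h in first_fields]
        if "combined_score" in header:
            score_idx = header.index("combined_score")
        elif "score" in header:
            score_idx = header.index("score")
        else:
            score_idx = 2
        data = lines[1:]
    else:
        score_idx = 2
        data = lines

    best: dict[tuple[str, str], float] = {}
    for lineno, line in data:
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: edge row needs at least 3 columns")
        a = normalize_symbol(fields[0])
        b = normalize_symbol(fields[1])
        score = _normalize_edge_score(
            _parse_number(fields[score_idx], path, lineno, "score"), path, lineno
        )
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        best[key] = max(score, best.get(key, 0.0))
    return [
        EdgeRecord(a, b, s)
        for (a, b), s in sorted(best.items())
        if s >= score_threshold
    ]


def write_edge_table(edges: Iterable[EdgeRecord], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node1\tnode2\tcombined_score\n")
        for e in sorted(edges, key=lambda e: e.key):
            fh.write(f"{e.node_a}\t{e.node_b}\t{e.score!r}\n")


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------


def read_gmt(path: PathLike, category: str = "") -> GeneSetCollection:
    """Read a standard GMT file: term_id TAB description TAB member..."""
    terms: list[GeneSet] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
        term = GeneSet.from_symbols(fields[0].strip(), fields[1].strip(), fields[2:], category)
        if not term.members:
            raise FormatError(f"{path}:{lineno}: term {term.term_id!r} has no members")
        terms.append(term)
    return GeneSetCollection(terms)


def write_gmt(collection: GeneSetCollection, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in collection:
            fh.write(
                "\t".join([term.term_id, term.term_name, *sorted(term.members)]) + "\n"
            )


# ---------------------------------------------------------------------------
# network export (SIF + node attributes)
# ---------------------------------------------------------------------------


def write_network_export(network: CDTDNetwork, prefix: PathLike) -> tuple[Path, Path]:
    """Write a network as SIF plus a node-attribute TSV.

    SIF lines are "source TAB relation TAB target", sorted, so the export
    is byte-identical across runs.  Returns (sif_path, nodes_path).
    """
    for a, b, rel in network.edges:
        for endpoint in (a, b):
            if endpoint not in network.nodes:
                raise FormatError(f"edge endpoint {endpoint!r} missing from node table")
    prefix = Path(prefix)
    sif_path = prefix.with_suffix(".sif")
    nodes_path = prefix.parent / (prefix.name + "_nodes.tsv")
    sif_lines = sorted(f"{a}\t{rel}\t{b}" for a, b, rel in network.edges)
    sif_path.write_text("\n".join(sif_lines) + ("\n" if sif_lines else ""), encoding="utf-8")
    with open(nodes_path, "w", encoding="utf-8") as fh:
        fh.write("node\tnode_type\tdegree\n")
        for node in sorted(network.nodes):
            fh.write(f"{node}\t{network.nodes[node]}\t{network.degree(node)}\n")
    return sif_path, nodes_path


# ---------------------------------------------------------------------------
# docking tables
# ---------------------------------------------------------------------------


def read_docking_table(path: PathLike) -> DockingMatrix:
    """Read a docking-score TSV (columns compound, target, energy).

    Repeated poses for one pair are all retained; picking the best pose is
    the summarizer's job.  Non-finite energies are row-level errors.
    """
    header, rows = _read_tsv(path)
    if not header:
        return DockingMatrix()
    for col in ("compound", "target", "energy"):
        if col not in header:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    idx = {col: header.index(col) for col in header}
    matrix = DockingMatrix()
    for lineno, fields in rows:
        energy = _parse_number(fields[idx["energy"]], path, lineno, "energy")
        try:
            matrix.add(
                fields[idx["compound"]].strip(),
                normalize_symbol(fields[idx["target"]]),
                energy,
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    return matrix


def write_docking_table(matrix: DockingMatrix, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("compound\ttarget\tenergy\n")
        for (compound, target) in sorted(matrix.entries):
            for energy in matrix.entries[(compound, target)]:
                fh.write(f"{compound}\t{target}\t{energy!r}\n")


def write_json(obj, path: PathLike) -> None:
    """Deterministic JSON dump (sorted keys, trailing newline)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
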