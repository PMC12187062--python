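"""Segmentation distance between two pangenome graphs.

For each genome shared by both graphs, the two paths induce two breakpoint
sets B_a and B_b on the same sequence.  The minimal edit set transforming
one segmentation into the other is their symmetric difference: a *merge*
removes a breakpoint private to the first graph, a *split* adds one
private to the second.  The per-genome distance is |B_a (+) B_b| and the
graph distance is its sum over shared genomes — a metric, since the
symmetric-difference cardinality is an XOR distance.

The scan is a single simultaneous pass with two cursors that advance to
the next closest breakpoint across both sets; it touches each element of
B_a ∪ B_b exactly once, so the per-genome cost is O(|B_a ∪ B_b|).
"""

from __future__ import annotations

import os
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import IO, Mapping, Optional, Union

from pansegdist.gfa_io import GFAError, PangenomeGraph, PathRecord, path_length
from pansegdist.segmentation import BreakpointSet, breakpoints_of_path, mask_spurious

__all__ = [
    "EditRecord",
    "ScanResult",
    "PathComparison",
    "DistanceReport",
    "segmentation_distance",
    "edit_records_for_path",
    "graph_distance",
    "write_edits_tsv",
    "read_edits_tsv",
    "EDITS_TSV_HEADER",
]

MERGE = "merge"
SPLIT = "split"
_OP_CODE = {MERGE: "M", SPLIT: "S"}
_CODE_OP = {v: k for k, v in _OP_CODE.items()}


@dataclass(frozen=True)
class EditRecord:
    """One merge or split, localized in both graphs.

    ``position`` is the breakpoint coordinate (0-based bp from the genome
    start).  ``node_a``/``node_b`` are the nodes whose occurrence interval
    (start, end] contains the position in each graph; for the graph that
    has a junction exactly at the position, this is the node ending there,
    so ``end`` equals ``position`` on that side.
    """

    path_name: str
    position: int
    operation: str  # MERGE or SPLIT
    node_a: str
    node_b: str
    end_a: int
    end_b: int

    @property
    def code(self) -> str:
        """One-letter operation encoding: 'M' for merge, 'S' for split."""
        return _OP_CODE[self.operation]


@dataclass(frozen=True)
class ScanResult:
    """Outcome of the two-cursor scan over one genome."""

    merges: tuple[int, ...]  # positions private to the first segmentation
    splits: tuple[int, ...]  # positions private to the second
    iterations: int  # cursor advances; bounded by |B_a ∪ B_b|

    @property
    def distance(self) -> int:
        return len(self.merges) + len(self.splits)


def segmentation_distance(bset_a: BreakpointSet, bset_b: BreakpointSet) -> ScanResult:
    """Minimal merge/split sets between two segmentations of one genome.

    Both sets must describe the same genome (same name and length).  The
    two breakpoint lists are swept simultaneously: the current position p
    advances to the next closest breakpoint across both lists, counting a
    merge when p is private to ``bset_a``, a split when private to
    ``bset_b``, and nothing when shared.  A virtual sentinel at the genome
    length terminates both cursors and is never emitted as an edit.
    """
    if bset_a.genome_name != bset_b.genome_name:
        raise GFAError(
            f"genome name mismatch: {bset_a.genome_name!r} vs {bset_b.genome_name!r}"
        )
    if bset_a.genome_length != bset_b.genome_length:
        raise GFAError(
            f"{bset_a.genome_name!r}: genome length mismatch "
            f"({bset_a.genome_length} vs {bset_b.genome_length}); "
            "the paths do not represent the same sequence"
        )
    length = bset_a.genome_length
    a = bset_a.positions + (length,)  # sentinel closes the scan
    b = bset_b.positions + (length,)
    i = j = 0
    merges: list[int] = []
    splits: list[int] = []
    iterations = 0
    p = min(a[0], b[0])
    while p < length:
        iterations += 1
        if p == a[i] and p == b[j]:
            i += 1
            j += 1
        elif p == a[i]:
            merges.append(p)
            i += 1
        else:
            splits.append(p)
            j += 1
        p = min(a[i], b[j])
    return ScanResult(tuple(merges), tuple(splits), iterations)


def _occurrence_ends(graph: PangenomeGraph, path: PathRecord) -> tuple[list[int], list[str]]:
    """Cumulative end coordinate and node id of each path occurrence."""
    ends: list[int] = []
    node_ids: list[str] = []
    total = 0
    for step in path.steps:
        total += graph.nodes[step.node_id].length
        ends.append(total)
        node_ids.append(step.node_id)
    return ends, node_ids


def _locate(ends: list[int], node_ids: list[str], position: int) -> tuple[str, int]:
    """Node occurrence whose interval (start, end] contains ``position``."""
    idx = bisect_left(ends, position)
    return node_ids[idx], ends[idx]


def edit_records_for_path(
    bset_a: BreakpointSet,
    bset_b: BreakpointSet,
    path_a: PathRecord,
    path_b: PathRecord,
    graph_a: PangenomeGraph,
    graph_b: PangenomeGraph,
) -> list[EditRecord]:
    """Materialize one :class:`EditRecord` per differing breakpoint.

    Records are ordered by position.  Node occurrences are per-traversal:
    in a cyclic path the same node id may appear in several records with
    different end coordinates.
    """
    scan = segmentation_distance(bset_a, bset_b)
    ends_a, ids_a = _occurrence_ends(graph_a, path_a)
    ends_b, ids_b = _occurrence_ends(graph_b, path_b)
    records = []
    tagged = [(p, MERGE) for p in scan.merges] + [(p, SPLIT) for p in scan.splits]
    for position, op in sorted(tagged):
        node_a, end_a = _locate(ends_a, ids_a, position)
        node_b, end_b = _locate(ends_b, ids_b, position)
        records.append(
            EditRecord(bset_a.genome_name, position, op, node_a, node_b, end_a, end_b)
        )
    return records


@dataclass
class PathComparison:
    """Comparison of one shared genome across the two graphs."""

    name: str
    genome_length: int
    bset_a: BreakpointSet  # effective (post-masking when enabled)
    bset_b: BreakpointSet
    merges: tuple[int, ...]
    splits: tuple[int, ...]
    edits: list[EditRecord]
    iterations: int
    b_name: Optional[str] = None  # original name in graph B when renamed

    @property
    def merge_count(self) -> int:
        return len(self.merges)

    @property
    def split_count(self) -> int:
        return len(self.splits)

    @property
    def distance(self) -> int:
        return len(self.merges) + len(self.splits)


@dataclass
class DistanceReport:
    """Full result of comparing two graphs: per-path edits and totals."""

    per_path: dict[str, PathComparison] = field(default_factory=dict)
    shared_paths: list[str] = field(default_factory=list)
    private_paths_a: list[str] = field(default_factory=list)
    private_paths_b: list[str] = field(default_factory=list)
    masked: bool = False

    @property
    def total_merges(self) -> int:
        return sum(c.merge_count for c in self.per_path.values())

    @property
    def total_splits(self) -> int:
        return sum(c.split_count for c in self.per_path.values())

    @property
    def total_distance(self) -> int:
        return self.total_merges + self.total_splits

    @property
    def total_genome_bp(self) -> int:
        """Summed length of the compared (shared) genomes."""
        return sum(c.genome_length for c in self.per_path.values())

    def all_edits(self) -> list[EditRecord]:
        out: list[EditRecord] = []
        for name in sorted(self.per_path):
            out.extend(self.per_path[name].edits)
        return out


def graph_distance(
    graph_a: PangenomeGraph,
    graph_b: PangenomeGraph,
    mask_spurious_flag: bool = False,
    path_rename: Optional[Mapping[str, str]] = None,
) -> DistanceReport:
    """Segmentation distance between two graphs embedding shared genomes.

    ``path_rename`` maps path names in ``graph_b`` to their names in
    ``graph_a`` (to reconcile e.g. walk-derived vs P-line naming).  The
    distance is computed over the intersection of path names after
    renaming; paths private to either graph are listed in the report and
    excluded.  With ``mask_spurious_flag`` the breakpoints generated by
    non-branching junctions are removed in each graph independently before
    the scan.
    """
    rename = dict(path_rename or {})
    b_name_for: dict[str, str] = {}  # a-side name -> original b name
    for b_name in graph_b.paths:
        b_name_for[rename.get(b_name, b_name)] = b_name

    shared = sorted(set(graph_a.paths) & set(b_name_for))
    if not shared:
        raise GFAError("no shared path between the two graphs (after renaming)")

    report = DistanceReport(
        shared_paths=shared,
        private_paths_a=sorted(set(graph_a.paths) - set(shared)),
        private_paths_b=sorted(
            b_name_for[n] for n in set(b_name_for) - set(shared)
        ),
        masked=mask_spurious_flag,
    )

    for name in shared:
        b_name = b_name_for[name]
        len_a = path_length(graph_a, name)
        len_b = path_length(graph_b, b_name)
        if len_a != len_b:
            raise GFAError(
                f"shared path {name!r} has length {len_a} in the first graph "
                f"but {len_b} in the second"
            )
        bset_a = breakpoints_of_path(graph_a, name)
        bset_b = breakpoints_of_path(graph_b, b_name)
        if mask_spurious_flag:
            bset_a = mask_spurious(bset_a, graph_a, name)
            bset_b = mask_spurious(bset_b, graph_b, b_name)
        if bset_b.genome_name != name:
            bset_b = BreakpointSet(name, bset_b.genome_length, bset_b.positions)
        scan = segmentation_distance(bset_a, bset_b)
        edits = edit_records_for_path(
            bset_a, bset_b, graph_a.paths[name], graph_b.paths[b_name], graph_a, graph_b
        )
        report.per_path[name] = PathComparison(
            name,
            len_a,
            bset_a,
            bset_b,
            scan.merges,
            scan.splits,
            edits,
            scan.iterations,
            b_name=b_name,
        )
    return report


EDITS_TSV_HEADER = "#path\tposition\toperation\tnode_a\tnode_b\tend_a\tend_b"


def write_edits_tsv(report: DistanceReport, sink: Union[str, os.PathLike, IO[str]]) -> None:
    """Write the edit list as TSV, one edit per line.

    Columns: path name, position, one-letter operation ('M'/'S'), node in
    each graph, and each node's ending breakpoint.  Rows are sorted by
    (path, position).
    """
    if isinstance(sink, (str, os.PathLike)):
        with open(sink, "wt", encoding="utf-8") as handle:
            write_edits_tsv(report, handle)
            return
    sink.write(EDITS_TSV_HEADER + "\n")
    for rec in report.all_edits():
        sink.write(
            f"{rec.path_name}\t{rec.position}\t{rec.code}\t"
            f"{rec.node_a}\t{rec.node_b}\t{rec.end_a}\t{rec.end_b}\n"
        )


def read_edits_tsv(source: Union[str, os.PathLike, IO[str]]) -> list[EditRecord]:
    """Read an edit TSV written by :func:`write_edits_tsv`."""
    if isinstance(source, (str, os.PathLike)):
        with open(source, "rt", encoding="utf-8") as handle:
            return read_edits_tsv(handle)
    records = []
    for line_number, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 7:
            raise GFAError(f"edits TSV line {line_number}: expected 7 columns")
        if fields[2] not in _CODE_OP:
            raise GFAError(f"edits TSV line {line_number}: bad operation {fields[2]!r}")
        records.append(
            EditRecord(
                fields[0],
                int(fields[1]),
                _CODE_OP[fields[2]],
                fields[3],
                fields[4],
                int(fields[5]),
                int(fields[6]),
            )
        )
    return records
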