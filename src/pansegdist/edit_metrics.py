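"""Analytics over edit lists: sizes, positions, densities, matrices.

Every edit can be read as a split by exchanging the roles of the two
segmentations: a merge at position x (breakpoint private to graph A)
splits the node of graph B spanning x, and a split splits the node of
graph A.  Geometry is therefore always measured on the *split-side*
segment: the interval of the effective segmentation (post-masking when
the report was masked) strictly containing the edit position.

- edit position: distance in bp from the edit to the nearest border of
  the split segment (always ≤ half the segment length);
- edit size: size of the smallest piece the single operation produces,
  treating the segment borders and all co-occurring edits on the same
  segment as simultaneous boundaries.
"""

from __future__ import annotations

import os
from bisect import bisect_left, bisect_right
from collections import Counter
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from pansegdist.distance import (
    MERGE,
    DistanceReport,
    EditRecord,
    graph_distance,
)
from pansegdist.gfa_io import GFAError, PangenomeGraph

__all__ = [
    "EditGeometry",
    "WindowDensity",
    "DistanceMatrix",
    "SizeSummary",
    "edit_geometry",
    "summarize_sizes",
    "stratify_by_node_length",
    "max_node_edit_count",
    "edits_per_kilobase",
    "window_density",
    "distance_matrix",
    "matrix_to_csv",
    "write_window_tsv",
]


@dataclass(frozen=True)
class EditGeometry:
    record: EditRecord
    split_node_id: str
    split_node_length: int  # length of the split-side segment (bp)
    offset_in_node: int  # bp from the segment start, in (0, length)
    edit_position: int  # min(offset, length - offset)
    edit_size: int  # smallest piece produced, co-edits as boundaries


def _segment_boundaries(comparison) -> tuple[list[int], list[int]]:
    """Effective segment boundaries (0, breakpoints..., L) for each side."""
    length = comparison.genome_length
    bounds_a = [0, *comparison.bset_a.positions, length]
    bounds_b = [0, *comparison.bset_b.positions, length]
    return bounds_a, bounds_b


def edit_geometry(
    report: DistanceReport,
    graph_a: PangenomeGraph,
    graph_b: PangenomeGraph,
) -> list[EditGeometry]:
    """Per-edit split-side geometry for every edit in the report.

    The split side is graph B for a merge and graph A for a split.  The
    split segment is the interval of that side's effective segmentation
    strictly containing the position; its node id is resolved from the
    split-side graph's path traversal.  All edits falling on the same
    split segment count as simultaneous boundaries for each other's size.
    """
    from pansegdist.distance import _locate, _occurrence_ends  # shared helpers

    geoms: list[EditGeometry] = []
    for name in sorted(report.per_path):
        comp = report.per_path[name]
        bounds_a, bounds_b = _segment_boundaries(comp)
        ends_a, ids_a = _occurrence_ends(graph_a, graph_a.paths[name])
        b_path_name = comp.b_name if comp.b_name is not None else name
        if b_path_name not in graph_b.paths:
            raise GFAError(
                f"path {b_path_name!r} not found in the second graph; "
                "was the report produced from these graphs?"
            )
        ends_b, ids_b = _occurrence_ends(graph_b, graph_b.paths[b_path_name])

        # Group edit positions by the split segment they land in, per side.
        merge_by_seg: dict[int, list[int]] = {}
        split_by_seg: dict[int, list[int]] = {}
        for p in comp.merges:
            merge_by_seg.setdefault(bisect_left(bounds_b, p), []).append(p)
        for p in comp.splits:
            split_by_seg.setdefault(bisect_left(bounds_a, p), []).append(p)

        for rec in comp.edits:
            if rec.operation == MERGE:
                bounds, seg_map, ends, ids = bounds_b, merge_by_seg, ends_b, ids_b
            else:
                bounds, seg_map, ends, ids = bounds_a, split_by_seg, ends_a, ids_a
            idx = bisect_left(bounds, rec.position)
            start, end = bounds[idx - 1], bounds[idx]
            if rec.position in (start, end):
                raise GFAError(
                    f"edit at {rec.position} lies on a split-side boundary of "
                    f"{name!r}: inconsistent report"
                )
            length = end - start
            offset = rec.position - start
            co_edits = seg_map[idx]
            boundaries = [start, end] + [q for q in co_edits if q != rec.position]
            size = min(abs(rec.position - b) for b in boundaries)
            node_id, _ = _locate(ends, ids, rec.position)
            geoms.append(
                EditGeometry(
                    rec, node_id, length, offset, min(offset, length - offset), size
                )
            )
    return geoms


@dataclass(frozen=True)
class SizeSummary:
    count: int
    fraction_size1: float
    mean_size: float
    histogram: dict[int, int]


def summarize_sizes(geoms: list[EditGeometry]) -> SizeSummary:
    """Count, size-1 fraction, mean size and integer-size histogram."""
    if not geoms:
        raise GFAError("no edits: size summary undefined")
    sizes = [g.edit_size for g in geoms]
    hist = dict(sorted(Counter(sizes).items()))
    return SizeSummary(
        count=len(sizes),
        fraction_size1=sizes.count(1) / len(sizes),
        mean_size=sum(sizes) / len(sizes),
        histogram=hist,
    )


def stratify_by_node_length(
    geoms: list[EditGeometry],
    graphs: Iterable[PangenomeGraph],
    threshold: int,
) -> tuple[float, float]:
    """Edits on small nodes vs the genomic share of small nodes.

    Returns ``(fraction_of_edits_on_nodes ≤ threshold,
    fraction_of_total_node_length_in_nodes ≤ threshold)``.  The coverage
    denominator pools the node tables of the given graphs, since a single
    report's split nodes live in both graphs.
    """
    if threshold < 1:
        raise GFAError("threshold must be ≥ 1 bp")
    if not geoms:
        raise GFAError("no edits to stratify")
    small_edits = sum(1 for g in geoms if g.split_node_length <= threshold)
    total_len = 0
    small_len = 0
    for graph in graphs:
        for node in graph.nodes.values():
            total_len += node.length
            if node.length <= threshold:
                small_len += node.length
    if total_len == 0:
        raise GFAError("graphs have zero total node length")
    return small_edits / len(geoms), small_len / total_len


def max_node_edit_count(geoms: list[EditGeometry]) -> tuple[str, int]:
    """Most-edited split-side node, aggregated over occurrences by id.

    Ties are broken by lexicographically smallest node id.
    """
    if not geoms:
        raise GFAError("no edits")
    counts = Counter(g.split_node_id for g in geoms)
    best_count = max(counts.values())
    best_id = min(k for k, v in counts.items() if v == best_count)
    return best_id, best_count


def edits_per_kilobase(
    report: DistanceReport, total_genome_bp: Optional[int] = None
) -> float:
    """Average edit density: 1000 × distance / summed shared-genome bp."""
    if total_genome_bp is None:
        total_genome_bp = report.total_genome_bp
    if total_genome_bp <= 0:
        raise GFAError("total genome length must be positive")
    return 1000.0 * report.total_distance / total_genome_bp


@dataclass(frozen=True)
class WindowDensity:
    path_name: str
    window_start: int
    window_end: int
    edits_per_kb: float
    nodes_per_kb_a: Optional[float] = None
    nodes_per_kb_b: Optional[float] = None


def window_density(
    report: DistanceReport,
    path_name: str,
    window_bp: int,
    graph_a: Optional[PangenomeGraph] = None,
    graph_b: Optional[PangenomeGraph] = None,
) -> list[WindowDensity]:
    """Edit density per fixed window along one genome, in units per kb.

    Windows are half-open [start, start+window) and tile the genome; the
    last may be short.  When graphs are supplied, node occurrence counts
    per window (occurrences bucketed by their start coordinate) are
    reported alongside.
    """
    if window_bp < 1:
        raise GFAError("window must be ≥ 1 bp")
    if path_name not in report.per_path:
        raise GFAError(f"path {path_name!r} is not part of the comparison")
    comp = report.per_path[path_name]
    length = comp.genome_length
    positions = sorted(p for p in (*comp.merges, *comp.splits))

    def occurrence_starts(graph: PangenomeGraph) -> list[int]:
        starts = []
        total = 0
        for step in graph.paths[path_name].steps:
            starts.append(total)
            total += graph.nodes[step.node_id].length
        return starts

    starts_a = occurrence_starts(graph_a) if graph_a is not None else None
    starts_b = occurrence_starts(graph_b) if graph_b is not None else None

    out: list[WindowDensity] = []
    for w_start in range(0, length, window_bp):
        w_end = min(w_start + window_bp, length)
        width = w_end - w_start
        n_edits = bisect_left(positions, w_end) - bisect_left(positions, w_start)

        def per_kb(count: Optional[int]) -> Optional[float]:
            return None if count is None else 1000.0 * count / width

        n_a = (
            bisect_left(starts_a, w_end) - bisect_left(starts_a, w_start)
            if starts_a is not None
            else None
        )
        n_b = (
            bisect_left(starts_b, w_end) - bisect_left(starts_b, w_start)
            if starts_b is not None
            else None
        )
        out.append(
            WindowDensity(
                path_name, w_start, w_end, 1000.0 * n_edits / width, per_kb(n_a), per_kb(n_b)
            )
        )
    return out


@dataclass
class DistanceMatrix:
    """All-pairs graph distances: symmetric, zero diagonal."""

    labels: list[str]
    values: np.ndarray  # integer, shape (n, n)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def distance_matrix(
    graphs: Mapping[str, PangenomeGraph],
    mask_spurious_flag: bool = False,
) -> DistanceMatrix:
    """Pairwise segmentation distances among ≥ 2 graphs of one collection."""
    labels = list(graphs)
    if len(labels) < 2:
        raise GFAError("need at least two graphs")
    n = len(labels)
    values = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                report = graph_distance(
                    graphs[labels[i]], graphs[labels[j]], mask_spurious_flag
                )
            except GFAError as exc:
                raise GFAError(
                    f"comparing {labels[i]!r} vs {labels[j]!r}: {exc}"
                ) from None
            values[i, j] = values[j, i] = report.total_distance
    return DistanceMatrix(labels, values)


def matrix_to_csv(matrix: DistanceMatrix, sink: Union[str, os.PathLike, IO[str]]) -> None:
    """CSV with a header row of labels and one integer row per graph."""
    matrix.to_frame().to_csv(sink)


def write_window_tsv(
    densities: list[WindowDensity], sink: Union[str, os.PathLike, IO[str]]
) -> None:
    if isinstance(sink, (str, os.PathLike)):
        with open(sink, "wt", encoding="utf-8") as handle:
            write_window_tsv(densities, handle)
            return
    sink.write("#path\tstart\tend\tedits_per_kb\tnodes_per_kb_a\tnodes_per_kb_b\n")
    for w in densities:
        na = "" if w.nodes_per_kb_a is None else f"{w.nodes_per_kb_a:.6g}"
        nb = "" if w.nodes_per_kb_b is None else f"{w.nodes_per_kb_b:.6g}"
        sink.write(
            f"{w.path_name}\t{w.window_start}\t{w.window_end}\t"
            f"{w.edits_per_kb:.6g}\t{na}\t{nb}\n"
        )
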