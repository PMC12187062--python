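"""Genome segmentations: breakpoint sets, spurious junctions, masking.

A path through the graph partitions its genome into consecutive intervals;
the internal boundaries are *breakpoints*, measured in bp from the genome
start (0-based: a breakpoint at x separates offsets x-1 and x).  The genome
ends 0 and L are never breakpoints.

Some junctions between nodes are *spurious*: no path anywhere in the graph
distinguishes the two nodes (typically the result of chopping long nodes
into bounded-size pieces during construction).  Breakpoints generated by
such junctions model no genomic variation and can be masked before
computing distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from pansegdist.gfa_io import GFAError, OrientedStep, PangenomeGraph, PathRecord

__all__ = [
    "BreakpointSet",
    "Side",
    "Junction",
    "junction_of_pair",
    "breakpoints_of_path",
    "spurious_junctions",
    "mask_spurious",
]

# A node side: ('n1', 'L') is the start of n1's forward orientation,
# ('n1', 'R') its end.  A junction is the unordered pair of sides that two
# consecutive steps glue together; reading the same junction in reverse
# orientation swaps the pair, so sorting makes the identity canonical.
Side = tuple[str, str]
Junction = tuple[Side, Side]


def _out_side(step: OrientedStep) -> Side:
    return (step.node_id, "R" if step.orientation == "+" else "L")


def _in_side(step: OrientedStep) -> Side:
    return (step.node_id, "L" if step.orientation == "+" else "R")


def junction_of_pair(a: OrientedStep, b: OrientedStep) -> Junction:
    """Canonical junction glued by consecutive steps ``a`` then ``b``."""
    s1, s2 = _out_side(a), _in_side(b)
    return (s1, s2) if s1 <= s2 else (s2, s1)


@dataclass(frozen=True)
class BreakpointSet:
    """Internal breakpoints of one genome, plus its total length.

    ``positions`` is strictly increasing with every element in the open
    interval (0, genome_length).
    """

    genome_name: str
    genome_length: int
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        prev = 0
        for p in self.positions:
            if not (0 < p < self.genome_length):
                raise GFAError(
                    f"{self.genome_name!r}: breakpoint {p} outside (0, {self.genome_length})"
                )
            if p <= prev:
                raise GFAError(f"{self.genome_name!r}: positions not strictly increasing")
            prev = p

    def __len__(self) -> int:
        return len(self.positions)

    def __iter__(self) -> Iterator[int]:
        return iter(self.positions)


def breakpoints_of_path(graph: PangenomeGraph, name: str) -> BreakpointSet:
    """Breakpoint set induced on genome ``name`` by its path.

    Positions are the cumulative sums of step node lengths, excluding the
    final sum (the genome length).  A single-node path has no breakpoints.
    Zero-length nodes are rejected: they would duplicate positions.
    """
    if name not in graph.paths:
        raise GFAError(f"unknown path {name!r}")
    positions = []
    total = 0
    for step in graph.paths[name].steps:
        length = graph.nodes[step.node_id].length
        if length == 0:
            raise GFAError(
                f"path {name!r} traverses zero-length node {step.node_id!r}"
            )
        total += length
        positions.append(total)
    positions.pop()  # the final sum is the genome end, not a breakpoint
    return BreakpointSet(name, total, tuple(positions))


def spurious_junctions(graph: PangenomeGraph) -> set[Junction]:
    """Junctions that no path in the graph can distinguish.

    A junction between node sides s1 and s2 is spurious when, over every
    path traversal: s1 only ever connects to s2 and vice versa, neither
    side is ever a path endpoint, and the edge set (when present) offers no
    other adjacency on either side.  Merging the two nodes across such a
    junction would leave every path's sequence unchanged — the breakpoints
    it generates are construction artifacts.

    Path traversals are read in canonical orientation, so a junction
    crossed forward by one path and backward by another is counted once.
    """
    if not graph.paths:
        raise GFAError("graph has no paths")

    path_adj: dict[Side, set[Side]] = {}
    endpoint: set[Side] = set()
    observed: set[Junction] = set()

    for path in graph.paths.values():
        steps = path.steps
        endpoint.add(_in_side(steps[0]))
        endpoint.add(_out_side(steps[-1]))
        for a, b in zip(steps, steps[1:]):
            s1, s2 = _out_side(a), _in_side(b)
            path_adj.setdefault(s1, set()).add(s2)
            path_adj.setdefault(s2, set()).add(s1)
            observed.add(junction_of_pair(a, b))

    edge_adj: dict[Side, set[Side]] = {}
    for (u, ou), (v, ov) in graph.edges:
        a = OrientedStep(u, ou)
        b = OrientedStep(v, ov)
        s1, s2 = _out_side(a), _in_side(b)
        edge_adj.setdefault(s1, set()).add(s2)
        edge_adj.setdefault(s2, set()).add(s1)

    result: set[Junction] = set()
    for junction in observed:
        s1, s2 = junction
        if s1 == s2:
            continue  # inversion fold-back; the nodes cannot be merged
        if s1 in endpoint or s2 in endpoint:
            continue
        if path_adj.get(s1) != {s2} or path_adj.get(s2) != {s1}:
            continue
        if edge_adj and (edge_adj.get(s1, set()) - {s2} or edge_adj.get(s2, set()) - {s1}):
            continue
        result.add(junction)
    return result


def mask_spurious(
    bset: BreakpointSet, graph: PangenomeGraph, name: str
) -> BreakpointSet:
    """Remove breakpoints generated by spurious junctions.

    ``bset`` must derive from ``graph``'s path ``name`` (possibly already
    masked — masking is idempotent).  The genome length is cross-checked.
    """
    if name not in graph.paths:
        raise GFAError(f"unknown path {name!r}")
    steps = graph.paths[name].steps
    total = sum(graph.nodes[s.node_id].length for s in steps)
    if total != bset.genome_length:
        raise GFAError(
            f"breakpoint set for {bset.genome_name!r} has genome length "
            f"{bset.genome_length}, path {name!r} has {total}"
        )
    spurious = spurious_junctions(graph)
    junction_at: dict[int, Junction] = {}
    pos = 0
    for a, b in zip(steps, steps[1:]):
        pos += graph.nodes[a.node_id].length
        junction_at[pos] = junction_of_pair(a, b)
    kept = tuple(
        p for p in bset.positions if junction_at.get(p) not in spurious
    )
    return BreakpointSet(bset.genome_name, bset.genome_length, kept)
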