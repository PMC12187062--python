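"""GFA 1.x input/output and the pangenome-graph container.

The graph model is G = (V, E, P): nodes carry a length and optionally a
nucleotide label, edges are directed and oriented at both ends, and each
genome (or scaffold) is embedded as one named path of oriented node steps.
A graph is *complete* when concatenating each path's oriented labels
reproduces the corresponding genome exactly; :func:`validate_complete`
checks this property against a set of reference sequences.

Both GFA 1.0 ``P`` path lines and GFA 1.1 ``W`` walk lines are accepted in
the same file; walks become paths named ``sample#haplotype#seqid`` (PanSN
style).  Segments may carry an explicit sequence or ``*`` plus an ``LN:i``
length tag — the distance computation only needs lengths.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping, Optional, Union

__all__ = [
    "Node",
    "OrientedStep",
    "Edge",
    "PathRecord",
    "PangenomeGraph",
    "GFAError",
    "GFAParseError",
    "ValidationReport",
    "read_gfa",
    "write_gfa",
    "path_length",
    "validate_complete",
    "read_fasta",
    "reverse_complement",
]


class GFAError(ValueError):
    """Structural error in a pangenome graph."""


class GFAParseError(GFAError):
    """Malformed GFA input; carries the 1-based line number."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}: A<->T, C<->G, N fixed."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Node:
    """A graph segment: an identifier, a length in bp, optionally a label.

    When a label is present its length must equal ``length``.
    """

    id: str
    length: int
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise GFAError("node id must be non-empty")
        if self.length < 0:
            raise GFAError(f"node {self.id!r}: negative length {self.length}")
        if self.label is not None and len(self.label) != self.length:
            raise GFAError(
                f"node {self.id!r}: label length {len(self.label)} != length {self.length}"
            )


@dataclass(frozen=True, order=True)
class OrientedStep:
    """One oriented traversal of a node; orientation is '+' or '-'."""

    node_id: str
    orientation: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise GFAError(f"bad orientation {self.orientation!r}")

    def flipped(self) -> "OrientedStep":
        return OrientedStep(self.node_id, "-" if self.orientation == "+" else "+")

    def __str__(self) -> str:
        return self.node_id + self.orientation


# An edge and its reverse complement denote the same adjacency; edges are
# stored under this canonical key so the set is orientation-normalized.
EdgeKey = tuple[tuple[str, str], tuple[str, str]]


@dataclass(frozen=True)
class Edge:
    """Directed edge between two oriented node ends (blunt, no overlap)."""

    from_step: OrientedStep
    to_step: OrientedStep

    def reverse(self) -> "Edge":
        return Edge(self.to_step.flipped(), self.from_step.flipped())

    def key(self) -> EdgeKey:
        a = (
            (self.from_step.node_id, self.from_step.orientation),
            (self.to_step.node_id, self.to_step.orientation),
        )
        r = self.reverse()
        b = (
            (r.from_step.node_id, r.from_step.orientation),
            (r.to_step.node_id, r.to_step.orientation),
        )
        return min(a, b)


@dataclass
class PathRecord:
    """An ordered, oriented node list embedding one genome or scaffold."""

    name: str
    steps: list[OrientedStep]

    def __post_init__(self) -> None:
        if not self.steps:
            raise GFAError(f"path {self.name!r}: empty step list")


@dataclass
class PangenomeGraph:
    """G = (V, E, P): nodes, orientation-normalized edges, named paths."""

    nodes: dict[str, Node] = field(default_factory=dict)
    edges: set[EdgeKey] = field(default_factory=set)
    paths: dict[str, PathRecord] = field(default_factory=dict)

    def add_node(self, node: Node) -> None:
        if node.id in self.nodes:
            raise GFAError(f"duplicate node id {node.id!r}")
        self.nodes[node.id] = node

    def add_edge(self, edge: Edge) -> None:
        for step in (edge.from_step, edge.to_step):
            if step.node_id not in self.nodes:
                raise GFAError(f"edge endpoint references unknown node {step.node_id!r}")
        self.edges.add(edge.key())

    def add_path(self, path: PathRecord) -> None:
        if path.name in self.paths:
            raise GFAError(f"duplicate path name {path.name!r}")
        for step in path.steps:
            if step.node_id not in self.nodes:
                raise GFAError(
                    f"path {path.name!r} references unknown node {step.node_id!r}"
                )
        self.paths[path.name] = path

    def has_edge(self, a: OrientedStep, b: OrientedStep) -> bool:
        return Edge(a, b).key() in self.edges

    def check_path_edges(self) -> None:
        """Verify every consecutive step pair is supported by an edge.

        Only meaningful when the edge set is non-empty (a lengths-and-paths
        file without L lines is still usable for the distance).
        """
        if not self.edges:
            return
        for path in self.paths.values():
            for a, b in zip(path.steps, path.steps[1:]):
                if not self.has_edge(a, b):
                    raise GFAError(
                        f"path {path.name!r}: step pair {a}->{b} not supported by any edge"
                    )


def _parse_tags(fields: Iterable[str], line_number: int) -> dict[str, str]:
    tags = {}
    for f in fields:
        parts = f.split(":", 2)
        if len(parts) != 3:
            raise GFAParseError(f"malformed tag {f!r}", line_number)
        tags[parts[0]] = parts[2]
    return tags


_BLUNT_OVERLAPS = {"*", "", "0M"}


def _check_blunt(overlap_field: str, line_number: int) -> None:
    # Variation graphs here are blunt-ended; any true overlap breaks the
    # segmentation arithmetic, so only '*' / '0M' (or lists thereof) pass.
    for item in overlap_field.split(","):
        if item not in _BLUNT_OVERLAPS:
            raise GFAParseError(
                f"non-blunt overlap {item!r} not supported (only '*' or '0M')",
                line_number,
            )


def _parse_walk(walk: str, line_number: int) -> list[OrientedStep]:
    steps: list[OrientedStep] = []
    token = ""
    orient = ""
    for ch in walk:
        if ch in "><":
            if token:
                steps.append(OrientedStep(token, orient))
            token = ""
            orient = "+" if ch == ">" else "-"
        else:
            if not orient:
                raise GFAParseError(f"walk must start with '>' or '<': {walk!r}", line_number)
            token += ch
    if token:
        steps.append(OrientedStep(token, orient))
    if not steps:
        raise GFAParseError("empty walk", line_number)
    return steps


def read_gfa(source: Union[str, os.PathLike, IO[str]]) -> PangenomeGraph:
    """Parse GFA 1.x text (S/L/P/W lines) into a :class:`PangenomeGraph`.

    ``source`` may be a path or an open text stream.  Node lengths come from
    the S-line sequence, or from the ``LN:i`` tag when the sequence is
    ``*``.  W walk lines become paths named ``sample#haplotype#seqid``.
    Parsing is insensitive to record order: paths and edges are resolved
    against the node table after the whole file is read.

    Raises :class:`GFAParseError` (with line number) on malformed input and
    :class:`GFAError` on structural inconsistencies such as duplicate node
    ids or path steps referencing unknown nodes.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source, "rt", encoding="utf-8") as handle:
            return read_gfa(handle)

    graph = PangenomeGraph()
    pending_edges: list[tuple[int, Edge]] = []
    pending_paths: list[tuple[int, PathRecord]] = []

    for line_number, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        kind = fields[0]
        if kind == "H":
            continue
        if kind == "S":
            if len(fields) < 3:
                raise GFAParseError("S line needs id and sequence", line_number)
            seg_id, seq = fields[1], fields[2]
            tags = _parse_tags(fields[3:], line_number)
            if seq == "*":
                if "LN" not in tags:
                    raise GFAParseError(
                        f"segment {seg_id!r} has '*' sequence and no LN:i tag", line_number
                    )
                try:
                    length = int(tags["LN"])
                except ValueError:
                    raise GFAParseError(
                        f"segment {seg_id!r}: bad LN tag {tags['LN']!r}", line_number
                    ) from None
                node = Node(seg_id, length)
            else:
                node = Node(seg_id, len(seq), seq.upper())
            try:
                graph.add_node(node)
            except GFAError as exc:
                raise GFAParseError(str(exc), line_number) from None
        elif kind == "L":
            if len(fields) < 6:
                raise GFAParseError("L line needs 5 fields", line_number)
            _check_blunt(fields[5], line_number)
            try:
                edge = Edge(
                    OrientedStep(fields[1], fields[2]),
                    OrientedStep(fields[3], fields[4]),
                )
            except GFAError as exc:
                raise GFAParseError(str(exc), line_number) from None
            pending_edges.append((line_number, edge))
        elif kind == "P":
            if len(fields) < 3:
                raise GFAParseError("P line needs name and steps", line_number)
            if len(fields) >= 4:
                _check_blunt(fields[3], line_number)
            steps = []
            for token in fields[2].split(","):
                if len(token) < 2 or token[-1] not in "+-":
                    raise GFAParseError(f"bad path step {token!r}", line_number)
                steps.append(OrientedStep(token[:-1], token[-1]))
            try:
                pending_paths.append((line_number, PathRecord(fields[1], steps)))
            except GFAError as exc:
                raise GFAParseError(str(exc), line_number) from None
        elif kind == "W":
            if len(fields) < 7:
                raise GFAParseError("W line needs 6 fields", line_number)
            sample, hap, seqid = fields[1], fields[2], fields[3]
            name = "#".join((sample, hap, seqid))
            steps = _parse_walk(fields[6], line_number)
            pending_paths.append((line_number, PathRecord(name, steps)))
        elif kind in ("C", "J"):
            raise GFAParseError(f"unsupported record type {kind!r}", line_number)
        else:
            raise GFAParseError(f"unrecognized record type {kind!r}", line_number)

    for line_number, edge in pending_edges:
        try:
            graph.add_edge(edge)
        except GFAError as exc:
            raise GFAParseError(str(exc), line_number) from None
    for line_number, path in pending_paths:
        try:
            graph.add_path(path)
        except GFAError as exc:
            raise GFAParseError(str(exc), line_number) from None
    graph.check_path_edges()
    return graph


def write_gfa(graph: PangenomeGraph, sink: Union[str, os.PathLike, IO[str]]) -> None:
    """Emit the graph as GFA 1.0 (H, S, L, P lines).

    Node labels are written when present, otherwise ``*`` with an ``LN:i``
    tag.  Output is deterministic: segments and edges are sorted, paths
    appear in insertion order.
    """
    if isinstance(sink, (str, os.PathLike)):
        with open(sink, "wt", encoding="utf-8") as handle:
            write_gfa(graph, handle)
            return

    for path in graph.paths.values():
        for step in path.steps:
            if step.node_id not in graph.nodes:
                raise GFAError(
                    f"path {path.name!r} references missing node {step.node_id!r}"
                )

    sink.write("H\tVN:Z:1.0\n")
    for node_id in sorted(graph.nodes):
        node = graph.nodes[node_id]
        if node.label is not None:
            sink.write(f"S\t{node.id}\t{node.label}\n")
        else:
            sink.write(f"S\t{node.id}\t*\tLN:i:{node.length}\n")
    for (u, ou), (v, ov) in sorted(graph.edges):
        sink.write(f"L\t{u}\t{ou}\t{v}\t{ov}\t0M\n")
    for path in graph.paths.values():
        steps = ",".join(str(s) for s in path.steps)
        sink.write(f"P\t{path.name}\t{steps}\t*\n")


def path_length(graph: PangenomeGraph, name: str) -> int:
    """Total length in bp of the genome embedded as path ``name``.

    Orientation does not change a node's length, so this is just the sum of
    step node lengths.
    """
    if name not in graph.paths:
        raise GFAError(f"unknown path {name!r}")
    return sum(graph.nodes[s.node_id].length for s in graph.paths[name].steps)


@dataclass
class PathValidation:
    name: str
    ok: bool
    first_mismatch: Optional[int] = None  # offset of first differing base
    detail: str = ""


@dataclass
class ValidationReport:
    """Outcome of the completeness check, per path plus a global verdict."""

    per_path: dict[str, PathValidation]
    path_count_ok: bool  # |P| == number of genomes given

    @property
    def ok(self) -> bool:
        return self.path_count_ok and all(v.ok for v in self.per_path.values())


def validate_complete(
    graph: PangenomeGraph, genomes: Mapping[str, str]
) -> ValidationReport:
    """Check the complete-pangenome-graph property against reference genomes.

    For each path, the genome sequence is reconstructed by concatenating the
    step labels (reverse-complementing reverse-oriented steps) and compared
    with ``genomes[path_name]``.  The report records per-path pass/fail with
    the first mismatch offset, and whether the path set matches the genome
    set one-to-one.

    Raises :class:`GFAError` if any traversed node lacks a label — a
    lengths-only graph supports the distance but not this verification.
    """
    per_path: dict[str, PathValidation] = {}
    for name, path in graph.paths.items():
        pieces = []
        for step in path.steps:
            node = graph.nodes[step.node_id]
            if node.label is None:
                raise GFAError(
                    f"node {node.id!r} has no label: completeness cannot be verified "
                    "(graph is lengths-only; distances remain available)"
                )
            pieces.append(
                node.label if step.orientation == "+" else reverse_complement(node.label)
            )
        rebuilt = "".join(pieces)
        if name not in genomes:
            per_path[name] = PathValidation(name, False, None, "no reference genome given")
            continue
        expected = genomes[name].upper()
        if rebuilt == expected:
            per_path[name] = PathValidation(name, True)
        else:
            offset = next(
                (k for k, (x, y) in enumerate(zip(rebuilt, expected)) if x != y),
                min(len(rebuilt), len(expected)),
            )
            per_path[name] = PathValidation(
                name, False, offset,
                f"mismatch at offset {offset} (path yields {len(rebuilt)} bp, "
                f"genome is {len(expected)} bp)",
            )
    path_count_ok = set(graph.paths) == set(genomes)
    return ValidationReport(per_path, path_count_ok)


def read_fasta(source: Union[str, os.PathLike, IO[str]]) -> dict[str, str]:
    """Read a FASTA file into a name -> uppercase sequence map."""
    from Bio import SeqIO

    if isinstance(source, (str, os.PathLike)):
        with open(source, "rt", encoding="utf-8") as handle:
            return read_fasta(handle)
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(source, "fasta")}
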