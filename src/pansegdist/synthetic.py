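"""Synthetic complete pangenome graph pairs with known edit ground truth.

The generator draws random genomes, then a pair of segmentations per
genome with a controlled number of shared breakpoints; the exact private
breakpoint sets are the ground-truth merges and splits, so the distance
modules can be validated end to end without any external data.  The
default graphs use per-genome disjoint node sets (one linear chain per
genome), which is a valid complete pangenome graph; the shared-node
regime (identical segments collapsed into nodes traversed by several
paths) is covered separately by :func:`shared_node_graph`, and
:func:`chop_nodes` emulates the construction-time chopping of long nodes
that produces spurious breakpoints.

Not emulated: realistic variation (SNPs, structural variants, repeats)
or builder alignment heuristics — segmentation discordance is injected
directly as random breakpoint sets.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import IO, Mapping, Optional, Sequence, Union

import numpy as np

from pansegdist.gfa_io import (
    Edge,
    GFAError,
    Node,
    OrientedStep,
    PangenomeGraph,
    PathRecord,
)
from pansegdist.segmentation import Junction, junction_of_pair

__all__ = [
    "SyntheticSpec",
    "SegmentationPair",
    "random_genomes",
    "paired_segmentations",
    "build_linear_graph",
    "chop_nodes",
    "shared_node_graph",
    "generate_pair",
    "write_ground_truth_tsv",
]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic graph pair.

    Defaults describe a small but non-trivial collection: 5 genomes of
    10 kb, 200 breakpoints per genome on each side with half of them
    shared — a segmentation density (one node per ~50 bp) in the range
    real chromosome-scale graphs exhibit.
    """

    n_genomes: int = 5
    genome_length: int = 10_000
    n_breakpoints_a: int = 200
    n_breakpoints_b: int = 200
    shared_fraction: float = 0.5
    chop_size: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1 or self.genome_length < 1:
            raise GFAError("need at least one genome of length ≥ 1")
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise GFAError("shared_fraction must be in [0, 1]")
        if max(self.n_breakpoints_a, self.n_breakpoints_b) > self.genome_length - 1:
            raise GFAError("more breakpoints than internal positions")
        if self.chop_size is not None and self.chop_size < 1:
            raise GFAError("chop_size must be ≥ 1")

    @property
    def n_shared(self) -> int:
        return math.ceil(
            self.shared_fraction * min(self.n_breakpoints_a, self.n_breakpoints_b)
        )


@dataclass(frozen=True)
class SegmentationPair:
    """Two segmentations of one genome plus the exact edit ground truth."""

    b_a: tuple[int, ...]
    b_b: tuple[int, ...]
    merges: tuple[int, ...]  # private to side A
    splits: tuple[int, ...]  # private to side B

    @property
    def distance(self) -> int:
        return len(self.merges) + len(self.splits)


def _genome_names(spec: SyntheticSpec) -> list[str]:
    return [f"g{k:02d}" for k in range(spec.n_genomes)]


def random_genomes(spec: SyntheticSpec) -> dict[str, str]:
    """Uniform random genomes over {A,C,G,T}, reproducible from the seed."""
    rng = np.random.default_rng([spec.seed, 1])
    out = {}
    for name in _genome_names(spec):
        draws = rng.integers(0, 4, size=spec.genome_length)
        out[name] = _ALPHABET[draws].tobytes().decode("ascii")
    return out


def paired_segmentations(spec: SyntheticSpec) -> dict[str, SegmentationPair]:
    """Per-genome breakpoint-set pairs with known private sets.

    Shared positions are drawn first (⌈shared_fraction × min(n_a, n_b)⌉ of
    them), then the private positions of each side, all without
    replacement from the internal positions 1..L-1, so shared and private
    sets are pairwise disjoint and the symmetric difference is exactly the
    union of the two private sets.
    """
    rng = np.random.default_rng([spec.seed, 2])
    n_shared = spec.n_shared
    n_priv_a = spec.n_breakpoints_a - n_shared
    n_priv_b = spec.n_breakpoints_b - n_shared
    total = n_shared + n_priv_a + n_priv_b
    if total > spec.genome_length - 1:
        raise GFAError(
            f"cannot place {total} distinct breakpoints in a "
            f"{spec.genome_length} bp genome"
        )
    out = {}
    for name in _genome_names(spec):
        draw = rng.choice(spec.genome_length - 1, size=total, replace=False) + 1
        shared = draw[:n_shared]
        priv_a = draw[n_shared : n_shared + n_priv_a]
        priv_b = draw[n_shared + n_priv_a :]
        out[name] = SegmentationPair(
            b_a=tuple(sorted(int(x) for x in np.concatenate([shared, priv_a]))),
            b_b=tuple(sorted(int(x) for x in np.concatenate([shared, priv_b]))),
            merges=tuple(sorted(int(x) for x in priv_a)),
            splits=tuple(sorted(int(x) for x in priv_b)),
        )
    return out


def build_linear_graph(
    genomes: Mapping[str, str],
    segmentations: Mapping[str, Sequence[int]],
    node_prefix: str = "",
) -> PangenomeGraph:
    """One linear labeled chain per genome, cut at the given positions.

    Node ids are ``{prefix}{genome}.{k}``; the result is complete by
    construction (each path's labels concatenate to its genome).
    """
    graph = PangenomeGraph()
    for name, genome in genomes.items():
        positions = list(segmentations.get(name, ()))
        bounds = [0, *positions, len(genome)]
        steps = []
        for k, (start, end) in enumerate(zip(bounds, bounds[1:])):
            if not 0 <= start < end <= len(genome):
                raise GFAError(f"{name!r}: bad breakpoint interval [{start}, {end})")
            node = Node(f"{node_prefix}{name}.{k}", end - start, genome[start:end])
            graph.add_node(node)
            steps.append(OrientedStep(node.id, "+"))
        graph.add_path(PathRecord(name, steps))
        for a, b in zip(steps, steps[1:]):
            graph.add_edge(Edge(a, b))
    return graph


def chop_nodes(
    graph: PangenomeGraph, max_len: int
) -> tuple[PangenomeGraph, set[Junction]]:
    """Replace every node longer than ``max_len`` by a chain of pieces.

    Pieces have length ``max_len`` except possibly the last; paths, labels
    and edges are rewritten so completeness is preserved.  Returns the new
    graph together with the set of junctions the chopping introduced
    (canonical side pairs, the same representation
    :func:`pansegdist.segmentation.spurious_junctions` uses).
    """
    if max_len < 1:
        raise GFAError("max_len must be ≥ 1")

    chopped = PangenomeGraph()
    pieces_of: dict[str, list[str]] = {}
    introduced: set[Junction] = set()

    for node in graph.nodes.values():
        if node.length <= max_len:
            chopped.add_node(node)
            pieces_of[node.id] = [node.id]
            continue
        ids = []
        for k, start in enumerate(range(0, node.length, max_len)):
            end = min(start + max_len, node.length)
            label = node.label[start:end] if node.label is not None else None
            piece = Node(f"{node.id}.c{k}", end - start, label)
            chopped.add_node(piece)
            ids.append(piece.id)
        pieces_of[node.id] = ids
        for u, v in zip(ids, ids[1:]):
            introduced.add(
                junction_of_pair(OrientedStep(u, "+"), OrientedStep(v, "+"))
            )

    def expand(step: OrientedStep) -> list[OrientedStep]:
        ids = pieces_of[step.node_id]
        if step.orientation == "+":
            return [OrientedStep(i, "+") for i in ids]
        return [OrientedStep(i, "-") for i in reversed(ids)]

    for path in graph.paths.values():
        steps: list[OrientedStep] = []
        for step in path.steps:
            steps.extend(expand(step))
        chopped.add_path(PathRecord(path.name, steps))

    # Re-derive the edge set: internal chain edges plus the old adjacencies
    # re-attached to the outermost pieces.
    for ids in pieces_of.values():
        for u, v in zip(ids, ids[1:]):
            chopped.add_edge(Edge(OrientedStep(u, "+"), OrientedStep(v, "+")))
    for (u, ou), (v, ov) in graph.edges:
        new_from = expand(OrientedStep(u, ou))[-1]
        new_to = expand(OrientedStep(v, ov))[0]
        chopped.add_edge(Edge(new_from, new_to))
    return chopped, introduced


def shared_node_graph(
    genomes: Mapping[str, str], joint_segmentation: Sequence[int]
) -> PangenomeGraph:
    """Collapse identical segments at identical coordinates into one node.

    All genomes are cut at the same positions; segments that carry the
    same label at the same coordinates become a single node traversed by
    every path.  Genomes must agree segment-wise (label conflicts raise),
    which makes this the multi-traversal regime: one edit on a shared
    junction contributes once per traversing genome to the graph distance.
    """
    graph = PangenomeGraph()
    lengths = {len(g) for g in genomes.values()}
    if len(lengths) != 1:
        raise GFAError("shared-node generation requires equal-length genomes")
    (length,) = lengths
    bounds = [0, *joint_segmentation, length]
    node_ids: list[str] = []
    reference = next(iter(genomes.values()))
    for k, (start, end) in enumerate(zip(bounds, bounds[1:])):
        if not 0 <= start < end <= length:
            raise GFAError(f"bad breakpoint interval [{start}, {end})")
        label = reference[start:end]
        for name, genome in genomes.items():
            if genome[start:end] != label:
                raise GFAError(
                    f"label conflict in segment [{start}, {end}) between genomes"
                )
        node = Node(f"s{k}", end - start, label)
        graph.add_node(node)
        node_ids.append(node.id)
    steps = [OrientedStep(i, "+") for i in node_ids]
    for name in genomes:
        graph.add_path(PathRecord(name, list(steps)))
    for a, b in zip(steps, steps[1:]):
        graph.add_edge(Edge(a, b))
    return graph


def generate_pair(
    spec: SyntheticSpec,
) -> tuple[PangenomeGraph, PangenomeGraph, dict[str, SegmentationPair]]:
    """Genomes + two graphs segmenting them differently + ground truth.

    When ``spec.chop_size`` is set, the second graph is additionally
    chopped, so comparisons without masking see the chop-induced
    breakpoints while masked comparisons recover the ground truth.
    """
    genomes = random_genomes(spec)
    pairs = paired_segmentations(spec)
    graph_a = build_linear_graph(genomes, {n: p.b_a for n, p in pairs.items()})
    graph_b = build_linear_graph(genomes, {n: p.b_b for n, p in pairs.items()})
    if spec.chop_size is not None:
        graph_b, _ = chop_nodes(graph_b, spec.chop_size)
    return graph_a, graph_b, pairs


def write_ground_truth_tsv(
    pairs: Mapping[str, SegmentationPair], sink: Union[str, os.PathLike, IO[str]]
) -> None:
    """Expected edits as TSV: path, position, operation ('M'/'S')."""
    if isinstance(sink, (str, os.PathLike)):
        with open(sink, "wt", encoding="utf-8") as handle:
            write_ground_truth_tsv(pairs, handle)
            return
    sink.write("#path\tposition\toperation\n")
    for name in sorted(pairs):
        pair = pairs[name]
        rows = [(p, "M") for p in pair.merges] + [(p, "S") for p in pair.splits]
        for position, op in sorted(rows):
            sink.write(f"{name}\t{position}\t{op}\n")
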