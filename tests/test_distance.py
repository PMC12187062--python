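"""Two-cursor scan, edit materialization, graph-level distance."""

import io
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_edits, gfa_from_text
from pansegdist import synthetic
from pansegdist.distance import (
    MERGE,
    SPLIT,
    edit_records_for_path,
    graph_distance,
    read_edits_tsv,
    segmentation_distance,
    write_edits_tsv,
)
from pansegdist.gfa_io import GFAError
from pansegdist.segmentation import BreakpointSet, breakpoints_of_path


def bset(positions, length=10_000, name="g"):
    return BreakpointSet(name, length, tuple(sorted(positions)))


# Pairs of breakpoint sets over a 10 kb genome; hypothesis drives the
# overlap structure, covering empty, disjoint, nested and equal sets.
positions_sets = st.sets(st.integers(min_value=1, max_value=9_999), max_size=300)


def test_worked_example():
    result = segmentation_distance(bset({3, 8}, 10), bset({3, 5}, 10))
    assert result.merges == (8,)
    assert result.splits == (5,)
    assert result.distance == 2


def test_identical_sets_distance_zero():
    result = segmentation_distance(bset({3, 8}, 10), bset({3, 8}, 10))
    assert result.merges == result.splits == ()


def test_mismatched_genomes_rejected():
    with pytest.raises(GFAError, match="length mismatch"):
        segmentation_distance(bset({3}, 10), bset({3}, 11))
    with pytest.raises(GFAError, match="name mismatch"):
        segmentation_distance(bset({3}, 10), bset({3}, 10, name="other"))


@settings(derandomize=True, max_examples=200)
@given(positions_sets, positions_sets)
def test_scan_equals_set_oracle(a, b):
    """The scan reproduces the symmetric difference, element for element."""
    result = segmentation_distance(bset(a), bset(b))
    merges, splits = brute_force_edits(a, b)
    assert result.merges == merges
    assert result.splits == splits
    assert result.distance == len(set(a) ^ set(b))


@settings(derandomize=True, max_examples=100)
@given(positions_sets, positions_sets)
def test_role_swap_symmetry(a, b):
    fwd = segmentation_distance(bset(a), bset(b))
    rev = segmentation_distance(bset(b), bset(a))
    assert fwd.merges == rev.splits
    assert fwd.splits == rev.merges
    assert fwd.distance == rev.distance


@settings(derandomize=True, max_examples=100)
@given(positions_sets, positions_sets)
def test_conservation_law(a, b):
    """|B_a| - merges + splits == |B_b|."""
    result = segmentation_distance(bset(a), bset(b))
    assert len(a) - len(result.merges) + len(result.splits) == len(b)


@settings(derandomize=True, max_examples=100)
@given(positions_sets, positions_sets, positions_sets)
def test_triangle_inequality(a, b, c):
    d_ab = segmentation_distance(bset(a), bset(b)).distance
    d_bc = segmentation_distance(bset(b), bset(c)).distance
    d_ac = segmentation_distance(bset(a), bset(c)).distance
    assert d_ac <= d_ab + d_bc


@settings(derandomize=True, max_examples=100)
@given(positions_sets, positions_sets)
def test_scan_iteration_bound(a, b):
    """Cursor advances are bounded by |B_a ∪ B_b|."""
    result = segmentation_distance(bset(a), bset(b))
    assert result.iterations <= len(set(a) | set(b))


def test_forced_shared_positions_many_seeds():
    """200 draws per side with 50 forced shared, against the set oracle."""
    for seed in range(20):
        rng = random.Random(seed)
        pool = rng.sample(range(1, 10_000), 350)
        shared, rest = set(pool[:50]), pool[50:]
        a = shared | set(rest[:150])
        b = shared | set(rest[150:300])
        result = segmentation_distance(bset(a), bset(b))
        merges, splits = brute_force_edits(a, b)
        assert (result.merges, result.splits) == (merges, splits)
        assert result.distance == len(a ^ b)


def test_graph_distance_self_is_zero(synthetic_pair):
    _, graph_a, _, _ = synthetic_pair
    report = graph_distance(graph_a, graph_a)
    assert report.total_distance == 0
    assert all(c.distance == 0 for c in report.per_path.values())


def test_graph_distance_subset_segmentation():
    ga = gfa_from_text("S\tx1\t*\tLN:i:3\nS\tx2\t*\tLN:i:5\nS\tx3\t*\tLN:i:2\nP\tg\tx1+,x2+,x3+\t*\n")
    gb = gfa_from_text(
        "S\ty1\t*\tLN:i:3\nS\ty2\t*\tLN:i:2\nS\ty3\t*\tLN:i:3\nS\ty4\t*\tLN:i:2\n"
        "P\tg\ty1+,y2+,y3+,y4+\t*\n"
    )
    report = graph_distance(ga, gb)
    comp = report.per_path["g"]
    assert comp.merges == ()
    assert comp.splits == (5,)
    assert report.total_distance == 1


def test_graph_distance_matches_generator_truth(synthetic_pair):
    _, graph_a, graph_b, pairs = synthetic_pair
    report = graph_distance(graph_a, graph_b)
    for name, pair in pairs.items():
        comp = report.per_path[name]
        assert comp.merges == pair.merges
        assert comp.splits == pair.splits
    assert report.total_distance == sum(p.distance for p in pairs.values())


def test_graph_distance_symmetry(synthetic_pair):
    _, graph_a, graph_b, _ = synthetic_pair
    fwd = graph_distance(graph_a, graph_b)
    rev = graph_distance(graph_b, graph_a)
    assert fwd.total_distance == rev.total_distance
    for name in fwd.per_path:
        assert fwd.per_path[name].merges == rev.per_path[name].splits
        assert fwd.per_path[name].splits == rev.per_path[name].merges


def test_no_shared_path_is_an_error():
    ga = gfa_from_text("S\tA\tACG\nP\tg1\tA+\t*\n")
    gb = gfa_from_text("S\tB\tACG\nP\tg2\tB+\t*\n")
    with pytest.raises(GFAError, match="no shared path"):
        graph_distance(ga, gb)


def test_path_rename_reconciles_naming():
    ga = gfa_from_text("S\tA\tACG\nP\tg1\tA+\t*\n")
    gb = gfa_from_text("S\tB\tACG\nP\tsample#0#chr\tB+\t*\n")
    report = graph_distance(ga, gb, path_rename={"sample#0#chr": "g1"})
    assert report.shared_paths == ["g1"]
    assert report.total_distance == 0


def test_shared_path_length_mismatch_identifies_both():
    ga = gfa_from_text("S\tA\tACG\nP\tg\tA+\t*\n")
    gb = gfa_from_text("S\tB\tACGT\nP\tg\tB+\t*\n")
    with pytest.raises(GFAError, match=r"'g'.*3.*4"):
        graph_distance(ga, gb)


def test_private_paths_listed_and_excluded():
    ga = gfa_from_text("S\tA\tACG\nS\tX\tAA\nP\tg\tA+\t*\nP\tonly_a\tX+\t*\n")
    gb = gfa_from_text("S\tB\tACG\nS\tY\tCC\nP\tg\tB+\t*\nP\tonly_b\tY+\t*\n")
    report = graph_distance(ga, gb)
    assert report.shared_paths == ["g"]
    assert report.private_paths_a == ["only_a"]
    assert report.private_paths_b == ["only_b"]


def test_edit_record_nodes_and_ends():
    # graph A: node spanning (3, 8]; graph B: junctions at 5 and 8
    ga = gfa_from_text("S\ta1\t*\tLN:i:3\nS\ta2\t*\tLN:i:5\nS\ta3\t*\tLN:i:2\nP\tg\ta1+,a2+,a3+\t*\n")
    gb = gfa_from_text(
        "S\tb1\t*\tLN:i:5\nS\tb2\t*\tLN:i:3\nS\tb3\t*\tLN:i:2\nP\tg\tb1+,b2+,b3+\t*\n"
    )
    report = graph_distance(ga, gb)
    edits = report.per_path["g"].edits
    by_pos = {e.position: e for e in edits}
    assert set(by_pos) == {3, 5}
    merge_at_3 = by_pos[3]
    assert merge_at_3.operation == MERGE
    assert (merge_at_3.node_a, merge_at_3.end_a) == ("a1", 3)  # node ending at 3
    assert (merge_at_3.node_b, merge_at_3.end_b) == ("b1", 5)  # node spanning (0,5]
    split_at_5 = by_pos[5]
    assert split_at_5.operation == SPLIT
    assert (split_at_5.node_a, split_at_5.end_a) == ("a2", 8)  # node spanning (3,8]
    assert (split_at_5.node_b, split_at_5.end_b) == ("b1", 5)


def test_edit_records_match_interval_scan_oracle(synthetic_pair):
    _, graph_a, graph_b, _ = synthetic_pair
    report = graph_distance(graph_a, graph_b)

    def interval_of(graph, name, position):
        """Brute-force scan of the path's occurrence intervals."""
        start = 0
        for step in graph.paths[name].steps:
            end = start + graph.nodes[step.node_id].length
            if start < position <= end:
                return step.node_id, end
            start = end
        raise AssertionError("position beyond path")

    for name, comp in report.per_path.items():
        for rec in comp.edits:
            assert (rec.node_a, rec.end_a) == interval_of(graph_a, name, rec.position)
            assert (rec.node_b, rec.end_b) == interval_of(graph_b, name, rec.position)
            assert rec.position <= rec.end_a
            assert rec.position <= rec.end_b


def test_edit_records_ordered_by_position(synthetic_pair):
    _, graph_a, graph_b, _ = synthetic_pair
    report = graph_distance(graph_a, graph_b)
    for comp in report.per_path.values():
        positions = [e.position for e in comp.edits]
        assert positions == sorted(positions)


def test_cyclic_path_occurrences_are_per_traversal():
    # one node traversed twice: records at the same node id, distinct ends
    ga = gfa_from_text(
        "S\tr\t*\tLN:i:4\nL\tr\t+\tr\t+\t0M\nP\tg\tr+,r+\t*\n"
    )
    gb = gfa_from_text(
        "S\tu\t*\tLN:i:2\nS\tv\t*\tLN:i:6\nL\tu\t+\tv\t+\t0M\nP\tg\tu+,v+\t*\n"
    )
    report = graph_distance(ga, gb)
    comp = report.per_path["g"]
    assert comp.merges == (4,)
    assert comp.splits == (2,)
    by_pos = {e.position: e for e in comp.edits}
    assert by_pos[2].node_a == "r" and by_pos[2].end_a == 4
    assert by_pos[4].node_a == "r" and by_pos[4].end_a == 4


def test_edits_tsv_roundtrip(synthetic_pair):
    _, graph_a, graph_b, _ = synthetic_pair
    report = graph_distance(graph_a, graph_b)
    buf = io.StringIO()
    write_edits_tsv(report, buf)
    text = buf.getvalue()
    assert text.startswith("#path\tposition\toperation\tnode_a\tnode_b\tend_a\tend_b\n")
    back = read_edits_tsv(io.StringIO(text))
    assert back == report.all_edits()
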