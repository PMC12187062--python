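import io

import pytest

from pansegdist import synthetic
from pansegdist.gfa_io import read_gfa

MINI_GFA = "S\tA\tACG\nS\tB\tTT\nP\tg1\tA+,B+\t*\n"

WALK_GFA = (
    "S\tA\tACG\nS\tB\tTT\n"
    "W\tsampleX\t0\tchr1\t0\t5\t>A>B\n"
)


def gfa_from_text(text: str):
    return read_gfa(io.StringIO(text))


def brute_force_edits(b_a, b_b):
    """Independent set-algebra oracle: (merges, splits) as sorted tuples."""
    sa, sb = set(b_a), set(b_b)
    return tuple(sorted(sa - sb)), tuple(sorted(sb - sa))


@pytest.fixture
def mini_graph():
    return gfa_from_text(MINI_GFA)


@pytest.fixture(scope="session")
def synthetic_pair():
    """Default study conditions: 5 genomes x 10 kb, 200+200 breakpoints."""
    spec = synthetic.SyntheticSpec(seed=11)
    graph_a, graph_b, pairs = synthetic.generate_pair(spec)
    return spec, graph_a, graph_b, pairs
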