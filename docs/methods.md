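# Methods

## Model

A complete pangenome graph embeds every genome of a collection as one
path whose oriented node labels concatenate to the genome sequence. The
path of genome Γᵢ therefore induces a segmentation of Γᵢ: the set Bᵢ of
internal positions (0-based bp from the genome start) where consecutive
node occurrences meet. A breakpoint at x separates offsets x−1 and x;
the genome boundaries 0 and L are never breakpoints.

Two graphs built from the same genomes are compared per shared genome by
the symmetric difference of their breakpoint sets. A *merge* removes a
breakpoint private to the first graph, a *split* adds one private to the
second; |Bᵃ ⊖ Bᵇ| is the minimal number of such single-breakpoint edits,
and summing over the shared genomes gives the graph distance. Because
the symmetric-difference cardinality is an XOR distance, the result is a
metric: zero iff the segmentations agree, symmetric under exchanging the
graphs (merges and splits swap roles), and triangle-inequality-obeying.
These properties are asserted by the test suite rather than assumed.

The per-genome computation is a single simultaneous scan: two cursors
walk the sorted breakpoint lists, the current position always advancing
to the next closest breakpoint across both. A virtual sentinel equal to
the genome length terminates both cursors (the pseudocode's index
overflow case) and is never emitted as an edit. The scan touches each
element of Bᵃ ∪ Bᵇ exactly once; the recorded iteration count is checked
against this bound in the tests.

Comparisons between graphs whose path sets differ use the intersection
of path names (after an optional user-supplied rename map that
reconciles walk-derived `sample#hap#seqid` names with P-line names);
paths private to either graph are reported and excluded.

## Spurious breakpoints

Builders chop long nodes into bounded-size pieces for performance; the
resulting junctions model no variation. "Non-branching" is defined here
path-wise, on node *sides* (each node has a left and a right side;
traversing a node forward exits through its right side): a junction
between sides s₁ and s₂ is spurious iff across all path traversals s₁
only ever meets s₂ and vice versa, neither side is ever a path endpoint,
and the edge set (when the file carries edges) offers no other adjacency
on either side. Reading reverse traversals in canonical orientation
makes the side pair well-defined; a fold-back junction joining the same
side to itself is never spurious (the node cannot be merged with
itself). This path-based choice, rather than a purely degree-based one,
treats the paths as the ground truth of the structure and correctly
handles path endpoints and junctions crossed in both directions. Merging
across a spurious junction would change no path, so masking the
breakpoints it generates (the `--spurious` flag; off by default) makes
the distance invariant to chopping — verified for chop sizes 1, 2, 8 and
32.

Masking has one visible consequence for the synthetic default graphs:
a graph whose genomes occupy disjoint linear chains has *only*
non-branching junctions, so masking empties every breakpoint set. Masked
comparisons are therefore exercised on chopped graphs and on shared-node
graphs, where genuine branching survives masking; unmasked comparisons
validate the distance against ground truth.

## Edit localization and geometry

Every edit can be read as a split by exchanging the two segmentations:
a merge splits the node of the second graph spanning the position, a
split the node of the first. Per edit the output records the breakpoint
coordinate, the operation letter (M/S), and for both graphs the node
whose occurrence interval (start, end] contains the position together
with that occurrence's end coordinate — at a junction this is the node
ending exactly there, which keeps the reported end well-defined. Node
occurrences are per-traversal, so cyclic paths yield one record per
crossing.

Geometry is measured on the split-side segment of the *effective*
segmentation (post-masking when masking was requested): the edit
position is the distance to the nearest segment border (≤ half the
segment length), and the edit size is the smallest piece the operation
produces when the segment borders and all co-occurring edits on the same
segment count as simultaneous boundaries. Treating co-edits as
simultaneous rather than sequential makes sizes order-independent.
Per-node edit counts aggregate occurrences by node id.

One deliberate reading: the small-node stratification reports the
fraction of edits on nodes ≤ t bp against the fraction of summed node
length in such nodes *pooled over both graphs*, since one report's split
nodes live in both (merges on the second graph's nodes, splits on the
first's).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `--spurious` | off | mask non-branching breakpoints before the scan |
| window size | 1000 bp | half-open tiling for edit/node densities, in units per kb |
| node-length threshold | 50 bp | small-node stratification cut-off |
| chop size | none | synthetic only: max piece length for the chopped copy |

## Synthetic study conditions

The generator draws uniform A/C/G/T genomes and, per genome, a pair of
breakpoint sets with a controlled overlap: the shared positions
(⌈shared_fraction · min(nₐ, n_b)⌉ of them) are drawn first, then each
side's private positions, all without replacement from 1..L−1, so the
private sets *are* the exact expected merge and split sets. Defaults: 5
genomes of 10 kb, 200 breakpoints per genome per side, half shared —
one node per ~50 bp, a segmentation density in the range chromosome-
scale graphs exhibit. All draws derive from a single integer seed.

Default graphs give each genome its own linear chain of labeled nodes
(a valid complete graph; completeness is checked by reconstruction).
`shared_node_graph` covers the multi-traversal regime — identical
segments collapse into nodes crossed by every path, so one junction
difference counts once per traversing genome, matching the summation
over genomes. `chop_nodes` rewrites nodes, labels, edges and paths so
completeness is preserved and returns exactly the junctions it created.

What the generator does not emulate: realistic variation (SNPs,
structural variants, repeats), builder alignment heuristics, cycles
created by repeat collapse, or inter-genome node sharing outside the
shared-node construction. Passing tests therefore demonstrate the
correctness of the distance computation and its invariants, not that
any particular builder's graphs are well-formed; real comparisons run
through the same GFA path with nothing synthetic involved.

## Numerical and design choices

- Coordinates are 0-based; intervals are half-open [start, end) for
  windows and (start, end] for node-occurrence containment.
- Window densities are 1000 × count / window width; the last window may
  be short and is normalized by its true width, so window counts sum
  exactly to the per-path edit total.
- Edge identity is orientation-normalized (an edge and its reverse
  complement are one edge); P-line overlaps other than `*`/`0M` are
  rejected because true overlaps would break the segmentation
  arithmetic.
- Graphs may be lengths-only (`*` sequences with `LN:i` tags): the
  distance needs node lengths, not labels; only completeness validation
  requires labels.
- Max-node ties break to the lexicographically smallest node id.
- Degenerate inputs: zero-length nodes are rejected (duplicate
  positions); an empty edit list has no size summary (reported as null
  by the CLI); shared paths with unequal lengths are an error naming
  the path and both lengths.
- Problem sizes in the test suite and acceptance script (up to 10
  genomes × 10 kb × 500 breakpoints, 100 random instances) keep every
  oracle brute-forceable while covering the regime boundaries; the
  pipeline itself is linear in path length and handles chromosome-scale
  graphs.

## Known limitations

- The distance sees segmentations only: two graphs with identical
  breakpoint sets but different connectivity (differently shared nodes,
  cycles) are at distance zero. Topology-aware comparison is out of
  scope.
- Edits on nodes traversed by many genomes count once per traversal;
  this over-weighting is intentional (such differences affect more
  genomes) but is a modelling choice.
- Path name reconciliation between naming conventions is delegated to
  the user-supplied rename map; no fuzzy matching is attempted.
- Hierarchical clustering of distance matrices is not implemented; the
  CSV export is the interface to external tools.
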