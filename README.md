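# pansegdist

Segmentation edit distance between pangenome variation graphs built from
the same genome collection.

## The problem

A pangenome variation graph G = (V, E, P) embeds each input genome as a
path whose oriented node labels concatenate back to the genome sequence
(a *complete* graph). Construction pipelines such as Minigraph-Cactus and
PGGB apply different alignment heuristics and produce different graphs
from identical inputs, but simple summaries (node/edge counts) cannot say
*where* or *how much* two graphs disagree.

`pansegdist` compares two graphs through the genomes they share. The path
of genome Γᵢ induces a breakpoint set Bᵢ — the positions (bp from the
genome start) where node boundaries cut the sequence. For graphs Gₐ and
G_b the per-genome distance is the size of the symmetric difference

&nbsp;&nbsp;&nbsp;&nbsp;d_s(Pᵢᵃ, Pᵢᵇ) = |Bᵢᵃ ⊖ Bᵢᵇ|,

the minimal number of single-breakpoint edits — *merges* (remove a
breakpoint private to Gₐ) and *splits* (add one private to G_b) — that
transform one segmentation into the other. The graph distance
d(Gₐ, G_b) = Σᵢ d_s is a true metric (symmetric-difference/XOR distance)
and decomposes into a per-edit list that localizes every disagreement on
the genome and on the nodes of both graphs. Each genome is processed by a
single two-cursor scan in O(|Bᵃ ∪ Bᵇ|) steps.

Breakpoints at *non-branching* junctions (typically introduced when
builders chop long nodes into bounded pieces) model no variation; they
can be detected and masked (`--spurious`) so that chopping alone yields
distance zero.

## Worked example

```sh
pansegdist generate --genomes 3 --length 2000 --breakpoints-a 40 \
    --breakpoints-b 40 --shared-fraction 0.5 --seed 7 -o pair
pansegdist compare pair_a.gfa pair_b.gfa -o edits.tsv
```

prints (configuration log on stderr omitted):

```json
{
  "merges": 60,
  "splits": 60,
  "distance": 120,
  "edits_per_kb": 20.0,
  "shared_paths": ["g00", "g01", "g02"],
  "skipped_paths": []
}
```

Three 2 kb genomes were segmented twice with 40 breakpoints each and half
of them shared, so each side carries 20 private breakpoints per genome:
60 merges + 60 splits = 120 edits over 6 kb, i.e. 20 edits/kb. The first
edit rows of `edits.tsv`:

```
#path	position	operation	node_a	node_b	end_a	end_b
g00	27	M	g00.0	g00.0	27	34
g00	85	M	g00.2	g00.1	85	103
```

Each row gives the genome, the breakpoint coordinate, the one-letter
operation (M = merge, S = split), the node whose occurrence covers the
position in each graph, and both nodes' ending coordinates. Per-edit
analytics (edit sizes, small-node stratification, per-kb window
densities) come from `pansegdist stats`, and all-pairs comparisons of
many graphs from `pansegdist matrix`, whose CSV feeds external
clustering tools. Real graphs in GFA 1.0 (`P` lines) or 1.1 (`W` walks)
are compared the same way: `pansegdist compare mc.gfa pggb.gfa
--spurious -o edits.tsv`.

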