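# Methods

## Scope and model

motifquad computes the exact census of connected induced k-vertex
subgraphs of a simple graph, classifies subgraphs into isomorphism
classes, and scores each class against a degree-preserving random
ensemble. The graph model is deliberately narrow: simple (no
self-loops, no parallel arcs), unweighted, uncolored, directed or
undirected, small enough for adjacency to live in memory. Self-loops
and duplicate arcs in input files are preprocessing noise, not data,
and are dropped with a logged count; vertex ids are remapped to
`0..n-1` in first-appearance order, which also fixes the total vertex
order that the ESU enumeration requires. Any fixed order yields the
same census; this one makes runs reproducible from the input file
alone.

## Enumeration

ESU guarantees each connected induced k-subgraph is visited exactly
once: a subgraph is generated only from its minimum vertex, and
extension candidates are restricted to exclusive neighbours (neighbours
of the newly added vertex not already adjacent to the partial
subgraph) greater than that root. Neighbourhood is always the union of
in- and out-neighbours, so directed subgraphs are connected in the weak
sense. Candidates are consumed in ascending vertex order. A uniformly
random draw from the extension set would produce the same multiset of
visits — the census is order-invariant — so determinism costs nothing
and buys reproducible traces; the order-invariance is itself covered by
a relabeling property test.

The inner loops work on per-vertex neighbour bitmasks (Python
arbitrary-precision ints). Set algebra on whole neighbourhoods becomes
single integer operations, which is what lets a pure-Python census
clear roughly a million subgraphs per second on a dense
hundred-vertex graph.

## Classification through the quaternary tree

When vertex *w* extends a partial subgraph whose vertices, in
insertion order, are u₁…u_e, the pattern of connections
(u_i, w) is a string over four symbols: mutual, forward-only,
backward-only, absent. The quaternary tree is the prefix tree of these
strings accumulated over all extension steps; a complete k-subgraph
corresponds to a path of length k(k−1)/2. Symbols map to fixed child
slots (`-1→0, 0→1, 1→2, 2→3`), so descent is an array index per level.

Subgraphs sharing a leaf are isomorphic (their adjacency matrices are
equal under the insertion-order labeling), so each leaf memoizes the
isomorphism class computed for its first subgraph. The converse fails —
one class is typically spread over many leaves — which is why leaf
count, not class count, bounds the number of canonical-labeling calls.
Nodes store only a 4-slot child array and the class pointer: no parent
links, no per-node counters. Counts accumulate on class records and in
per-network census objects, keeping the tree as small as its
unavoidable growth allows (its memory footprint is the known cost of
the approach).

One tree serves the entire run. During random-network censuses the
tree keeps growing — later ensemble members therefore trigger fewer
and fewer canonical calls, a saturation the run summary exposes as
per-network new-leaf counts — while the class registry is frozen: a
leaf whose label is unknown to the frozen registry caches a "novel"
verdict and all subgraphs reaching it are excluded from counts (and
tallied separately).

## Canonical labeling

The canonical form of a k-vertex adjacency matrix is the minimum
row-major bit-string over all k! vertex permutations, giving a label of
length k² with zero diagonal. Minimisation is exhaustive with
row-by-row early termination against the incumbent; no partition
refinement is attempted. This is a deliberate trade: the labeling
routine runs once per quaternary leaf, leaves number in the thousands
at the sizes this package targets (k ≤ 6), and an exact, dependency-free
30-line minimiser is easier to trust than a refinement scheme. The
cost is factorial in k, so k beyond ~8 would need a stronger
canonicalizer. Equality of labels is exact isomorphism; the test suite
certifies this exhaustively against networkx's matcher for all directed
graphs on ≤ 4 vertices and all undirected graphs on 4 vertices.

The class registry is a hash map keyed by the label string. A
bit-trie over label bits would have identical observable behaviour;
the map was chosen because Python's dict is the faster exact lookup.

## Null model and significance

Random networks are produced by the switching Markov chain: pick two
arcs (a→b), (c→d) uniformly, propose (a→d), (c→b), reject proposals
creating self-loops or duplicates; rejected proposals still consume an
attempt. Attempts number ⌈3 × edges⌉ by default. With
`preserve_reciprocal` (default) mutual arc pairs swap only with mutual
pairs — both directions exchanged together — and single arcs only with
single arcs, conserving the reciprocal-pair count alongside the in- and
out-degree sequences; the flag exists because conserving reciprocity is
the convention of motif null models but not a mathematical necessity.
Undirected graphs treat each edge as one unit and choose between the
two re-pairings uniformly. Every ensemble member uses seed
`base + index`, so ensembles are reproducible and members independent.

z-scores use the population (divide-by-r) standard deviation over
exactly r random censuses, counting a class absent from a random
network as 0. A class with zero ensemble variance gets z = NA rather
than ±∞ — reporting infinite significance from a degenerate null
distribution would be fabrication. Only classes present in the
original network are reported. No frequency or uniqueness filters are
applied.

## Synthetic data

The fixture generator covers two needs. Analytic kinds (path, cycle,
star, complete) have closed-form censuses — n−k+1, n, C(n−1, k−1) and
C(n, k) subgraphs respectively, one class each — used as exact oracles.
Random kinds: Erdős–Rényi with per-arc probability p, and a power-law
directed generator that draws both arc endpoints from Zipf-like weights
(rank^(−1/(γ−1)), γ = 2.5) with rejection of loops and duplicates,
sized at 300 vertices and mean degree 2.5 to emulate the sparse,
hub-dominated shape of small transcription and metabolic networks —
hundreds of vertices, a couple of arcs per vertex — which is the regime
where leaf memoization pays off most.

What the synthetic graphs do not emulate: the degree correlations,
modularity and biological autocorrelation of real interaction networks.
Passing tests therefore certify algorithmic exactness (census counts,
conservation laws, class partitions) on graphs of realistic size and
sparsity, not any biological claim about specific motifs.

## Numerical and degenerate-input choices

- Census requires 2 ≤ k ≤ n; k larger than the largest connected
  component yields an empty census with a warning, not an error.
- Graphs admitting no valid switch (single edge, directed 3-cycle,
  complete graph) return identical copies from the randomizer, and a
  zero-variance ensemble then propagates to z = NA.
- Identical-index arc draws in the switching chain are rejected like
  any other failed proposal.
- All randomness flows through explicit `random.Random(seed)`
  instances; nothing touches global random state.
- Ties in the z-sorted report are broken by class id; undefined-z rows
  sort last.

## Problem sizes in the test suite

The suite checks exact agreement between the fused census and an
independent brute-force subset enumeration on ~200 random graphs
(n ≤ 12, k ∈ {3,4,5}, both orientations, densities 0.05–0.5), leaf
purity by brute-force permutation testing on a directed ER(30, 0.3)
graph at k = 4, full class discovery (all 6 connected undirected
4-vertex shapes) on ER(100, 0.3), and conservation laws over 100
rewirings of ER(100, 0.05). These sizes give complete combinatorial
coverage of the logic while keeping the whole suite under a minute.

## Known limitations

- Canonical labeling is factorial in k; practical up to k ≈ 8.
- The quaternary tree's node count grows with pattern variety, which is
  the method's documented memory cost on class-rich networks.
- No sampling (RAND-ESU-style) or parallel enumeration; the census is
  always exact and single-threaded.
- Weighted, colored and multi-graphs are out of scope, as is
  connectivity-preserving rewiring.
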