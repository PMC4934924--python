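# Methods

## Scope and model

`allomod` compares the modular decomposition of condition-specific
interaction networks. All graphs are simple and undirected; node
identifiers are opaque, case-sensitive strings (Entrez gene IDs in the
motivating application), and the canonical form of an edge is the
lexicographically sorted pair — every module, similarity and overlap
computation uses that canonicalisation, so (a, b) and (b, a) are always the
same edge.

A condition's *target network* is the subgraph of the global interaction
network induced by its differentially expressed genes. Differential
selection applies a strict inequality (value > threshold, default 1). Two
modes exist because mean-centered expression scores are signed: `signed`
(the default, the literal "greater than" rule) and `absolute`
(|value| > threshold). Which of the two the original study intended is not
decidable from its description; the default follows the literal rule and
the switch is exposed.

## Module detection

**MCODE** is re-implemented from the published three-stage description.

1. *Vertex weighting.* Nodes with degree below `degree_cutoff` (default 3)
   get weight 0 and never seed or join a complex. Otherwise the weight is
   the core-clustering coefficient: k × density of the highest k-core of
   the node's closed neighbourhood. Self-loops are excluded throughout
   (they are already removed at I/O).
2. *Complex prediction.* Seeds are processed in descending weight with ties
   broken by lexicographic node ID — the tie rule that makes the procedure
   fully deterministic. Breadth-first expansion admits an unvisited
   neighbour whose weight is ≥ seed weight × (1 − `node_score_cutoff`),
   to at most `max_depth` levels from the seed; visited nodes never join a
   second complex.
3. *Post-processing.* Complexes without a `k_core`-core (default 2) are
   discarded; `fluff` (before haircut) adds boundary neighbours whose
   closed-neighbourhood density exceeds `fluff_density`, and may create
   overlapping complexes; `haircut` trims the complex to its 2-core.
   A complex scores density × node count; output is sorted by descending
   score.

**MCL** is the standard column-stochastic iteration: self-loops of weight 1
are added (stabilises convergence), columns normalised, then expansion
(matrix power, default 2) alternates with inflation (elementwise power,
column renormalise) until the matrix change falls below `tol` (default
1e-6) or `max_iters` (200) is reached — non-convergence returns the
current interpretation with a warning flag. Clusters are read from
attractor rows; attractor systems sharing members are merged and any
unclaimed node is attached to its strongest column, so the output is
always a partition.

**Affinity propagation** delegates the responsibility/availability message
passing to scikit-learn on a precomputed similarity. The graph-to-
similarity transform is unit adjacency (1 for neighbours, 0 otherwise) with
`preference` on the same scale — the simplest choice consistent with an
unweighted interaction graph; it is overridable by passing an explicit
similarity matrix. Failure to converge falls back to singleton modules with
a warning flag rather than raising.

Parameter grids mirror the study design: preference 0.1–1.0 in steps of
0.1; inflation 1.5–5.0 in steps of 0.5; the 16 MCODE combinations of
haircut/fluff × max depth {100, 5, 4, 3} with the fixed cutoffs above.
Sweep failures are recorded on the returned decomposition, not raised.

## Network structure entropy

Node importance is the degree share Iᵢ = kᵢ/Σkⱼ and the structure entropy
is E = −Σ Iᵢ ln Iᵢ, in nats — natural logarithms throughout, since the
star-graph closed form E_min(N) = ½ ln 4(N−1) only closes in nats. Regular
graphs attain the ceiling ln N; the star attains the floor (hub importance
½, each of the N−1 leaves ½(N−1)⁻¹).

A *decomposition's* entropy is computed on the union of its module-induced
subgraphs, with degrees counted inside that union. This is a deliberate
choice where the source description is ambiguous: the union is the only
graph that actually varies with the clustering, and when the modules cover
the whole network the definition reduces to the plain network entropy. A
`degrees="global"` switch (degrees taken from the parent network) is
provided for sensitivity analysis. Selection takes the candidate with the
smallest entropy; ties break toward fewer modules, then method name.

**Known limitation.** Because the entropy is bounded by ln(union size), the
criterion intrinsically rewards small unions. In a sweep that mixes
methods, a candidate that leaves most nodes in sub-threshold clusters
(e.g. affinity propagation at high preference, after the ≥ 3-node filter)
can win with a degenerate two-or-three-node union. On large scale-free
networks the competing candidates all cover substantial subgraphs and the
criterion discriminates as intended; on small fixtures it is safest to
sweep within one method (the CLI therefore defaults to the MCODE grid, with
`--method all` available).

**Null model.** Degree-preserving randomization uses double-edge swaps with
rejection: 10 × |edges| attempted swaps, each proposal discarded if it
would create a self-loop or parallel edge, so the degree multiset is
preserved exactly and the graph stays simple. Graphs admitting no valid
swap (a triangle) return an identical copy with a warning. Significance of
an observed decomposition entropy against n (default 50) rewired
replicates is the add-one-smoothed empirical rank
p = (1 + #{E_rep ≤ E_obs})/(n+1) — distribution-free, p ∈ (0, 1], equal to
1/51 when the observed value undercuts all 50 replicates; a one-sample
t-test p-value is reported alongside. Replicates where detection yields no
scorable module are skipped and counted. Note the direction of the effect
is scale-dependent: on small planted fixtures rewiring *shrinks* detected
coverage and the null entropies fall below the observed one, so a small
p here indicates order only when the competing unions are comparable in
size.

## Enrichment

The p-value for a term is the exact hypergeometric upper tail
P(X ≥ k) with population |background|, successes |term|, draws
|module ∩ background| — exact summation via the survival function, no
normal approximation. An EASE-style variant (tail at k−1, floored at 0) is
available behind a flag for users who want the more conservative score.
The background defaults to the annotation universe and is clipped to the
analysed network's node set before testing (`restricted_to`), the usual
assayed-universe convention; it is overridable. Benjamini–Hochberg
correction is applied across terms (order-invariant, capped at 1, monotone
in rank), and F(m) is the set of terms with corrected p strictly below
alpha (default 0.05). Modules sharing no genes with the background get
F(m) = ∅ rather than an error so uncharacterized modules flow through
similarity scoring.

## SimiNEF and the taxonomy

The three component similarities are plain Jaccard coefficients over node
sets, canonical edge sets, and significant-term sets, each computed as a
ratio of integers — identical non-empty inputs give exactly 1.0, so the
conserved-module test (all components = 1) needs no floating-point
tolerance. When both inputs of a component are empty the component is
reported as 0.0 with an `undefined` flag and can never qualify at any
threshold; for function sets this is a deliberate conservative policy that
prevents spurious conserved calls between two functionally
uncharacterized modules.

S_nef > k holds iff S_n, S_e and S_f all strictly exceed k; the ladder's
terminal level (=100 %) instead requires exact equality of all three to 1.
The default ladder is (1, 25, 50, 70, 75, 100) percent. Pairs are compared
only across conditions.

Per ladder level, a compound module with no qualifying vehicle counterpart
is a GAM, a vehicle module with no qualifying counterpart in any compound
condition is a DAM; both are reported per level because "present/absent"
is threshold-relative. A CAM groups a vehicle module with every compound
module identical to it (level 100). An AM is any cross pair whose smallest
component lies strictly inside (0, 1) — some overlap, not complete — and
carries the highest non-terminal level it qualifies at. The watershed
(WAM) search scans non-terminal levels top-down; at each level it builds
the all-of-three overlap graph and looks for a connected component
containing modules of *every* condition; the first level with such a
spanning component wins, ties at that level are all returned ordered by
mean node similarity. Overlap graphs also support the any-of-three rule
used for descriptive overlap maps; the all-of-three graph is always a
subgraph of the any-of-three graph.

Gradient counts classify each module per level as overlapping (some
cross-condition counterpart qualifies under all-of-three) or
non-overlapping; the two always sum to the condition's module total. The
non-overlap trend is summarised by ordinary least squares of the count on
the level (percent scale) with the usual two-sided t-test on the slope,
and the topology/function association by the Pearson correlation between
each node's connecting percentage (intra-module degree share) and its
module's significant-term count.

## Synthetic data

The generator emulates the study design: one vehicle plus three compound
conditions, seven planted module families. Defaults: families of 5–8 genes
(matching the reported mean module sizes of ~5–6), within-family edge
probability p_in = 1 (cliques — the clique-like complexes the detectors
are tuned for), background edge probability p_out = 0, 120 background
genes, differential score 2.0 against a threshold of 1 with background
scores drawn from U(−0.8, 0.8). Two families are conserved into disjoint
compound subsets (so no conserved family spans all conditions), three are
generated in exactly one compound each, one is vehicle-only, and one is
present everywhere with 25 % of its nodes replaced per compound — the
planted watershed. Each family's edges are sampled once over its full gene
universe, so conserved copies are identical and rewired copies agree on
shared nodes by construction.

Ground truth is recorded by set arithmetic at generation time —
memberships, planned pairwise Jaccards, family labels, and the planted
watershed level (the highest ladder rung strictly below the family's
smallest cross-condition component) — independently of any detection run.
Expression is generated post hoc to satisfy the differential rule rather
than from a microarray noise model: the generator tests the network
computation, not normalisation. Consequences for interpretation: passing
recovery tests shows the pipeline recovers clique-shaped planted structure
under clean separation; it does not show robustness to hub-dominated
degree distributions, annotation incompleteness, or expression noise
around the differential threshold, none of which the generator emulates.
Same seed ⇒ byte-identical outputs; all randomness flows from the single
spec seed.

## Problem sizes and numerical choices

The recovery suite and the acceptance script run the MCODE grid (16
settings) over four conditions of ~20 genes each — seconds of runtime —
and the null-ensemble checks use 10–50 replicates of rewiring on
30–40-node graphs. Tolerances: exact integer-ratio comparisons wherever a
quantity is rational (Jaccards, empirical p-values); 1e-9 for centering
and importance sums; MCL convergence at 1e-6 with entries below 1e-12
pruned. Degenerate inputs are errors with named causes (edgeless graphs
for entropy, empty files, unknown condition labels) except where a defined
fallback is stated above (undefined similarity components, AP
non-convergence, sweep failures).
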