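# Methods

## Model

`pathxtalk` operationalizes pathway cross-talk as the existence of short,
regulated routes between the member proteins of two pathways in a unified
graph G that mixes pathway nodes and protein ("xref") nodes. Membership is
encoded as reciprocal directed edges between a pathway node and each member
protein; protein interactions are directed edges, with undirected rows
(binding, association, reactions without orientation) expanded into two
opposite directed edges. Because some interaction classes are inherently
directed (e.g. transcription factor → target), the detected pathway
interactions are directed as well: (Pn, Pm) and (Pm, Pn) are evaluated
separately.

The analysis context enters exclusively through edge weights. Every edge
u→v is weighted by the differential-expression statistic of its *target*:

    w(u→v) = f(T_v) = 1 / (1 + exp(alpha * (|T_v| - mu)))

a logistic soft threshold on |T| that maps strongly regulated genes to
weights near 0 and unregulated genes to weights near 1. An edge into an
unmeasured protein receives the maximum weight 1, and an edge into a
pathway node weight 0 (entering or leaving a pathway is free, so path
lengths measure only the protein chain). With the defaults mu = 3,
alpha = 2, the transform is exactly 0.5 at |T| = 3 and f(0) ≈ 0.9975, so a
path containing even one unregulated protein-protein step already costs
close to 1.

Underlying assumption: consistent differential expression of a chain of
interacting genes is taken as evidence that the corresponding protein-level
route is active in this context. Regulation that does not manifest at the
measured level (e.g. purely post-translational signaling) is invisible to
the method.

## Procedure

For the ordered pair (Pn, Pm):

1. **Neighborhood.** Restrict G to nodes reachable from Pn within `nb`
   directed steps, counting every edge (membership or interaction) as one
   step. With nb = 5 an admissible pathway-to-pathway path has at most
   three protein-protein edges (membership out + 3 interactions +
   membership in). Pairs whose target is unreachable are scored 0.
2. **Pair subgraph.** Keep Pn, Pm, their members, and proteins annotated to
   no pathway. Members of *other* pathways are excluded so a route crossing
   a third pathway is attributed to two separate interactions with that
   pathway rather than to (Pn, Pm). For each protein shared by Pn and Pm,
   the membership edge protein→Pm is removed: overlap by itself never
   registers as interaction, but the shared protein can still serve as an
   intermediate between distinct partners in the two pathways.
3. **Non-redundant shortest paths.** Repeatedly compute the weighted
   shortest path Pn→Pm (Dijkstra; length = sum of edge weights), record it,
   and delete its interior edges — those touching neither pathway node —
   then repeat while the shortest length stays ≤ `l_max`. Successive paths
   are therefore interior-edge-disjoint and represent distinct routes.
   Termination is guaranteed: every admissible path contains at least one
   deletable protein-protein edge (a direct two-edge hop through a shared
   protein is impossible after the overlap-edge removal).
4. **Score.** S = Σ_i 1/l_i over the recorded path lengths; more and
   shorter regulated routes give larger scores. S = 0 when no admissible
   path exists.
5. **Significance.** The null rewires Pm: each member is replaced by a
   distinct random non-member of similar strength (weighted degree — the
   summed weights of incident interaction edges), preserving the member
   count and approximate connectivity, and steps 1–4 are re-run on the
   rewired graph. p = #(S_null ≥ S_observed) / n. Stage 1 uses
   `n_perm_initial` permutations; pairs below `p_extend` receive
   `n_perm_extra` more, with the p-value pooled over all permutations.
   The p-value denominator is the raw permutation count, so p = 0 is
   reportable (the permutation count is always recorded alongside for
   users who prefer pseudo-counted versions).

A pair with observed score 0 is assigned p = 1 with a recorded permutation
count of 0, without running the permutation loop: every null score is ≥ 0,
so the counting definition yields 1 identically and the shortcut changes no
output.

Gene-set enrichment is computed independently of the path search: a
pathway's score is the mean |T| of its measured members, compared against
random member-count-matched gene sets drawn without replacement from the
measured universe (default 10,000 permutations). It annotates pathway nodes
(enriched at p < 0.05) but does not influence pair scores.

## Parameters

| parameter | units | default | role |
|---|---|---|---|
| `mu` | T-statistic | 3 | |T| receiving weight 0.5; emphasizes genes beyond this threshold |
| `alpha` | 1/T | 2 | steepness of the soft threshold |
| `nb` | visited edges | 5 | neighborhood radius; caps protein-protein edges per path at 3 |
| `l_max` | summed weight | 0.9 | admissibility bound; below 2·f(0), so a path needs regulated genes |
| `n_perm_initial` | count | 100 | stage-1 permutations per scored pair |
| `n_perm_extra` | count | 1000 | stage-2 permutations for pairs with p < `p_extend` |
| `p_extend` | probability | 0.1 | threshold to enter stage 2 (pooled p over 1100) |
| `n_strata` | count | 20 | quantile strata of strength for null rewiring |
| edge p threshold | probability | 0.001 | pair significance for network edges (strict <) |

## Numerical and design choices

- **Sigmoid form.** f(T) = 1/(1 + exp(alpha(|T| − mu))) is the standard
  logistic on |T| with the required properties (range (0,1), center mu at
  0.5, steepness alpha, decreasing in |T|). It sits behind a single
  function so an alternative transform can be swapped in.
- **Overlap denominator.** Pathway overlap for merging is |A∩B|/min(|A|,|B|)
  — the most inclusive reading; `union` (Jaccard) and `mean` are available.
  Merging processes pathways in lexical id order within a round, merges each
  with its most-overlapping partner (ties toward the lexically smaller id),
  skips pathways already consumed in the round, and repeats to a fixed
  point. The lexical conventions make the result independent of input
  order.
- **Shortest-path tie-breaks.** Dijkstra relaxes successors in lexical
  order with strict-improvement updates, so equal-length alternatives
  resolve deterministically and identical seeds give identical outputs.
  Exact ties are measure-zero for continuous weights.
- **Strength matching.** "Similar strength" is implemented as 20 quantile
  strata; replacements are drawn uniformly from the member's stratum
  excluding current members and already-used replacements, falling back to
  the nearest-strength eligible node if a stratum empties.
- **Permutations** randomize the target pathway only; the source stays
  fixed. Each ordered pair draws its nulls independently, and stage-2
  p-values pool the stage-1 permutations (1100 total).
- **Degenerate inputs.** Empty GMT files, malformed lines, unknown
  interaction types, non-numeric statistics and negative edge weights are
  rejected with specific errors; empty result sets produce header-only
  tables and empty (but valid) network files.
- **Betweenness normalization.** Pathway betweenness is computed on the
  directed network and divided by (n−1)(n−2) — the number of ordered node
  pairs excluding the focal node — so a full mediator scores 1. An
  undirected variant is available behind a flag.

## Synthetic data

The fixture generator emulates the structure of the real inputs, not any
particular organism: a Chung–Lu random graph with Pareto expected degrees
(tail exponent `degree_exponent`, default 2.5; mean degree 4 — sparse and
heavy-tailed like curated interactomes), pathways sampled as connected
modules by seeded breadth-first growth (8–15 members, disjoint unless an
overlap is requested to exercise merging and the shared-protein rules), and
background statistics T ~ Normal(0, 1), matching the null distribution of a
moderated t. Planted cross-talk wires vertex-disjoint directed bridges
between exclusive members of the two pathways, assigning |T| = 6 to bridge
genes; indirect bridges pass through a pathway-free intermediate. Two-sided
normal p-values and Benjamini–Hochberg q-values accompany the statistics.

The default benchmark uses 300 proteins, 12 pathways and three planted
ordered pairs (two direct, one indirect; two bridges each) — small enough
for exhaustive testing while leaving > 100 pathway-free proteins as
potential intermediates. Passing the recovery tests shows that the
implementation finds exactly the planted routes and calibrates its null
under these idealized conditions; it does not demonstrate robustness to
false interaction annotations, correlated expression, incomplete
identifier mapping or the much larger and denser graphs of real
interactomes, where run time is dominated by the permutation loop.

## Limitations

- Scores depend on annotation completeness: pathways with unmeasured or
  sparsely annotated members cannot produce short paths, and missing
  TF-target coverage limits detectable transcriptional routes.
- Only mRNA-level evidence enters the weights; post-translational
  signaling is invisible unless accompanied by expression changes.
- The permutation null matches connectivity (strength) but not community
  structure; highly modular graphs may be mildly anti-conservative.
- Empirical p-values are bounded below by 1/1100 under the default
  two-stage scheme; edge thresholds much below 0.001 require more
  permutations.
- The exhaustive-oracle guarantee of the greedy path search is verified on
  small graphs; on large graphs the greedy procedure is the definition,
  not an approximation, of the reported path sets.
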