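# Methods

## Pipeline model and assumptions

`recombnet` treats hotspot regulation as a two-layer inference problem.
The first layer is direct: a transcription factor whose motif occurs in
significantly more hotspots than coldspots is a candidate trans-regulator.
This assumes coldspots are a fair negative set — the synthetic generator
enforces this by length-matching them to the hotspots — and that "binds an
interval" can be approximated by "has at least one motif occurrence fully
contained in the interval". The second layer is indirect: regulators act
through physical machinery, so influence is propagated from the
prioritized seeds through a PPI network by a random walk with restart, and
the dense regions of the top-ranked subnetwork are proposed as the
machinery itself. Genes and proteins are treated interchangeably, and
identifiers are opaque case-sensitive strings; no symbol mapping is done.

All genomic coordinates are 0-based half-open internally. BED input is
consumed as-is; FIMO-style TSV (1-based inclusive) and GAF are converted
on read. Strand is ignored for intervals; the scanner handles both strands
itself.

## Motif scanning

Position frequency matrices are converted to log2-odds with
background-proportional pseudocounts (default 0.1 total per column,
uniform background). The null distribution of window scores is computed
exactly by position-wise convolution on a score grid discretized at 1e-3
bits; window scores are computed from the same quantized matrix, so
p-value lookups are exact on the grid. A window is a hit iff its upper-tail
p-value is at most the threshold (default 1e-4, the common FIMO default;
the decision boundary sits far above the 1e-3-bit grid resolution). The
reverse strand is scored with the reverse-complemented matrix and, when
the background is asymmetric, its own null distribution. Windows
containing non-ACGT characters are skipped.

A consequence worth noting for strict one-hot matrices: the maximal score
has tail mass 4^-w, so a threshold must be at least 4^-w for any hit to be
reported; at such a threshold hit counts coincide exactly with literal
substring search on both strands, which the tests exploit as an oracle.

## Prioritization

* **Odds ratio** O_hc = (HM/HN)/(CM/CN). Degenerate cells use fixed
  conventions (HM=0 → 0; CM=0 with HM>0, or HM=N_H → +inf; both zero → 0
  with an undefined flag and warning). A Haldane-style +0.5 on all four
  cells is available but off by default, to leave regular scores
  untouched. Ties in the ranking break by descending HM, then motif id.
* **HB relevance.** Hotspot-binding profiles count bound hotspots per
  genomic bin (default 5 Mb), assigning each hotspot to the bin containing
  its midpoint — an unambiguous rule for boundary-straddling hotspots. HB
  network edges require Pearson correlation strictly greater than 0.7;
  zero-variance profiles correlate 0 with everything. Conserved clusters
  are consumed as a file (one whitespace-separated cluster per line); a
  naive fallback (connected components of the ortholog-consistent
  intersection of two HB networks) is provided and clearly documented as
  not equivalent to a real cross-species network aligner.
* **KM consensus.** The footrule-optimal consensus ranking is an exact
  minimum-cost assignment over the complete genes × positions bipartite
  graph with w(t,p) = |σ_o(t)−p| + |σ_h(t)−p|, solved by
  `scipy.optimize.linear_sum_assignment`. Optima can be non-unique; genes
  enter the solver in lexicographic order so the returned optimum is
  deterministic, and tests assert the cost, not the permutation.
* **Seeds.** k = ceil(fraction × n) top genes (default fraction 0.10; the
  ceiling reproduces 18/177, 16/158 and 15/148). Seed restart scores are
  the prioritization scores (odds ratio, relevance, or 1/position for the
  consensus); infinite odds ratios are clamped to twice the largest finite
  seed score before normalization, and a uniform restart vector is a
  config switch, since no formula for the restart weights is canonical.

## Random walk with restart

p_{t+1} = (1−γ) W p_t + γ p_0 with γ = 0.7, column-stochastic
W(i,j) = A(i,j)/deg_w(j), and unit self-loops on isolated columns so mass
is conserved exactly. For an undirected (symmetric) adjacency the row and
column normalization conventions give the same walk; the column form is
used because it preserves probability mass under iteration. Convergence is
declared when the L1 change drops below 1e-10 (max 10,000 iterations; the
flag is returned either way), and the iterative fixed point agrees with
the closed-form solve γ(I−(1−γ)W)^(-1) p_0 to 1e-8 per entry on test
graphs. Isolated non-seed nodes keep p = 0; the full graph is used rather
than the largest component.

## Complex detection and conserved matching

For each vertex v the neighborhood graph on {v} ∪ N(v) is reduced by
repeatedly deleting a minimum-degree vertex (never v; ties by node id)
until density 2|E|/(|V|(|V|−1)) reaches the threshold (default 0.7).
Cores of fewer than three vertices are discarded: any single edge is
trivially "dense", and admitting 2-cores would attach their neighborhoods
and report arbitrary low-density stars. Outside proteins with at least
attach_ratio (default 0.5, weak inequality) of the core as neighbors are
attached. Complexes of size < 3 are dropped; duplicates are merged; and of
any pair with neighborhood affinity ≥ 0.25 only the denser complex is kept
(ties: larger, then lexicographically first member).

NA(A,B) = |A∩B|²/(|A|·|B|); across species the intersection counts
ortholog pairs. Under many-to-many orthology the raw value can exceed 1;
it is clamped to 1 with a warning rather than silently rescaled. Conserved
pairs come from an exact maximum-total-weight one-to-one matching over NA
edges ≥ 0.25 (solved as a rectangular assignment; zero-weight assignments
are filtered afterwards), which can beat greedy pairing whenever one
complex dominates two partners.

## GO evaluation

Term–term similarity uses the relation-weighted ancestor-contribution
scheme: S-values decay by 0.8 per is_a and 0.6 per part_of edge along the
best path from the query term, and sim(t,u) is the sum of both terms'
S-values over common ancestors divided by the sum of all their S-values.
Cross-namespace comparisons return 0 with a warning. Gene-level similarity
is the best match over the gene's annotations (unannotated genes score 0);
set-level similarity is the mean over the evaluated set — the mean (1/|V|)
normalization is the only choice that makes the seed set and the universe
comparable inside the gap score (S(t,HG) − S(t,G))/S(t,G). Terms with
S(t,G) = 0 get an undefined gap and are excluded from rankings.
Hypergeometric enrichment p-values are upper tails P(X ≥ k) computed in
log space via `scipy.stats.hypergeom`; Bonferroni and Benjamini–Hochberg
adjustments are opt-in post-processing. The recombination-related
evaluation terms GO:0006310 (DNA recombination) and GO:0007126 (meiosis)
are exposed as named constants.

## Synthetic data: what it emulates and what it does not

The generator draws every input class from one integer seed, forked into
labelled substreams so adding a generator never perturbs another's output;
identical configs yield byte-identical bundles. The default ("strong
signal") conditions: two 500 kb chromosomes of i.i.d. uniform sequence;
200 hotspots and 200 length-matched, non-overlapping coldspots of
300–700 bp; 30 TFs with distinct width-8 consensus motifs (pairwise
distinct including reverse complements), of which 3 "hot" TFs are planted
into hotspots at rate 0.8 versus 0.1 in coldspots while the rest plant at
0.1 everywhere; per species a 300-node PPI network containing three
planted 6-cliques over disjoint members, Erdős–Rényi background at
p = 0.01 (mean degree ≈ 3, a sparse PPI regime), and each hot TF wired to
exactly two members of its own complex — enough to route restart mass into
the machinery without making the regulator a de facto member; ortholog
maps covering all TFs plus exactly round(0.8 × size) members per complex;
12 conserved clusters in which hot TFs recur; and a balanced is_a GO DAG
(depth 3, branching 3) whose marker term annotates the planted regulators
and complex members while all other genes are annotated to a distant
branch. Planted complexes are cliques because the recovery guarantee is
defined in terms of cliques: the redundancy rule keeps the densest
candidate, so a complex planted at density < 1 can legitimately lose to a
denser subset of itself.

What passing tests on this bundle do **not** show: real genomes are not
i.i.d. uniform (GC skew is available as a config, repeats are not
modeled); real motif libraries contain degenerate, overlapping and
variable-width motifs; real PPI networks have hubs and heavy-tailed
degrees rather than ER background; real orthology is many-to-many; and
real coldspot definitions are a scientific choice, not a length-matched
complement. The bundle validates the machinery and its contracts, not
biological effect sizes.

## Numerical and engineering choices

* Score grid 1e-3 bits; distribution mass checked to 1 ± 1e-9.
* Duplicate PPI edges keep the maximum weight; self-loops are dropped on
  read (the endpoints remain); edge-list files cannot represent isolated
  nodes, so file round-trips keep only connected nodes.
* All orderings that could be rng- or hash-dependent are pinned
  lexicographically (node order in the transition matrix, tie-breaks in
  rankings, candidate order in redundancy pruning), making pipeline
  output a pure function of config + inputs; re-runs are
  checksum-identical and the run manifest records config hash, input
  checksums and per-stage counts.
* Tests run on down-scaled bundles (12 + 12 spots, 6 TFs, ~65-node
  networks); the acceptance script uses the full strong-signal conditions
  with 10 replicates.

## Known limitations

The HB branch consumes conserved clusters from a file; the cross-species
HB-network alignment that would produce them is out of scope, and the
bundled fallback is intentionally naive. Complex matching is one-to-one
between two species; overlapping or multi-species matchings are not
attempted. The walk does not support directed or signed interactions.
Motif scanning uses a 0-order background only.
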