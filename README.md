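# recombnet

Network pipeline for finding *trans*-regulatory genes and protein complexes
of meiotic recombination hotspots.

Meiotic crossovers cluster in short genomic windows ("hotspots"). A few
trans-acting regulators are known — most prominently the zinc-finger
protein PRDM9 — but they explain only part of hotspot activity, and
recombination is carried out by multi-protein machinery rather than single
proteins. `recombnet` implements a pipeline for proposing further
candidates: it starts from transcription factors (TFs) with known binding
motifs, asks which of them prefer to bind hotspots over matched coldspots,
propagates that signal through protein–protein interaction (PPI) networks
to reach proteins *without* binding data, and finally mines and
cross-species-matches dense protein complexes from the top-ranked
subnetwork. It is aimed at computational biologists who have hotspot
intervals, motif libraries, and PPI data, and want a reproducible,
scriptable analysis.

## Method

**Prioritization.** For a TF with motif hits in `HM` of `N_H` hotspots and
`CM` of `N_C` coldspots, its binding preference is the odds ratio

    O_hc = (HM / HN) / (CM / CN),    HN = N_H − HM,  CN = N_C − CM.

A complementary relevance score comes from hotspot-binding (HB) profiles:
the genome is cut into fixed-length bins, each TF gets a per-bin count of
bound hotspots, TFs with Pearson-correlated profiles (r > 0.7) are joined
in an HB network, and a TF's relevance R(g) is its frequency across
cross-species conserved clusters of that network, normalized by the
maximum frequency. The two rankings σ_o and σ_h are combined into a
consensus σ* minimizing the summed Spearman footrule distance

    σ* = argmin_σ Σ_i |σ_o(i) − σ(i)| + |σ_h(i) − σ(i)|,

solved exactly as a minimum-cost assignment of genes to rank positions
(Kuhn–Munkres). The top 10% of the chosen ranking become seed genes.

**Network propagation.** Seeds inject restart mass into a random walk with
restart over the PPI network:

    p_{t+1} = (1 − γ) W p_t + γ p_0,    γ = 0.7,

with W the column-normalized adjacency matrix, iterated to an L1 change
below 1e-10. The subnetwork induced by the top 200 nodes of p_∞ is mined
for complexes by a core-attachment procedure (dense-core extraction per
vertex neighborhood, then attachment of peripheral proteins). Complexes
detected in two species are matched one-to-one by maximum-weight bipartite
matching under the neighborhood affinity score

    w(H_i, M_j) = |H_i ∩ M_j|² / (|H_i| · |M_j|),

where the intersection counts ortholog pairs and edges below 0.25 are
discarded.

**Evaluation.** GO-based: relation-weighted ancestor-contribution semantic
similarity between terms, best-match similarity between a term and a
gene's annotations, mean similarity to gene sets, gap scores
(S(t,HG) − S(t,G)) / S(t,G) contrasting seeds against the TF universe, and
hypergeometric upper-tail p-values for complex–term enrichment.

A fully seeded synthetic-data module generates every input class (genome +
spots with planted motif occurrences, two PPI networks with planted
complexes, ortholog maps, conserved clusters, a GO DAG with annotations)
together with ground-truth tables, so the entire pipeline runs and is
testable without downloads.

## Worked example

```bash
recombnet simulate --seed 7 --out bundle
recombnet run --config configs/default.yaml
```

which logs, per stage (seed 7, default strong-signal bundle):

```
INFO recombnet: scan: 30 motifs, 1819 hits
INFO recombnet: prioritize: KM aggregation cost 252
INFO recombnet: prioritize: 30 TFs scored, 3 seeds (or)
INFO recombnet: rwr: 279 nodes, 18 iterations, converged=True
INFO recombnet: complexes: 6 detected in top-200 subnetwork
INFO recombnet: rwr: 282 nodes, 18 iterations, converged=True
INFO recombnet: complexes: 5 detected in top-200 subnetwork
INFO recombnet: conserved: 3 pairs
INFO recombnet: go-gap: 40 terms ranked
8 stages completed; manifest in recombnet_out/manifest.json
```

Reading the output: the scanner found 1819 motif windows at p ≤ 1e-4; the
odds-ratio ranking of the 30 TFs put 3 seeds (top 10%) into the walk — in
this bundle exactly the three TFs whose motifs were planted preferentially
into hotspots; the walk converged in 18 iterations on each species'
network (279/282 nodes, since the edge-list files carry only connected
nodes); complex mining on each top-200 subnetwork recovered the three
planted complexes (plus a couple of small dense background modules), and
the cross-species matching paired all three correctly, e.g.

```
members_a                                                 members_b                                    na
A_cx1_1,...,A_cx1_6,TF01   B_cx1_1,...,B_cx1_6   0.5952
```

(NA = 25/42: five of six members are orthologous by construction, and the
species-A complex carries its regulator TF01 as an attachment).
`recombnet_out/` contains the ranking tables (`ranking_or.tsv`, …),
per-node steady-state relevance (`rwr_a.tsv`), complexes, conserved pairs
with NA weights, and the GO gap table.

Every stage is also runnable standalone (`recombnet scan|prioritize|rwr|
complexes|conserved|go-gap --help`) on its predecessor's files.

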