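"""GO-based evaluation: semantic similarity, gap scores, enrichment p-values.

Term-term similarity follows the relation-weighted ancestor-contribution
scheme (Wang-style): starting from S(t) = 1 at the term itself, each
ancestor a receives S(a) = max over child edges of w_rel * S(child) with
is_a weighted 0.8 and part_of 0.6; the similarity of two terms is the sum
of both terms' S-values over their common ancestors divided by the sum of
all their S-values. Gene-level similarity takes the best-matching
annotation (S(t, g) = max over t' in T(g) of sim(t, t')); set-level
similarity is the mean over the evaluated gene set.

The gap score (S(t, HG) - S(t, G)) / S(t, G) contrasts a term's
similarity to a prioritized subset HG against the full TF universe G.
Complex enrichment uses the hypergeometric upper-tail p-value
P(X >= k) for k annotated members out of |C| drawn from a universe of
|V| genes containing |F| annotated ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
from scipy.stats import hypergeom

#: recombination-related evaluation terms used throughout the field
DNA_RECOMBINATION = "GO:0006310"
MEIOSIS = "GO:0007126"

DEFAULT_RELATION_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


class GoDag:
    """Directed acyclic ontology graph; edges point child -> parent."""

    def __init__(self, relation_weights=None):
        self.graph = nx.MultiDiGraph()
        self.namespace: dict = {}
        self.name: dict = {}
        self.relation_weights = dict(relation_weights or DEFAULT_RELATION_WEIGHTS)
        self._svalues = lru_cache(maxsize=None)(self._svalues_uncached)

    @classmethod
    def from_obonet(cls, graph: nx.MultiDiGraph, relation_weights=None) -> "GoDag":
        dag = cls(relation_weights)
        for term, data in graph.nodes(data=True):
            dag.add_term(term, data.get("namespace", ""), data.get("name", ""))
        for child, parent, key in graph.edges(keys=True):
            if key in dag.relation_weights:
                dag.add_edge(child, parent, key)
        return dag

    def add_term(self, term: str, namespace: str = "", name: str = "") -> None:
        self.graph.add_node(term)
        self.namespace[term] = namespace
        self.name[term] = name

    def add_edge(self, child: str, parent: str, relation: str = "is_a") -> None:
        if relation not in self.relation_weights:
            raise ValueError(f"unknown relation {relation!r}")
        self.graph.add_edge(child, parent, key=relation)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError(f"edge {child} -> {parent} creates a cycle")
        self._svalues.cache_clear()

    def __contains__(self, term) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def terms(self):
        return list(self.graph.nodes)

    def _svalues_uncached(self, term: str) -> dict:
        """S-value of every ancestor of ``term`` (term itself included)."""
        if term not in self.graph:
            raise KeyError(f"unknown term {term!r}")
        closure = {term} | nx.descendants(self.graph, term)  # ancestors (child->parent)
        order = [t for t in nx.topological_sort(self.graph.subgraph(closure))]
        s = {term: 1.0}
        for node in order:
            if node == term:
                continue
            best = 0.0
            for child, _, rel in self.graph.in_edges(node, keys=True):
                if child in s:
                    best = max(best, self.relation_weights[rel] * s[child])
            if best > 0:
                s[node] = best
        return s

    def svalues(self, term: str) -> dict:
        return dict(self._svalues(term))


@dataclass
class AnnotationMap:
    """gene id -> set of GO term ids (the T(g) of the similarity formulas)."""

    annotations: dict = field(default_factory=dict)

    def terms_for(self, gene) -> set:
        return self.annotations.get(gene, set())

    @property
    def genes(self) -> set:
        return set(self.annotations)

    def genes_with_term(self, term, dag: GoDag = None) -> set:
        """Genes annotated to ``term`` directly or via a descendant term."""
        if dag is None or term not in dag:
            return {g for g, ts in self.annotations.items() if term in ts}
        covered = {term} | nx.ancestors(dag.graph, term)  # descendants of term
        return {g for g, ts in self.annotations.items() if ts & covered}

    def __contains__(self, gene):
        return gene in self.annotations


@dataclass
class GapResult:
    term: str
    s_hg: float
    s_g: float
    gap: float
    defined: bool = True


def term_similarity(t: str, u: str, dag: GoDag) -> float:
    """Relation-weighted ancestor-contribution similarity in [0, 1]."""
    if t not in dag or u not in dag:
        raise KeyError(f"unknown term {t if t not in dag else u!r}")
    if dag.namespace.get(t) != dag.namespace.get(u):
        warnings.warn(f"terms {t} and {u} are in different namespaces")
        return 0.0
    if t == u:
        return 1.0
    st, su = dag._svalues(t), dag._svalues(u)
    common = set(st) & set(su)
    if not common:
        return 0.0
    return sum(st[a] + su[a] for a in common) / (sum(st.values()) + sum(su.values()))


def term_gene_similarity(t: str, gene, ann: AnnotationMap, dag: GoDag) -> float:
    """S(t, g) = max over the gene's annotations; unannotated genes score 0."""
    if gene not in ann:
        raise KeyError(f"unknown gene {gene!r}")
    terms = ann.terms_for(gene)
    if not terms:
        return 0.0
    return max(term_similarity(t, tp, dag) for tp in terms)


def geneset_similarity(t: str, genes, ann: AnnotationMap, dag: GoDag) -> float:
    """Mean of S(t, g) over the evaluated gene set.

    Genes missing from the annotation map count as unannotated (score 0).
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    total = 0.0
    for g in genes:
        if g in ann:
            total += term_gene_similarity(t, g, ann, dag)
    return total / len(genes)


def gap_score(t: str, hg, g, ann: AnnotationMap, dag: GoDag) -> GapResult:
    """Relative excess of the term's similarity to HG over the universe G."""
    hg, g = set(hg), set(g)
    if not hg <= g:
        raise ValueError("HG must be a subset of G")
    s_hg = geneset_similarity(t, hg, ann, dag)
    s_g = geneset_similarity(t, g, ann, dag)
    if s_g == 0:
        return GapResult(t, s_hg, s_g, float("nan"), defined=False)
    return GapResult(t, s_hg, s_g, (s_hg - s_g) / s_g)


def rank_terms_by_gap(terms, hg, g, ann: AnnotationMap, dag: GoDag) -> list:
    """GapResults in descending gap order; undefined gaps excluded."""
    if not terms:
        raise ValueError("no terms to rank")
    results = [gap_score(t, hg, g, ann, dag) for t in terms]
    defined = [r for r in results if r.defined]
    defined.sort(key=lambda r: (-r.gap, r.term))
    return defined


def hypergeom_pvalue(complex_members, term_genes, universe_size: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k), k = |C intersect F|.

    Computed in log space by scipy's survival function; k = 0 returns 1.
    """
    c = set(complex_members)
    f = set(term_genes)
    if len(c) > universe_size or len(f) > universe_size:
        raise ValueError("set larger than the universe")
    k = len(c & f)
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, universe_size, len(f), len(c)))


def complex_enrichment(complexes, ann: AnnotationMap, dag: GoDag, universe,
                       terms=None, adjust: str = None) -> list:
    """Hypergeometric enrichment of each complex against each term.

    Returns rows (complex index, term, k, |F|, p, p_adjusted). ``adjust``
    may be None, 'bonferroni' or 'bh'.
    """
    universe = set(universe)
    terms = list(terms) if terms is not None else dag.terms()
    rows = []
    term_sets = {t: ann.genes_with_term(t, dag) & universe for t in terms}
    for idx, c in enumerate(complexes):
        members = set(c.members) & universe
        for t in terms:
            f = term_sets[t]
            if not f:
                continue
            k = len(members & f)
            p = hypergeom_pvalue(members, f, len(universe))
            rows.append([idx, t, k, len(f), p, p])
    if adjust and rows:
        ps = [r[4] for r in rows]
        m = len(ps)
        if adjust == "bonferroni":
            adj = [min(1.0, p * m) for p in ps]
        elif adjust == "bh":
            order = sorted(range(m), key=lambda i: ps[i])
            adj = [0.0] * m
            prev = 1.0
            for rank_from_end, i in enumerate(reversed(order)):
                rank = m - rank_from_end
                prev = min(prev, ps[i] * m / rank)
                adj[i] = prev
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        for r, a in zip(rows, adj):
            r[5] = a
    return [tuple(r) for r in rows]


def write_gap_table(results, dag: GoDag, path) -> None:
    with open(path, "w") as fh:
        fh.write("term\tdescription\tS_HG\tS_G\tgap\n")
        for r in results:
            fh.write(
                f"{r.term}\t{dag.name.get(r.term, '')}\t{r.s_hg:.6g}\t{r.s_g:.6g}\t{r.gap:.6g}\n"
            )


def write_enrichment_table(rows, path) -> None:
    with open(path, "w") as fh:
        fh.write("complex\tterm\tk\tF\tp_value\tadjusted_p\n")
        for idx, t, k, f, p, adj in rows:
            fh.write(f"{idx}\t{t}\t{k}\t{f}\t{p:.6g}\t{adj:.6g}\n")
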