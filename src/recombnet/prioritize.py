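"""Prioritization of TFs as candidate trans-regulators of hotspots.

Three complementary rankings are produced:

* **OR** — odds ratio O_hc = (HM/HN)/(CM/CN) contrasting a TF's binding in
  hotspots vs coldspots (HM hotspots with >= 1 motif hit, HN without, CM/CN
  likewise for coldspots).
* **HB** — relevance from hotspot-binding (HB) profiles: the genome is cut
  into fixed-length bins, each TF gets a per-bin bound-hotspot count vector,
  TFs with Pearson-correlated profiles are linked in an HB network, and a
  gene's relevance is its frequency in cross-species conserved clusters of
  that network, normalized by the maximum frequency.
* **KM** — a consensus ranking minimizing the total Spearman footrule
  distance to the OR and HB rankings, obtained as an exact minimum-cost
  assignment of genes to rank positions (Kuhn-Munkres).

The top fraction (default 10%) of a ranking becomes the seed set for the
random walk with restart.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .motif_scan import HitTable


@dataclass
class ORRecord:
    motif_id: str
    hm: int
    hn: int
    cm: int
    cn: int
    odds_ratio: float
    undefined: bool = False


@dataclass
class Ranking:
    """Bijection between gene ids and 1-based positions (1 = top)."""

    order: list

    def __post_init__(self):
        if len(set(self.order)) != len(self.order):
            raise ValueError("ranking contains duplicate gene ids")
        self._pos = {g: i + 1 for i, g in enumerate(self.order)}

    @property
    def n(self) -> int:
        return len(self.order)

    def position(self, gene) -> int:
        return self._pos[gene]

    def genes(self):
        return list(self.order)

    def __iter__(self):
        return iter(self.order)

    def __len__(self):
        return len(self.order)


@dataclass
class SeedSet:
    """Seed genes with their prioritization scores (feeds the RWR p0)."""

    scores: dict

    def __post_init__(self):
        if not self.scores:
            raise ValueError("seed set must be nonempty")
        if any(s < 0 for s in self.scores.values()):
            raise ValueError("seed scores must be >= 0")

    @property
    def genes(self):
        return set(self.scores)

    def __len__(self):
        return len(self.scores)

    def __contains__(self, gene):
        return gene in self.scores


@dataclass
class HBProfile:
    motif_id: str
    b: np.ndarray
    bin_length: int


# ---------------------------------------------------------------------------
# odds ratio


def odds_ratio(motif_id: str, hm: int, n_h: int, cm: int, n_c: int,
               haldane: bool = False) -> ORRecord:
    """Odds ratio O_hc = (HM/HN)/(CM/CN) with HN = N_H-HM, CN = N_C-CM.

    Degenerate cells follow fixed conventions: HM=0 gives 0 (flagged
    undefined when CM=0 as well); CM=0 with HM>0, or HM=N_H, gives +inf.
    With ``haldane=True`` 0.5 is added to all four cells instead.
    """
    if not (0 <= hm <= n_h) or not (0 <= cm <= n_c):
        raise ValueError(f"{motif_id}: counts out of range")
    if n_h <= 0 or n_c <= 0:
        raise ValueError("need at least one hotspot and one coldspot")
    hn, cn = n_h - hm, n_c - cm
    if haldane:
        o = ((hm + 0.5) / (hn + 0.5)) / ((cm + 0.5) / (cn + 0.5))
        return ORRecord(motif_id, hm, hn, cm, cn, o)
    if hm == 0 and cm == 0:
        warnings.warn(f"{motif_id}: no hits in hotspots or coldspots; OR undefined")
        return ORRecord(motif_id, hm, hn, cm, cn, 0.0, undefined=True)
    if hm == 0:
        return ORRecord(motif_id, hm, hn, cm, cn, 0.0)
    if hm == n_h or cm == 0:
        return ORRecord(motif_id, hm, hn, cm, cn, math.inf)
    return ORRecord(motif_id, hm, hn, cm, cn, (hm / hn) / (cm / cn))


def odds_ratios_from_table(table: HitTable, motif_ids, haldane: bool = False):
    """OR records for every motif in ``motif_ids`` (zero counts if unseen)."""
    records = []
    for motif_id in motif_ids:
        hm, _, cm, _ = table.counts(motif_id)
        records.append(odds_ratio(motif_id, hm, table.n_hot, cm, table.n_cold, haldane))
    return records


def rank_by_or(records) -> Ranking:
    """Descending odds ratio; ties by descending HM, then motif id."""
    if not records:
        raise ValueError("no records to rank")
    ordered = sorted(records, key=lambda r: (-r.odds_ratio, -r.hm, r.motif_id))
    return Ranking([r.motif_id for r in ordered])


# ---------------------------------------------------------------------------
# HB profiles and network


def _bin_layout(chrom_lengths: dict, bin_length: int):
    offsets, total = {}, 0
    for chrom, length in chrom_lengths.items():
        offsets[chrom] = total
        total += math.ceil(length / bin_length)
    return offsets, total


def build_hb_profile(motif_id: str, bound_hotspots, chrom_lengths: dict,
                     bin_length: int) -> HBProfile:
    """Per-bin counts of bound hotspots (assigned by hotspot midpoint).

    Bins of ``bin_length`` bases are laid per chromosome, then concatenated
    in the order of ``chrom_lengths``.
    """
    if bin_length <= 0:
        raise ValueError("bin_length must be > 0")
    offsets, total = _bin_layout(chrom_lengths, bin_length)
    b = np.zeros(total, dtype=int)
    for iv in bound_hotspots:
        b[offsets[iv.chrom] + iv.midpoint // bin_length] += 1
    return HBProfile(motif_id, b, bin_length)


def build_hb_network(profiles, threshold: float = 0.7) -> nx.Graph:
    """Edge between two TFs iff Pearson(profiles) > threshold.

    Zero-variance profiles correlate 0 with everything (no edges).
    """
    if not profiles:
        return nx.Graph()
    lam = len(profiles[0].b)
    if lam < 2:
        raise ValueError("profiles need >= 2 bins for correlation")
    if any(len(p.b) != lam for p in profiles):
        raise ValueError("profiles have differing bin counts")
    g = nx.Graph()
    g.add_nodes_from(p.motif_id for p in profiles)
    mat = np.array([p.b for p in profiles], dtype=float)
    sd = mat.std(axis=1)
    centered = mat - mat.mean(axis=1, keepdims=True)
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            if sd[i] == 0 or sd[j] == 0:
                continue
            r = float(centered[i] @ centered[j] / (lam * sd[i] * sd[j]))
            if r > threshold:
                g.add_edge(profiles[i].motif_id, profiles[j].motif_id, weight=r)
    return g


def relevance_from_clusters(clusters, universe) -> dict:
    """R(g) = cluster frequency of g / maximum frequency over all genes."""
    if not clusters:
        raise ValueError("need at least one cluster")
    freq: dict = {}
    for cluster in clusters:
        for gene in cluster:
            freq[gene] = freq.get(gene, 0) + 1
    if not freq:
        raise ValueError("all clusters are empty")
    fmax = max(freq.values())
    return {g: freq.get(g, 0) / fmax for g in set(universe) | set(freq)}


def rank_by_relevance(relevance: dict) -> Ranking:
    ordered = sorted(relevance, key=lambda g: (-relevance[g], g))
    return Ranking(ordered)


def naive_conserved_clusters(hb_a: nx.Graph, hb_b: nx.Graph, orthologs) -> list:
    """Fallback conserved-cluster finder (NOT the NCT alignment algorithm).

    Keeps species-A HB edges whose endpoints both have orthologs joined by
    an edge in the species-B HB network, and returns connected components
    of size >= 2 of the retained graph.
    """
    omap: dict = {}
    for a, b in orthologs:
        omap.setdefault(a, set()).add(b)
    kept = nx.Graph()
    for u, v in hb_a.edges():
        for bu in omap.get(u, ()):  # any orthologous edge in B suffices
            if any(hb_b.has_edge(bu, bv) for bv in omap.get(v, ())):
                kept.add_edge(u, v)
                break
    return [frozenset(c) for c in nx.connected_components(kept) if len(c) >= 2]


# ---------------------------------------------------------------------------
# footrule + KM aggregation


def footrule_distance(a: Ranking, b: Ranking) -> int:
    """Spearman's footrule: sum of absolute rank displacements."""
    if set(a.order) != set(b.order):
        raise ValueError("rankings are over different gene universes")
    return sum(abs(a.position(g) - b.position(g)) for g in a.order)


def km_aggregate(sigma_o: Ranking, sigma_h: Ranking):
    """Consensus ranking by exact minimum-cost assignment.

    Builds the complete bipartite graph of genes vs positions with cost
    w(t, p) = |sigma_o(t) - p| + |sigma_h(t) - p| and solves it exactly;
    the total cost is the global minimum of the summed footrule distances.
    Genes are fed to the solver in lexicographic order, which makes the
    returned optimum deterministic among ties.
    """
    if set(sigma_o.order) != set(sigma_h.order):
        raise ValueError("rankings are over different gene universes")
    genes = sorted(sigma_o.order)
    n = len(genes)
    positions = np.arange(1, n + 1)
    cost = np.empty((n, n), dtype=int)
    for i, g in enumerate(genes):
        cost[i] = np.abs(sigma_o.position(g) - positions) + np.abs(
            sigma_h.position(g) - positions
        )
    rows, cols = linear_sum_assignment(cost)
    order = [None] * n
    for i, p in zip(rows, cols):
        order[p] = genes[i]
    return Ranking(order), int(cost[rows, cols].sum())


# ---------------------------------------------------------------------------
# seed selection


def select_seeds(ranking: Ranking, scores: dict = None, fraction: float = 0.1,
                 mode: str = "scores") -> SeedSet:
    """Top ceil(fraction * n) genes with their prioritization scores.

    ``scores`` maps gene -> prioritization score (OR score, relevance R, or
    1/position for an aggregated ranking when omitted). ``mode='uniform'``
    assigns every seed the same weight. Infinite scores are clamped to twice
    the largest finite seed score so the RWR restart vector is normalizable.
    """
    if ranking.n == 0:
        raise ValueError("empty ranking")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    k = math.ceil(fraction * ranking.n)
    top = ranking.order[:k]
    if mode == "uniform":
        return SeedSet({g: 1.0 for g in top})
    if scores is None:
        scores = {g: 1.0 / ranking.position(g) for g in top}
    vals = {g: float(scores[g]) for g in top}
    finite = [v for v in vals.values() if math.isfinite(v)]
    if any(not math.isfinite(v) for v in vals.values()):
        cap = 2.0 * max(finite) if finite else 1.0
        vals = {g: (v if math.isfinite(v) else cap) for g, v in vals.items()}
    if sum(vals.values()) <= 0:
        vals = {g: 1.0 for g in top}
    return SeedSet(vals)


def write_ranking(ranking: Ranking, scores: dict, method: str, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tmethod\tscore\trank\n")
        for g in ranking:
            fh.write(f"{g}\t{method}\t{scores.get(g, float('nan')):g}\t{ranking.position(g)}\n")


def read_ranking(path):
    """Read a ranking TSV written by write_ranking; returns (Ranking, scores)."""
    order, scores = [], {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            gene, _method, score, _rank = line.rstrip("\n").split("\t")
            order.append(gene)
            scores[gene] = float(score)
    return Ranking(order), scores
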