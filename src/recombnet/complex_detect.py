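"""Core-attachment protein complex detection and cross-species matching.

Complexes are mined from a (sub)network by a core-attachment procedure:
for every vertex v, the neighborhood graph on {v} u N(v) is stripped of
minimum-degree vertices until its density reaches the threshold; the
surviving vertices form a candidate core, to which every outside protein
with enough neighbors in the core is attached. Cores of fewer than three
vertices are discarded (any single edge is trivially dense), as are final
complexes of size < 3; near-duplicate complexes are pruned by neighborhood
affinity.

The neighborhood affinity (NA) score between complexes A and B is
|A n B|^2 / (|A| * |B|); across species the intersection counts ortholog
pairs. Conserved complex pairs are extracted by an exact maximum-weight
bipartite matching over NA edges at or above a threshold (default 0.25).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment


@dataclass(frozen=True)
class ProteinComplex:
    members: frozenset
    density: float
    core: frozenset = None

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("a complex needs at least 2 members")

    def __len__(self):
        return len(self.members)

    def sorted_members(self):
        return sorted(self.members)


@dataclass(frozen=True)
class ConservedPair:
    complex_a: ProteinComplex
    complex_b: ProteinComplex
    na_weight: float


def graph_density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _mine_core(net: nx.Graph, v, density_threshold: float):
    """Strip min-degree vertices from {v} u N(v) until dense enough."""
    sub = net.subgraph([v, *net.neighbors(v)]).copy()
    while sub.number_of_nodes() >= 3 and graph_density(sub) < density_threshold:
        candidates = [u for u in sub.nodes if u != v]
        victim = min(candidates, key=lambda u: (sub.degree(u), u))
        sub.remove_node(victim)
    if sub.number_of_nodes() < 3 or graph_density(sub) < density_threshold:
        return None
    return sub


def detect_complexes(net: nx.Graph, density_threshold: float = 0.7,
                     attach_ratio: float = 0.5, redundancy_na: float = 0.25) -> list:
    """Mine core-attachment complexes from ``net``.

    Returns ProteinComplex records (size >= 3), redundancy-pruned: of any
    pair with NA >= ``redundancy_na`` only the denser complex is kept
    (ties: larger, then lexicographically first member).
    """
    for name, val in (("density_threshold", density_threshold),
                      ("attach_ratio", attach_ratio),
                      ("redundancy_na", redundancy_na)):
        if not (0 < val <= 1):
            raise ValueError(f"{name} must be in (0, 1]")
    candidates: dict = {}
    for v in sorted(net.nodes()):
        core_graph = _mine_core(net, v, density_threshold)
        if core_graph is None:
            continue
        core = frozenset(core_graph.nodes)
        members = set(core)
        for p in net.nodes:
            if p in core:
                continue
            shared = sum(1 for u in net.neighbors(p) if u in core)
            if shared / len(core) >= attach_ratio:
                members.add(p)
        if len(members) < 3:
            continue
        members = frozenset(members)
        if members not in candidates:
            candidates[members] = ProteinComplex(
                members, graph_density(net.subgraph(members)), core
            )
    ordered = sorted(
        candidates.values(),
        key=lambda c: (-c.density, -len(c.members), c.sorted_members()),
    )
    kept = []
    for c in ordered:
        if all(na_score(c, other) < redundancy_na for other in kept):
            kept.append(c)
    return kept


def na_score(a: ProteinComplex, b: ProteinComplex, orthologs=None) -> float:
    """Neighborhood affinity overlap^2 / (|A|*|B|).

    ``orthologs`` is a set of (a_gene, b_gene) pairs for cross-species
    comparisons; omitted, the identity map is used (overlap = |A n B|).
    With many-to-many orthology the raw score can exceed 1; it is clamped
    to 1 with a warning.
    """
    ma, mb = a.members, b.members
    if orthologs is None:
        overlap = len(ma & mb)
    else:
        overlap = sum(1 for x, y in orthologs if x in ma and y in mb)
    score = overlap * overlap / (len(ma) * len(mb))
    if score > 1.0:
        warnings.warn(
            "NA score exceeds 1 under many-to-many orthology; clamped to 1"
        )
        return 1.0
    return score


def match_conserved(complexes_a, complexes_b, orthologs, threshold: float = 0.25):
    """Exact maximum-total-weight one-to-one matching of conserved complexes.

    NA edges below ``threshold`` are removed before matching; each complex
    appears in at most one pair.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if not complexes_a or not complexes_b:
        return []
    weights = np.zeros((len(complexes_a), len(complexes_b)))
    for i, ca in enumerate(complexes_a):
        for j, cb in enumerate(complexes_b):
            w = na_score(ca, cb, orthologs)
            if w >= threshold:
                weights[i, j] = w
    rows, cols = linear_sum_assignment(weights, maximize=True)
    pairs = [
        ConservedPair(complexes_a[i], complexes_b[j], float(weights[i, j]))
        for i, j in zip(rows, cols)
        if weights[i, j] >= threshold
    ]
    pairs.sort(key=lambda p: -p.na_weight)
    return pairs


def write_complexes(complexes, path) -> None:
    """One complex per line: density followed by sorted member ids."""
    with open(path, "w") as fh:
        for c in complexes:
            fh.write(f"{c.density:.4f} " + " ".join(c.sorted_members()) + "\n")


def read_complexes(path) -> list:
    complexes = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if len(fields) < 3:
                continue
            complexes.append(ProteinComplex(frozenset(fields[1:]), float(fields[0])))
    return complexes


def write_conserved_pairs(pairs, path) -> None:
    with open(path, "w") as fh:
        fh.write("members_a\tmembers_b\tna\n")
        for p in pairs:
            fh.write(
                ",".join(p.complex_a.sorted_members())
                + "\t"
                + ",".join(p.complex_b.sorted_members())
                + f"\t{p.na_weight:.4f}\n"
            )
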