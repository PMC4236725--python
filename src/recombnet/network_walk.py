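"""Random walk with restart (RWR) over a PPI network.

The walk iterates p_{t+1} = (1-gamma) * W * p_t + gamma * p_0 where W is
the column-stochastic degree-normalized adjacency matrix, p_0 the seed
restart vector (seed prioritization scores normalized to sum 1) and gamma
the restart probability (default 0.7). Iteration stops when the L1 change
drops below ``tol`` (default 1e-10). Columns of isolated nodes get a unit
self-loop so probability mass is conserved exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import sparse

from .prioritize import Ranking, SeedSet


@dataclass
class TransitionMatrix:
    w: sparse.csr_matrix
    nodes: list

    def __post_init__(self):
        self.index = {v: i for i, v in enumerate(self.nodes)}


@dataclass
class RelevanceVector:
    p: np.ndarray
    nodes: list
    gamma: float
    iterations: int
    converged: bool

    def __post_init__(self):
        self.index = {v: i for i, v in enumerate(self.nodes)}

    def score(self, node) -> float:
        return float(self.p[self.index[node]])

    def as_dict(self) -> dict:
        return {v: float(self.p[i]) for i, v in enumerate(self.nodes)}


def normalize_adjacency(net: nx.Graph) -> TransitionMatrix:
    """Column-stochastic transition matrix W(i,j) = A(i,j) / deg_w(j).

    Nodes are ordered lexicographically for determinism; isolated nodes get
    W(j,j) = 1 so every column sums to 1.
    """
    nodes = sorted(net.nodes())
    if not nodes:
        raise ValueError("empty network")
    a = nx.to_scipy_sparse_array(net, nodelist=nodes, weight="weight", format="csc")
    if (a.data < 0).any():
        raise ValueError("negative edge weight")
    deg = np.asarray(a.sum(axis=0)).ravel()
    isolated = deg == 0
    inv = np.divide(1.0, deg, out=np.zeros_like(deg, dtype=float), where=~isolated)
    w = (a @ sparse.diags(inv)).tolil()
    for j in np.nonzero(isolated)[0]:
        w[j, j] = 1.0
    return TransitionMatrix(w.tocsr(), nodes)


def rwr(tm: TransitionMatrix, seeds: SeedSet, gamma: float = 0.7,
        tol: float = 1e-10, max_iter: int = 10_000) -> RelevanceVector:
    """Iterate the restart recurrence to the steady state.

    Seeds absent from the network are dropped with a warning; at least one
    must remain. With gamma = 1 the walk returns p_0 exactly.
    """
    if not (0 < gamma <= 1):
        raise ValueError("gamma must be in (0, 1]")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    p0 = np.zeros(len(tm.nodes))
    present = []
    for gene, score in seeds.scores.items():
        i = tm.index.get(gene)
        if i is None:
            warnings.warn(f"seed {gene!r} absent from network; dropped")
            continue
        p0[i] = score
        present.append(i)
    if not present:
        raise ValueError("no seed is present in the network")
    if p0.sum() <= 0:
        p0[present] = 1.0  # all-zero scores fall back to uniform over seeds
    p0 /= p0.sum()

    if gamma == 1.0:
        return RelevanceVector(p0, tm.nodes, gamma, 0, True)
    p = p0.copy()
    for it in range(1, max_iter + 1):
        p_next = (1 - gamma) * (tm.w @ p) + gamma * p0
        delta = np.abs(p_next - p).sum()
        p = p_next
        if delta < tol:
            return RelevanceVector(p, tm.nodes, gamma, it, True)
    return RelevanceVector(p, tm.nodes, gamma, max_iter, False)


def rwr_direct(tm: TransitionMatrix, seeds: SeedSet, gamma: float = 0.7) -> np.ndarray:
    """Closed-form steady state p = gamma (I - (1-gamma) W)^-1 p0.

    Dense linear solve; intended for small networks and as a cross-check of
    the iterative solver.
    """
    n = len(tm.nodes)
    p0 = np.zeros(n)
    for gene, score in seeds.scores.items():
        if gene in tm.index:
            p0[tm.index[gene]] = score
    p0 /= p0.sum()
    a = np.eye(n) - (1 - gamma) * tm.w.toarray()
    return gamma * np.linalg.solve(a, p0)


def rank_nonseeds(rv: RelevanceVector, seeds: SeedSet) -> Ranking:
    """Non-seed nodes by descending steady-state relevance; ties by id."""
    nonseeds = [v for v in rv.nodes if v not in seeds]
    nonseeds.sort(key=lambda v: (-rv.score(v), v))
    return Ranking(nonseeds)


def induce_top_subnetwork(net: nx.Graph, rv: RelevanceVector, k: int) -> nx.Graph:
    """Vertex-induced subgraph on the k nodes of highest relevance."""
    if not (1 <= k <= len(rv.nodes)):
        raise ValueError(f"k must be in [1, {len(rv.nodes)}]")
    top = sorted(rv.nodes, key=lambda v: (-rv.score(v), v))[:k]
    return net.subgraph(top).copy()


def write_relevance(rv: RelevanceVector, seeds: SeedSet, path) -> None:
    order = sorted(rv.nodes, key=lambda v: (-rv.score(v), v))
    with open(path, "w") as fh:
        fh.write("gene_id\tp_infinity\tis_seed\trank\n")
        for rank, v in enumerate(order, 1):
            fh.write(f"{v}\t{rv.score(v):.10g}\t{int(v in seeds)}\t{rank}\n")
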