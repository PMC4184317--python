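"""Network module-based gene signature discovery from expression data.

The FI network is re-weighted by co-expression (|Pearson r| of each edge's
two genes across samples), clustered with Markov Clustering (MCL), and each
sufficiently large, sufficiently co-expressed module is summarised into a
per-sample feature (the mean expression of its genes). The resulting
module x sample feature matrix is the candidate gene signature.

MCL here is the standard alternation of expansion (matrix squaring) and
inflation (entrywise power + column renormalisation) on a column-stochastic
matrix with self-loops, with small entries pruned for sparsity, iterated to
a fixed point. Clusters are read off the attractor rows of the limit
matrix; overlapping attractor systems are merged, so the result is a hard
partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix, FINetwork
from .modules import ModuleAssignment

log = logging.getLogger(__name__)

__all__ = ["WeightedNetwork", "correlation_weight_network", "mcl_cluster", "module_scores"]

_PRUNE = 1e-5


@dataclass
class WeightedNetwork:
    """FI network with an edge weight in [0, 1] (|correlation| by default)."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        for a, b, d in self.graph.edges(data=True):
            w = d.get("weight")
            if w is None or not (0.0 <= w <= 1.0):
                raise ValueError(f"edge ({a},{b}) weight {w} outside [0, 1]")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def weight(self, a: str, b: str) -> float:
        return self.graph.edges[a, b]["weight"]


def correlation_weight_network(
    net: FINetwork, expr: ExpressionMatrix, signed: bool = False
) -> WeightedNetwork:
    """Weight each FI edge by the Pearson correlation of its genes' expression.

    Genes are intersected between network and matrix; the default weight is
    |r| (sign-blind — both co-activation and mutual exclusion make an edge
    "tight"), ``signed=True`` keeps max(r, 0) instead. Edges with undefined
    correlation (a zero-variance gene) are dropped with a warning.
    """
    if len(expr.samples) < 3:
        raise ValueError("need >= 3 samples to estimate correlations")
    common = sorted(net.nodes & set(expr.genes))
    x = expr.df.loc[common].to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((x * x).sum(axis=1))
    idx = {g: i for i, g in enumerate(common)}
    out = nx.Graph()
    out.add_nodes_from(common)
    n_dropped = 0
    for e in net.edges:
        a, b = sorted(e)
        if a not in idx or b not in idx:
            continue
        i, j = idx[a], idx[b]
        if norms[i] == 0.0 or norms[j] == 0.0:
            n_dropped += 1
            continue
        r = float(x[i] @ x[j] / (norms[i] * norms[j]))
        r = min(max(r, -1.0), 1.0)
        w = abs(r) if not signed else max(r, 0.0)
        out.add_edge(a, b, weight=w)
    if n_dropped:
        log.warning("%d edges dropped: zero-variance expression", n_dropped)
    return WeightedNetwork(out)


def mcl_cluster(
    wnet: WeightedNetwork,
    inflation: float = 2.0,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> ModuleAssignment:
    """Markov Clustering of the weighted network.

    Self-loops are added with weight equal to each node's maximum incident
    weight (1 for isolated nodes), columns normalised, then expansion /
    inflation iterated with pruning below 1e-5 until the matrix changes by
    less than ``tol``. Deterministic; raises on non-convergence.
    """
    if not (1.0 < inflation <= 10.0):
        raise ValueError("inflation must lie in (1, 10]")
    nodes = sorted(wnet.nodes)
    if not nodes:
        raise ValueError("empty weighted network")
    m, converged = _mcl_limit(_mcl_start(wnet, nodes), inflation, max_iter, tol)
    if not converged:
        raise RuntimeError(
            f"MCL did not converge in {max_iter} iterations; try a higher inflation"
        )
    mapping = _clusters_from_limit(m, nodes)
    return ModuleAssignment(
        mapping,
        algorithm="mcl",
        parameters={"inflation": inflation, "tol": tol},
    )


def _mcl_start(wnet: WeightedNetwork, nodes: list[str]) -> np.ndarray:
    """Column-stochastic start matrix with max-incident-weight self-loops."""
    n = len(nodes)
    m = nx.to_numpy_array(wnet.graph, nodelist=nodes, weight="weight")
    loop = m.max(axis=0)
    loop[loop == 0.0] = 1.0
    m[np.diag_indices(n)] = loop
    return m / m.sum(axis=0, keepdims=True)


def _mcl_step(m: np.ndarray, inflation: float) -> np.ndarray:
    """One expansion + inflation + prune + renormalise step."""
    m = m @ m
    m = np.power(m, inflation)
    m[m < _PRUNE] = 0.0
    colsum = m.sum(axis=0, keepdims=True)
    colsum[colsum == 0.0] = 1.0
    return m / colsum


def _mcl_limit(
    m: np.ndarray, inflation: float, max_iter: int, tol: float
) -> tuple[np.ndarray, bool]:
    for _ in range(max_iter):
        prev = m
        m = _mcl_step(m, inflation)
        if np.max(np.abs(m - prev)) < tol:
            return m, True
    return m, False


def _clusters_from_limit(m: np.ndarray, nodes: list[str]) -> dict[str, int]:
    """Read clusters off the limit matrix: attractor rows span the clusters;
    attractor systems with shared members are merged."""
    n = len(nodes)
    attractors = [i for i in range(n) if m[i, i] > 0]
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for a in attractors:
        members = np.where(m[a] > 0)[0]
        for j in members:
            union(j, a)
    # every column has mass on some attractor row (columns sum to one)
    for j in range(n):
        support = np.where(m[:, j] > 0)[0]
        for i in support:
            union(j, i)
    return {nodes[i]: find(i) for i in range(n)}


def module_scores(
    assign: ModuleAssignment,
    expr: ExpressionMatrix,
    min_size: int = 5,
    min_avg_corr: float = 0.25,
) -> pd.DataFrame:
    """Per-sample feature matrix of the retained modules.

    A module is retained if it has >= ``min_size`` genes measured in the
    matrix and its mean pairwise |r| (over all within-module gene pairs) is
    >= ``min_avg_corr``. The feature is the mean expression of the module's
    genes per sample; rows are labelled ``module_<index>``.
    """
    if min_size < 0 or min_avg_corr < 0:
        raise ValueError("thresholds must be >= 0")
    feats = {}
    measured = set(expr.genes)
    for idx, comm in enumerate(assign.modules()):
        genes = sorted(comm & measured)
        if len(genes) < min_size:
            continue
        x = expr.df.loc[genes].to_numpy(dtype=float)
        if len(genes) >= 2:
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(x)
            iu = np.triu_indices(len(genes), k=1)
            vals = np.abs(r[iu])
            avg = float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else 0.0
        else:
            avg = 1.0
        if avg < min_avg_corr:
            continue
        feats[f"module_{idx}"] = x.mean(axis=0)
    return pd.DataFrame(feats, index=expr.samples).T
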