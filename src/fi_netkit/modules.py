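"""Network module discovery by modularity-maximising spectral clustering.

Modules are found by Newman's leading-eigenvector method: the modularity
matrix B = A - k k^T / 2m is recursively bipartitioned along the sign of its
leading eigenvector, each split fine-tuned by a Kernighan-Lin style sweep of
single-gene moves, and recursion stops as soon as a split no longer
increases modularity. The procedure is fully deterministic: the eigenvector
sign is fixed by orienting it so the lexicographically smallest gene with a
non-zero entry gets a positive value, all tie-breaks are lexicographic, and
modules are numbered by decreasing size (ties by smallest member).

Modularity here is the standard Newman Q on the unweighted adjacency,

    Q = (1/2m) * sum_ij [A_ij - k_i k_j / (2m)] * delta(c_i, c_j),

so Q = 0 for the single-community partition and Q in [-1, 1] always.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import FINetwork
from .subnetwork import FISubnetwork

log = logging.getLogger(__name__)

__all__ = ["ModuleAssignment", "modularity", "cluster_network", "filter_modules"]

_EPS = 1e-12


@dataclass
class ModuleAssignment:
    """Partition of genes into numbered modules.

    Module indices are contiguous from 0, ordered by decreasing module size
    with ties broken by the lexicographically smallest member, so module 0
    is always the largest.
    """

    mapping: dict[str, int]
    algorithm: str = ""
    parameters: dict = field(default_factory=dict)
    removed_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.mapping = _canonical_order(self.mapping)

    def modules(self) -> list[set[str]]:
        out: list[set[str]] = [set() for _ in range(self.n_modules)]
        for g, i in self.mapping.items():
            out[i].add(g)
        return out

    @property
    def n_modules(self) -> int:
        return max(self.mapping.values()) + 1 if self.mapping else 0

    def sizes(self) -> list[int]:
        return [len(m) for m in self.modules()]

    def genes(self) -> set[str]:
        return set(self.mapping)


def _canonical_order(mapping: dict[str, int]) -> dict[str, int]:
    """Re-index modules by (-size, smallest member); validates contiguity."""
    if not mapping:
        return {}
    groups: dict[int, list[str]] = {}
    for g, i in mapping.items():
        groups.setdefault(i, []).append(g)
    ordered = sorted(groups.values(), key=lambda ms: (-len(ms), min(ms)))
    return {g: idx for idx, ms in enumerate(ordered) for g in ms}


def _graph_of(net: FINetwork | FISubnetwork | nx.Graph) -> nx.Graph:
    if isinstance(net, FISubnetwork):
        return net.graph.graph
    if isinstance(net, FINetwork):
        return net.graph
    return net


def modularity(net: FINetwork | FISubnetwork | nx.Graph, partition: ModuleAssignment) -> float:
    """Newman modularity Q of a partition on the unweighted graph."""
    g = _graph_of(net)
    if g.number_of_edges() == 0:
        raise ValueError("modularity undefined on an edgeless network")
    uncovered = set(g.nodes) - set(partition.mapping)
    if uncovered:
        raise ValueError(f"partition does not cover nodes: {sorted(uncovered)[:5]}")
    m = g.number_of_edges()
    q = 0.0
    # Q = sum_c [e_c/m - (d_c/2m)^2] over communities c
    for comm in partition.modules():
        inside = comm & set(g.nodes)
        e_c = sum(1 for a, b in g.edges(inside) if a in inside and b in inside)
        d_c = sum(g.degree(n) for n in inside)
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return q


def cluster_network(net: FINetwork | FISubnetwork, seed: int = 0) -> ModuleAssignment:
    """Leading-eigenvector spectral modularity clustering with KL refinement.

    Each connected component is clustered independently; module indices are
    assigned globally afterwards. The result is deterministic (``seed`` is
    accepted for interface symmetry but the algorithm involves no sampling).
    """
    g = _graph_of(net)
    if g.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty network")
    communities: list[set[str]] = []
    for comp in nx.connected_components(g):
        comp = set(comp)
        if len(comp) == 1 or g.subgraph(comp).number_of_edges() == 0:
            communities.append(comp)
            continue
        communities.extend(_split_component(g.subgraph(comp)))
    mapping = {gene: i for i, comm in enumerate(communities) for gene in comm}
    return ModuleAssignment(
        mapping,
        algorithm="leading-eigenvector+KL",
        parameters={"seed": seed},
    )


def _split_component(g: nx.Graph) -> list[set[str]]:
    nodes = sorted(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    k = a.sum(axis=1)
    two_m = k.sum()
    b = a - np.outer(k, k) / two_m

    result: list[np.ndarray] = []
    stack: list[np.ndarray] = [np.arange(len(nodes))]
    while stack:
        group = stack.pop()
        halves = _bipartition(b, group, nodes)
        if halves is None:
            result.append(group)
        else:
            stack.extend(halves)
    return [{nodes[i] for i in grp} for grp in result]


def _generalized_b(b: np.ndarray, group: np.ndarray) -> np.ndarray:
    """Newman's B^(g) for subdividing an existing group."""
    bg = b[np.ix_(group, group)].copy()
    bg[np.diag_indices_from(bg)] -= bg.sum(axis=1)
    return bg


def _bipartition(b: np.ndarray, group: np.ndarray, nodes: list[str]) -> tuple[np.ndarray, np.ndarray] | None:
    """Split ``group`` by the leading eigenvector of B^(g); None if no gain."""
    if len(group) < 2:
        return None
    bg = _generalized_b(b, group)
    vals, vecs = np.linalg.eigh(bg)
    lead = vecs[:, -1]
    if vals[-1] <= _EPS:
        return None
    # deterministic sign: smallest-named gene with a non-zero entry is positive
    order = np.argsort([nodes[i] for i in group])
    for j in order:
        if abs(lead[j]) > 1e-9:
            if lead[j] < 0:
                lead = -lead
            break
    s = np.where(lead >= 0, 1.0, -1.0)
    s = _kl_refine(bg, s, [nodes[i] for i in group])
    gain = s @ bg @ s  # proportional to delta-Q (factor 1/4m > 0)
    if gain <= _EPS or abs(s.sum()) == len(s):
        return None
    return group[s > 0], group[s < 0]


def _kl_refine(bg: np.ndarray, s: np.ndarray, names: list[str]) -> np.ndarray:
    """Kernighan-Lin style sweep: greedy single-node flips, keep best prefix.

    Each pass flips every node exactly once in order of best immediate gain
    (ties to the lexicographically smallest gene), records the running
    objective, and restarts from the best intermediate state; passes repeat
    until no improvement.
    """
    n = len(s)
    order_key = np.argsort(names)
    rank = np.empty(n, dtype=int)
    rank[order_key] = np.arange(n)
    best_s = s.copy()
    best_obj = best_s @ bg @ best_s
    improved = True
    while improved:
        improved = False
        cur = best_s.copy()
        cur_obj = best_obj
        moved = np.zeros(n, dtype=bool)
        trace: list[tuple[float, int]] = []
        # flipping node i changes obj by -4 s_i (B s)_i + 4 B_ii
        for _ in range(n):
            bs = bg @ cur
            deltas = -4.0 * cur * bs + 4.0 * np.diag(bg)
            deltas[moved] = -np.inf
            cand = np.where(deltas == deltas.max())[0]
            i = cand[np.argmin(rank[cand])]
            cur[i] = -cur[i]
            moved[i] = True
            cur_obj = cur_obj + deltas[i]
            trace.append((cur_obj, i))
        objs = np.array([t[0] for t in trace])
        jbest = int(np.argmax(objs))
        if objs[jbest] > best_obj + _EPS:
            new_s = best_s.copy()
            for _, i in trace[: jbest + 1]:
                new_s[i] = -new_s[i]
            # disallow collapsing to a single side
            if abs(new_s.sum()) < n:
                best_s, best_obj = new_s, objs[jbest]
                improved = True
    return best_s


def filter_modules(assign: ModuleAssignment, min_size: int) -> ModuleAssignment:
    """Drop modules smaller than ``min_size``; re-index and report removals."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    keep: dict[str, int] = {}
    removed: set[str] = set()
    for comm in assign.modules():
        if len(comm) >= min_size:
            nxt = (max(keep.values()) + 1) if keep else 0
            keep.update((g, nxt) for g in comm)
        else:
            removed |= comm
    if not keep:
        log.warning("min_size=%d removed every module", min_size)
    return ModuleAssignment(
        keep,
        algorithm=assign.algorithm,
        parameters={**assign.parameters, "min_size": min_size},
        removed_genes=removed,
    )
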