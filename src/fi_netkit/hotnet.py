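"""HotNet-style heat-diffusion mutation analysis.

Each gene receives an initial "heat" (by default its distinct-sample
mutation count); heat flows over the FI network under a diffusion kernel
and pairs of genes that exchange enough heat are joined into "hot"
subnetworks. Two standard kernels are provided:

* ``diffusion``: M = exp(-t L), L = D - A the combinatorial Laplacian.
  Columns of M sum to one on a connected graph (heat is conserved).
* ``inverse``:   M = gamma (gamma I + L)^-1, the regularised inverse.

Hot subnetworks are the connected components of the graph joining genes
i, j with  min(M_ij, M_ji) * min(h_i, h_j) >= delta  (the symmetrised
influence weighted by the smaller heat). Statistical significance of the
number of components of size >= s is assessed by permuting heats uniformly
over the network's nodes, with the add-one rule so permutation p-values are
never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.linalg import expm
from scipy.sparse.csgraph import connected_components as _sp_components

from .io import FINetwork, MutationTable

__all__ = [
    "HeatAssignment",
    "InfluenceMatrix",
    "HotSubnetworks",
    "heat_from_mutations",
    "influence_matrix",
    "hot_subnetworks",
    "significance_test",
    "auto_delta",
]


@dataclass
class HeatAssignment:
    """Non-negative heat per gene; genes must exist in the network used."""

    heat: dict[str, float]

    def __post_init__(self) -> None:
        bad = {g: h for g, h in self.heat.items() if h < 0}
        if bad:
            raise ValueError(f"negative heats: {bad}")


def heat_from_mutations(mut: MutationTable) -> HeatAssignment:
    """Default heat: distinct-sample mutation count per gene."""
    return HeatAssignment(mut.distinct_sample_counts().astype(float).to_dict())


@dataclass
class InfluenceMatrix:
    genes: list[str]
    M: np.ndarray  # M[i, j] = influence of gene j on gene i
    kernel: str
    parameter: float
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {g: i for i, g in enumerate(self.genes)}


@dataclass
class HotSubnetworks:
    components: list[frozenset[str]]
    delta: float
    size_pvalues: dict[int, float] = field(default_factory=dict)


def influence_matrix(net: FINetwork, kernel: str = "diffusion", parameter: float = 0.1) -> InfluenceMatrix:
    """Heat-influence matrix of the FI network.

    Computed independently per connected component (cross-component
    influence is identically zero); genes are ordered alphabetically.
    """
    if kernel not in ("diffusion", "inverse"):
        raise ValueError(f"unknown kernel {kernel!r}")
    # t = 0 is the degenerate-but-valid no-diffusion limit (M = I); the
    # regularised inverse needs gamma strictly positive.
    if parameter < 0 or (kernel == "inverse" and parameter == 0):
        raise ValueError("kernel parameter must be positive")
    g = net.graph
    genes = sorted(g.nodes)
    index = {gn: i for i, gn in enumerate(genes)}
    m = np.zeros((len(genes), len(genes)))
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        ids = [index[c] for c in comp]
        a = nx.to_numpy_array(g, nodelist=comp, weight=None)
        lap = np.diag(a.sum(axis=1)) - a
        if kernel == "diffusion":
            block = expm(-parameter * lap)
        else:
            gamma = parameter
            block = gamma * np.linalg.inv(gamma * np.eye(len(comp)) + lap)
        m[np.ix_(ids, ids)] = block
    return InfluenceMatrix(genes=genes, M=m, kernel=kernel, parameter=parameter)


def _hot_edge_matrix(sym_infl: np.ndarray, heats: np.ndarray, delta: float) -> np.ndarray:
    """Boolean adjacency of the delta-thresholded hot graph (zero diagonal)."""
    w = sym_infl * np.minimum.outer(heats, heats)
    adj = w >= delta
    np.fill_diagonal(adj, False)
    adj &= (heats > 0)[:, None]
    adj &= (heats > 0)[None, :]
    return adj


def _component_sets(adj: np.ndarray, hot_mask: np.ndarray) -> list[np.ndarray]:
    """Connected components (as index arrays) among hot nodes, size >= 1."""
    ids = np.where(hot_mask)[0]
    if len(ids) == 0:
        return []
    sub = adj[np.ix_(ids, ids)]
    n_comp, labels = _sp_components(sub, directed=False)
    return [ids[labels == c] for c in range(n_comp)]


def hot_subnetworks(
    infl: InfluenceMatrix,
    heat: HeatAssignment,
    delta: float,
    min_singleton_heat: float = 2.0,
) -> HotSubnetworks:
    """Extract delta-thresholded hot subnetworks.

    Returns components of size >= 2 plus singleton genes whose heat is at
    least ``min_singleton_heat``; components are ordered by decreasing size
    then lexicographically.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    heats = np.array([heat.heat.get(g, 0.0) for g in infl.genes])
    if not (heats > 0).any():
        raise ValueError("all heats are zero")
    sym = np.minimum(infl.M, infl.M.T)
    adj = _hot_edge_matrix(sym, heats, delta)
    comps = []
    for ids in _component_sets(adj, heats > 0):
        members = frozenset(infl.genes[i] for i in ids)
        if len(ids) >= 2 or heats[ids[0]] >= min_singleton_heat:
            comps.append(members)
    comps.sort(key=lambda c: (-len(c), sorted(c)))
    return HotSubnetworks(components=comps, delta=delta)


def _stat_components_ge(adj: np.ndarray, hot_mask: np.ndarray, s: int) -> int:
    return sum(1 for ids in _component_sets(adj, hot_mask) if len(ids) >= s)


def significance_test(
    net: FINetwork,
    infl: InfluenceMatrix,
    heat: HeatAssignment,
    delta: float,
    sizes: list[int],
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[int, float]:
    """Permutation p-values for the number of hot components of size >= s.

    Heats are reassigned to network nodes by a uniform permutation per
    iteration; p(s) = (1 + #{perm stat >= observed}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if delta <= 0:
        raise ValueError("delta must be > 0")
    rng = np.random.default_rng(seed)
    heats = np.array([heat.heat.get(g, 0.0) for g in infl.genes])
    sym = np.minimum(infl.M, infl.M.T)
    observed = {
        s: _stat_components_ge(_hot_edge_matrix(sym, heats, delta), heats > 0, s) for s in sizes
    }
    exceed = {s: 0 for s in sizes}
    for _ in range(n_perm):
        perm = rng.permutation(heats)
        adj = _hot_edge_matrix(sym, perm, delta)
        mask = perm > 0
        for s in sizes:
            if _stat_components_ge(adj, mask, s) >= observed[s]:
                exceed[s] += 1
    return {s: (1 + exceed[s]) / (1 + n_perm) for s in sizes}


def auto_delta(
    infl: InfluenceMatrix,
    heat: HeatAssignment,
    s: int,
    n_perm: int = 100,
    seed: int = 0,
    quantile: float = 0.95,
) -> float:
    """Smallest delta whose largest *null* component stays below size ``s``
    in at least ``quantile`` of heat permutations.

    Candidate deltas are the distinct positive pairwise scores, scanned in
    increasing order.
    """
    rng = np.random.default_rng(seed)
    heats = np.array([heat.heat.get(g, 0.0) for g in infl.genes])
    sym = np.minimum(infl.M, infl.M.T)
    perms = [rng.permutation(heats) for _ in range(n_perm)]
    scores = sym * np.minimum.outer(heats, heats)
    np.fill_diagonal(scores, 0.0)
    cands = np.unique(scores[scores > 0])
    for delta in cands:
        ok = 0
        for perm in perms:
            comps = _component_sets(_hot_edge_matrix(sym, perm, float(delta)), perm > 0)
            if not comps or max(len(c) for c in comps) < s:
                ok += 1
        if ok / n_perm >= quantile:
            return float(delta)
    return float(cands[-1]) if len(cands) else np.inf
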