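"""Independent oracles used across the test suite.

Everything here is deliberately naive — exhaustive double sums, partition
enumeration, brute-force marginalisation — so it checks the package's fast
paths without sharing code with them.
"""

from __future__ import annotations

import itertools
from math import comb

import networkx as nx
import numpy as np

from fi_netkit.io import FINetwork


def make_fi(edges, nodes=()) -> FINetwork:
    net = FINetwork()
    for n in nodes:
        net.add_node(n)
    for a, b in edges:
        net.add_edge(a, b)
    return net


def modularity_double_sum(g: nx.Graph, mapping: dict[str, int]) -> float:
    """Q via the exhaustive double sum over ordered node pairs."""
    nodes = list(g.nodes)
    m = g.number_of_edges()
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    k = a.sum(axis=1)
    q = 0.0
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if mapping[u] == mapping[v]:
                q += a[i, j] - k[i] * k[j] / (2.0 * m)
    return q / (2.0 * m)


def set_partitions(items: list, max_blocks: int):
    """All set partitions of ``items`` into at most ``max_blocks`` blocks."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest, max_blocks):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        if len(part) < max_blocks:
            yield part + [[first]]


def best_partition_q(g: nx.Graph, max_blocks: int = 4) -> float:
    """Globally optimal Q over all partitions into <= max_blocks blocks."""
    nodes = list(g.nodes)
    best = -np.inf
    for part in set_partitions(nodes, max_blocks):
        mapping = {n: i for i, blk in enumerate(part) for n in blk}
        best = max(best, modularity_double_sum(g, mapping))
    return best


def binom_tail_exact(k: int, n: int, pi: float) -> float:
    """Upper binomial tail by direct (integer-combinatorics) summation."""
    return float(sum(comb(n, j) * pi**j * (1 - pi) ** (n - j) for j in range(k, n + 1)))


def enumerate_posteriors(factors, variables, evidence=None) -> dict[str, np.ndarray]:
    """Exact marginals of a discrete factor graph by full enumeration.

    ``factors`` are (scope, table) pairs over 3-state variables ordered
    (-1, 0, +1); ``evidence`` maps variable -> 3-vector.
    """
    evidence = evidence or {}
    var_list = list(variables)
    vidx = {v: i for i, v in enumerate(var_list)}
    marg = {v: np.zeros(3) for v in var_list}
    for states in itertools.product(range(3), repeat=len(var_list)):
        w = 1.0
        for scope, table in factors:
            w *= table[tuple(states[vidx[v]] for v in scope)]
        for v, dist in evidence.items():
            w *= dist[states[vidx[v]]]
        for v in var_list:
            marg[v][states[vidx[v]]] += w
    return {v: m / m.sum() for v, m in marg.items()}


def logrank_chi2_hand(times, events, groups) -> float:
    """Two-sample log-rank chi-square by the textbook observed-expected sum."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups, dtype=int)
    event_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return float(o_minus_e**2 / var)
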