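"""FI subnetwork construction from a gene list, with optional linker genes.

The typical entry point of a mutation analysis: pick recurrently mutated
genes (mutated in at least ``min_samples`` distinct samples), then induce the
FI subgraph on them. Query genes that end up isolated are dropped but
reported, because a gene with no functional interactions in the subnetwork
cannot join any module.

Linker mode admits a small number of non-query "connector" genes so that
more query genes end up in one connected component. The selection rule is a
greedy Steiner-style heuristic: repeatedly add the non-query gene lying on
the largest number of length-<=2 shortest paths between currently
disconnected query components, breaking ties lexicographically, until no
candidate connects two components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .io import FINetwork, GeneSet, MutationTable

log = logging.getLogger(__name__)

__all__ = ["FISubnetwork", "gene_frequency_filter", "build_subnetwork"]


@dataclass
class FISubnetwork:
    """An FI network restricted to query genes plus any admitted linkers."""

    graph: FINetwork
    query_genes: GeneSet
    linker_genes: set[str] = field(default_factory=set)
    dropped_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.linker_genes & set(self.query_genes.genes)
        if overlap:
            raise ValueError(f"linker genes overlap query genes: {sorted(overlap)}")
        for g in self.linker_genes:
            if self.graph.graph.degree(g) < 2:
                raise ValueError(f"linker {g} has degree < 2 in the subnetwork")


def gene_frequency_filter(mut: MutationTable, min_samples: int) -> GeneSet:
    """Genes mutated in at least ``min_samples`` *distinct* samples.

    Counting is per distinct sample, not per mutation record: a gene hit
    twice in the same tumour counts once.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if len(mut) == 0:
        log.warning("empty mutation table; frequency filter returns no genes")
        return GeneSet("frequent_genes", frozenset())
    counts = mut.distinct_sample_counts()
    keep = counts.index[counts >= min_samples]
    return GeneSet("frequent_genes", frozenset(keep))


def build_subnetwork(net: FINetwork, genes: GeneSet, use_linkers: bool = False) -> FISubnetwork:
    """Induce the FI subnetwork on a gene list, optionally adding linkers.

    Without linkers the result is exactly the induced subgraph on the query
    genes present in ``net``, minus isolated query genes (reported in
    ``dropped_genes``). With linkers, connector genes are greedily admitted
    so that disconnected query components (including isolated query genes)
    merge; every linker touches >= 2 components when added, hence has degree
    >= 2 in the result.
    """
    if not genes.genes:
        raise ValueError("query gene set is empty")
    present = set(genes.genes) & net.nodes
    absent = set(genes.genes) - present
    if not present:
        raise ValueError("no query gene is present in the FI network")
    if absent:
        log.info("%d query genes absent from the FI network", len(absent))

    linkers: set[str] = set()
    if use_linkers:
        linkers = _greedy_linkers(net.graph, present)

    sub = net.subgraph(present | linkers)
    isolated = {g for g in present if sub.graph.degree(g) == 0}
    if isolated:
        log.info("dropping %d isolated query genes: %s", len(isolated), sorted(isolated))
        sub = net.subgraph((present - isolated) | linkers)
    return FISubnetwork(
        graph=sub,
        query_genes=genes,
        linker_genes=linkers,
        dropped_genes=isolated | absent,
    )


def _greedy_linkers(g: nx.Graph, query: set[str]) -> set[str]:
    """Greedy connector selection over length-<=2 paths between components."""
    linkers: set[str] = set()
    while True:
        current = set(query) | linkers
        comp_id: dict[str, int] = {}
        sub = g.subgraph(current)
        for i, comp in enumerate(nx.connected_components(sub)):
            if comp & query:  # pure-linker components cannot arise, but be safe
                comp_id.update((n, i) for n in comp)
        n_comps = len(set(comp_id.values()))
        if n_comps <= 1:
            break
        best: tuple[int, str] | None = None
        for cand in g.nodes:
            if cand in current or cand in query:
                continue
            # neighbours of cand per query component
            touched: dict[int, int] = {}
            for nb in g.neighbors(cand):
                cid = comp_id.get(nb)
                if cid is not None:
                    touched[cid] = touched.get(cid, 0) + 1
            if len(touched) < 2:
                continue
            # number of a-cand-b shortest paths joining distinct components
            counts = list(touched.values())
            total = sum(counts)
            n_paths = (total * total - sum(c * c for c in counts)) // 2
            if best is None or n_paths > best[0] or (n_paths == best[0] and cand < best[1]):
                best = (n_paths, cand)
        if best is None:
            break
        linkers.add(best[1])
    return linkers
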