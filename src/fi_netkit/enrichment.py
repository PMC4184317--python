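"""Binomial-test pathway enrichment with Benjamini-Hochberg FDR control.

For a query list of n genes tested against a pathway of m genes drawn from a
background of N genes, the enrichment p-value is the exact upper binomial
tail

    p = P(X >= k),  X ~ Binomial(n, m/N),

where k is the observed overlap. The test is one-sided (enrichment only).
The default background is the loaded FI network's gene set; FDR across a
collection uses Benjamini-Hochberg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from statsmodels.stats.multitest import multipletests

from .io import GeneSet, PathwayCollection
from .modules import ModuleAssignment

__all__ = [
    "EnrichmentResult",
    "binomial_tail",
    "binomial_enrichment",
    "enrich_collection",
    "annotate_modules",
]


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    query_size: int
    set_size: int
    background_size: int
    p_value: float
    fdr: float
    overlap_genes: frozenset[str]


def binomial_tail(k: int, n: int, pi: float) -> float:
    """Exact upper tail P(X >= k) for X ~ Binomial(n, pi).

    Computed as a direct term sum; the leading term comes from log-gamma
    and subsequent terms from the stable ratio recurrence
    t_{j+1} = t_j * (n-j)/(j+1) * pi/(1-pi).
    """
    if not 0.0 <= pi <= 1.0:
        raise ValueError("pi must lie in [0, 1]")
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    if pi == 0.0:
        return 0.0
    if pi == 1.0:
        return 1.0
    def log_pmf(j: int) -> float:
        return (
            math.lgamma(n + 1)
            - math.lgamma(j + 1)
            - math.lgamma(n - j + 1)
            + j * math.log(pi)
            + (n - j) * math.log1p(-pi)
        )

    ratio = pi / (1.0 - pi)
    if k > n * pi:
        # upper-tail terms decrease from j = k: sum ascending, seeded there
        t = math.exp(log_pmf(k))
        total = t
        for j in range(k, n):
            t *= (n - j) / (j + 1) * ratio
            total += t
        return min(total, 1.0)
    # k at or below the mean: the complementary lower tail has its largest
    # term at j = k - 1; sum descending so underflow only hits negligible terms
    t = math.exp(log_pmf(k - 1))
    total = t
    for j in range(k - 1, 0, -1):
        t *= j / (n - j + 1) / ratio
        total += t
    return min(max(1.0 - total, 0.0), 1.0)


def binomial_enrichment(
    query: GeneSet,
    pset: GeneSet,
    background_size: int,
    background: frozenset[str] | set[str] | None = None,
) -> EnrichmentResult:
    """One-sided binomial enrichment of ``query`` in ``pset``.

    If ``background`` (the explicit gene universe) is given, both query and
    pathway are intersected with it first and ``background_size`` may be 0
    to mean ``len(background)``.
    """
    qgenes = set(query.genes)
    pgenes = set(pset.genes)
    if background is not None:
        bg = {g.upper() for g in background}
        qgenes &= bg
        pgenes &= bg
        if background_size in (0, None):
            background_size = len(bg)
    n_bg = int(background_size)
    if n_bg <= 0:
        raise ValueError("background size must be positive")
    if len(pgenes) == 0:
        raise ValueError(f"pathway {pset.name!r} is empty within the background")
    if n_bg < len(pgenes):
        raise ValueError("background smaller than the pathway")
    n = len(qgenes)
    if n == 0:
        raise ValueError("query is empty within the background")
    overlap = qgenes & pgenes
    k = len(overlap)
    p = binomial_tail(k, n, len(pgenes) / n_bg)
    return EnrichmentResult(
        set_name=pset.name,
        overlap=k,
        query_size=n,
        set_size=len(pgenes),
        background_size=n_bg,
        p_value=p,
        fdr=p,
        overlap_genes=frozenset(overlap),
    )


def enrich_collection(
    query: GeneSet,
    coll: PathwayCollection,
    background_size: int,
    background: frozenset[str] | set[str] | None = None,
) -> list[EnrichmentResult]:
    """Test every pathway in a collection; keep overlaps >= 1; BH-adjust.

    Results come back sorted by ascending p-value, ties by set name.
    """
    if len(coll) == 0:
        raise ValueError("empty pathway collection")
    results = []
    for pset in coll:
        res = binomial_enrichment(query, pset, background_size, background)
        if res.overlap >= 1:
            results.append(res)
    if results:
        _, fdrs, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, q in zip(results, fdrs):
            r.fdr = float(min(q, 1.0))
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def annotate_modules(
    assign: ModuleAssignment,
    coll: PathwayCollection,
    background_size: int,
    background: frozenset[str] | set[str] | None = None,
) -> dict[int, list[EnrichmentResult]]:
    """Run pathway enrichment for each module; FDR is within-module."""
    out: dict[int, list[EnrichmentResult]] = {}
    for idx, comm in enumerate(assign.modules()):
        if not comm:
            out[idx] = []
            continue
        query = GeneSet(f"module_{idx}", frozenset(comm))
        try:
            out[idx] = enrich_collection(query, coll, background_size, background)
        except ValueError:
            # module entirely outside the background: nothing to test
            out[idx] = []
    return out
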