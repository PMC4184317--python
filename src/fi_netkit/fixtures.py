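"""Seeded synthetic-data generators for the full analysis workflow.

These emulate a TCGA-style cohort study over an FI network: a network with
planted dense gene modules, a MAF-dialect mutation table in which the
planted modules are recurrently mutated, clinical follow-up where carrying
a planted-module mutation multiplies the hazard (so a module can be
protective or deleterious), and an expression matrix in which planted
modules share a latent factor.

Every generator is a pure function of its spec (seed included): repeated
calls are byte-identical, and the files they write parse back through the
``fi_netkit.io`` readers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ClinicalTable,
    DIRECTIONS,
    EdgeAnnotation,
    ExpressionMatrix,
    FINetwork,
    GeneSet,
    MutationTable,
    PathwayCollection,
    SemanticType,
    write_clinical,
    write_expression,
    write_gmt,
    write_maf,
    write_network,
)

__all__ = [
    "PlantedModule",
    "FixtureSpec",
    "default_demo_spec",
    "synth_network",
    "synth_maf",
    "synth_clinical",
    "synth_expression",
    "synth_pathways",
    "module_carriers",
    "write_demo",
]

_FUNCTIONAL = "Missense_Mutation"
_SILENT = "Silent"
_SILENT_FRACTION = 0.1  # planted to exercise the MAF variant filter


@dataclass(frozen=True)
class PlantedModule:
    genes: tuple[str, ...]
    mutation_rate: float = 0.05
    expression_r: float = 0.8
    hazard_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must lie in (0, 1]")
        if not (0.0 <= self.expression_r < 1.0):
            raise ValueError("expression_r must lie in [0, 1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")


@dataclass(frozen=True)
class FixtureSpec:
    n_genes: int = 300
    n_samples: int = 300
    planted_modules: tuple[PlantedModule, ...] = ()
    background_mutation_rate: float = 0.01
    censoring_fraction: float = 0.2
    within_module_edge_prob: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 1:
            raise ValueError("n_genes and n_samples must be positive")
        if not (0.0 < self.background_mutation_rate <= 1.0):
            raise ValueError("background_mutation_rate must lie in (0, 1]")
        if not (0.0 <= self.censoring_fraction < 1.0):
            raise ValueError("censoring_fraction must lie in [0, 1)")
        seen: set[str] = set()
        for mod in self.planted_modules:
            overlap = seen & set(mod.genes)
            if overlap:
                raise ValueError(f"planted modules overlap: {sorted(overlap)}")
            seen |= set(mod.genes)
        if len(seen) > self.n_genes:
            raise ValueError("planted modules exceed n_genes")

    @property
    def gene_names(self) -> list[str]:
        planted = [g for mod in self.planted_modules for g in mod.genes]
        n_bg = self.n_genes - len(planted)
        return planted + [f"BG{i:04d}" for i in range(n_bg)]

    @property
    def sample_names(self) -> list[str]:
        # exactly 12 characters: the TCGA participant prefix length, so the
        # default MAF barcode truncation is the identity on these ids
        return [f"TCGA-SY-{i:04d}" for i in range(self.n_samples)]


def _module_genes(prefix: str, size: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{i:02d}" for i in range(size))


def default_demo_spec(seed: int = 0) -> FixtureSpec:
    """The demo cohort: ~300 genes, 300 samples, three planted modules, one
    protective (hazard ratio 0.4, mirroring a module whose carriers survive
    longer)."""
    return FixtureSpec(
        n_genes=300,
        n_samples=300,
        planted_modules=(
            PlantedModule(_module_genes("MA", 12), mutation_rate=0.05, expression_r=0.7),
            PlantedModule(_module_genes("MB", 10), mutation_rate=0.05, expression_r=0.8),
            PlantedModule(
                _module_genes("MC", 10), mutation_rate=0.05, expression_r=0.8, hazard_ratio=0.4
            ),
        ),
        background_mutation_rate=0.005,
        censoring_fraction=0.2,
        seed=seed,
    )


def synth_network(spec: FixtureSpec) -> FINetwork:
    """Planted dense blocks (within-module edge prob 0.8 by default) on a
    sparse random background (edge prob 4/n); annotations sampled uniformly."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    genes = spec.gene_names
    module_of: dict[str, int] = {}
    for mi, mod in enumerate(spec.planted_modules):
        for g in mod.genes:
            module_of[g] = mi
    p_bg = min(4.0 / spec.n_genes, 1.0)
    sem_types = [t for t in SemanticType]
    net = FINetwork()
    for g in genes:
        net.add_node(g)
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = genes[i], genes[j]
            same = module_of.get(a) is not None and module_of.get(a) == module_of.get(b)
            p = spec.within_module_edge_prob if same else p_bg
            if rng.random() < p:
                ann = EdgeAnnotation(
                    semantic_type=sem_types[rng.integers(len(sem_types))],
                    direction=DIRECTIONS[rng.integers(len(DIRECTIONS))],
                    score=round(float(rng.uniform(0.5, 1.0)), 2),
                )
                net.add_edge(a, b, ann)
    return net


def synth_maf(spec: FixtureSpec, net: FINetwork | None = None) -> MutationTable:
    """Mutation table: planted-module genes mutate at their module's rate,
    background genes at the background rate; ~10% of records are Silent."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    genes = spec.gene_names
    rate = np.full(len(genes), spec.background_mutation_rate)
    pos = 0
    for mod in spec.planted_modules:
        rate[pos : pos + len(mod.genes)] = mod.mutation_rate
        pos += len(mod.genes)
    rows = []
    for sample in spec.sample_names:
        hits = rng.random(len(genes)) < rate
        for gi in np.where(hits)[0]:
            vc = _SILENT if rng.random() < _SILENT_FRACTION else _FUNCTIONAL
            rows.append((genes[gi], sample, vc))
    df = pd.DataFrame(rows, columns=["gene", "sample", "variant_classification"])
    return MutationTable(df)


def module_carriers(spec: FixtureSpec, maf: MutationTable) -> dict[int, set[str]]:
    """Samples carrying >= 1 *functional* (non-Silent) mutation per planted module."""
    functional = MutationTable(maf.df[maf.df["variant_classification"] != _SILENT].copy())
    return {
        mi: functional.carriers(mod.genes) for mi, mod in enumerate(spec.planted_modules)
    }


def synth_clinical(spec: FixtureSpec, maf: MutationTable) -> ClinicalTable:
    """Exponential survival (baseline rate 1); carrying a planted module's
    functional mutation multiplies the hazard by that module's hazard ratio.

    Censoring is independent: with probability ``censoring_fraction`` the
    event is replaced by censoring at a uniform fraction of the event time.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 303]))
    carriers = module_carriers(spec, maf)
    times, events = [], []
    for sample in spec.sample_names:
        hazard = 1.0
        for mi, mod in enumerate(spec.planted_modules):
            if sample in carriers[mi]:
                hazard *= mod.hazard_ratio
        t = rng.exponential(1.0 / hazard)
        if rng.random() < spec.censoring_fraction:
            times.append(t * rng.uniform())
            events.append(0)
        else:
            times.append(t)
            events.append(1)
    df = pd.DataFrame({"sample": spec.sample_names, "time": times, "event": events})
    return ClinicalTable(df)


def synth_expression(spec: FixtureSpec) -> ExpressionMatrix:
    """Planted modules share a latent factor giving pairwise correlation
    ~ expression_r (x = sqrt(rho) f + sqrt(1 - rho) eps); background genes
    are i.i.d. standard normal."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 404]))
    genes = spec.gene_names
    x = rng.standard_normal((len(genes), spec.n_samples))
    pos = 0
    for mod in spec.planted_modules:
        k = len(mod.genes)
        f = rng.standard_normal(spec.n_samples)
        rho = mod.expression_r
        x[pos : pos + k] = np.sqrt(rho) * f + np.sqrt(1.0 - rho) * x[pos : pos + k]
        pos += k
    df = pd.DataFrame(x, index=genes, columns=spec.sample_names)
    return ExpressionMatrix(df)


def synth_pathways(spec: FixtureSpec, n_random_sets: int = 20, set_size: int = 15) -> PathwayCollection:
    """Gene-set collection: one set per planted module plus random decoys."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 505]))
    genes = spec.gene_names
    sets = [
        GeneSet(f"PLANTED_MODULE_{mi}", frozenset(mod.genes))
        for mi, mod in enumerate(spec.planted_modules)
    ]
    for i in range(n_random_sets):
        members = rng.choice(len(genes), size=min(set_size, len(genes)), replace=False)
        sets.append(GeneSet(f"RANDOM_SET_{i:02d}", frozenset(genes[j] for j in members)))
    return PathwayCollection(sets, source="synthetic")


def write_demo(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write the full demo input bundle plus the planted ground truth.

    Emits fi.tsv, demo.maf, clin.tsv, expr.tsv, pathways.gmt and truth.json
    into ``out_dir``; returns the paths keyed by artifact name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = synth_network(spec)
    maf = synth_maf(spec, net)
    clin = synth_clinical(spec, maf)
    expr = synth_expression(spec)
    paths = {
        "network": out / "fi.tsv",
        "maf": out / "demo.maf",
        "clinical": out / "clin.tsv",
        "expression": out / "expr.tsv",
        "pathways": out / "pathways.gmt",
        "truth": out / "truth.json",
    }
    write_network(net, paths["network"])
    write_maf(maf, paths["maf"])
    write_clinical(clin, paths["clinical"])
    write_expression(expr, paths["expression"])
    write_gmt(synth_pathways(spec), paths["pathways"])
    carriers = module_carriers(spec, maf)
    truth = {
        "spec": asdict(spec),
        "modules": [
            {
                "index": mi,
                "genes": sorted(mod.genes),
                "mutation_rate": mod.mutation_rate,
                "expression_r": mod.expression_r,
                "hazard_ratio": mod.hazard_ratio,
                "carriers": sorted(carriers[mi]),
            }
            for mi, mod in enumerate(spec.planted_modules)
        ],
    }
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
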