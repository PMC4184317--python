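"""End-to-end workflow: gene list / MAF -> subnetwork -> modules ->
annotation -> survival, with optional HotNet, signature and factor-graph
stages, driven by a validated run configuration.

Each stage writes a TSV artifact; the run finishes with a JSON manifest
recording input checksums, parameters, seed and package versions so a run
can be audited and reproduced. No stage mutates another stage's output, so
the pipeline is restartable from any intermediate file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrichment import annotate_modules
from .fixtures import default_demo_spec, write_demo
from .hotnet import heat_from_mutations, hot_subnetworks, influence_matrix, significance_test
from .io import (
    read_clinical,
    read_expression,
    read_fi_network,
    read_gene_list,
    read_gmt,
    read_maf,
    write_network,
    write_table,
)
from .modules import cluster_network, filter_modules, modularity
from .signature import correlation_weight_network, mcl_cluster, module_scores
from .subnetwork import build_subnetwork, gene_frequency_filter
from .survival import module_survival_scan
from .factor_graph import pathway_activity, read_pathway_model

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated configuration for :func:`run_pipeline`.

    Unknown keys in a YAML config are rejected; every parameter is checked
    against its stage's documented domain before any stage runs.
    """

    network: str = ""
    out_dir: str = "results"
    genes: str | None = None
    maf: str | None = None
    clinical: str | None = None
    expression: str | None = None
    gmt: str | None = None
    pathway_model: str | None = None
    # stage parameters
    min_samples: int = 3
    use_linkers: bool = False
    min_module_size: int = 3
    background: int | None = None
    run_hotnet: bool = False
    t: float = 0.1
    delta: float = 1e-3
    sizes: tuple[int, ...] = (3, 4, 5)
    n_perm: int = 100
    min_singleton_heat: float = 2.0
    run_signature: bool = False
    inflation: float = 2.0
    min_signature_size: int = 5
    min_avg_corr: float = 0.25
    epsilon: float = 0.1
    drop_unmutated_samples: bool = False
    seed: int = 13
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.network:
            raise ValueError("config requires a 'network' path")
        if self.genes is None and self.maf is None:
            raise ValueError("config requires 'genes' or 'maf'")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")
        if self.background is not None and self.background < 1:
            raise ValueError("background must be >= 1")
        if self.t <= 0:
            raise ValueError("t must be > 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.run_hotnet and self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if not (1.0 < self.inflation <= 10.0):
            raise ValueError("inflation must lie in (1, 10]")
        if not (0.0 < self.epsilon < 0.5):
            raise ValueError("epsilon must lie in (0, 0.5)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "sizes" in raw and raw["sizes"] is not None:
            raw["sizes"] = tuple(int(s) for s in raw["sizes"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured workflow; returns the manifest dictionary.

    Stage order: subnetwork -> cluster -> annotate (if a GMT is given) ->
    survival (if clinical data is given), then optional hotnet / signature /
    factor-graph stages. A stage failure raises :class:`PipelineError`
    naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stats: dict[str, object] = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return deco

    # ---- inputs ---------------------------------------------------------
    @stage("load")
    def _inputs():
        net = read_fi_network(config.network, "sif" if config.network.endswith(".sif") else "tsv")
        mut = read_maf(config.maf) if config.maf else None
        return net, mut

    net, mut = _inputs

    # ---- subnetwork -----------------------------------------------------
    @stage("subnetwork")
    def sub():
        if config.genes:
            genes = read_gene_list(config.genes)
        else:
            genes = gene_frequency_filter(mut, config.min_samples)
        s = build_subnetwork(net, genes, use_linkers=config.use_linkers)
        path = out / "subnetwork.tsv"
        write_network(s.graph, path)
        artifacts["subnetwork"] = str(path)
        stats["subnetwork_genes"] = s.graph.number_of_nodes()
        stats["subnetwork_edges"] = s.graph.number_of_edges()
        stats["dropped_genes"] = len(s.dropped_genes)
        return s

    # ---- clustering -----------------------------------------------------
    @stage("cluster")
    def assign():
        a = cluster_network(sub, seed=config.seed)
        q = modularity(sub, a)
        a = filter_modules(a, config.min_module_size)
        path = out / "modules.tsv"
        rows = pd.DataFrame(
            sorted(a.mapping.items()), columns=["gene", "module"]
        ).sort_values(["module", "gene"])
        write_table(rows, path)
        artifacts["modules"] = str(path)
        stats["n_modules"] = a.n_modules
        stats["modularity_q"] = q
        return a

    # ---- annotation -----------------------------------------------------
    if config.gmt:
        @stage("annotate")
        def _annotate():
            coll = read_gmt(config.gmt)
            n_bg = config.background or net.number_of_nodes()
            per_module = annotate_modules(assign, coll, n_bg)
            rows = []
            for mod, results in sorted(per_module.items()):
                for r in results:
                    rows.append(
                        {
                            "module": mod,
                            "set_name": r.set_name,
                            "overlap": r.overlap,
                            "query_size": r.query_size,
                            "set_size": r.set_size,
                            "background_size": r.background_size,
                            "p_value": r.p_value,
                            "fdr": r.fdr,
                            "overlap_genes": ",".join(sorted(r.overlap_genes)),
                        }
                    )
            path = out / "enrichment.tsv"
            write_table(pd.DataFrame(rows), path)
            artifacts["enrichment"] = str(path)

    # ---- survival -------------------------------------------------------
    if config.clinical and mut is not None:
        @stage("survival")
        def _survival():
            clin = read_clinical(config.clinical)
            scan = module_survival_scan(
                assign,
                mut,
                clin,
                min_module_size=config.min_module_size,
                drop_unmutated_samples=config.drop_unmutated_samples,
            )
            path = out / "survival.tsv"
            write_table(scan, path)
            artifacts["survival"] = str(path)
            if len(scan):
                stats["best_survival_module"] = int(scan.iloc[0]["module"])
                stats["best_coxph_p"] = float(scan.iloc[0]["coxph_p"])

    # ---- optional stages ------------------------------------------------
    if config.run_hotnet and mut is not None:
        @stage("hotnet")
        def _hotnet():
            heat = heat_from_mutations(mut)
            infl = influence_matrix(net, "diffusion", config.t)
            hot = hot_subnetworks(infl, heat, config.delta, config.min_singleton_heat)
            pvals = significance_test(
                net, infl, heat, config.delta, list(config.sizes),
                n_perm=config.n_perm, seed=config.seed,
            )
            rows = [
                {"component": i, "size": len(c), "genes": ",".join(sorted(c))}
                for i, c in enumerate(hot.components)
            ]
            path = out / "hotnet.tsv"
            write_table(pd.DataFrame(rows), path)
            ppath = out / "hotnet_pvalues.tsv"
            write_table(
                pd.DataFrame(
                    [{"size": s, "p": p} for s, p in sorted(pvals.items())]
                ),
                ppath,
            )
            artifacts["hotnet"] = str(path)
            artifacts["hotnet_pvalues"] = str(ppath)

    if config.run_signature and config.expression:
        @stage("signature")
        def _signature():
            expr = read_expression(config.expression)
            wnet = correlation_weight_network(net, expr)
            massign = mcl_cluster(wnet, inflation=config.inflation)
            feats = module_scores(
                massign, expr,
                min_size=config.min_signature_size,
                min_avg_corr=config.min_avg_corr,
            )
            path = out / "features.tsv"
            feats.to_csv(path, sep="\t", index_label="module", lineterminator="\n")
            artifacts["features"] = str(path)
            stats["n_signature_modules"] = len(feats)

    if config.pathway_model and config.expression:
        @stage("paradigm")
        def _paradigm():
            model = read_pathway_model(config.pathway_model)
            expr = read_expression(config.expression)
            ipa = pathway_activity(model, expr, epsilon=config.epsilon)
            path = out / "ipa.tsv"
            ipa.to_csv(path, sep="\t", index_label="entity", lineterminator="\n")
            artifacts["ipa"] = str(path)

    # ---- manifest -------------------------------------------------------
    inputs = {
        k: {"path": str(p), "sha256": _sha256(Path(p))}
        for k, p in (
            ("network", config.network),
            ("genes", config.genes),
            ("maf", config.maf),
            ("clinical", config.clinical),
            ("expression", config.expression),
            ("gmt", config.gmt),
            ("pathway_model", config.pathway_model),
        )
        if p
    }
    manifest = {
        "tool": "fi-netkit",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": config.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items()
            if k not in ("network", "genes", "maf", "clinical", "expression",
                         "gmt", "pathway_model", "out_dir")
        },
        "inputs": inputs,
        "artifacts": artifacts,
        "stats": stats,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
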