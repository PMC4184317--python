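"""Readers and writers for the external formats and the canonical in-memory types.

The toolkit works over a pre-built functional-interaction (FI) network: an
undirected graph on gene symbols whose edges may carry a semantic annotation
(catalysis, activation, inhibition, ...), a direction glyph and a confidence
score. Everything downstream (subnetwork construction, clustering, HotNet,
survival scans) consumes the containers defined here.

Conventions shared by every reader:

* gene symbols are uppercased and stripped at ingest (no alias resolution);
* files are UTF-8, tab-separated, ``\\n`` line endings;
* every writer round-trips through its reader on semantic content.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "SemanticType",
    "EdgeAnnotation",
    "FINetwork",
    "MutationTable",
    "GeneSet",
    "PathwayCollection",
    "ExpressionMatrix",
    "ClinicalTable",
    "normalize_symbol",
    "read_fi_network",
    "read_maf",
    "read_gmt",
    "read_gene_list",
    "read_expression",
    "read_clinical",
    "write_network",
    "write_table",
    "write_gene_list",
    "write_gmt",
    "write_expression",
    "write_clinical",
    "write_maf",
    "DEFAULT_EXCLUDED_VARIANTS",
    "DEFAULT_BARCODE_LENGTH",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class SemanticType(str, enum.Enum):
    """Semantic meaning of a functional interaction."""

    CATALYSIS = "catalysis"
    ACTIVATION = "activation"
    INHIBITION = "inhibition"
    EXPRESSION_REGULATION = "expression_regulation"
    COMPLEX = "complex"
    PREDICTED = "predicted"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, text: str) -> "SemanticType":
        try:
            return cls(text.strip().lower())
        except ValueError:
            return cls.UNKNOWN


#: Direction glyphs an FI edge may carry (undirected "-", activating "->"/"<-",
#: inhibiting "-|"/"|-").
DIRECTIONS = ("->", "-|", "-", "<-", "|-")


@dataclass(frozen=True)
class EdgeAnnotation:
    semantic_type: SemanticType = SemanticType.UNKNOWN
    direction: str = "-"
    score: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction glyph {self.direction!r}")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"edge score {self.score} outside [0, 1]")


def normalize_symbol(symbol: str) -> str:
    """Uppercase/strip a gene symbol. Idempotent; rejects empty strings."""
    out = symbol.strip().upper()
    if not out:
        raise ValueError("empty gene symbol")
    return out


class FINetwork:
    """Undirected functional-interaction network over gene symbols.

    Thin wrapper around :class:`networkx.Graph`: nodes are uppercase gene
    symbols, each edge carries an :class:`EdgeAnnotation`. Self-loops are
    rejected; edges are stored order-independently.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    # -- construction ----------------------------------------------------
    def add_node(self, gene: str) -> str:
        gene = normalize_symbol(gene)
        self.graph.add_node(gene)
        return gene

    def add_edge(self, a: str, b: str, annotation: EdgeAnnotation | None = None) -> None:
        a, b = normalize_symbol(a), normalize_symbol(b)
        if a == b:
            raise ValueError(f"self-loop on {a} not allowed")
        ann = annotation or EdgeAnnotation()
        if self.graph.has_edge(a, b):
            old: EdgeAnnotation = self.graph.edges[a, b]["annotation"]
            # duplicate edges merge; the record with the highest score wins
            if _score_key(ann) > _score_key(old):
                self.graph.edges[a, b]["annotation"] = ann
        else:
            self.graph.add_edge(a, b, annotation=ann)

    # -- queries ---------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def annotation(self, a: str, b: str) -> EdgeAnnotation:
        return self.graph.edges[normalize_symbol(a), normalize_symbol(b)]["annotation"]

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(normalize_symbol(a), normalize_symbol(b))

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def subgraph(self, genes: Iterable[str]) -> "FINetwork":
        keep = {normalize_symbol(g) for g in genes}
        return FINetwork(self.graph.subgraph(keep).copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FINetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"FINetwork({self.number_of_nodes()} genes, {self.number_of_edges()} FIs)"


def _score_key(ann: EdgeAnnotation) -> float:
    return -np.inf if ann.score is None else ann.score


@dataclass
class MutationTable:
    """Long-form gene x sample mutation events.

    ``df`` has columns ``gene``, ``sample``, ``variant_classification``;
    fully duplicated records are removed at construction.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene", "sample", "variant_classification"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"MutationTable missing columns {missing}")
        self.df = self.df[required].drop_duplicates().reset_index(drop=True)
        self.df["gene"] = self.df["gene"].map(normalize_symbol)

    def genes(self) -> set[str]:
        return set(self.df["gene"])

    def samples(self) -> set[str]:
        return set(self.df["sample"])

    def distinct_sample_counts(self) -> pd.Series:
        """Number of distinct mutated samples per gene."""
        return self.df.groupby("gene")["sample"].nunique()

    def carriers(self, genes: Iterable[str]) -> set[str]:
        """Samples carrying >= 1 mutation in any of ``genes``."""
        gset = {normalize_symbol(g) for g in genes}
        return set(self.df.loc[self.df["gene"].isin(gset), "sample"])

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("GeneSet requires a non-empty name")
        object.__setattr__(self, "genes", frozenset(normalize_symbol(g) for g in self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


@dataclass
class PathwayCollection:
    sets: list[GeneSet]
    source: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate gene-set names: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass
class ExpressionMatrix:
    """Gene x sample real matrix, stored as a DataFrame (genes as index)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df.index = [normalize_symbol(g) for g in self.df.index]
        if self.df.index.has_duplicates:
            log.warning("duplicate gene rows averaged in expression matrix")
            self.df = self.df.groupby(level=0, sort=False).mean()
        self.df = self.df.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.df.index)

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()


@dataclass
class ClinicalTable:
    """Per-sample follow-up: columns ``sample``, ``time``, ``event``."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample", "time", "event"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"ClinicalTable missing columns {missing}")
        self.df = self.df[required].reset_index(drop=True)
        if self.df["sample"].duplicated().any():
            dup = self.df.loc[self.df["sample"].duplicated(), "sample"].iloc[0]
            raise ValueError(f"duplicate clinical sample id {dup!r}")
        self.df["time"] = self.df["time"].astype(float)
        self.df["event"] = self.df["event"].astype(int)
        if (self.df["time"] < 0).any():
            raise ValueError("clinical times must be >= 0")
        if not self.df["event"].isin([0, 1]).all():
            bad = self.df.loc[~self.df["event"].isin([0, 1]), "event"].iloc[0]
            raise ValueError(f"clinical event must be 0 or 1, got {bad}")

    def samples(self) -> set[str]:
        return set(self.df["sample"])

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_SIF_RELATIONS = {t.value: t for t in SemanticType}


def read_fi_network(path: str | Path, format: str = "tsv") -> FINetwork:
    """Read an FI network from a tab-delimited edge list or a SIF file.

    tsv columns: geneA, geneB, optional annotation, direction, score (extra
    columns ignored with a warning); SIF lines: ``node relation node [node...]``.
    Duplicate edges are merged keeping the highest-scored record.
    """
    path = Path(path)
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown network format {format!r}")
    net = FINetwork()
    n_lines = 0
    warned_extra = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if lineno == 1 and format == "tsv" and _looks_like_header(fields):
                continue
            n_lines += 1
            if format == "tsv":
                if len(fields) < 2 or not fields[1].strip():
                    raise FormatError(f"{path}:{lineno}: expected >= 2 columns, got {len(fields)}")
                if len(fields) > 5 and not warned_extra:
                    log.warning("%s:%d: extra columns beyond 5 ignored", path, lineno)
                    warned_extra = True
                ann = _parse_tsv_annotation(fields, path, lineno)
                net.add_edge(fields[0], fields[1], ann)
            else:  # sif
                if len(fields) == 1:
                    net.add_node(fields[0])
                    continue
                if len(fields) < 3:
                    raise FormatError(f"{path}:{lineno}: SIF line needs 'node relation node'")
                sem = SemanticType.parse(fields[1])
                for target in fields[2:]:
                    net.add_edge(fields[0], target, EdgeAnnotation(semantic_type=sem))
    if n_lines == 0:
        raise FormatError(f"{path}: empty network file")
    return net


def _looks_like_header(fields: Sequence[str]) -> bool:
    head = [f.strip().lower() for f in fields[:2]]
    return head[:1] == ["genea"] or head == ["gene1", "gene2"] or head[:1] == ["gene_a"]


def _parse_tsv_annotation(fields: Sequence[str], path: Path, lineno: int) -> EdgeAnnotation:
    sem = SemanticType.parse(fields[2]) if len(fields) > 2 and fields[2].strip() else SemanticType.UNKNOWN
    direction = fields[3].strip() if len(fields) > 3 and fields[3].strip() else "-"
    if direction not in DIRECTIONS:
        raise FormatError(f"{path}:{lineno}: unknown direction glyph {direction!r}")
    score: float | None = None
    if len(fields) > 4 and fields[4].strip():
        try:
            score = float(fields[4])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric score {fields[4]!r}") from exc
        if not (0.0 <= score <= 1.0):
            raise FormatError(f"{path}:{lineno}: score {score} outside [0, 1]")
    return EdgeAnnotation(semantic_type=sem, direction=direction, score=score)


#: Variant classes excluded by default: restrict to candidate functional
#: mutations, the standard MAF practice.
DEFAULT_EXCLUDED_VARIANTS = frozenset({"Silent", "Intron", "3'UTR", "5'UTR", "IGR", "RNA"})

#: TCGA-style sample barcodes are truncated to the participant-level 12-character
#: prefix so mutation and clinical tables join on the same id.
DEFAULT_BARCODE_LENGTH = 12


def read_maf(
    path: str | Path,
    excluded_variants: Iterable[str] | None = DEFAULT_EXCLUDED_VARIANTS,
    barcode_length: int | None = DEFAULT_BARCODE_LENGTH,
) -> MutationTable:
    """Read a Mutation Annotation Format (MAF) table.

    Requires columns ``Hugo_Symbol`` and ``Tumor_Sample_Barcode``;
    ``Variant_Classification`` is optional. Rows whose variant class is in
    ``excluded_variants`` are dropped (pass ``None`` to keep everything);
    barcodes are truncated to ``barcode_length`` characters (``None`` = keep).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in ("Hugo_Symbol", "Tumor_Sample_Barcode"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required MAF column {col!r}")
    if "Variant_Classification" not in df.columns:
        df["Variant_Classification"] = ""
    if excluded_variants is not None:
        df = df[~df["Variant_Classification"].isin(set(excluded_variants))]
    samples = df["Tumor_Sample_Barcode"].str.strip()
    if barcode_length is not None:
        samples = samples.str[:barcode_length]
    out = pd.DataFrame(
        {
            "gene": df["Hugo_Symbol"],
            "sample": samples,
            "variant_classification": df["Variant_Classification"],
        }
    )
    return MutationTable(out)


def read_gmt(path: str | Path) -> PathwayCollection:
    """Read a GMT gene-set collection (name, description, genes...)."""
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: GMT line needs name and description")
            name = fields[0].strip()
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            seen.add(name)
            genes = [g for g in (f.strip() for f in fields[2:]) if g]
            if not genes:
                log.warning("%s:%d: gene set %r has no genes; dropped", path, lineno, name)
                continue
            sets.append(GeneSet(name, frozenset(genes)))
    return PathwayCollection(sets, source=str(path))


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene list; blank lines and ``#`` comments skipped."""
    path = Path(path)
    genes = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return GeneSet(name or path.stem, frozenset(genes))


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample expression TSV (first column = gene symbols)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any() and not df[col].isna().all():
            bad = converted.index[converted.isna() & df[col].notna()]
            if len(bad):
                raise FormatError(
                    f"{path}: non-numeric expression value at gene {bad[0]!r}, sample {col!r}"
                )
        df[col] = converted
    return ExpressionMatrix(df)


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV with columns sample, time, event."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    return ClinicalTable(df)


# ---------------------------------------------------------------------------
# writers (all UTF-8, tab-separated, '\n' endings; round-trip their readers)
# ---------------------------------------------------------------------------


def write_network(net: FINetwork, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown network format {format!r}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if format == "tsv":
            fh.write("geneA\tgeneB\tannotation\tdirection\tscore\n")
            for a, b in sorted(tuple(sorted(e)) for e in net.edges):
                ann = net.annotation(a, b)
                score = "" if ann.score is None else f"{ann.score:g}"
                fh.write(f"{a}\t{b}\t{ann.semantic_type.value}\t{ann.direction}\t{score}\n")
        else:
            for a, b in sorted(tuple(sorted(e)) for e in net.edges):
                ann = net.annotation(a, b)
                fh.write(f"{a}\t{ann.semantic_type.value}\t{b}\n")
            for node in sorted(net.nodes):
                if net.graph.degree(node) == 0:
                    fh.write(f"{node}\n")


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as a TSV with header."""
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_gene_list(genes: GeneSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in sorted(genes.genes):
            fh.write(g + "\n")


def write_gmt(coll: PathwayCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for s in coll.sets:
            fh.write("\t".join([s.name, coll.source or "na", *sorted(s.genes)]) + "\n")


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.df.to_csv(path, sep="\t", index_label="gene", lineterminator="\n")


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    clin.df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_maf(mut: MutationTable, path: str | Path) -> None:
    out = mut.df.rename(
        columns={
            "gene": "Hugo_Symbol",
            "sample": "Tumor_Sample_Barcode",
            "variant_classification": "Variant_Classification",
        }
    )
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")
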