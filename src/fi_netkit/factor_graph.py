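"""Simplified PARADIGM-style factor-graph pathway activity inference.

A pathway is modelled as a set of three-state entities (-1 = inactivated,
0 = baseline, +1 = activated), one per biological layer (genome, mRNA,
protein, activity) per gene, connected by signed regulatory links. Each
regulated entity gets a conditional factor: its *expected* state is the
sign-weighted majority vote of its regulators (0 on a tie) and the factor
assigns probability 1 - epsilon to the expected state, epsilon/2 to each
other state. Unregulated entities get a uniform prior.

Omic measurements enter as soft evidence on the matching layer; posteriors
come from loopy sum-product belief propagation (exact on trees). The
inferred pathway activity (IPA) of an entity compares the posterior with
evidence to the evidence-free posterior:

    IPA = log2 P(+1|E) / P(+1) - log2 P(-1|E) / P(-1)

so positive scores mean the evidence activates the entity. This engine is
deliberately minimal: factor parameters are user-set (no EM learning).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, normalize_symbol

log = logging.getLogger(__name__)

__all__ = [
    "Entity",
    "PathwayModel",
    "Factor",
    "FactorGraph",
    "read_pathway_model",
    "pathway_to_factor_graph",
    "loopy_bp",
    "BPResult",
    "ipa_score",
    "omics_evidence",
    "pathway_activity",
]

LAYERS = ("genome", "mrna", "protein", "activity")
STATES = (-1, 0, 1)
MAX_REGULATORS = 5


@dataclass(frozen=True)
class Entity:
    gene: str
    layer: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_symbol(self.gene))
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")

    @property
    def name(self) -> str:
        return f"{self.gene}:{self.layer}"


@dataclass
class PathwayModel:
    """Entities plus signed links (source, target, +1 activates / -1 inhibits)."""

    entities: list[Entity]
    links: list[tuple[Entity, Entity, int]]

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entities:
            if e in seen:
                raise ValueError(f"duplicate entity {e.name}")
            seen.add(e)
        for src, dst, sign in self.links:
            if sign not in (-1, 1):
                raise ValueError(f"link sign must be +-1, got {sign}")
            if src not in seen or dst not in seen:
                raise ValueError(f"link references unknown entity {src.name}->{dst.name}")
            if src == dst:
                raise ValueError(f"self-link on {src.name}")
        self._check_chains()

    def _check_chains(self) -> None:
        # within a gene, links must follow the central-dogma layer order
        order = {layer: i for i, layer in enumerate(LAYERS)}
        for src, dst, _ in self.links:
            if src.gene == dst.gene and order[src.layer] >= order[dst.layer]:
                raise ValueError(
                    f"within-gene link {src.name}->{dst.name} violates the "
                    "genome->mrna->protein->activity chain"
                )

    @classmethod
    def from_links(cls, links: list[tuple[str, str, int]]) -> "PathwayModel":
        """Build from (source, target, sign) strings 'GENE:layer'."""
        def parse(text: str) -> Entity:
            gene, _, layer = text.partition(":")
            return Entity(gene, layer or "activity")

        ents: dict[str, Entity] = {}
        parsed = []
        for s, t, sign in links:
            es, et = parse(s), parse(t)
            ents[es.name], ents[et.name] = es, et
            parsed.append((es, et, int(sign)))
        return cls(entities=list(ents.values()), links=parsed)

    @classmethod
    def central_dogma(cls, gene: str) -> list[tuple[Entity, Entity, int]]:
        """The genome->mRNA->protein->activity chain for one gene."""
        ents = [Entity(gene, layer) for layer in LAYERS]
        return [(a, b, 1) for a, b in zip(ents, ents[1:])]


def read_pathway_model(path: str) -> PathwayModel:
    """Read a pathway link list TSV: columns source, target, sign.

    Entity syntax ``GENE:layer`` with layer in genome/mrna/protein/activity
    (bare gene names mean the activity layer).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("source", "target", "sign"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing pathway model column {col!r}")
    links = [(r.source, r.target, int(r.sign)) for r in df.itertuples()]
    return PathwayModel.from_links(links)


@dataclass
class Factor:
    scope: tuple[str, ...]          # variable names, target last for CPD factors
    table: np.ndarray               # shape (3,) * len(scope), state order (-1, 0, +1)

    def __post_init__(self) -> None:
        if self.table.shape != (3,) * len(self.scope):
            raise ValueError("factor table shape does not match scope")
        if (self.table < 0).any() or self.table.sum() <= 0:
            raise ValueError("factor table must be non-negative with positive sum")


@dataclass
class FactorGraph:
    variables: list[str]
    factors: list[Factor]
    evidence: dict[str, np.ndarray] = field(default_factory=dict)

    def with_evidence(self, evidence: dict[str, np.ndarray]) -> "FactorGraph":
        ev = {}
        for var, dist in evidence.items():
            if var not in self.variables:
                raise KeyError(f"evidence on unknown variable {var}")
            arr = np.asarray(dist, dtype=float)
            if arr.shape != (3,) or (arr < 0).any() or arr.sum() <= 0:
                raise ValueError(f"evidence for {var} must be a non-negative 3-vector")
            ev[var] = arr / arr.sum()
        out = FactorGraph(self.variables, self.factors, dict(self.evidence))
        out.evidence.update(ev)
        return out


def _vote_state(reg_states: tuple[int, ...], signs: tuple[int, ...]) -> int:
    total = sum(s * st for s, st in zip(signs, reg_states))
    return (total > 0) - (total < 0)


def pathway_to_factor_graph(model: PathwayModel, epsilon: float = 0.1) -> FactorGraph:
    """Compile a pathway model into a factor graph over 3-state variables."""
    if not (0.0 < epsilon < 0.5):
        raise ValueError("epsilon must lie in (0, 0.5)")
    regulators: dict[Entity, list[tuple[Entity, int]]] = {e: [] for e in model.entities}
    for src, dst, sign in model.links:
        regulators[dst].append((src, sign))
    factors: list[Factor] = []
    for ent in model.entities:
        regs = sorted(regulators[ent], key=lambda r: r[0].name)
        if not regs:
            factors.append(Factor((ent.name,), np.full(3, 1.0 / 3.0)))
            continue
        if len(regs) > MAX_REGULATORS:
            raise ValueError(
                f"{ent.name} has {len(regs)} regulators; the factor-table guard "
                f"allows at most {MAX_REGULATORS}"
            )
        signs = tuple(s for _, s in regs)
        scope = tuple(r.name for r, _ in regs) + (ent.name,)
        table = np.empty((3,) * len(scope))
        for reg_states in itertools.product(STATES, repeat=len(regs)):
            expected = _vote_state(reg_states, signs)
            ridx = tuple(st + 1 for st in reg_states)
            for tstate in STATES:
                table[ridx + (tstate + 1,)] = (1.0 - epsilon) if tstate == expected else epsilon / 2.0
        factors.append(Factor(scope, table))
    return FactorGraph([e.name for e in model.entities], factors)


@dataclass
class BPResult:
    posteriors: dict[str, np.ndarray]
    converged: bool
    n_iter: int

    def __getitem__(self, var: str) -> np.ndarray:
        return self.posteriors[var]


def loopy_bp(
    fg: FactorGraph,
    max_iter: int = 200,
    tol: float = 1e-10,
    damping: float = 0.0,
) -> BPResult:
    """Sum-product belief propagation with a flooding schedule.

    Messages are normalised every step and damped as
    ``new = (1 - damping) * computed + damping * old``. On acyclic graphs
    the result equals exact marginalisation; on loopy graphs convergence is
    not guaranteed — a non-converged run returns the last iterate with a
    logged warning and ``converged=False``.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if not (0.0 <= damping < 1.0):
        raise ValueError("damping must lie in [0, 1)")
    factors = list(fg.factors)
    for var, dist in fg.evidence.items():
        factors.append(Factor((var,), np.asarray(dist, dtype=float)))
    var_factors: dict[str, list[int]] = {v: [] for v in fg.variables}
    for fi, f in enumerate(factors):
        for v in f.scope:
            var_factors[v].append(fi)
    uniform = np.full(3, 1.0 / 3.0)
    msg_vf = {(v, fi): uniform.copy() for v in fg.variables for fi in var_factors[v]}
    msg_fv = {(fi, v): uniform.copy() for fi, f in enumerate(factors) for v in f.scope}

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        delta = 0.0
        # factor -> variable
        new_fv = {}
        for fi, f in enumerate(factors):
            for pos, v in enumerate(f.scope):
                t = f.table
                for qpos, q in enumerate(f.scope):
                    if q == v and qpos == pos:
                        continue
                    shape = [1] * t.ndim
                    shape[qpos] = 3
                    t = t * msg_vf[(q, fi)].reshape(shape)
                axes = tuple(a for a in range(len(f.scope)) if a != pos)
                out = t.sum(axis=axes) if axes else t
                s = out.sum()
                out = out / s if s > 0 else uniform.copy()
                new_fv[(fi, v)] = (1.0 - damping) * out + damping * msg_fv[(fi, v)]
        for key, val in new_fv.items():
            delta = max(delta, float(np.abs(val - msg_fv[key]).max()))
            msg_fv[key] = val
        # variable -> factor
        new_vf = {}
        for v in fg.variables:
            incoming = {fi: msg_fv[(fi, v)] for fi in var_factors[v]}
            for fi in var_factors[v]:
                prod = uniform * 3.0
                for fj, msg in incoming.items():
                    if fj != fi:
                        prod = prod * msg
                s = prod.sum()
                prod = prod / s if s > 0 else uniform.copy()
                new_vf[(v, fi)] = (1.0 - damping) * prod + damping * msg_vf[(v, fi)]
        for key, val in new_vf.items():
            delta = max(delta, float(np.abs(val - msg_vf[key]).max()))
            msg_vf[key] = val
        if delta < tol:
            converged = True
            break
    if not converged:
        log.warning("loopy BP did not converge in %d iterations (last delta pass)", max_iter)

    posteriors = {}
    for v in fg.variables:
        prod = np.ones(3)
        for fi in var_factors[v]:
            prod = prod * msg_fv[(fi, v)]
        s = prod.sum()
        posteriors[v] = prod / s if s > 0 else uniform.copy()
    return BPResult(posteriors=posteriors, converged=converged, n_iter=it)


_FLOOR = 1e-6


def ipa_score(
    posterior_with: dict[str, np.ndarray],
    posterior_without: dict[str, np.ndarray],
) -> dict[str, float]:
    """Inferred pathway activity per entity (positive = activated).

    score = log2 P(+|E)/P(+|0) - log2 P(-|E)/P(-|0), probabilities floored
    at 1e-6; identically 0 when the two posteriors coincide.
    """
    out = {}
    for var, pw in posterior_with.items():
        po = posterior_without[var]
        plus = max(pw[2], _FLOOR) / max(po[2], _FLOOR)
        minus = max(pw[0], _FLOOR) / max(po[0], _FLOOR)
        out[var] = float(np.log2(plus) - np.log2(minus))
    return out


def omics_evidence(
    expr: ExpressionMatrix,
    sample: str,
    layer: str = "mrna",
    confidence: float = 0.9,
) -> dict[str, np.ndarray]:
    """Discretise one sample's omic profile into soft evidence.

    Per gene, the sample's value is ranked against that gene's distribution
    across samples: lower quartile -> state -1, upper quartile -> +1,
    middle -> 0, encoded as a soft distribution putting ``confidence`` on
    the chosen state.
    """
    if not (0.0 < confidence <= 1.0):
        raise ValueError("confidence must lie in (0, 1]")
    if sample not in expr.samples:
        raise KeyError(f"unknown sample {sample!r}")
    lo = expr.df.quantile(0.25, axis=1)
    hi = expr.df.quantile(0.75, axis=1)
    rest = (1.0 - confidence) / 2.0
    evidence = {}
    for gene in expr.genes:
        v = expr.df.at[gene, sample]
        state = -1 if v <= lo[gene] else (1 if v >= hi[gene] else 0)
        dist = np.full(3, rest)
        dist[state + 1] = confidence
        evidence[f"{gene}:{layer}"] = dist
    return evidence


def pathway_activity(
    model: PathwayModel,
    expr: ExpressionMatrix,
    cnv: ExpressionMatrix | None = None,
    epsilon: float = 0.1,
    damping: float = 0.5,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Per-sample IPA scores for every entity of a pathway model.

    Expression evidence attaches to the mRNA layer, copy-number evidence to
    the genome layer. Returns an entity x sample DataFrame.
    """
    fg = pathway_to_factor_graph(model, epsilon)
    base = loopy_bp(fg, max_iter=max_iter, tol=tol, damping=damping)
    model_vars = set(fg.variables)
    cols = {}
    for sample in expr.samples:
        evidence = {
            k: v for k, v in omics_evidence(expr, sample, "mrna").items() if k in model_vars
        }
        if cnv is not None and sample in cnv.samples:
            evidence.update(
                {k: v for k, v in omics_evidence(cnv, sample, "genome").items() if k in model_vars}
            )
        res = loopy_bp(fg.with_evidence(evidence), max_iter=max_iter, tol=tol, damping=damping)
        cols[sample] = ipa_score(res.posteriors, base.posteriors)
    return pd.DataFrame(cols).loc[[e.name for e in model.entities]]
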