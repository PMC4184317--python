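"""Module-based survival analysis.

For each network module, samples split into Group 1 (carrying a mutation in
at least one module gene) and Group 0 (no module gene mutated). Group
membership is then related to overall survival three ways:

* Kaplan-Meier product-limit curves per group;
* the two-sample log-rank test (chi-squared, 1 df);
* a univariate Cox proportional-hazards fit on the group indicator
  (Efron tie handling, Wald p-value), whose exp(coef) is the hazard ratio
  of Group 1 versus Group 0.

The module scan repeats this per module and controls the FDR across modules
by Benjamini-Hochberg on the CoxPH p-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from statsmodels.stats.multitest import multipletests

from .io import ClinicalTable, GeneSet, MutationTable
from .modules import ModuleAssignment

log = logging.getLogger(__name__)

__all__ = [
    "GroupLabels",
    "CoxResult",
    "split_samples",
    "km_curves",
    "km_logrank",
    "coxph_group",
    "module_survival_scan",
    "plot_km",
]


@dataclass
class GroupLabels:
    """0/1 mutation-status label per sample for one module."""

    labels: dict[str, int]
    module: int = -1
    dropped_samples: set[str] | None = None

    def group(self, which: int) -> set[str]:
        return {s for s, v in self.labels.items() if v == which}


@dataclass
class CoxResult:
    hazard_ratio: float
    p_value: float
    log_hr: float
    se: float
    converged: bool

    def __iter__(self):  # allows (hr, p) unpacking per the two-value contract
        return iter((self.hazard_ratio, self.p_value))


def split_samples(
    module_genes: GeneSet,
    mut: MutationTable,
    clin: ClinicalTable,
    drop_unmutated_samples: bool = False,
) -> GroupLabels:
    """Label clinical samples by module mutation status.

    A sample is Group 1 iff it carries >= 1 mutated gene belonging to the
    module. Samples present in the clinical table but absent from the
    mutation table count as Group 0 by default (no observed mutation); pass
    ``drop_unmutated_samples=True`` to restrict to samples present in both.
    Samples with mutations but no clinical record are dropped and reported.
    """
    clin_samples = clin.samples()
    mut_samples = mut.samples()
    shared = clin_samples & mut_samples
    if not shared:
        raise ValueError("no sample shared between mutation and clinical tables")
    population = shared if drop_unmutated_samples else clin_samples
    carriers = mut.carriers(module_genes.genes)
    labels = {s: int(s in carriers) for s in sorted(population)}
    dropped = mut_samples - clin_samples
    if dropped:
        log.info("%d mutated samples lack clinical data; dropped", len(dropped))
    return GroupLabels(labels=labels, dropped_samples=dropped)


def _group_frames(groups: GroupLabels, clin: ClinicalTable) -> pd.DataFrame:
    df = clin.df[clin.df["sample"].isin(groups.labels)].copy()
    df["group"] = df["sample"].map(groups.labels)
    return df


def km_curves(groups: GroupLabels, clin: ClinicalTable) -> dict[int, pd.DataFrame]:
    """Kaplan-Meier step-function table per group.

    Each table has columns time, at_risk, events, survival (the
    product-limit estimate just after ``time``).
    """
    df = _group_frames(groups, clin)
    out: dict[int, pd.DataFrame] = {}
    for grp, sub in df.groupby("group"):
        if len(sub) == 0:
            raise ValueError(f"group {grp} has no samples")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        ev = kmf.event_table
        table = pd.DataFrame(
            {
                "time": ev.index.to_numpy(dtype=float),
                "at_risk": ev["at_risk"].to_numpy(dtype=int),
                "events": ev["observed"].to_numpy(dtype=int),
                "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
            }
        )
        out[int(grp)] = table.reset_index(drop=True)
    return out


def km_logrank(groups: GroupLabels, clin: ClinicalTable) -> tuple[dict[int, pd.DataFrame], float]:
    """KM curves per group plus the two-sample log-rank p-value."""
    df = _group_frames(groups, clin)
    present = sorted(df["group"].unique())
    if present != [0, 1]:
        raise ValueError(f"need both groups present, got {present}")
    curves = km_curves(groups, clin)
    g0 = df[df["group"] == 0]
    g1 = df[df["group"] == 1]
    res = logrank_test(g0["time"], g1["time"], event_observed_A=g0["event"], event_observed_B=g1["event"])
    return curves, float(res.p_value)


def coxph_group(groups: GroupLabels, clin: ClinicalTable) -> CoxResult:
    """Univariate CoxPH fit of survival on the binary group indicator.

    Efron handling of tied event times; Wald p-value. Complete separation
    (monotone likelihood) yields a flagged result with an infinite hazard
    ratio rather than an exception.
    """
    df = _group_frames(groups, clin)[["time", "event", "group"]]
    if df["event"].sum() == 0:
        raise ValueError("no events observed; CoxPH undefined")
    if df["group"].nunique() < 2:
        raise ValueError("group indicator is constant")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError:
        sign = 1.0 if df.loc[df["group"] == 1, "event"].mean() >= df.loc[df["group"] == 0, "event"].mean() else -1.0
        return CoxResult(
            hazard_ratio=np.inf if sign > 0 else 0.0,
            p_value=1.0,
            log_hr=sign * np.inf,
            se=np.inf,
            converged=False,
        )
    row = cph.summary.loc["group"]
    # monotone likelihood (complete separation) shows up as an exploding
    # coefficient / standard error rather than an exception
    if abs(row["coef"]) > 15 or row["se(coef)"] > 100:
        return CoxResult(
            hazard_ratio=np.inf if row["coef"] > 0 else 0.0,
            p_value=1.0,
            log_hr=float(np.sign(row["coef"]) * np.inf),
            se=np.inf,
            converged=False,
        )
    return CoxResult(
        hazard_ratio=float(np.exp(row["coef"])),
        p_value=float(row["p"]),
        log_hr=float(row["coef"]),
        se=float(row["se(coef)"]),
        converged=True,
    )


def module_survival_scan(
    assign: ModuleAssignment,
    mut: MutationTable,
    clin: ClinicalTable,
    min_module_size: int = 3,
    drop_unmutated_samples: bool = False,
) -> pd.DataFrame:
    """Survival scan over all modules of at least ``min_module_size`` genes.

    Returns one row per testable module with columns module, size, n0, n1,
    hazard_ratio, coxph_p, logrank_p, fdr, sorted by ascending coxph_p;
    FDR is Benjamini-Hochberg across the scanned modules.
    """
    rows = []
    for idx, comm in enumerate(assign.modules()):
        if len(comm) < min_module_size:
            continue
        module = GeneSet(f"module_{idx}", frozenset(comm))
        groups = split_samples(module, mut, clin, drop_unmutated_samples)
        groups.module = idx
        n0, n1 = len(groups.group(0)), len(groups.group(1))
        if n0 == 0 or n1 == 0:
            log.warning("module %d: degenerate split (n0=%d, n1=%d); skipped", idx, n0, n1)
            continue
        _, lr_p = km_logrank(groups, clin)
        cox = coxph_group(groups, clin)
        rows.append(
            {
                "module": idx,
                "size": len(comm),
                "n0": n0,
                "n1": n1,
                "hazard_ratio": cox.hazard_ratio,
                "coxph_p": cox.p_value,
                "logrank_p": lr_p,
            }
        )
    if not rows:
        log.warning("no module passed min_module_size=%d; empty scan", min_module_size)
        return pd.DataFrame(
            columns=["module", "size", "n0", "n1", "hazard_ratio", "coxph_p", "logrank_p", "fdr"]
        )
    out = pd.DataFrame(rows)
    _, fdr, _, _ = multipletests(out["coxph_p"], method="fdr_bh")
    out["fdr"] = np.minimum(fdr, 1.0)
    return out.sort_values("coxph_p", kind="mergesort").reset_index(drop=True)


def plot_km(groups: GroupLabels, clin: ClinicalTable, path: str) -> None:
    """Write a two-group Kaplan-Meier plot (SVG/PNG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = _group_frames(groups, clin)
    fig, ax = plt.subplots(figsize=(5, 4))
    for grp, color in ((0, "crimson"), (1, "seagreen")):
        sub = df[df["group"] == grp]
        if len(sub) == 0:
            continue
        kmf = KaplanMeierFitter(label=f"Group {grp} (n={len(sub)})")
        kmf.fit(sub["time"], sub["event"])
        kmf.plot_survival_function(ax=ax, color=color)
    ax.set_xlabel("time")
    ax.set_ylabel("overall survival")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
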