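# fi-netkit

Pathway- and network-based analysis of gene lists, mutation tables,
expression matrices and clinical follow-up over a **functional interaction
(FI) network** — a headless toolkit for the workflow popularised by
Cytoscape-style FI analysis apps: project noisy high-throughput cancer data
onto a curated gene–gene interaction network, find densely connected gene
modules, and ask whether those modules are functionally coherent and
clinically meaningful.

It is written for computational biologists who have

* a pre-built FI network (tab-delimited edge list or SIF, with optional
  semantic annotations such as catalysis / activation / inhibition),
* a gene list, or a MAF-dialect mutation table (`Hugo_Symbol`,
  `Tumor_Sample_Barcode`, `Variant_Classification`),
* optionally a GMT pathway collection, a gene × sample expression TSV and a
  `sample / time / event` clinical table,

and want a reproducible, scriptable pipeline instead of a GUI.

## What it computes

**Subnetwork construction.** Genes mutated in ≥ *k* distinct samples (the
recurrence filter) induce an FI subnetwork; optional "linker" genes are
admitted greedily when they lie on many length-≤2 paths between
disconnected query components.

**Module discovery.** Newman leading-eigenvector spectral clustering of the
modularity matrix **B** = **A** − **k kᵀ**/2m with Kernighan–Lin
refinement, maximising

&nbsp;&nbsp;&nbsp;&nbsp;Q = (1/2m) Σᵢⱼ [Aᵢⱼ − kᵢkⱼ/2m] δ(cᵢ, cⱼ).

Deterministic: fixed eigenvector-sign convention, lexicographic tie-breaks,
modules numbered by decreasing size.

**Pathway enrichment.** For a query of n genes against a pathway of m genes
in a background of N, the exact one-sided binomial tail
p = P(X ≥ k), X ~ Bin(n, m/N), with Benjamini–Hochberg FDR across a GMT
collection; per-module functional annotation re-uses the same test.

**HotNet mutation analysis.** Gene heat = distinct-sample mutation count;
influence under the diffusion kernel M = exp(−tL) (or the regularised
inverse γ(γI + L)⁻¹); hot subnetworks are components of the graph joining
genes with min(Mᵢⱼ, Mⱼᵢ)·min(hᵢ, hⱼ) ≥ δ; significance of component counts
by uniform heat permutation with the add-one rule.

**Module-based survival.** Samples split into Group 1 (≥ 1 mutated module
gene) vs Group 0; Kaplan–Meier curves, the two-sample log-rank test, and a
univariate Cox proportional-hazards fit of the group indicator (Efron ties,
Wald p) per module, with BH-FDR across modules.

**Signature discovery.** FI edges re-weighted by |Pearson r| of expression,
Markov Clustering (expansion/inflation to a fixed point), and per-sample
module features (mean expression of each tight module).

**Factor-graph pathway activity (experimental).** A simplified
PARADIGM-style engine: 3-state entities per gene layer
(genome→mRNA→protein→activity), sign-weighted majority-vote factors, loopy
sum-product belief propagation, and signed inferred-pathway-activity (IPA)
scores against the evidence-free posterior.

A seeded synthetic-cohort generator (`fi_netkit.fixtures`) emulates every
input — planted network modules, recurrent mutations, exponential survival
with per-module hazard ratios, censoring, latent-factor co-expression — so
the whole pipeline runs and is tested without any download.

## Worked example

Generate a demo cohort (300 genes, 300 samples, three planted modules, one
protective with hazard ratio 0.4) and run the full workflow:

```bash
fi-netkit fixtures --seed 1 --out-dir demo_ex
cat > run.yaml <<EOF
network: demo_ex/fi.tsv
maf: demo_ex/demo.maf
clinical: demo_ex/clin.tsv
gmt: demo_ex/pathways.gmt
out_dir: demo_out
min_samples: 3
min_module_size: 5
seed: 11
EOF
fi-netkit run --config run.yaml
```

prints

```
pipeline complete; manifest: demo_out/manifest.json
  subnetwork_genes: 62
  subnetwork_edges: 170
  dropped_genes: 19
  n_modules: 3
  modularity_q: 0.6354498269896192
  best_survival_module: 2
  best_coxph_p: 2.2680298328054683e-13
```

62 recurrently mutated genes survive the ≥3-samples filter and induce a
subnetwork that clusters into 3 modules (Q ≈ 0.64). The survival scan
(`demo_out/survival.tsv`) ranks module 2 first:

```
module  size  n0   n1   hazard_ratio  coxph_p   logrank_p  fdr
2       15    194  106  0.325         2.27e-13  3.42e-14   6.80e-13
0       15    170  130  0.943         0.650     0.650      0.762
1       15    179  121  1.041         0.762     0.762      0.762
```

Module 2 is the planted protective module: its 106 carriers have about a
third of the baseline hazard (true simulated value 0.4), and the pathway
annotation table (`demo_out/enrichment.tsv`) puts the matching planted gene
set at the top of that module with p ≈ 8.7 × 10⁻¹⁵. The two null modules
show hazard ratios near 1 and large p-values, as they should.

Every stage is also available as its own subcommand (`subnetwork`,
`cluster`, `enrich`, `hotnet`, `survival`, `signature`, `paradigm`);
`fi-netkit run` writes a `manifest.json` with input checksums, parameters
and the seed so a run can be audited and exactly repeated.

## Layout

```
src/fi_netkit/   io, subnetwork, modules, enrichment, hotnet, survival,
                 signature, factor_graph, fixtures, pipeline, cli
tests/           pytest suite (unit, property and acceptance tests)
docs/methods.md  models, parameters, numerical choices, limitations
```
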