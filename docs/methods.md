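# Methods

This note documents the models and procedures implemented in fi-netkit,
the defaults and why they were chosen, the numerical conventions that make
runs reproducible, what the synthetic cohorts do and do not emulate, and
the known limitations.

## Input model

All analyses run over an undirected FI network on uppercase gene symbols.
Edges may carry a semantic type (catalysis, activation, inhibition,
expression regulation, complex membership, predicted, unknown), a direction
glyph (`->`, `-|`, `-`, `<-`, `|-`) and a confidence score in [0, 1].
Duplicate edges merge keeping the highest-scored record. Symbols are
uppercased at ingest and never alias-resolved; identifier mapping is out of
scope and should happen upstream.

MAF ingestion keeps one record per (gene, sample, variant class) row and by
default drops `Silent`, `Intron`, `3'UTR`, `5'UTR`, `IGR` and `RNA`
variants — the usual restriction to candidate functional mutations. The
excluded list is configurable because annotation pipelines differ. Sample
barcodes are truncated to 12 characters (the TCGA participant prefix) so
mutation and clinical tables join on the same id; set
`barcode_length=None` to keep full barcodes.

## Subnetwork construction

The recurrence filter keeps genes mutated in at least `min_samples`
*distinct* samples (a gene hit twice in one tumour counts once); the
default of 3 matches common practice for cohort-scale mutation data. The
subnetwork is the exact induced subgraph on the retained genes; isolated
query genes are removed but reported, never silently dropped.

Linker mode is a greedy Steiner-style heuristic: among non-query genes,
repeatedly admit the one lying on the most length-≤2 shortest paths between
currently disconnected query components (ties broken lexicographically),
stopping when no candidate touches two components. Every admitted linker
therefore has degree ≥ 2 in the result. This is a declared, deterministic
rule — minimal Steiner trees are NP-hard and unnecessary here.

## Module discovery

Clustering is Newman's leading-eigenvector method on the modularity matrix
B = A − k kᵀ/2m, recursively bipartitioning along the sign of the leading
eigenvector of the generalized matrix B⁽ᵍ⁾ (with the diagonal correction
for subdivided groups), refined by a Kernighan–Lin sweep of single-gene
flips, and stopping when a split's modularity gain is ≤ 0. Three
conventions make output bit-stable:

* eigenvectors are oriented so the lexicographically smallest gene with a
  non-zero entry gets a positive value;
* all tie-breaks (KL move order, equal gains) go to the lexicographically
  smallest gene;
* final modules are numbered by decreasing size, ties by smallest member,
  so module 0 is always the largest.

Disconnected subnetworks are clustered per component with indices assigned
globally afterwards. Modularity is always the unweighted Newman Q; the
reported Q is recomputed from the returned partition, not carried through
the recursion. The display filter hides modules below 3 genes by default —
smaller modules rarely support enrichment or survival contrasts.

## Binomial enrichment

For n query genes, a pathway of m genes and a background of N genes with
overlap k, p = P(X ≥ k) for X ~ Binomial(n, m/N), enrichment-sided only.
The tail is an explicit term sum: the seed term comes from log-gamma and
subsequent terms from the ratio recurrence; when k lies at or below the
mean the complementary lower tail is summed instead (descending from its
largest term) so neither branch loses mass to underflow. The sum matches
the reference survival function to 1e-12 across n up to several hundred.

The default background is the FI network's gene count — the self-contained
analogue of "pathway-annotated genome". FDR is Benjamini–Hochberg; for
per-module annotation it is computed within each module, since each module
is a separate question asked of the same collection. Because the binomial
model treats genes as i.i.d. draws, the test is conservative under the
null (empirical P(p ≤ 0.05) ≈ 0.02 in our calibration), which is the safe
direction for annotation.

## HotNet heat diffusion

Default heat is the distinct-sample mutation count. Two kernels are
implemented per connected component (cross-component influence is exactly
zero): the diffusion kernel M = exp(−tL) with L = D − A, and the
regularised inverse M = γ(γI + L)⁻¹. Default t = 0.1 — small enough that
heat stays local on typical FI degree distributions. t = 0 is accepted as
the degenerate no-diffusion limit (M = I); the inverse kernel requires
γ > 0. On a connected graph the diffusion kernel's columns sum to one
(heat conservation), which the tests check to 1e-10.

The hot graph joins genes i, j when min(Mᵢⱼ, Mⱼᵢ) · min(hᵢ, hⱼ) ≥ δ; the
min-symmetrisation means both genes must influence each other and both
must be hot, so a single hub cannot drag a cold neighbourhood in.
Components of size ≥ 2 are reported, plus singletons with heat ≥ 2 by
default. Raising δ refines components monotonically.

Significance: heats are reassigned to network nodes by uniform
permutation; the statistic is the number of components of size ≥ s, and
p(s) = (1 + #{perm ≥ obs}) / (1 + n_perm), never zero by construction.
Permutation preserves the heat distribution but destroys its placement,
which is the null of interest (mutations land without regard to network
position). Because the statistic is a small integer count, p-values are
discrete and the test is conservative; calibration fixtures need enough
network for the count to spread (the acceptance fixture uses a 200-node
graph where the null count has ~8 achievable values). `auto_delta` scans
the distinct pairwise scores for the smallest δ whose largest null
component stays below s in ≥ 95% of permutations.

## Module-based survival

For each module, Group 1 = samples carrying ≥ 1 mutated module gene,
Group 0 = the rest. Clinical samples absent from the MAF count as Group 0
by default (no observed mutation ≠ missing data in a sequenced cohort);
`drop_unmutated_samples=True` restricts to samples present in both tables.
Mutated samples without clinical follow-up are dropped and reported.

Per module we fit a univariate Cox proportional-hazards model on the group
indicator (Efron tie handling — the modern default and the better
approximation with many ties — Wald p-value), plus Kaplan–Meier curves
and the two-sample log-rank test. Monotone likelihood (complete
separation) is detected post-fit by an exploding coefficient/standard
error and returned as a flagged result with an infinite (or zero) hazard
ratio rather than an exception, so a scan never dies on one degenerate
module. The scan reports one row per module of ≥ `min_module_size` genes,
BH-FDR across the scanned modules' CoxPH p-values, sorted ascending.

On large two-group cohorts the Wald and log-rank p-values agree closely
(the tests require |Δp| < 0.01 at n = 1000), a standard asymptotic
identity that doubles as a cross-check between the two code paths
(lifelines' Cox fit vs the log-rank statistic).

## Signature discovery

Edges are weighted by |Pearson r| of the two genes' expression across
samples (≥ 3 samples required; zero-variance genes drop their edges with a
warning). Absolute correlation is the default because mutual exclusion is
as much evidence of functional coupling as co-activation; a signed variant
keeps max(r, 0).

MCL runs on the column-stochastic matrix with self-loops set to each
node's maximum incident weight (1 for isolated nodes): expansion (matrix
square), inflation (entrywise power, default 2.0), pruning below 1e-5,
column renormalisation, iterated until the matrix changes by < 1e-8.
Clusters are read off attractor rows of the limit matrix with overlapping
attractor systems merged, giving a hard partition. Modules pass to the
feature stage if they have ≥ 5 measured genes and mean pairwise |r| ≥ 0.25
over *all* within-module pairs (not only edges — the stricter and less
topology-dependent choice); the feature is the per-sample mean expression
of the module's genes.

## Factor-graph pathway activity

Each gene contributes up to four 3-state entities (−1 inactivated, 0
baseline, +1 activated) along the genome→mRNA→protein→activity chain;
signed links connect entities within and between genes. A regulated
entity's factor puts probability 1−ε on the sign-weighted majority vote of
its regulators (0 on ties) and ε/2 elsewhere; unregulated entities get a
uniform prior. ε defaults to 0.1 and is user-set — there is no EM
learning, by design: this engine is a minimal, testable core, and learned
factor tables would not be identifiable from the small inputs it targets.
A guard rejects entities with more than 5 regulators (3⁶-entry tables).

Inference is loopy sum-product with a flooding schedule, message
normalisation, and damped updates (damping 0.5 by default on cyclic
graphs); on trees it reproduces exact enumeration to 1e-8. Omic evidence
is discretised per gene by rank: lower quartile → −1, upper quartile → +1,
middle → 0, encoded as soft evidence with confidence 0.9 (expression
attaches to the mRNA layer, copy number to the genome layer). The IPA
score log₂[P₊(E)/P₊(∅)] − log₂[P₋(E)/P₋(∅)] (probabilities floored at
1e-6) is zero exactly when evidence leaves the posterior unchanged.

## Synthetic cohorts

The generators emulate a TCGA-style cohort: planted gene modules as dense
blocks (within-module edge probability 0.8) on a sparse background (edge
probability 4/n); per-sample Bernoulli mutations at a module-specific rate
against a low background rate, with ~10% of records Silent to exercise the
variant filter; exponential survival with baseline rate 1 where carrying a
module's functional mutation multiplies the hazard by that module's
hazard ratio, and independent censoring replacing the event with a
uniform fraction of the event time at the target censoring probability;
and latent-factor expression blocks x = √ρ·f + √(1−ρ)·ε giving pairwise
correlation ρ in expectation. Every generator is a pure function of its
spec (seed included) — repeated calls are byte-identical.

The default demo cohort is 300 genes × 300 samples with three planted
modules (mutation rate 0.05 per gene per sample, one module protective
with hazard ratio 0.4, censoring 0.2) — qualitatively the scale at which
a recurrence filter of ≥ 3 samples keeps tens of genes and a protective
module of ~100 carriers is detectable. These cohorts deliberately do not
emulate realistic mutation spectra, gene-length effects, barcode semantics
beyond the 12-character prefix, or covariate-confounded survival; passing
tests therefore demonstrate correctness and power of the machinery under
the stated generative model, not performance on real tumour data.

## Problem sizes used in the checks

The self-checks run at sizes chosen to make each property measurable while
keeping the whole suite quick: exhaustive modularity enumeration on graphs
of ≤ 10 nodes (partitions into ≤ 4 blocks), diffusion-kernel series checks
on ≤ 8 nodes, BP-vs-enumeration on trees of ≤ 12 variables, hazard-ratio
recovery at n = 1000 with 20% censoring, scan power over 50 seeded
cohorts of 250 samples, and null calibrations at 1000 simulations
(binomial and HotNet permutation, n_perm = 100 each).

## Known limitations

* No identifier mapping or network-version management: the toolkit
  consumes one pre-built FI network as given.
* Enrichment is binomial-only (no hypergeometric or rank-based variants)
  and one-sided; depletion is not tested.
* HotNet here is the first-generation formulation; the insulated-diffusion
  Markov variant and two-stage FDR machinery are not implemented.
* Survival is univariate overall survival; no clinical covariates,
  competing risks or time-dependent effects.
* The factor-graph engine fixes factor tables from ε; it does not learn
  parameters and its per-sample significance is not permutation-calibrated.
* Dense linear algebra throughout (eigendecompositions, matrix
  exponentials): comfortable to a few thousand subnetwork genes, not meant
  for whole-interactome kernels.
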