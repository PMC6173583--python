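# cordnet

Systems-level analysis of the spinal cord injury (SCI) transcriptome:
signed gene coexpression networks, interactome-based validation of a
literature-curated gene set, module preservation across datasets,
module-level differential-expression meta-analysis, severity scoring, and
hub-gene biomarker nomination — together with a synthetic-data generator
that plants all of this structure so the entire pipeline can be exercised
and verified end to end without any external download.

## Who this is for

Researchers integrating heterogeneous SCI (or other CNS injury)
expression studies at the level of coexpression modules rather than
single genes, and anyone who needs a tested, self-contained
reimplementation of this analysis stack: WGCNA-style signed networks,
degree-preserving interactome nulls, DIAMOnD seed-gene recovery,
permutation Zsummary preservation, mean-rank gene-set meta-analysis and
LDA biomarker evaluation.

## The model and statistics

**Coexpression network.** Genes are correlated with the biweight
midcorrelation (at most 5% of samples per side of the median treated as
outliers), transformed to a signed adjacency

    a_ij = ((1 + cor_ij) / 2)^beta,

with `beta` the smallest exponent for which the connectivity distribution
satisfies the approximate scale-free criterion (signed fit R² > 0.8).
Adjacency is converted to the topological overlap matrix

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

and modules are branches of the average-linkage dendrogram of `1 − TOM`
found by an adaptive top-down cut (minimum module size 20), merged when
their eigengenes — each module's first principal component — are closer
than 0.2 in correlation dissimilarity. A gene's kME is its correlation
with a module eigengene; hubs are the top decile of kME.

**Validation against the interactome.** A gene set's internal edge count
and largest connected component (LCC) are compared with 1000
degree-preserving rewired networks; the empirical p-value uses the
add-one estimator `p = (1 + #{null ≥ obs}) / (1 + N)`, so 1000 nulls
bound p at ~1e-3. Co-complex clustering and shared-GO-term enrichment use
random gene sets of equal size. DIAMOnD iteratively adds the node with
the most significant hypergeometric connectivity to the seed set; seed
recovery withholds 20% of the gene set and measures how early the
withheld genes are re-found versus a random control
(Kolmogorov–Smirnov test).

**Preservation.** With reference module labels fixed, density statistics
(mean intra-module correlation and adjacency, eigengene variance
explained, mean kME) and connectivity statistics (reference–test
correlations of intramodular connectivity, kME, and the correlation
structure itself) are standardized against label permutations;
`Zsummary = (median Z_density + median Z_connectivity)/2`, with > 10
strong, > 5 moderate and < 2 no evidence of preservation. A Spearman
variant serves proteomic data.

**Meta-analysis and severity.** Per study, genes are ranked by a
two-sample t statistic (injured vs sham); each module is tested for
coordinated up- and downregulation by a mean-rank (Wilcoxon rank-sum)
gene-set test, Bonferroni-corrected over modules × 2 directions. Modules
significant in the same direction in all studies are consensus modules
(all but one: majority). Severity analyses score each gene as
`s = ρ · (−log10 p)` from the Spearman correlation of expression with
injury severity (0/100/200 kdyn), test modules for enrichment of
positive/negative scores, and correlate module eigengenes with severity.
Hub genes are evaluated as biomarkers with two-class linear discriminant
analysis (pooled covariance, equal priors) under leave-one-out
cross-validation.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data with planted structure (five modules among 1000 genes; 71-sample
reference; five injured/sham studies):

```bash
python analysis/01_simulate.py            # data -> scratch/synthetic/
python analysis/02_curate_and_validate.py
python analysis/03_coexpression_modules.py
python analysis/04_preservation.py
python analysis/05_meta_analysis.py
python analysis/06_severity_biomarkers.py
```

Representative output (seed 1), with result tables under `results/`:

```
curation summary: {'unique_genes': 120, 'n_up': 97, 'n_down': 49, 'n_phospho': 0, 'n_multi_study': 39}
PPI enrichment: observed 183, null mean 78.6, p = 9.99e-04
LCC: observed 91, null mean 60.1, p = 9.99e-04
DIAMOnD recovery at 200 iterations: 0.68 vs control 0.23 (KS 0.56, p = 1.43e-175)
soft threshold beta = 8 (scale-free criterion satisfied: False)
module sizes: {1: 65, 2: 53, 3: 50, 4: 41, 5: 40}
adjusted Rand index vs planted modules: 0.970
modules enriched for curated genes (Bonferroni p < 0.05): [1, 3]
removal breakdown fractions for enriched modules: {1: 0.8, 3: 0.8}
all planted modules strongly preserved (Z > 10): True
random gene set Zsummary: 0.43 (none)
consensus modules reversed under treatment: 4/4
acute/chronic sign-flip flags: {1: False, 2: False, 3: False, 4: False, 5: True}
modules enriched for severity-correlated genes: [1]; anticorrelated: [2]
strongest eigengene-severity correlation: module 1 (rho = 0.91, p = 2.2e-23)
module 1 hubs (6 genes): 6 with accuracy >= 0.9; top hub accuracy 1.00; combined model 1.00
hubness vs biomarker accuracy: Spearman rho = 0.44, p = 3.7e-04
```

Reading this: the parsed curated table reproduces the generator's ground
truth exactly; the curated set is densely wired in the interactome and
preferentially recovered by DIAMOnD; the network build recovers the
planted modules almost perfectly and finds the curated set enriched in
exactly the two seeded modules, robust to removing up to 80% of seed
genes; all planted modules are strongly preserved in independent studies
while a random gene set is not; the consensus injury signature reverses
under a normalizing treatment; one module flips from acutely
downregulated to chronically upregulated; severity signal localizes to
the single planted module, whose hub genes stratify moderate vs severe
injury perfectly and whose hubness predicts per-gene biomarker accuracy.

A CLI mirrors the scripts for ad-hoc use
(`cordnet simulate | coexpress | network-validate | preserve | meta |
severity | reversal | biomarkers`; see `cordnet --help`).

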