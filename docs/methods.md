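# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the known limitations of the package. Everything stated here
is computed by the test suite, the analysis scripts or
`scripts/acceptance.py`; nothing is quoted from elsewhere.

## The synthetic study

The generator (`cordnet.simulate`) emulates the inputs of an integrative
SCI analysis so the pipeline can be verified against a known ground
truth. Coexpression follows a single-latent-factor model per module:

    x_gs = λ_g · e_{m(g),s} + ε_gs,    ε_gs ~ N(0, σ²)

with one standard-normal eigengene `e_m` per module and sample.
Per-gene loadings are `λ_g = module_signal · U(0.6, 1.0)` for module
genes and 0 for background. The uniform loading gradient matters: with
constant loadings every module gene is equally discriminative, making
hub selection and the hubness–accuracy relationship degenerate; the
gradient gives kME a real ordering to recover.

Defaults are the study conditions used throughout tests and acceptance:
1000 genes; module sizes (60, 50, 50, 40, 40); `module_signal = 0.9`,
`σ = 0.2`; a 71-sample healthy reference cohort; five test studies of 20
samples alternating sham/injured; severity levels 0/100/200 (kdyn of
impact force, sham = 0); time points 1/3/7/28 days. Injury shifts the
module-m eigengene of an injured sample by
`de_effect[m] · severity/max(severity)` — severity acts linearly on the
eigengene mean, matching a monotone severity–expression relationship
without inventing curvature. The default effect pattern is (+2, −2, +2,
+2) for modules 1–4; module 5 is the acute/chronic flip module: its
effect is −flip_effect at the earliest time point, +flip_effect at the
latest, 0 in between, so it averages to no net consensus effect while
flipping sign over time.

The curated gene set holds 120 genes: 70% sampled from the two target
modules (1 and 3), 30% uniform false positives. Curation records carry
synthetic study ids, directions (up/down/phospho at roughly 72/27/1%),
techniques, models, species and time points; non-human records use
species-prefixed accessions resolvable through seven synthetic ortholog
databases (each present for a given id with probability 0.85, error rate
0 by default, configurable). The interactome is a configuration-model
graph with Pareto-tailed degrees (exponent 2.5, minimum degree 1) whose
curated true positives are additionally wired to a planted density.
Annotations comprise GO-like terms in three categories across three
breadth classes (5–15, 16–60, 61–200 genes/term), half of them
module-concordant; protein complexes of size 2–8 enriched for curated
true positives; and lognormal cell-type profiles in which one cell type
over-expresses the marker module's genes 8-fold.

Each output object draws from its own RNG stream spawned from
`rng_seed`, so generating one output never perturbs another and a seed
fully determines the study.

Two generator design choices deserve emphasis:

- **Planted interactome density.** The default planted density is 0.2 of
  all within-set pairs, but the interactome analyses use 0.05. At the
  simulated graph size (1000 nodes, mean background degree ≈ 3), density
  0.2 would give every planted gene degree ≈ 11 — the planted set would
  *be* the network's hubs, and degree-preserving nulls would reconnect it
  almost as densely as the original graph, making the LCC statistic
  uninformative. Density 0.05 keeps planted degrees on the scale of the
  background distribution, which is the regime the LCC test is designed
  for.
- **Exclusive severity coupling.** In the severity cohort
  (`severity_exclusive=True`) the eigengenes of modules planted as
  non-responsive are residualized against the severity covariate. Without
  this, a null module's *chance* eigengene–severity correlation (of
  order 1/√n) is inherited coherently by all its genes, and the
  mean-rank test — whose effective sample size for a coherent shift is
  the number of samples, not the number of genes — flags it regardless of
  cohort size. Residualizing makes "only the designated module tracks
  severity" a well-defined planted truth. The flag is off by default so
  null-calibration properties are unaffected.

### What the generator does not emulate

Count noise (negative binomial), batch effects, probe-level microarray
artifacts, platform-specific gene coverage, and correlated measurement
error are all absent. Passing tests therefore demonstrate that the
pipeline recovers the structures it targets under a clean factor model —
not that it is robust to real-data artifacts, which the out-of-scope
normalization/batch tools (e.g. ComBat) address upstream. Per-study gene
centering is available in `ingest` as a declared, simpler stand-in, off
by default.

## Preprocessing

Expression filtering keeps genes above 0.1 (strictly) in at least 10
samples. Sample quantile normalization maps each sample onto the average
empirical distribution; ties receive the mean of their target quantiles.
The per-gene inverse normal transform uses `Φ⁻¹((rank − 0.5)/n)` with
mid-ranks: the offset is symmetric and avoids infinities. Cross-sample
ties introduced by quantile normalization mean the transformed rows are
standardized only up to mid-rank effects (tested at a 0.05 tolerance;
exact for tie-free data). Ortholog mapping accepts a human gene only if
at least half of the databases carrying an entry for the source id agree
(`⌈|D|/2⌉`); two genes both reaching the bar is ambiguous and maps to
nothing — conservative, logged.

## Network construction

Biweight midcorrelation follows the standard weighting
`u = (x − med)/(9·MAD)`, `w = (1 − u²)² · 1[|u| < 1]`, with the
denominator inflated per side so that at most 5% of samples on either
side of the median receive zero weight; rows with zero MAD fall back to
Pearson (per-row fallback; constant rows correlate 0). The soft
threshold scans β = 1..20 and fits log10 p(k) against log10 k over 10
equal-width connectivity bins (empty bins dropped), sign-adjusted so a
positive slope counts negative; the smallest β with fit > 0.8 wins, else
the best-fitting β is used and flagged. On the synthetic factor-model
data the criterion is typically not reached (the planted connectivity
distribution is bimodal rather than scale-free), so the flagged maximum
— β ≈ 8–11 — is used; module recovery is insensitive to this choice
(ARI ≥ 0.95 across seeds).

Module detection is an adaptive top-down cut of the average-linkage
dendrogram of `1 − TOM`: descending from the root, a branch with at
least `min_size` leaves is accepted as a module when its mean
within-branch dissimilarity falls below `cohesion` (default 0.4) times
the background level, estimated as the 75th percentile of all pairwise
dissimilarities; otherwise its children are examined. Accepted branches
are trimmed by returning members whose mean dissimilarity to the rest of
the branch exceeds the same threshold. This variant is fully determined
by the dendrogram and two interpretable parameters, assigns homogeneous
noise entirely to the background (label 0), and recovers planted
partitions with ARI 0.95–1.0. The background-quantile yardstick was
chosen over the mean because most genes may belong to modules in small
designed datasets, which deflates the mean. Eigengene signs are fixed by
non-negative mean member correlation (ties break positive); merging
iteratively joins the closest eigengene pair below cut height 0.2 and
recomputes.

## Preservation

The seven observed statistics are split into a density class (mean
intra-module correlation, mean signed adjacency at the reference β,
eigengene variance explained, mean kME) and a connectivity class
(reference–test correlations of intramodular connectivity, of kME, and
of the vectorized intra-module correlation matrix). The permutation null
reassigns module labels uniformly (sizes preserved) in both datasets,
keeping the expression correlation structure intact; 100 permutations by
default. `Zsummary` is the mean of the two class medians; a statistic
with zero permutation spread is dropped from its median. In the pure
factor model the connectivity statistics carry little signal (within a
module all pairwise correlations are equal up to noise, so there is no
heterogeneity to preserve); planted-module Zsummary values of 20–35 are
driven by the density class, and random gene sets land within ±2.
Spearman mode rank-transforms both matrices first and is intended for
proteomic data.

## Meta-analysis, severity and biomarkers

The mean-rank set test is a Wilcoxon rank-sum of the module genes'
statistics against all other genes: exact enumeration when both sides
have ≤ 10 untied values, otherwise the tie-corrected normal
approximation with continuity correction. Plain (unmoderated) t
statistics rank the genes; the set test consumes ranks, which
empirical-Bayes moderation would perturb only marginally — a declared
divergence from moderated pipelines. Bonferroni families are modules × 2
directions within each study; calls require adjusted p < 0.05.

One property of competitive set tests matters for interpretation: under
inter-gene correlation they are anti-conservative. A *coexpressed*
module with no planted effect is falsely called within a single study
~58% of the time (measured over 40 replicates), because a chance
factor–contrast correlation shifts all member genes coherently — with
independent genes the p-values are uniform (tested). The pipeline's
specificity comes from the consensus rule: chance calls do not replicate
in direction across five studies (measured consensus false-call rate
≈ 0.4%). This mirrors how the analysis is meant to be read: per-study
module p-values are evidence to be combined, not standalone tests.

Severity scores use base-10 logs (`s = ρ · (−log10 p)`); the module
ranking is invariant to the base. Temporal profiles stratify each study
by time point (strata with fewer than two samples per arm are skipped,
logged) and flag modules whose earliest and latest consensus/majority
directions have opposite signs. Reversal tests run the
treated-vs-control contrast per consensus module with the alternative
fixed opposite to the consensus direction, plus a one-tailed Wilcoxon on
the module eigengene's sample scores.

The specificity index is a rank-mean approximation: SI(g, c) is the mean
over other cell types of the rank of `log2((e_gc + ε)/(e_gc′ + ε))`
(ε = 1 pseudocount, configurable) among all genes, normalized to (0, 1];
pSI shuffles gene labels independently within each pairwise comparison
(1000 permutations by default). Exact numerical replication of published
specificity-index software is not attempted. LDA uses pooled covariance
and equal priors (group sizes are balanced by design, n = 5/group in the
biomarker cohort); the scikit-learn SVD solver handles singular
covariance. Sham samples are excluded from moderate-vs-severe
classification.

## Null-distribution conventions

Empirical p-values use the add-one (Davison–Hinkley) estimator
throughout, bounded in `[1/(N+1), 1]` — never zero. On discrete
statistics (edge counts, LCC sizes, co-complex pairs, Fisher tables)
ties between observed and null values make this estimator conservative,
so its raw distribution under the null is super-uniform by construction.
Calibration tests therefore check two things: exact uniformity of the
tie-randomized transform of the same null ensembles (which isolates the
exchangeability of the null from the discreteness of the estimator), and
conservative validity of the reported p (rejection rate ≤ nominal). The
continuous mean-rank p is checked for literal uniformity. Degree
preservation under rewiring is exact; edge-presence frequencies over
many rewirings match the exactly enumerated uniform ensemble of simple
graphs with the same degree sequence (a stronger oracle than the
configuration-model formula `d_i d_j / 2|E|`, which is biased on small
dense graphs).

## Problem sizes

Tests and the acceptance script run the full conditions where feasible
(1000 genes, 71 + 5×20 samples, 100 permutations) and scale down only
the pure Monte-Carlo layers: calibration uses 200 replicates with 99
nulls each on 60-node graphs; DIAMOnD recovery uses 200 iterations and
20–50 bootstraps on the 1000-node interactome; interactome enrichment in
the acceptance script uses 200 rewired networks (the analysis scripts
use the full 1000). These sizes were chosen so each stage completes in
seconds to a couple of minutes on a single CPU while keeping every
statistical conclusion at its stated threshold.

## Known limitations

- The dynamic branch cut is a documented variant, not a re-implementation
  of published tree-cut software; on real data module counts and
  boundaries may differ from analyses run with that software (no PAM-like
  reassignment stage is included).
- The factor model gives modules with homogeneous internal correlation,
  which under-exercises the connectivity class of preservation
  statistics and makes competitive set tests maximally anti-conservative
  per study (see above).
- Empirical-Bayes moderation, batch correction, and probe-level
  normalization are out of scope; inputs are assumed preprocessed to a
  genes × samples matrix.
- The ortholog vote treats databases as exchangeable and ignores
  paralogy structure beyond the one-to-many mapping sets.
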