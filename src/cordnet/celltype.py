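"""Cell-type specificity of modules and hub-gene biomarker evaluation.

A rank-based specificity index marks genes preferentially expressed in
one cell population relative to the others; per-gene permutation
p-values (pSI) define marker sets at nested thresholds, which are tested
for overlap with coexpression modules by Fisher's exact test.  Module hub
genes (top decile of kME) are evaluated as severity biomarkers with
two-class linear discriminant analysis under leave-one-out
cross-validation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .containers import CellTypeProfile, ExpressionStudy, ModulePartition
from .differential import bonferroni

log = logging.getLogger(__name__)


@dataclass
class SpecificityResult:
    si: pd.DataFrame  # genes x cell types, mean normalized rank (0..1], lower = more specific
    p_si: pd.DataFrame  # genes x cell types, permutation p
    n_permutations: int


def _pairwise_ranks(profiles: np.ndarray, eps: float) -> np.ndarray:
    """ranks[c, c', g]: rank of gene g's log2 fold ratio of cell type c over
    c' among all genes (rank 1 = most enriched in c)."""
    n_genes, n_ct = profiles.shape
    ranks = np.zeros((n_ct, n_ct, n_genes))
    for c in range(n_ct):
        for c2 in range(n_ct):
            if c2 == c:
                continue
            ratio = np.log2((profiles[:, c] + eps) / (profiles[:, c2] + eps))
            # descending: the largest ratio gets rank 1
            ranks[c, c2] = stats.rankdata(-ratio, method="average")
    return ranks


def specificity_index(
    profiles: CellTypeProfile,
    eps: float = 1.0,
    n_permutations: int = 1000,
    rng_seed: int = 0,
) -> SpecificityResult:
    """Rank-based specificity index with permutation p-values.

    SI(g, c) is the mean over the other cell types c' of the rank of
    ``log2((expr_gc + eps)/(expr_gc' + eps))`` among all genes (rank 1 =
    most enriched), normalized by the gene count so values lie in (0, 1].
    The permutation null shuffles gene labels independently within each
    pairwise comparison; pSI is the add-one fraction of permuted SI values
    at least as specific (small) as the observed one.
    """
    x = profiles.profiles.to_numpy(dtype=float)
    n_genes, n_ct = x.shape
    if n_ct < 2:
        raise ValueError("need >= 2 cell types")
    rng = np.random.default_rng(rng_seed)
    ranks = _pairwise_ranks(x, eps)
    others = {c: [c2 for c2 in range(n_ct) if c2 != c] for c in range(n_ct)}
    si = np.stack([ranks[c, others[c]].mean(axis=0) for c in range(n_ct)], axis=1)
    si /= n_genes

    exceed = np.zeros_like(si)
    for _ in range(n_permutations):
        perm_si = np.zeros((n_genes, n_ct))
        for c in range(n_ct):
            acc = np.zeros(n_genes)
            for c2 in others[c]:
                acc += ranks[c, c2][rng.permutation(n_genes)]
            perm_si[:, c] = acc / len(others[c]) / n_genes
        exceed += perm_si <= si
    p = (1.0 + exceed) / (1.0 + n_permutations)
    idx, cols = profiles.profiles.index, profiles.profiles.columns
    return SpecificityResult(
        pd.DataFrame(si, index=idx, columns=cols),
        pd.DataFrame(p, index=idx, columns=cols),
        n_permutations,
    )


def celltype_module_enrichment(
    partition: ModulePartition,
    specificity: SpecificityResult,
    thresholds=(0.05, 0.01, 0.001, 0.0001),
) -> pd.DataFrame:
    """Fisher enrichment of pSI-defined marker sets within each module.

    One-sided (greater) Fisher exact test of module membership against
    (pSI < threshold), Bonferroni-corrected over modules x cell types at
    each threshold.
    """
    universe = specificity.p_si.index
    labels = partition.labels.reindex(universe).fillna(0)
    modules = partition.module_ids
    cell_types = specificity.p_si.columns
    rows = []
    for thr in thresholds:
        m_tests = len(modules) * len(cell_types)
        for ct in cell_types:
            markers = set(universe[specificity.p_si[ct] < thr])
            if not markers:
                log.info("no markers for %s at pSI < %g; skipped", ct, thr)
                continue
            for m in modules:
                in_mod = labels == m
                a = int((in_mod & labels.index.isin(markers)).sum())
                b = int(in_mod.sum() - a)
                c = int(len(markers) - a)
                d = int(len(universe) - a - b - c)
                _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
                rows.append(
                    {
                        "threshold": thr,
                        "cell_type": ct,
                        "module": m,
                        "n_overlap": a,
                        "p": float(p),
                        "adj_p": bonferroni(float(p), m_tests),
                    }
                )
    return pd.DataFrame(rows)


def select_hubs(
    partition: ModulePartition, module: int, top_frac: float = 0.10
) -> list:
    """The ceil(top_frac * size) member genes with the highest kME
    (deterministic tie-break by gene id)."""
    if partition.kme is None:
        raise ValueError("partition carries no kME matrix")
    members = partition.members(module)
    if len(members) == 0:
        raise ValueError(f"module {module} is empty")
    n_hubs = max(1, math.ceil(top_frac * len(members)))
    if len(members) < 10:
        log.warning("module %d has < 10 genes; returning the single top gene", module)
        n_hubs = 1
    kme_m = partition.kme.loc[members, module]
    order = sorted(zip(-kme_m.to_numpy(), members))
    return [g for _, g in order[:n_hubs]]


@dataclass
class ClassifierResult:
    accuracy: float
    predictions: pd.Series  # per-sample LOOCV prediction
    classes: tuple


def lda_loocv(
    study: ExpressionStudy, features, class_labels: pd.Series
) -> ClassifierResult:
    """Two-class LDA (pooled covariance, equal priors) with leave-one-out
    cross-validation on the given feature genes."""
    class_labels = class_labels.loc[study.samples]
    classes = tuple(sorted(class_labels.unique()))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    counts = class_labels.value_counts()
    if (counts < 2).any():
        raise ValueError("each class needs >= 2 samples")
    features = [f for f in features if f in study.genes]
    if not features:
        raise ValueError("no feature genes present in the study")
    X = study.matrix.loc[features].to_numpy().T  # samples x features
    y = class_labels.to_numpy()
    n = len(y)
    preds = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        clf = LinearDiscriminantAnalysis(priors=(0.5, 0.5), solver="svd")
        clf.fit(X[mask], y[mask])
        preds.append(clf.predict(X[i : i + 1])[0])
    preds = pd.Series(preds, index=study.samples)
    accuracy = float((preds.to_numpy() == y).mean())
    return ClassifierResult(accuracy, preds, classes)


def per_gene_biomarker_accuracy(
    study: ExpressionStudy, genes, class_labels: pd.Series
) -> pd.Series:
    """LOOCV accuracy of a single-gene LDA classifier for each gene."""
    return pd.Series(
        {g: lda_loocv(study, [g], class_labels).accuracy for g in genes}
    ).rename("accuracy")


def hubness_accuracy_correlation(
    kme_ref: pd.Series, accuracies: pd.Series
) -> tuple[float, float]:
    """Spearman correlation between reference kME (hubness) and per-gene
    biomarker accuracy.  Returns (rho, p); (nan, nan) when undefined."""
    shared = kme_ref.index.intersection(accuracies.index)
    if len(shared) < 10:
        raise ValueError("need >= 10 genes with both hubness and accuracy")
    a = kme_ref.loc[shared].to_numpy(dtype=float)
    b = accuracies.loc[shared].to_numpy(dtype=float)
    if np.ptp(b) == 0 or np.ptp(a) == 0:
        log.warning("constant vector: hubness-accuracy correlation undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)
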