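"""Signed weighted coexpression network construction and module detection.

The chain is the classic one: a robust signed correlation matrix
(biweight midcorrelation with a cap on the fraction of samples treated as
outliers), soft thresholding ``a = ((1 + cor)/2)^beta`` with beta chosen
as the smallest exponent reaching approximate scale-free topology, the
topological overlap matrix (TOM), average-linkage clustering of
``1 - TOM``, and an adaptive top-down cut of the dendrogram into modules
with a minimum size.  Modules are summarized by eigengenes (first
principal component of the standardized member expression) and genes by
kME, their correlation to each eigengene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import ExpressionStudy, ModulePartition

log = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    values: pd.DataFrame  # genes x genes
    method: str  # bicor | spearman | pearson

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")


@dataclass
class SoftThresholdResult:
    candidates: np.ndarray
    r_squared: np.ndarray  # signed scale-free fit index per candidate
    mean_connectivity: np.ndarray
    beta: int
    satisfied: bool  # whether any candidate cleared the R^2 cut


def _bicor_transform(x: np.ndarray, max_p_outliers: float) -> np.ndarray:
    """Rows of x -> median-centered, biweight-weighted, unit-norm rows.

    Rows with zero MAD (or degenerate weights) fall back to the Pearson
    transform (mean-centered, unit norm); fully constant rows become zero
    vectors so their correlation with anything is 0.
    """
    n_rows, n = x.shape
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True)
    out = np.zeros_like(x, dtype=float)

    ok = mad[:, 0] > 0
    if ok.any():
        xo = x[ok]
        u = (xo - med[ok]) / (9.0 * mad[ok])
        if max_p_outliers < 0.5:
            # inflate the denominator on each side so that at most a
            # fraction max_p_outliers of samples per side gets zero weight
            qlo = np.quantile(xo, max_p_outliers, axis=1, keepdims=True)
            qhi = np.quantile(xo, 1.0 - max_p_outliers, axis=1, keepdims=True)
            ulo = (qlo - med[ok]) / (9.0 * mad[ok])
            uhi = (qhi - med[ok]) / (9.0 * mad[ok])
            lo_scale = np.maximum(1.0, -ulo)
            hi_scale = np.maximum(1.0, uhi)
            u = np.where(u < 0, u / lo_scale, u / hi_scale)
        w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
        centered = (xo - med[ok]) * w
        norm = np.linalg.norm(centered, axis=1, keepdims=True)
        good = norm[:, 0] > 0
        centered[good] /= norm[good]
        out_ok = np.zeros_like(xo)
        out_ok[good] = centered[good]
        # degenerate weighting -> Pearson fallback for those rows
        fallback_rows = np.where(ok)[0][~good]
        out[ok] = out_ok
    else:
        fallback_rows = np.array([], dtype=int)

    pearson_rows = np.concatenate([np.where(~ok)[0], fallback_rows]).astype(int)
    for i in np.unique(pearson_rows):
        row = x[i] - x[i].mean()
        norm = np.linalg.norm(row)
        if norm > 0:
            out[i] = row / norm
        else:
            log.warning("constant row %d: correlations set to 0", i)
    return out


def bicor(study: ExpressionStudy, max_p_outliers: float = 0.05) -> CorrelationMatrix:
    """Biweight midcorrelation between all gene pairs.

    Samples beyond 9 MADs from the median get zero weight; the weighting
    is rescaled so that at most ``max_p_outliers`` of samples on either
    side of the median can be zero-weighted.  Genes with zero MAD fall
    back to Pearson.
    """
    if study.n_samples < 4:
        raise ValueError("need >= 4 samples for biweight midcorrelation")
    t = _bicor_transform(study.values(), max_p_outliers)
    c = np.clip(t @ t.T, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(
        pd.DataFrame(c, index=study.genes, columns=study.genes), "bicor"
    )


def spearman_cor(study: ExpressionStudy) -> CorrelationMatrix:
    ranks = np.apply_along_axis(stats.rankdata, 1, study.values())
    ranks -= ranks.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(ranks, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    t = ranks / norm
    c = np.clip(t @ t.T, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(
        pd.DataFrame(c, index=study.genes, columns=study.genes), "spearman"
    )


def adjacency_signed(cor: CorrelationMatrix | np.ndarray, beta: float) -> np.ndarray:
    """Signed adjacency ``a_ij = ((1 + cor_ij)/2)^beta`` with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    c = cor.values.to_numpy() if isinstance(cor, CorrelationMatrix) else np.asarray(cor)
    a = ((1.0 + c) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10 p(k) vs log10 k over equal-width connectivity bins.

    Empty bins are skipped; the fit is sign-adjusted so that a positive
    slope (anti-scale-free) yields a negative index.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if len(k) < 2 or np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mask = counts > 0
    if mask.sum() < 3:
        return 0.0
    logp = np.log10(counts[mask] / counts.sum())
    logk = np.log10(centers[mask])
    slope, _, r, _, _ = stats.linregress(logk, logp)
    return -np.sign(slope) * r**2


def pick_soft_threshold(
    cor: CorrelationMatrix,
    candidates=range(1, 21),
    r2_cut: float = 0.8,
    n_bins: int = 10,
) -> SoftThresholdResult:
    """Choose the smallest beta whose network satisfies the scale-free
    topology criterion (signed fit R^2 > ``r2_cut``).

    If no candidate clears the cut, the candidate with the maximal fit is
    returned and flagged via ``satisfied=False``.
    """
    c = cor.values.to_numpy()
    if np.ptp(c[np.triu_indices_from(c, k=1)]) == 0:
        raise ValueError("degenerate (constant) correlation matrix")
    cand = np.array(list(candidates), dtype=int)
    fits = np.empty(len(cand))
    mean_k = np.empty(len(cand))
    for i, beta in enumerate(cand):
        a = adjacency_signed(cor, beta)
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        fits[i] = scale_free_fit(k, n_bins=n_bins)
        mean_k[i] = k.mean()
    passing = np.where(fits > r2_cut)[0]
    if len(passing):
        chosen = int(cand[passing[0]])
        satisfied = True
    else:
        chosen = int(cand[int(np.argmax(fits))])
        satisfied = False
        log.warning(
            "no candidate beta reached R^2 > %.2f; using beta=%d (max fit %.3f)",
            r2_cut, chosen, fits.max(),
        )
    return SoftThresholdResult(cand, fits, mean_k, chosen, satisfied)


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap: shared-neighbor weight plus direct adjacency,
    normalized by the smaller connectivity.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with
    k the off-diagonal row sums and unit diagonal.
    """
    a = np.asarray(adj, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    numer = a @ a + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _branch_leaves(Z: np.ndarray, n: int):
    """Leaf sets for every internal node of a scipy linkage matrix."""
    leaves = [None] * (n - 1)
    for i in range(n - 1):
        members = []
        for child in (int(Z[i, 0]), int(Z[i, 1])):
            if child < n:
                members.append([child])
            else:
                members.append(leaves[child - n])
        leaves[i] = members[0] + members[1]
    return leaves


def cluster_modules(
    tom: np.ndarray,
    gene_index: pd.Index,
    min_size: int = 20,
    cohesion: float = 0.4,
) -> pd.Series:
    """Adaptive top-down cut of the average-linkage TOM dendrogram.

    Starting at the root, a branch is accepted as a module if it has at
    least ``min_size`` leaves and is cohesive — its mean within-branch
    dissimilarity is below ``cohesion`` times the background level (the
    75th percentile of all pairwise dissimilarities); otherwise its
    children are examined.  Accepted branches are then trimmed: members
    whose mean dissimilarity to the rest of the branch exceeds the same
    threshold are returned to the background.  On homogeneous noise no
    branch is cohesive and (nearly) all genes stay unassigned (label 0).
    Modules are numbered by decreasing size.
    """
    n = tom.shape[0]
    labels = pd.Series(0, index=gene_index, dtype=int)
    if n < max(min_size, 2):
        log.warning("fewer genes than min_size: all genes unassigned")
        return labels
    d = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(d, 0.0)
    offdiag = d[np.triu_indices(n, k=1)]
    overall = np.quantile(offdiag, 0.75)
    if overall <= 0:
        labels[:] = 1
        return labels
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    leaves = _branch_leaves(Z, n)

    def mean_within(idx) -> float:
        sub = d[np.ix_(idx, idx)]
        m = len(idx)
        return sub[np.triu_indices(m, k=1)].mean() if m > 1 else 0.0

    modules = []

    def descend(node: int) -> None:
        idx = leaves[node]
        if len(idx) < min_size:
            return
        if mean_within(idx) <= cohesion * overall:
            modules.append(idx)
            return
        for child in (int(Z[node, 0]), int(Z[node, 1])):
            if child >= n:
                descend(child - n)

    descend(n - 2)  # root
    # trim loosely attached members (mean dissimilarity to the rest of the
    # branch above the cohesion threshold)
    trimmed = []
    for idx in modules:
        idx = np.asarray(idx)
        while len(idx) > min_size:
            sub = d[np.ix_(idx, idx)]
            mean_to_rest = sub.sum(axis=1) / (len(idx) - 1)
            if mean_to_rest.max() <= cohesion * overall:
                break
            idx = np.delete(idx, int(np.argmax(mean_to_rest)))
        if len(idx) >= min_size:
            trimmed.append(idx)
    trimmed.sort(key=len, reverse=True)
    for m, idx in enumerate(trimmed, start=1):
        labels.iloc[idx] = m
    return labels


def module_eigengenes(
    study: ExpressionStudy, labels: pd.Series
) -> tuple[pd.DataFrame, dict]:
    """First principal component of each module's standardized expression.

    Eigengenes are unit-norm right singular vectors, oriented so the mean
    correlation with member genes is non-negative (ties break positive).
    Returns (modules x samples eigengene matrix, proportion of variance
    explained per module).
    """
    labels = labels.loc[study.genes]
    x = study.values()
    eigs = {}
    pve = {}
    for m in sorted(int(v) for v in labels.unique() if v != 0):
        rows = np.where(labels.to_numpy() == m)[0]
        if len(rows) < 2:
            raise ValueError(f"module {m} has fewer than 2 genes")
        sub = x[rows]
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - mu) / sd
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]
        mean_cor = np.mean([np.corrcoef(e, row)[0, 1] for row in z])
        if mean_cor < 0 or (mean_cor == 0 and e[0] < 0):
            e = -e
        eigs[m] = e
        pve[m] = float(s[0] ** 2 / np.sum(s**2))
    eigen = pd.DataFrame(
        eigs, index=study.samples
    ).T.rename_axis("module")
    return eigen, pve


def kme(
    study: ExpressionStudy, eigengenes: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Correlation of every gene with every module eigengene."""
    x = study.values()
    if method == "spearman":
        x = np.apply_along_axis(stats.rankdata, 1, x)
        e = np.apply_along_axis(stats.rankdata, 1, eigengenes.to_numpy())
    elif method == "pearson":
        e = eigengenes.to_numpy()
    else:
        raise ValueError(f"unknown method {method!r}")

    def _standardize(a: np.ndarray) -> np.ndarray:
        a = a - a.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(a, axis=1, keepdims=True)
        zero = norm[:, 0] == 0
        if zero.any():
            log.warning("%d constant rows: kME set to 0", int(zero.sum()))
        norm[zero] = 1.0
        return a / norm

    gz = _standardize(x)
    ez = _standardize(e)
    vals = np.clip(gz @ ez.T, -1.0, 1.0)
    return pd.DataFrame(vals, index=study.genes, columns=eigengenes.index)


def build_partition(
    study: ExpressionStudy, labels: pd.Series, kme_method: str = "pearson"
) -> ModulePartition:
    eigen, pve = module_eigengenes(study, labels)
    k = kme(study, eigen, method=kme_method)
    return ModulePartition(labels, eigen, k, pve)


def merge_close_modules(
    partition: ModulePartition, study: ExpressionStudy, cut_height: float = 0.2
) -> ModulePartition:
    """Iteratively merge module pairs with eigengene dissimilarity
    ``1 - cor`` below ``cut_height``, recomputing eigengenes after each
    merge until no pair qualifies."""
    labels = partition.labels.copy()
    while True:
        eigen, _ = module_eigengenes(study, labels)
        mods = list(eigen.index)
        if len(mods) < 2:
            break
        e = eigen.to_numpy()
        e = e - e.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(e, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        cor = (e / norms) @ (e / norms).T
        diss = 1.0 - cor
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= cut_height:
            break
        keep, drop = sorted((mods[i], mods[j]))
        labels[labels == drop] = keep
        # renumber to keep labels contiguous by size
        sizes = labels[labels != 0].value_counts()
        remap = {old: new for new, old in enumerate(sizes.index, start=1)}
        labels = labels.map(lambda v: remap.get(v, 0))
    return build_partition(study, labels)


def eigengene_network(eigengenes: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Module meta-network: pairwise Spearman correlation of eigengenes and
    the average-linkage dendrogram of ``1 - rho``."""
    if eigengenes.shape[0] < 2:
        raise ValueError("need >= 2 modules for an eigengene network")
    ranks = np.apply_along_axis(stats.rankdata, 1, eigengenes.to_numpy())
    rho = np.corrcoef(ranks)
    cor = pd.DataFrame(rho, index=eigengenes.index, columns=eigengenes.index)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    return cor, Z


def fit_coexpression_network(
    study: ExpressionStudy,
    min_size: int = 20,
    cut_height: float = 0.2,
    beta: int | None = None,
    r2_cut: float = 0.8,
    max_p_outliers: float = 0.05,
    cohesion: float = 0.85,
) -> tuple[ModulePartition, SoftThresholdResult | None]:
    """End-to-end network build: bicor -> soft threshold -> TOM -> modules
    -> merge.  ``beta=None`` selects the exponent automatically."""
    cor = bicor(study, max_p_outliers=max_p_outliers)
    soft = None
    if beta is None:
        soft = pick_soft_threshold(cor, r2_cut=r2_cut)
        beta = soft.beta
    adj = adjacency_signed(cor, beta)
    tom = tom_similarity(adj)
    labels = cluster_modules(tom, study.genes, min_size=min_size, cohesion=cohesion)
    if labels.max() == 0:
        return ModulePartition(labels), soft
    partition = build_partition(study, labels)
    partition = merge_close_modules(partition, study, cut_height=cut_height)
    return partition, soft
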