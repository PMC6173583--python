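"""Module-level differential expression, consensus calls, severity scores,
curated-set enrichment and reversal tests.

Per study, genes are ranked by a two-sample t statistic (injured vs sham)
or by Spearman correlation against a continuous covariate; each module is
then tested for coordinated up- and downregulation with a mean-rank
gene-set test (Wilcoxon rank-sum of the module genes' statistics against
all other genes), Bonferroni-corrected over modules x 2 directions within
each study.  A module significant in the same direction in every study is
a consensus module; in all but one, a majority module.  Severity analyses
score each gene by rho * -log10(p) of its Spearman correlation with
injury severity and test modules for enrichment of high/low scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CuratedGeneSet, ExpressionStudy, ModulePartition
from .coexpression import module_eigengenes

log = logging.getLogger(__name__)


@dataclass
class GeneStatistics:
    """Per-gene ranking statistics for one contrast in one study."""

    values: pd.Series  # signed statistic per gene
    p_values: pd.Series
    kind: str  # t | spearman_rho
    study_id: str
    contrast: str


def bonferroni(p: float, m: int) -> float:
    return float(min(1.0, p * m))


def wilcoxon_rank_sum(
    x: np.ndarray, y: np.ndarray, alternative: str = "greater"
) -> float:
    """Rank-sum p-value: exact enumeration when both groups have <= 10
    untied observations, otherwise the tie-corrected normal approximation
    with continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and max(len(x), len(y)) <= 10) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative=alternative, method=method).pvalue
    )


def gene_statistics(
    study: ExpressionStudy,
    contrast: str = "condition",
    group_a: str = "injured",
    group_b: str = "sham",
    covariate: str | None = None,
) -> GeneStatistics:
    """Two-sample t statistics for a group contrast, or Spearman rho
    (t-approximation p) against a continuous covariate."""
    x = study.values()
    if covariate is not None:
        sev = study.sample_meta[covariate].to_numpy(dtype=float)
        if np.ptp(sev) == 0:
            raise ValueError(f"covariate {covariate!r} is constant")
        rho, p = _spearman_rows(x, sev)
        return GeneStatistics(
            pd.Series(rho, index=study.genes),
            pd.Series(p, index=study.genes),
            "spearman_rho",
            str(study.sample_meta["study_id"].iloc[0]),
            f"spearman:{covariate}",
        )
    groups = study.sample_meta[contrast].to_numpy()
    a = x[:, groups == group_a]
    b = x[:, groups == group_b]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError(
            f"need >= 2 samples per level of {contrast!r} "
            f"({group_a}: {a.shape[1]}, {group_b}: {b.shape[1]})"
        )
    t, p = stats.ttest_ind(a, b, axis=1)
    t = np.nan_to_num(t, nan=0.0)
    p = np.nan_to_num(p, nan=1.0)
    return GeneStatistics(
        pd.Series(t, index=study.genes),
        pd.Series(p, index=study.genes),
        "t",
        str(study.sample_meta["study_id"].iloc[0]),
        f"{group_a}_vs_{group_b}",
    )


def _spearman_rows(x: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman correlation with the vector v, with the usual
    t-distribution approximation for p."""
    n = x.shape[1]
    rx = np.apply_along_axis(stats.rankdata, 1, x)
    rv = stats.rankdata(v)
    rxc = rx - rx.mean(axis=1, keepdims=True)
    rvc = rv - rv.mean()
    denom = np.linalg.norm(rxc, axis=1) * np.linalg.norm(rvc)
    zero = denom == 0
    denom[zero] = 1.0
    rho = np.clip(rxc @ rvc / denom, -1.0, 1.0)
    rho[zero] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    p[zero] = 1.0
    return rho, np.clip(p, np.finfo(float).tiny, 1.0)


def mean_rank_set_test(
    statistics: GeneStatistics | pd.Series, gene_set, alternative: str = "up"
) -> float:
    """Mean-rank gene-set test: Wilcoxon rank-sum of the set genes'
    statistics against all other genes.  ``alternative='up'`` tests
    whether the set's statistics tend to be larger."""
    values = (
        statistics.values if isinstance(statistics, GeneStatistics) else statistics
    )
    in_set = values.index.isin(set(gene_set))
    if in_set.sum() < 2 or (~in_set).sum() < 2:
        raise ValueError("gene set and complement must each contain >= 2 genes")
    alt = {"up": "greater", "down": "less"}[alternative]
    return wilcoxon_rank_sum(
        values.to_numpy()[in_set], values.to_numpy()[~in_set], alternative=alt
    )


@dataclass
class ModuleDEResult:
    """Per-study module-level DE table and the derived consensus labels."""

    per_study: pd.DataFrame  # rows (study, module): p_up, p_down, adj, call
    consensus: pd.Series | None = None  # module -> label

    @property
    def studies(self) -> list:
        return sorted(self.per_study["study_id"].unique())


def module_de(
    studies: list[ExpressionStudy],
    partition: ModulePartition,
    alpha: float = 0.05,
) -> ModuleDEResult:
    """Mean-rank up/down tests for every module in every study, Bonferroni
    over modules x 2 directions within each study, direction calls at
    adjusted p < alpha, and consensus labels across studies."""
    rows = []
    modules = partition.module_ids
    m_tests = len(modules) * 2
    for study in studies:
        gs = gene_statistics(study)
        universe_labels = partition.labels.reindex(gs.values.index).fillna(0)
        for m in modules:
            members = universe_labels.index[universe_labels == m]
            p_up = mean_rank_set_test(gs, members, "up")
            p_down = mean_rank_set_test(gs, members, "down")
            adj_up = bonferroni(p_up, m_tests)
            adj_down = bonferroni(p_down, m_tests)
            if adj_up < alpha and adj_up <= adj_down:
                call = "up"
            elif adj_down < alpha:
                call = "down"
            else:
                call = "none"
            rows.append(
                {
                    "study_id": gs.study_id,
                    "module": m,
                    "p_up": p_up,
                    "p_down": p_down,
                    "adj_p_up": adj_up,
                    "adj_p_down": adj_down,
                    "call": call,
                }
            )
    table = pd.DataFrame(rows)
    result = ModuleDEResult(table)
    if table["study_id"].nunique() >= 2:
        result.consensus = consensus_calls(result)
    return result


def consensus_calls(de_result: ModuleDEResult) -> pd.Series:
    """consensus_up/down: the same significant direction in all studies;
    majority_up/down: in all but one; otherwise none."""
    table = de_result.per_study
    n_studies = table["study_id"].nunique()
    if n_studies < 2:
        raise ValueError("consensus requires >= 2 studies")
    labels = {}
    for m, sub in table.groupby("module"):
        n_up = int((sub["call"] == "up").sum())
        n_down = int((sub["call"] == "down").sum())
        if n_up == n_studies:
            labels[m] = "consensus_up"
        elif n_down == n_studies:
            labels[m] = "consensus_down"
        elif n_up == n_studies - 1 and n_down == 0:
            labels[m] = "majority_up"
        elif n_down == n_studies - 1 and n_up == 0:
            labels[m] = "majority_down"
        else:
            labels[m] = "none"
    return pd.Series(labels).rename_axis("module")


def temporal_profiles(
    studies: list[ExpressionStudy],
    partition: ModulePartition,
    timepoints=(1.0, 3.0, 7.0, 28.0),
    alpha: float = 0.05,
) -> tuple[dict, pd.Series]:
    """Module DE stratified by time point, plus flags for modules whose
    consensus direction flips between the earliest and latest time point."""
    results: dict = {}
    for tp in timepoints:
        strat = []
        for study in studies:
            meta = study.sample_meta
            if meta["timepoint_days"].isna().all():
                raise ValueError("missing time-point metadata")
            keep = meta.index[meta["timepoint_days"] == tp]
            sub = study.subset_samples(keep)
            conds = sub.sample_meta["condition"]
            if (conds == "injured").sum() < 2 or (conds == "sham").sum() < 2:
                log.info(
                    "study %s: empty/thin stratum at day %s skipped",
                    meta["study_id"].iloc[0], tp,
                )
                continue
            strat.append(sub)
        if len(strat) >= 2:
            results[tp] = module_de(strat, partition, alpha=alpha)
        else:
            log.info("time point %s has < 2 informative studies; skipped", tp)
    flips = {}
    tps = sorted(results)
    if len(tps) >= 2:
        first, last = results[tps[0]].consensus, results[tps[-1]].consensus
        direction = {
            "consensus_up": 1, "majority_up": 1,
            "consensus_down": -1, "majority_down": -1, "none": 0,
        }
        for m in first.index:
            d0, d1 = direction[first[m]], direction[last.get(m, "none")]
            flips[m] = bool(d0 != 0 and d1 != 0 and d0 != d1)
    return results, pd.Series(flips, dtype=bool).rename_axis("module")


@dataclass
class SeverityResult:
    gene_scores: pd.DataFrame  # rho, p, score per gene
    module_enrichment: pd.DataFrame  # p_pos, p_neg + Bonferroni per module
    eigengene_correlation: pd.DataFrame  # rho, p per module


def severity_scores(
    study: ExpressionStudy,
    partition: ModulePartition,
    severity_col: str = "severity",
) -> SeverityResult:
    """Severity association scores and module-level enrichment.

    The per-gene score is ``rho * -log10(p)`` of the Spearman correlation
    between expression and injury severity.  Modules are tested for
    enrichment of positively and negatively scored genes with the
    mean-rank test (Bonferroni over modules x 2), and each module
    eigengene is correlated with severity.
    """
    sev = study.sample_meta[severity_col].to_numpy(dtype=float)
    if np.ptp(sev) == 0:
        raise ValueError("severity is constant across samples")
    if len(np.unique(sev)) < 3 and len(sev) < 8:
        raise ValueError("need >= 3 severity levels or >= 8 samples")
    rho, p = _spearman_rows(study.values(), sev)
    score = rho * (-np.log10(p))
    genes = pd.DataFrame(
        {"rho": rho, "p": p, "score": score}, index=study.genes
    )
    score_series = genes["score"]
    modules = partition.module_ids
    m_tests = len(modules) * 2
    labels = partition.labels.reindex(study.genes).fillna(0)
    rows = []
    for m in modules:
        members = labels.index[labels == m]
        p_pos = mean_rank_set_test(score_series, members, "up")
        p_neg = mean_rank_set_test(score_series, members, "down")
        rows.append(
            {
                "module": m,
                "p_pos": p_pos,
                "p_neg": p_neg,
                "adj_p_pos": bonferroni(p_pos, m_tests),
                "adj_p_neg": bonferroni(p_neg, m_tests),
            }
        )
    enrich = pd.DataFrame(rows).set_index("module")
    eigen, _ = module_eigengenes(study, labels)
    erows = []
    for m in eigen.index:
        r, pv = stats.spearmanr(eigen.loc[m].to_numpy(), sev)
        erows.append({"module": m, "rho": float(r), "p": float(pv)})
    eig_cor = pd.DataFrame(erows).set_index("module")
    return SeverityResult(genes, enrich, eig_cor)


def curated_enrichment(
    partition: ModulePartition, curated: CuratedGeneSet | set, universe
) -> pd.DataFrame:
    """One-sided Fisher exact test (module membership x curated membership)
    per module, Bonferroni over modules."""
    curated_genes = (
        set(curated.genes) if isinstance(curated, CuratedGeneSet) else set(curated)
    )
    universe = pd.Index(universe)
    curated_in = curated_genes & set(universe)
    if not curated_in:
        raise ValueError("curated set does not overlap the universe")
    labels = partition.labels.reindex(universe).fillna(0)
    modules = partition.module_ids
    rows = []
    for m in modules:
        in_mod = labels == m
        if in_mod.sum() == 0:
            log.info("module %d empty in universe; skipped", m)
            continue
        a = int((in_mod & labels.index.isin(curated_in)).sum())
        b = int(in_mod.sum() - a)
        c = int(len(curated_in) - a)
        d = int(len(universe) - a - b - c)
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"module": m, "n_overlap": a, "p": float(p)})
    table = pd.DataFrame(rows).set_index("module")
    table["adj_p"] = (table["p"] * len(table)).clip(upper=1.0)
    return table


def enrichment_robustness(
    partition: ModulePartition,
    curated: CuratedGeneSet | set,
    universe,
    removal_grid=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    addition_grid=(0.0, 0.25, 0.5, 0.75, 1.0),
    n_boot: int = 100,
    rng_seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Breakdown analysis of the curated-set enrichment.

    For each perturbation fraction f, ``n_boot`` perturbed curated sets are
    built (removing floor(f*n) genes, or adding floor(f*n) random universe
    genes) and the Bonferroni Fisher p recomputed.  The breakdown point of
    a module is the largest f at which its median adjusted p stays below
    alpha (NaN if even f=0 is not significant; removal f=1 is undefined
    and reported as NA).
    """
    curated_genes = sorted(
        set(curated.genes) if isinstance(curated, CuratedGeneSet) else set(curated)
    )
    universe = pd.Index(universe)
    rng = np.random.default_rng(rng_seed)
    n = len(curated_genes)
    modules = partition.module_ids
    out = {"removal": {}, "addition": {}}
    median_p: dict = {"removal": {}, "addition": {}}
    for mode, grid in (("removal", removal_grid), ("addition", addition_grid)):
        for f in grid:
            if not 0.0 <= f <= 1.0:
                raise ValueError("perturbation fractions must lie in [0, 1]")
            k = int(np.floor(f * n))
            if mode == "removal" and k >= n:
                median_p[mode][f] = pd.Series(np.nan, index=modules)
                continue
            ps = []
            for _ in range(n_boot if k > 0 else 1):
                if mode == "removal":
                    keep = rng.choice(curated_genes, size=n - k, replace=False)
                    perturbed = set(keep)
                else:
                    pool = universe.difference(pd.Index(curated_genes))
                    extra = rng.choice(pool.to_numpy(), size=min(k, len(pool)),
                                       replace=False)
                    perturbed = set(curated_genes) | set(extra)
                tab = curated_enrichment(partition, perturbed, universe)
                ps.append(tab["adj_p"])
            median_p[mode][f] = pd.concat(ps, axis=1).median(axis=1)
        frame = pd.DataFrame(median_p[mode])
        breakdown = {}
        for m in modules:
            sig = frame.loc[m] < alpha
            breakdown[m] = max(
                (f for f in frame.columns if sig[f] and not np.isnan(frame.loc[m, f])),
                default=np.nan,
            )
        out[mode] = {"median_p": frame, "breakdown": pd.Series(breakdown)}
    return out


@dataclass
class ReversalResult:
    per_module: pd.DataFrame
    n_reversed: int
    n_consensus: int


def reversal_test(
    treated_study: ExpressionStudy,
    control_study: ExpressionStudy,
    partition: ModulePartition,
    consensus: pd.Series,
    alpha: float = 0.05,
) -> ReversalResult:
    """Do consensus modules move in the opposite direction under treatment?

    For each consensus module the treated-vs-control contrast is tested
    with the mean-rank test in the direction opposite to the module's
    consensus call, plus a one-tailed Wilcoxon rank-sum on the module
    eigengene's per-sample scores (alternative fixed by the expected
    reversal).
    """
    shared = treated_study.genes.intersection(control_study.genes)
    if len(shared) < 10:
        raise ValueError("too few shared genes between treated and control")
    tr = treated_study.subset_genes(shared)
    ct = control_study.subset_genes(shared)
    matrix = pd.concat([tr.matrix, ct.matrix], axis=1)
    meta = pd.concat([tr.sample_meta, ct.sample_meta])
    meta = meta.assign(condition=["treated"] * tr.n_samples + ["control"] * ct.n_samples)
    combined = ExpressionStudy(matrix, meta)
    gs = gene_statistics(combined, group_a="treated", group_b="control")
    labels = partition.labels.reindex(shared).fillna(0)
    eigen, _ = module_eigengenes(combined, labels)
    rows = []
    direction = {"consensus_up": 1, "majority_up": 1,
                 "consensus_down": -1, "majority_down": -1}
    consensus_mods = [m for m in consensus.index if consensus[m] in direction]
    m_tests = max(len(consensus_mods), 1)
    for m in consensus_mods:
        d = direction[consensus[m]]
        members = labels.index[labels == m]
        # reversal: consensus-up modules should go DOWN under treatment
        p_rev = mean_rank_set_test(gs, members, "down" if d > 0 else "up")
        e = eigen.loc[m].to_numpy()
        treated_scores = e[: tr.n_samples]
        control_scores = e[tr.n_samples:]
        p_wilcoxon = wilcoxon_rank_sum(
            treated_scores, control_scores,
            alternative="less" if d > 0 else "greater",
        )
        rows.append(
            {
                "module": m,
                "consensus": consensus[m],
                "p_reversal": p_rev,
                "adj_p_reversal": bonferroni(p_rev, m_tests),
                "p_eigengene_wilcoxon": p_wilcoxon,
                "reversed": bonferroni(p_rev, m_tests) < alpha,
            }
        )
    table = pd.DataFrame(rows).set_index("module") if rows else pd.DataFrame()
    n_rev = int(table["reversed"].sum()) if len(table) else 0
    return ReversalResult(table, n_rev, len(consensus_mods))
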