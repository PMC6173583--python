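"""Parsing of curated gene tables and expression preprocessing.

The preprocessing chain mirrors the reference-cohort pipeline: keep genes
expressed above a floor in enough individuals, quantile-normalize each
sample to the average empirical distribution, then inverse-normal
transform each gene so its values match standard-normal quantiles.
Curated records from model organisms are lifted to human genes by a
majority vote across ortholog databases: a human gene is accepted only if
at least half of the databases that carry an entry for the source id agree
on it.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DIRECTIONS, CuratedGeneSet, ExpressionStudy, OrthologTable
from .io import read_curated_table

log = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


def map_orthologs_majority(source_ids, tables: list[OrthologTable]) -> dict:
    """Consensus-ortholog mapping: source id -> human gene id or None.

    For each source id, let D be the databases containing an entry for it.
    A human gene is returned iff it appears in at least ceil(|D|/2) of D.
    If two distinct human genes both clear the bar the call is ambiguous
    and None is returned.  The vote is independent of table order.
    """
    if not tables:
        raise ValueError("need at least one ortholog table")
    out: dict = {}
    for sid in source_ids:
        entries = [t.mapping[sid] for t in tables if sid in t.mapping]
        if not entries:
            out[sid] = None
            continue
        need = -(-len(entries) // 2)  # ceil(|D|/2)
        votes: dict = {}
        for targets in entries:
            for gene in targets:
                votes[gene] = votes.get(gene, 0) + 1
        winners = sorted(g for g, v in votes.items() if v >= need)
        if len(winners) == 1:
            out[sid] = winners[0]
        else:
            if len(winners) > 1:
                log.info("ambiguous ortholog vote for %s: %s", sid, winners)
            out[sid] = None
    return out


def parse_curated_table(
    path, ortholog_tables: list[OrthologTable] | None = None
) -> CuratedGeneSet:
    """Parse a curation TSV into a deduplicated human gene set.

    Non-human records are mapped through the majority vote; unmappable
    records are dropped (logged).  Study counts are the number of distinct
    study ids supporting each unique human gene.
    """
    records = read_curated_table(path)
    human = records["species"].str.lower() == "human"
    mapped = records["source_id"].where(human, other=None)
    if (~human).any():
        if not ortholog_tables:
            raise ParseError(
                "curated table contains non-human records but no ortholog "
                "tables were provided"
            )
        vote = map_orthologs_majority(
            records.loc[~human, "source_id"].unique(), ortholog_tables
        )
        mapped = mapped.copy()
        mapped[~human] = records.loc[~human, "source_id"].map(vote)
    records = records.assign(human_gene=mapped)
    n_dropped = int(records["human_gene"].isna().sum())
    if n_dropped:
        log.info("dropped %d unmappable curated records", n_dropped)
    kept = records[records["human_gene"].notna()]
    if kept.empty:
        raise ParseError("no curated records could be mapped to human genes")
    counts = kept.groupby("human_gene")["study_id"].nunique()
    return CuratedGeneSet(
        records=records,
        genes=frozenset(kept["human_gene"]),
        study_counts=counts,
    )


def filter_expression(
    study: ExpressionStudy, min_value: float = 0.1, min_individuals: int = 10
) -> ExpressionStudy:
    """Keep genes with expression > ``min_value`` in >= ``min_individuals``
    samples (strict threshold on the value, inclusive on the count)."""
    x = study.values()
    keep = (x > min_value).sum(axis=1) >= min_individuals
    if not keep.any():
        raise ValueError("no genes survive the expression filter")
    return ExpressionStudy(study.matrix.loc[keep], study.sample_meta)


def quantile_normalize_samples(study: ExpressionStudy) -> ExpressionStudy:
    """Quantile-transform each sample to the average empirical distribution.

    After the transform the sorted values of every sample are identical
    and equal to the per-rank mean over samples; ties within a sample get
    the mean of their target quantiles.
    """
    x = study.values()
    n_genes, n_samples = x.shape
    if n_samples == 1:
        log.warning("single sample: quantile normalization is the identity")
        return study
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(n_samples):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty(n_genes)
        mapped[order] = reference
        out[:, j] = _average_over_ties(col, mapped)
    matrix = pd.DataFrame(out, index=study.genes, columns=study.samples)
    return ExpressionStudy(matrix, study.sample_meta)


def _average_over_ties(col: np.ndarray, mapped: np.ndarray) -> np.ndarray:
    """Replace the mapped values of tied entries with their group mean."""
    df = pd.DataFrame({"col": col, "mapped": mapped})
    return df.groupby("col")["mapped"].transform("mean").to_numpy()


def inverse_normal_transform_genes(study: ExpressionStudy) -> ExpressionStudy:
    """Per-gene rank-based inverse normal transform.

    Each gene row becomes Phi^-1((rank - 0.5)/n) with mid-ranks on ties;
    a constant row maps to all zeros (logged).
    """
    x = study.values()
    n = x.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples for the inverse normal transform")
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        row = x[i]
        if np.ptp(row) == 0:
            log.warning("constant gene row %s -> zeros", study.genes[i])
            out[i] = 0.0
            continue
        ranks = stats.rankdata(row, method="average")
        out[i] = stats.norm.ppf((ranks - 0.5) / n)
    matrix = pd.DataFrame(out, index=study.genes, columns=study.samples)
    return ExpressionStudy(matrix, study.sample_meta)


def collapse_duplicates_median(study: ExpressionStudy, id_map: dict) -> ExpressionStudy:
    """Collapse multiple probes per gene to the element-wise median.

    ``id_map`` maps row (probe) ids to gene ids; rows without a mapping
    are dropped.
    """
    genes = study.matrix.index.map(lambda r: id_map.get(r))
    keep = genes.notna()
    if not keep.any():
        raise ValueError("id_map covers no rows of the matrix")
    collapsed = (
        study.matrix.loc[keep]
        .groupby(genes[keep])
        .median()
        .rename_axis("gene")
    )
    return ExpressionStudy(collapsed, study.sample_meta)


def preprocess_reference(
    study: ExpressionStudy, min_value: float = 0.1, min_individuals: int = 10
) -> ExpressionStudy:
    """Full preprocessing chain: filter, sample quantile normalization,
    per-gene inverse normal transform."""
    study = filter_expression(study, min_value, min_individuals)
    study = quantile_normalize_samples(study)
    return inverse_normal_transform_genes(study)
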