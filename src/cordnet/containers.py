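"""Core in-memory containers shared across the pipeline.

Expression data travel as an :class:`ExpressionStudy` (a genes x samples
DataFrame plus aligned per-sample metadata); module structure as a
:class:`ModulePartition` (gene labels, eigengenes, kME); permutation /
randomization tests as a :class:`NullEnsembleResult`.  Protein-interaction
networks are plain :class:`networkx.Graph` objects over gene identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Accepted values for the curated-record direction column.
DIRECTIONS = ("up", "down", "phospho")

#: Metadata columns every ExpressionStudy carries, aligned 1:1 with samples.
META_COLUMNS = ("study_id", "condition", "severity", "timepoint_days", "platform")


@dataclass
class ExpressionStudy:
    """A genes x samples expression matrix with per-sample metadata.

    Parameters
    ----------
    matrix
        Expression values, rows indexed by unique gene identifiers, columns
        by sample identifiers.
    sample_meta
        One row per sample (same order as ``matrix`` columns) with columns
        ``study_id, condition, severity, timepoint_days, platform``.
    """

    matrix: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.matrix.index.duplicated().any():
            dup = self.matrix.index[self.matrix.index.duplicated()][0]
            raise ValueError(f"duplicated gene identifier: {dup!r}")
        if list(self.matrix.columns) != list(self.sample_meta.index):
            raise ValueError("sample metadata rows must align 1:1 with matrix columns")
        missing = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns: {missing}")

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def samples(self) -> pd.Index:
        return self.matrix.columns

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def subset_genes(self, genes) -> "ExpressionStudy":
        return ExpressionStudy(self.matrix.loc[genes], self.sample_meta)

    def subset_samples(self, samples) -> "ExpressionStudy":
        return ExpressionStudy(self.matrix[samples], self.sample_meta.loc[samples])

    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)


@dataclass
class CuratedGeneSet:
    """Literature-curation records and the derived unique human gene set.

    ``records`` keeps one row per (study, gene) association with the original
    source accession, species, regulation direction, experimental technique,
    injury model and time point.  ``genes`` is the deduplicated set of human
    gene identifiers after ortholog mapping; ``study_counts`` maps each gene
    to the number of distinct studies implicating it.
    """

    records: pd.DataFrame
    genes: frozenset
    study_counts: pd.Series

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("curated gene set is empty after mapping/deduplication")
        if (self.study_counts < 1).any():
            raise ValueError("every curated gene must be supported by >= 1 study")

    def summary(self) -> dict:
        """Headline curation counts: unique genes, per-direction gene counts,
        and the number of genes implicated by more than one study.

        A gene counts toward a direction if any of its records carry it, so
        the per-direction counts may sum to more than the unique total.
        """
        rec = self.records[self.records["human_gene"].notna()]
        by_dir = {
            d: rec.loc[rec["direction"] == d, "human_gene"].nunique()
            for d in DIRECTIONS
        }
        return {
            "unique_genes": len(self.genes),
            "n_up": by_dir["up"],
            "n_down": by_dir["down"],
            "n_phospho": by_dir["phospho"],
            "n_multi_study": int((self.study_counts > 1).sum()),
        }


@dataclass
class OrthologTable:
    """One ortholog database: source-species gene id -> set of human gene ids."""

    database_name: str
    mapping: dict

    def __post_init__(self) -> None:
        empty = [k for k, v in self.mapping.items() if not v]
        for k in empty:  # never store empty target sets
            del self.mapping[k]


@dataclass
class ModulePartition:
    """Gene -> module assignment with eigengenes and kME.

    Labels are non-negative integers; 0 marks unassigned (background) genes.
    Eigengenes are unit-norm, oriented so the mean correlation with member
    genes is non-negative.
    """

    labels: pd.Series
    eigengenes: pd.DataFrame | None = None  # modules x samples
    kme: pd.DataFrame | None = None  # genes x modules
    prop_var_explained: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.labels < 0).any():
            raise ValueError("module labels must be >= 0")

    @property
    def module_ids(self) -> list:
        return sorted(int(m) for m in self.labels.unique() if m != 0)

    @property
    def sizes(self) -> dict:
        return {m: int((self.labels == m).sum()) for m in self.module_ids}

    def members(self, module: int) -> pd.Index:
        return self.labels.index[self.labels == module]


@dataclass
class NullEnsembleResult:
    """An observed statistic against a randomization null ensemble.

    The empirical p-value uses the add-one estimator
    ``(1 + #{null >= observed}) / (1 + N)`` so it is never zero and is
    bounded below by ``1/(N+1)`` — the convention behind reporting
    "p < 1e-3" from 1000 randomized networks.
    """

    observed: float
    null_values: np.ndarray

    @property
    def n_null(self) -> int:
        return len(self.null_values)

    @property
    def empirical_p(self) -> float:
        n_ge = int(np.sum(np.asarray(self.null_values) >= self.observed))
        return (1.0 + n_ge) / (1.0 + self.n_null)

    def summary(self) -> dict:
        nv = np.asarray(self.null_values, dtype=float)
        return {
            "observed": float(self.observed),
            "null_mean": float(nv.mean()),
            "null_sd": float(nv.std(ddof=1)) if len(nv) > 1 else 0.0,
            "empirical_p": self.empirical_p,
            "n_null": self.n_null,
        }


@dataclass
class AnnotationSet:
    """Gene-set annotations (GO-like terms, complexes, marker sets).

    ``terms`` maps term id -> frozenset of genes; ``categories`` maps term
    id -> category (e.g. an ontology namespace).  Complexes are represented
    with a single category.
    """

    terms: dict
    categories: dict

    def __post_init__(self) -> None:
        missing = set(self.terms) - set(self.categories)
        if missing:
            raise ValueError(f"terms without a category: {sorted(missing)[:3]}")

    def breadth(self, term: str) -> int:
        return len(self.terms[term])

    def in_category(self, category: str) -> dict:
        return {t: g for t, g in self.terms.items() if self.categories[t] == category}

    @property
    def universe(self) -> frozenset:
        out: set = set()
        for g in self.terms.values():
            out |= g
        return frozenset(out)


@dataclass
class CellTypeProfile:
    """Mean expression of each gene in each cell population."""

    profiles: pd.DataFrame  # genes x cell types, non-negative
    dataset: str = "transcriptomic"

    def __post_init__(self) -> None:
        if self.profiles.shape[1] < 2:
            raise ValueError("need >= 2 cell types")
        if (self.profiles.to_numpy() < 0).any():
            raise ValueError("cell-type profiles must be non-negative")

    @property
    def cell_types(self) -> pd.Index:
        return self.profiles.columns
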