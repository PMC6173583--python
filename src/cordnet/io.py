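"""Plain-text readers and writers for the pipeline's file formats.

Formats: expression TSV (genes as rows, header = sample ids), sample
metadata TSV, two-column edge lists with lexicographically ordered
endpoints, GMT gene sets, curated-set TSV, per-database ortholog TSVs and
a JSON ground-truth record for synthetic data.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import (
    DIRECTIONS,
    META_COLUMNS,
    AnnotationSet,
    ExpressionStudy,
    OrthologTable,
)

CURATED_COLUMNS = (
    "source_id",
    "species",
    "direction",
    "technique",
    "model",
    "timepoint",
    "study_id",
)


def write_expression(study: ExpressionStudy, expr_path, meta_path=None) -> None:
    study.matrix.to_csv(expr_path, sep="\t", index_label="gene")
    if meta_path is not None:
        meta = study.sample_meta.copy()
        meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_expression(expr_path, meta_path=None, study_id: str = "study") -> ExpressionStudy:
    matrix = pd.read_csv(expr_path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        meta.index = meta.index.astype(str)
        meta = meta.loc[list(matrix.columns)]
    else:
        meta = default_metadata(matrix.columns, study_id)
    return ExpressionStudy(matrix, meta)


def default_metadata(samples, study_id: str = "study") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "study_id": study_id,
            "condition": "unknown",
            "severity": np.nan,
            "timepoint_days": np.nan,
            "platform": "unknown",
        },
        index=pd.Index(samples, name="sample_id"),
        columns=list(META_COLUMNS),
    )


def write_edge_list(graph: nx.Graph, path) -> None:
    """Write edges as two tab-separated columns, endpoints sorted within each
    edge and edges sorted lexicographically."""
    edges = sorted(tuple(sorted(map(str, e))) for e in graph.edges())
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def read_edge_list(path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", dtype=str)
    g = nx.Graph()
    g.add_edges_from(df.itertuples(index=False, name=None))
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def write_gmt(sets: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            desc = (descriptions or {}).get(name, "na")
            genes = "\t".join(sorted(map(str, sets[name])))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def read_gmt(path) -> dict:
    out: dict = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            out[parts[0]] = frozenset(p for p in parts[2:] if p)
    return out


def write_annotations(annotations: AnnotationSet, path) -> None:
    """AnnotationSet as GMT, with the category stored in the description field."""
    write_gmt(annotations.terms, path, descriptions=annotations.categories)


def read_annotations(path) -> AnnotationSet:
    terms: dict = {}
    categories: dict = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            terms[parts[0]] = frozenset(p for p in parts[2:] if p)
            categories[parts[0]] = parts[1]
    return AnnotationSet(terms, categories)


def write_curated_table(records: pd.DataFrame, path) -> None:
    records.loc[:, list(CURATED_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_curated_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CURATED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"curated table missing required column(s): {missing}")
    bad = set(df["direction"].unique()) - set(DIRECTIONS)
    if bad:
        raise ValueError(f"unknown direction value(s): {sorted(bad)}")
    return df


def write_ortholog_table(table: OrthologTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("source_id\thuman_gene\n")
        for src in sorted(table.mapping):
            for tgt in sorted(table.mapping[src]):
                fh.write(f"{src}\t{tgt}\n")


def read_ortholog_table(path, database_name: str | None = None) -> OrthologTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    mapping: dict = {}
    for src, tgt in df.itertuples(index=False, name=None):
        mapping.setdefault(src, set()).add(tgt)
    name = database_name or Path(path).stem
    return OrthologTable(name, mapping)


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("module").to_csv(path, sep="\t", index_label="gene")


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    s = df["module"].astype(int)
    s.index = s.index.astype(str)
    return s


def write_truth(truth_dict: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth_dict, fh, indent=1, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"cannot serialize {type(obj)}")
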