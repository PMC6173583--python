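"""Synthetic study generator with planted, recoverable structure.

The generator emulates the inputs of a systems-level spinal cord injury
(SCI) analysis: a healthy reference expression matrix with planted
coexpression modules, a panel of injured-vs-sham test studies sharing the
module structure, a heavy-tailed protein interactome containing a densely
wired planted neighborhood, GO-like annotations / complexes / cell-type
profiles, and a literature-curated gene set seeded from the planted
modules with a controlled false-positive rate.

Coexpression follows a single-latent-factor model per module:

    x_gs = lambda_g * e_{m(g),s} + eps_gs

with ``lambda_g = module_signal`` for module genes and 0 for background,
module eigengenes ``e_m`` i.i.d. standard normal across samples, and
``eps ~ N(0, noise_sd^2)``.  In injured samples the module eigengene mean
is shifted by ``de_effect[m] * severity/max(severity)``, so differential
expression scales linearly with injury severity; a designated module can
flip its effect sign between the most acute and the most chronic time
point, emulating modules involved in the acute-to-chronic transition.

Every output object draws from its own RNG stream spawned from
``rng_seed``, so generating one output never perturbs another, and the
seed fully determines all outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .containers import (
    AnnotationSet,
    CellTypeProfile,
    CuratedGeneSet,
    ExpressionStudy,
    OrthologTable,
)
from .io import default_metadata

SPECIES = ("rat", "mouse", "rabbit", "human")
TECHNIQUES = ("western blot", "qPCR", "IHC", "ELISA", "2D gel")
MODELS = ("contusion", "transection", "compression", "hemisection")
TIMEPOINT_LABELS = ("1 h", "24 h", "3 d", "7 d", "28 d", "6 mo")

# spawn keys: one RNG stream per output object
_STREAM = {
    "reference": 0,
    "test_studies": 1,
    "interactome": 2,
    "annotations": 3,
    "curated": 4,
    "orthologs": 5,
    "treatment": 6,
    "curated_records": 7,
}


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with study-condition defaults.

    Defaults mirror the analysis setting: a 71-sample reference (the size
    of the healthy human spinal cord cohort), five test studies, severity
    graded as 0/100/200 (kdyn of impact force), time points at 1/3/7/28
    days, and five planted modules of which two respond up, one down, one
    flips sign over time and one is null.
    """

    n_genes: int = 1000
    module_sizes: tuple = (60, 50, 50, 40, 40)
    n_samples_ref: int = 71
    n_test_studies: int = 5
    samples_per_study: int = 20
    module_signal: float | tuple = 0.9
    loading_range: tuple = (0.6, 1.0)
    noise_sd: float = 0.2
    severity_levels: tuple = (0.0, 100.0, 200.0)
    severity_coupled_module: int | None = 0
    severity_exclusive: bool = False
    de_effect: tuple | float | None = None
    sign_flip_module: int | None | str = "auto"
    flip_effect: float = 2.0
    timepoints: tuple = (1.0, 3.0, 7.0, 28.0)
    seed_gene_fraction: float = 0.7
    fp_rate: float = 0.3
    curated_size: int = 120
    curated_target_modules: tuple | str = "auto"
    interactome_degree_exponent: float = 2.5
    planted_subgraph_density: float = 0.2
    n_terms: int = 120
    annotation_concordance: float = 0.5
    n_complexes: int = 60
    complex_tp_fraction: float = 0.4
    n_cell_types: int = 5
    celltype_marker_module: int = 0
    marker_fold: float = 8.0
    ortholog_n_databases: int = 7
    ortholog_presence: float = 0.85
    ortholog_error_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "module_sizes", tuple(self.module_sizes))
        object.__setattr__(self, "severity_levels", tuple(self.severity_levels))
        object.__setattr__(self, "timepoints", tuple(self.timepoints))
        nm = len(self.module_sizes)
        # default injury pattern: up, down, up, up, time-flip, then null
        if self.de_effect is None:
            pattern = (2.0, -2.0, 2.0, 2.0, 0.0)
            eff = tuple(pattern[m] if m < len(pattern) else 0.0 for m in range(nm))
        else:
            eff = tuple(np.atleast_1d(np.asarray(self.de_effect, dtype=float)))
            if len(eff) == 1:
                eff = eff * nm
        object.__setattr__(self, "de_effect", eff)
        if self.sign_flip_module == "auto":
            object.__setattr__(self, "sign_flip_module", 4 if nm >= 5 else None)
        if self.curated_target_modules == "auto":
            object.__setattr__(
                self, "curated_target_modules", (0, 2) if nm >= 3 else (0,)
            )
        object.__setattr__(
            self, "curated_target_modules", tuple(self.curated_target_modules)
        )
        self._validate()

    # per-module signal as an array aligned with module_sizes
    @property
    def signal(self) -> np.ndarray:
        sig = np.broadcast_to(
            np.atleast_1d(np.asarray(self.module_signal, dtype=float)),
            (self.n_modules,),
        )
        return np.array(sig, dtype=float)

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def effects(self) -> np.ndarray:
        eff = np.broadcast_to(
            np.atleast_1d(np.asarray(self.de_effect, dtype=float)), (self.n_modules,)
        )
        return np.array(eff, dtype=float)

    def _validate(self) -> None:
        def bad(fieldname: str, why: str):
            raise ConfigurationError(f"{fieldname}: {why}")

        if self.n_genes < 1:
            bad("n_genes", "must be positive")
        if any(s < 1 for s in self.module_sizes):
            bad("module_sizes", "all module sizes must be positive")
        if sum(self.module_sizes) > self.n_genes:
            bad("module_sizes", "sum of module sizes exceeds n_genes")
        if self.n_samples_ref < 4:
            bad("n_samples_ref", "need >= 4 reference samples")
        if self.n_test_studies < 1:
            bad("n_test_studies", "need >= 1 test study")
        if self.samples_per_study < 4:
            bad("samples_per_study", "need >= 4 samples per study")
        if np.any(self.signal < 0) or np.any(self.signal > 1):
            bad("module_signal", "loadings must lie in [0, 1]")
        lo, hi = self.loading_range
        if not (0 < lo <= hi <= 1):
            bad("loading_range", "need 0 < low <= high <= 1")
        if not self.noise_sd > 0:
            bad("noise_sd", "must be positive")
        if np.any(np.diff(self.severity_levels) <= 0):
            bad("severity_levels", "must be strictly increasing")
        if len(self.effects) != self.n_modules:
            bad("de_effect", "length must match module_sizes")
        for frac_name in ("seed_gene_fraction", "fp_rate", "planted_subgraph_density",
                          "annotation_concordance", "complex_tp_fraction",
                          "ortholog_presence", "ortholog_error_rate"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                bad(frac_name, "must lie in [0, 1]")
        if self.seed_gene_fraction + self.fp_rate > 1.0 + 1e-12:
            bad("seed_gene_fraction", "seed_gene_fraction + fp_rate must be <= 1")
        if not self.interactome_degree_exponent > 0:
            bad("interactome_degree_exponent", "must be positive")
        if self.curated_size < 1 or self.curated_size > self.n_genes:
            bad("curated_size", "must be between 1 and n_genes")
        for idx_name in ("severity_coupled_module", "sign_flip_module",
                         "celltype_marker_module"):
            v = getattr(self, idx_name)
            if v is not None and not 0 <= v < self.n_modules:
                bad(idx_name, "module index out of range")
        if any(not 0 <= m < self.n_modules for m in self.curated_target_modules):
            bad("curated_target_modules", "module index out of range")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.rng_seed, spawn_key=(_STREAM[stream],))
        )

    def with_seed(self, rng_seed: int) -> "SimulationConfig":
        return replace(self, rng_seed=rng_seed)


@dataclass
class SyntheticTruth:
    """Immutable record of what was planted (labels use 1..M, 0=background)."""

    labels: pd.Series
    loadings: pd.Series
    curated_genes: tuple
    curated_is_tp: tuple
    planted_members: frozenset
    de_direction: dict  # module label -> {-1, 0, +1}
    severity_coupled_module: int | None
    sign_flip_module: int | None
    target_modules: tuple

    def module_members(self, module: int) -> pd.Index:
        return self.labels.index[self.labels == module]

    def as_dict(self) -> dict:
        return {
            "labels": self.labels.to_dict(),
            "loadings": self.loadings.round(6).to_dict(),
            "curated_genes": list(self.curated_genes),
            "curated_is_tp": [bool(b) for b in self.curated_is_tp],
            "planted_members": sorted(self.planted_members),
            "de_direction": {int(k): int(v) for k, v in self.de_direction.items()},
            "severity_coupled_module": self.severity_coupled_module,
            "sign_flip_module": self.sign_flip_module,
            "target_modules": list(self.target_modules),
        }


def gene_ids(n: int) -> pd.Index:
    return pd.Index([f"g{i:04d}" for i in range(n)], name="gene")


def _module_labels(config: SimulationConfig) -> pd.Series:
    labels = np.zeros(config.n_genes, dtype=int)
    start = 0
    for m, size in enumerate(config.module_sizes, start=1):
        labels[start : start + size] = m
        start += size
    return pd.Series(labels, index=gene_ids(config.n_genes))


def _draw_loadings(
    config: SimulationConfig, labels: pd.Series, rng: np.random.Generator
) -> pd.Series:
    """Per-gene loadings: module_signal[m] scaled by a uniform draw from
    loading_range for module genes (hub gradient), 0 for background."""
    lam = np.zeros(config.n_genes)
    lab = labels.to_numpy()
    lo, hi = config.loading_range
    for m in range(1, config.n_modules + 1):
        rows = lab == m
        lam[rows] = config.signal[m - 1] * rng.uniform(lo, hi, size=rows.sum())
    return pd.Series(lam, index=labels.index)


def _factor_matrix(
    config: SimulationConfig,
    labels: pd.Series,
    loadings: pd.Series,
    eigengenes: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """x = lambda_g * e_m + eps for module genes, eps alone for background."""
    n_samples = eigengenes.shape[1]
    x = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    lab = labels.to_numpy()
    lam = loadings.to_numpy()
    for m in range(1, config.n_modules + 1):
        rows = lab == m
        x[rows, :] += lam[rows, None] * eigengenes[m - 1]
    return x


def generate_reference_expression(
    config: SimulationConfig,
) -> tuple[ExpressionStudy, SyntheticTruth]:
    """Healthy reference cohort plus the immutable ground truth.

    The truth also fixes the composition of the curated gene set (true
    positives drawn from the target modules) and thereby the planted
    interactome neighborhood, so that all downstream generators agree.
    """
    rng = config.rng("reference")
    labels = _module_labels(config)
    loadings = _draw_loadings(config, labels, rng)
    eig = rng.standard_normal((config.n_modules, config.n_samples_ref))
    x = _factor_matrix(config, labels, loadings, eig, rng)
    samples = [f"ref{j:03d}" for j in range(config.n_samples_ref)]
    matrix = pd.DataFrame(x, index=labels.index, columns=samples)
    meta = default_metadata(samples, "reference")
    meta["condition"] = "healthy"
    meta["severity"] = 0.0
    meta["platform"] = "rnaseq"

    # curated composition: true positives from the target modules, the rest
    # uniform false positives
    crng = config.rng("curated")
    pool_tp = np.concatenate(
        [labels.index[labels == m + 1].to_numpy() for m in config.curated_target_modules]
    )
    n_tp = min(int(round(config.curated_size * config.seed_gene_fraction)), len(pool_tp))
    n_fp = config.curated_size - n_tp
    tp = crng.choice(pool_tp, size=n_tp, replace=False)
    pool_fp = labels.index.difference(pd.Index(tp)).to_numpy()
    fp = crng.choice(pool_fp, size=min(n_fp, len(pool_fp)), replace=False)
    curated = tuple(map(str, np.concatenate([tp, fp])))
    is_tp = tuple([True] * len(tp) + [False] * len(fp))

    de_dir = {m + 1: int(np.sign(config.effects[m])) for m in range(config.n_modules)}
    truth = SyntheticTruth(
        labels=labels,
        loadings=loadings,
        curated_genes=curated,
        curated_is_tp=is_tp,
        planted_members=frozenset(map(str, tp)),
        de_direction=de_dir,
        severity_coupled_module=(
            None
            if config.severity_coupled_module is None
            else config.severity_coupled_module + 1
        ),
        sign_flip_module=(
            None if config.sign_flip_module is None else config.sign_flip_module + 1
        ),
        target_modules=tuple(m + 1 for m in config.curated_target_modules),
    )
    return ExpressionStudy(matrix, meta), truth


def _timepoint_sign(config: SimulationConfig, module_idx: int, timepoint: float) -> float:
    """Effect-sign modifier: the designated flip module is suppressed at the
    most acute time point and induced at the most chronic one."""
    if config.sign_flip_module is None or module_idx != config.sign_flip_module:
        return 1.0
    if timepoint == min(config.timepoints):
        return -1.0
    if timepoint == max(config.timepoints):
        return 1.0
    return 0.0


def generate_test_studies(
    config: SimulationConfig, truth: SyntheticTruth
) -> list[ExpressionStudy]:
    """Injured-vs-sham studies sharing the reference module structure.

    Each study alternates sham and injured samples across time points;
    injured samples cycle through the nonzero severity levels.  The
    module-m eigengene of an injured sample is shifted by
    ``de_effect[m] * severity/max(severity)`` (times the time-point sign
    modifier for the designated flip module).
    """
    rng = config.rng("test_studies")
    max_sev = max(config.severity_levels)
    nonzero = [s for s in config.severity_levels if s > 0] or [max_sev]
    studies = []
    for s_idx in range(config.n_test_studies):
        n = config.samples_per_study
        sample_ids = [f"st{s_idx}_s{j:03d}" for j in range(n)]
        conditions, severities, tps = [], [], []
        sev_cycle = itertools.cycle(nonzero)
        tp_cycle = itertools.cycle(config.timepoints)
        for j in range(n):
            injured = j % 2 == 1
            conditions.append("injured" if injured else "sham")
            severities.append(next(sev_cycle) if injured else 0.0)
            if j % 2 == 0:
                current_tp = next(tp_cycle)
            tps.append(current_tp)
        eig = rng.standard_normal((config.n_modules, n))
        if config.severity_exclusive:
            # severity-cohort design: modules planted as non-responsive have
            # their eigengene residualized against severity, so severity
            # signal lives exclusively in the responsive modules
            sev_vec = np.asarray(severities, dtype=float)
            sev_c = sev_vec - sev_vec.mean()
            denom = float(sev_c @ sev_c)
            if denom > 0:
                for m in range(config.n_modules):
                    if config.effects[m] == 0.0 and not (
                        config.sign_flip_module is not None
                        and m == config.sign_flip_module
                    ):
                        eig[m] -= (eig[m] @ sev_c) / denom * sev_c
        for m in range(config.n_modules):
            base = (
                config.flip_effect
                if config.sign_flip_module is not None and m == config.sign_flip_module
                else config.effects[m]
            )
            for j in range(n):
                if conditions[j] == "injured":
                    sign = _timepoint_sign(config, m, tps[j])
                    eig[m, j] += base * severities[j] / max_sev * sign
        x = _factor_matrix(config, truth.labels, truth.loadings, eig, rng)
        matrix = pd.DataFrame(x, index=truth.labels.index, columns=sample_ids)
        meta = default_metadata(sample_ids, f"study{s_idx}")
        meta["condition"] = conditions
        meta["severity"] = severities
        meta["timepoint_days"] = tps
        meta["platform"] = "microarray"
        studies.append(ExpressionStudy(matrix, meta))
    return studies


def generate_treatment_pair(
    config: SimulationConfig, truth: SyntheticTruth, reversal: float = 1.0
) -> tuple[ExpressionStudy, ExpressionStudy]:
    """A treated/control pair for recovery analyses.

    Both arms are injured at maximal severity; the treatment arm's injury
    shift is scaled by ``1 - reversal``, so ``reversal=1`` fully normalizes
    module expression (a treatment that reverses the injury signature) and
    ``reversal=0`` is indistinguishable from the control arm.
    """
    rng = config.rng("treatment")
    n = config.samples_per_study
    out = []
    for arm, scale in (("treated", 1.0 - reversal), ("control", 1.0)):
        sample_ids = [f"{arm}_s{j:03d}" for j in range(n)]
        eig = rng.standard_normal((config.n_modules, n))
        for m in range(config.n_modules):
            eig[m, :] += config.effects[m] * scale
        x = _factor_matrix(config, truth.labels, truth.loadings, eig, rng)
        matrix = pd.DataFrame(x, index=truth.labels.index, columns=sample_ids)
        meta = default_metadata(sample_ids, f"nt3_{arm}")
        meta["condition"] = arm
        meta["severity"] = max(config.severity_levels)
        meta["timepoint_days"] = max(config.timepoints)
        meta["platform"] = "microarray"
        out.append(ExpressionStudy(matrix, meta))
    return out[0], out[1]


def _powerlaw_degrees(
    n: int, exponent: float, rng: np.random.Generator, k_min: int = 1
) -> np.ndarray:
    """Discrete heavy-tailed degree sequence (Pareto tail, capped, even sum)."""
    u = rng.random(n)
    k = np.floor(k_min * (1.0 - u) ** (-1.0 / (exponent - 1.0))).astype(int)
    k = np.clip(k, k_min, max(k_min + 1, n // 4))
    if k.sum() % 2 == 1:
        k[int(np.argmax(k))] += 1
    return k


def generate_interactome(
    config: SimulationConfig, truth: SyntheticTruth
) -> nx.Graph:
    """Configuration-model interactome with a densely wired planted set.

    Nodes are the gene universe; degrees follow a power law with the
    configured exponent.  Edges among the curated true positives are added
    until the planted subgraph reaches ``planted_subgraph_density``.
    Self-loops and parallel edges are removed.
    """
    rng = config.rng("interactome")
    genes = list(map(str, gene_ids(config.n_genes)))
    degrees = _powerlaw_degrees(
        config.n_genes, config.interactome_degree_exponent, rng
    )
    g_multi = nx.configuration_model(degrees.tolist(), seed=int(rng.integers(2**31)))
    g = nx.Graph(g_multi)
    g.remove_edges_from(nx.selfloop_edges(g))
    g = nx.relabel_nodes(g, dict(enumerate(genes)))

    members = sorted(truth.planted_members)
    k = len(members)
    if k >= 2 and config.planted_subgraph_density > 0:
        n_pairs = k * (k - 1) // 2
        target = int(round(config.planted_subgraph_density * n_pairs))
        if target > n_pairs:
            raise ConfigurationError(
                "planted_subgraph_density: infeasible for planted subgraph size"
            )
        have = {frozenset(e) for e in g.subgraph(members).edges()}
        absent = [
            (a, b)
            for a, b in itertools.combinations(members, 2)
            if frozenset((a, b)) not in have
        ]
        n_add = max(0, target - len(have))
        if n_add > 0:
            idx = rng.choice(len(absent), size=min(n_add, len(absent)), replace=False)
            g.add_edges_from(absent[i] for i in idx)
    return g


@dataclass
class SyntheticAnnotations:
    """Bundle of GO-like terms, protein complexes and cell-type profiles."""

    go: AnnotationSet
    complexes: dict  # complex id -> frozenset of genes
    cell_profiles: CellTypeProfile
    marker_cell_type: str


# term breadth classes (genes/term), spanning specific to broad annotations
BREADTH_CLASSES = ((5, 15), (16, 60), (61, 200))


def generate_annotations(
    config: SimulationConfig, truth: SyntheticTruth
) -> SyntheticAnnotations:
    """GO-like terms across three categories, complexes, cell-type profiles.

    A fraction ``annotation_concordance`` of terms is module-concordant
    (80% of its genes from one planted module); complexes are enriched for
    curated true positives; one cell type over-expresses the designated
    marker module's genes by ``marker_fold``.
    """
    rng = config.rng("annotations")
    genes = truth.labels.index.to_numpy()
    categories = ("BP", "CC", "MF")
    terms: dict = {}
    cats: dict = {}
    module_lists = {
        m: truth.module_members(m).to_numpy() for m in range(1, config.n_modules + 1)
    }
    for t in range(config.n_terms):
        lo, hi = BREADTH_CLASSES[t % len(BREADTH_CLASSES)]
        size = int(rng.integers(lo, min(hi, config.n_genes) + 1))
        concordant = rng.random() < config.annotation_concordance
        if concordant:
            m = int(rng.integers(1, config.n_modules + 1))
            pool = module_lists[m]
            n_in = min(int(np.ceil(0.8 * size)), len(pool))
            chosen = set(rng.choice(pool, size=n_in, replace=False))
            rest = np.setdiff1d(genes, list(chosen), assume_unique=False)
            chosen |= set(rng.choice(rest, size=size - n_in, replace=False))
        else:
            chosen = set(rng.choice(genes, size=size, replace=False))
        name = f"T{t:04d}"
        terms[name] = frozenset(map(str, chosen))
        cats[name] = categories[t % 3]

    tp = sorted(truth.planted_members)
    complexes: dict = {}
    for c in range(config.n_complexes):
        size = int(rng.integers(2, 9))
        if tp and rng.random() < config.complex_tp_fraction:
            n_in = min(size, len(tp))
            chosen = set(rng.choice(tp, size=n_in, replace=False))
            if size > n_in:
                rest = np.setdiff1d(genes, list(chosen))
                chosen |= set(rng.choice(rest, size=size - n_in, replace=False))
        else:
            chosen = set(rng.choice(genes, size=size, replace=False))
        complexes[f"C{c:03d}"] = frozenset(map(str, chosen))

    ct_names = [f"celltype{c}" for c in range(config.n_cell_types)]
    profiles = pd.DataFrame(
        rng.lognormal(mean=1.0, sigma=0.5, size=(config.n_genes, config.n_cell_types)),
        index=truth.labels.index,
        columns=ct_names,
    )
    marker_ct = ct_names[0]
    if config.celltype_marker_module is not None:
        mod = config.celltype_marker_module + 1
        profiles.loc[truth.module_members(mod), marker_ct] *= config.marker_fold
    return SyntheticAnnotations(
        go=AnnotationSet(terms, cats),
        complexes=complexes,
        cell_profiles=CellTypeProfile(profiles),
        marker_cell_type=marker_ct,
    )


def generate_curated_set(
    config: SimulationConfig, truth: SyntheticTruth
) -> tuple[CuratedGeneSet, pd.DataFrame]:
    """Curation records for the genes fixed in the ground truth.

    Returns the parsed :class:`CuratedGeneSet` plus the raw record table
    (the on-disk schema), whose source accessions are species-prefixed ids
    resolvable through the synthetic ortholog tables.
    """
    rng = config.rng("curated_records")
    rows = []
    study_pool = [f"S{j:02d}" for j in range(40)]
    for gene, is_tp in zip(truth.curated_genes, truth.curated_is_tp):
        n_rec = min(int(rng.geometric(0.7)), 4)
        studies = rng.choice(study_pool, size=n_rec, replace=False)
        for sid in studies:
            species = SPECIES[int(rng.integers(0, len(SPECIES)))]
            source = gene if species == "human" else f"{species}:{gene}"
            direction = rng.choice(
                ["up", "down", "phospho"], p=[0.72, 0.27, 0.01]
            )
            rows.append(
                {
                    "source_id": source,
                    "species": species,
                    "direction": direction,
                    "technique": str(rng.choice(TECHNIQUES)),
                    "model": str(rng.choice(MODELS)),
                    "timepoint": str(rng.choice(TIMEPOINT_LABELS)),
                    "study_id": str(sid),
                    "human_gene": gene,
                }
            )
    records = pd.DataFrame(rows)
    counts = records.groupby("human_gene")["study_id"].nunique()
    counts = counts.reindex(list(truth.curated_genes))
    curated = CuratedGeneSet(
        records=records,
        genes=frozenset(truth.curated_genes),
        study_counts=counts,
    )
    table = records.drop(columns=["human_gene"])
    return curated, table


def generate_ortholog_tables(
    config: SimulationConfig, truth: SyntheticTruth
) -> list[OrthologTable]:
    """Per-database ortholog maps for the species-prefixed source ids.

    Each database carries an entry for a given (species, gene) pair with
    probability ``ortholog_presence``; with probability
    ``ortholog_error_rate`` the entry points to a random wrong human gene.
    """
    rng = config.rng("orthologs")
    genes = list(map(str, truth.labels.index))
    tables = []
    for d in range(config.ortholog_n_databases):
        mapping: dict = {}
        for species in SPECIES:
            if species == "human":
                continue
            for gene in genes:
                if rng.random() >= config.ortholog_presence:
                    continue
                if rng.random() < config.ortholog_error_rate:
                    target = genes[int(rng.integers(len(genes)))]
                else:
                    target = gene
                mapping[f"{species}:{gene}"] = {target}
        tables.append(OrthologTable(f"db{d}", mapping))
    return tables
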