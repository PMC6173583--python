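"""Validation of a gene set against a protein-interaction network.

Observed statistics (number of interactions within the set, size of its
largest connected component) are compared with ensembles of
degree-preserving randomized networks; co-complex and shared-annotation
statistics with random gene sets of equal size.  Empirical p-values use
the add-one estimator, so 1000 nulls bound p below by 1/1001 — the
convention behind "p < 1e-3".  Candidate disease genes are prioritized by
iterative hypergeometric connectivity to the seed set (the plain,
unweighted DIAMOnD scheme).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .containers import AnnotationSet, NullEnsembleResult

log = logging.getLogger(__name__)


def _present(net: nx.Graph, genes) -> list:
    present = sorted(set(genes) & set(net.nodes), key=str)
    dropped = len(set(genes)) - len(present)
    if dropped:
        log.info("%d gene(s) absent from the network were dropped", dropped)
    if not present:
        raise ValueError("gene set has no overlap with the network nodes")
    return present


def count_set_interactions(net: nx.Graph, genes) -> int:
    """Number of edges with both endpoints in the gene set."""
    members = _present(net, genes)
    return int(net.subgraph(members).number_of_edges())


def largest_component_size(net: nx.Graph, genes) -> int:
    members = _present(net, genes)
    sub = net.subgraph(members)
    if sub.number_of_nodes() == 0:
        return 0
    return max(len(c) for c in nx.connected_components(sub))


def rewire_degree_preserving(
    net: nx.Graph, n_swaps: int | None = None, rng_seed: int = 0
) -> nx.Graph:
    """Degree-preserving randomization by repeated double edge swaps.

    Performs ``n_swaps`` successful swaps (default ``10 * |E|``), always
    keeping the graph simple.  If no legal swap can be found the input is
    returned unchanged with a warning.
    """
    if net.number_of_edges() < 2:
        raise ValueError("need >= 2 edges to rewire")
    rng = np.random.default_rng(rng_seed)
    g = net.copy()
    edges = [tuple(e) for e in g.edges()]
    edge_set = {frozenset(e) for e in edges}
    n_target = 10 * len(edges) if n_swaps is None else int(n_swaps)
    done = 0
    attempts = 0
    max_attempts = 100 * max(n_target, 1)
    m = len(edges)
    while done < n_target and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        e1, e2 = frozenset((a, d)), frozenset((c, b))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = (a, d)
        edges[j] = (c, b)
        done += 1
    if done == 0:
        log.warning("no legal double edge swap found; returning input graph")
        return net.copy()
    out = nx.Graph()
    out.add_nodes_from(g.nodes())
    out.add_edges_from(edges)
    return out


def _null_ensemble(
    net: nx.Graph,
    genes,
    statistic,
    n_null: int,
    rng_seed: int,
    n_swaps: int | None,
) -> NullEnsembleResult:
    observed = statistic(net, genes)
    seeds = np.random.SeedSequence(rng_seed).generate_state(n_null)
    nulls = np.array(
        [
            statistic(rewire_degree_preserving(net, n_swaps, int(s)), genes)
            for s in seeds
        ],
        dtype=float,
    )
    return NullEnsembleResult(float(observed), nulls)


def interaction_enrichment(
    net: nx.Graph,
    genes,
    n_null: int = 1000,
    rng_seed: int = 0,
    n_swaps: int | None = None,
) -> NullEnsembleResult:
    """Within-set interaction count vs degree-preserving rewired networks."""
    return _null_ensemble(
        net, genes, count_set_interactions, n_null, rng_seed, n_swaps
    )


def lcc_significance(
    net: nx.Graph,
    genes,
    n_null: int = 1000,
    rng_seed: int = 0,
    n_swaps: int | None = None,
) -> NullEnsembleResult:
    """Largest-connected-component size vs degree-preserving nulls."""
    return _null_ensemble(
        net, genes, largest_component_size, n_null, rng_seed, n_swaps
    )


def count_cocomplex_pairs(complexes: dict, genes) -> int:
    """Unordered pairs of set genes sharing at least one complex."""
    membership: dict = {}
    for cid, members in complexes.items():
        for g in members:
            membership.setdefault(g, set()).add(cid)
    genes = sorted(set(genes))
    count = 0
    for a, b in itertools.combinations(genes, 2):
        if membership.get(a, set()) & membership.get(b, set()):
            count += 1
    return count


def cocomplex_test(
    complexes: dict, genes, n_draws: int = 1000, rng_seed: int = 0
) -> NullEnsembleResult:
    """Co-complex pair count vs uniformly drawn random sets of equal size
    from the complex universe."""
    if not complexes:
        raise ValueError("no complexes provided")
    universe = sorted({g for members in complexes.values() for g in members})
    genes = sorted(set(genes))
    if len(genes) > len(universe):
        raise ValueError("gene set larger than the complex universe")
    observed = count_cocomplex_pairs(complexes, genes)
    rng = np.random.default_rng(rng_seed)
    nulls = np.array(
        [
            count_cocomplex_pairs(
                complexes, rng.choice(universe, size=len(genes), replace=False)
            )
            for _ in range(n_draws)
        ],
        dtype=float,
    )
    return NullEnsembleResult(float(observed), nulls)


def mean_shared_terms(terms: dict, genes, cutoff: float) -> float:
    """Mean over gene pairs of the number of shared terms, restricted to
    terms annotated to at most ``cutoff`` genes."""
    eligible = [t for t, members in terms.items() if len(members) <= cutoff]
    genes = sorted(set(genes))
    n = len(genes)
    if n < 2:
        raise ValueError("need >= 2 genes")
    gene_pos = {g: i for i, g in enumerate(genes)}
    total = 0
    for t in eligible:
        k = sum(1 for g in terms[t] if g in gene_pos)
        total += k * (k - 1) // 2
    return total / (n * (n - 1) / 2)


def shared_annotation_test(
    annotations: AnnotationSet,
    genes,
    breadth_cutoffs=(100, 1000, math.inf),
    n_null: int = 1000,
    rng_seed: int = 0,
) -> dict:
    """Per-(category, breadth cutoff) enrichment of shared annotations.

    The statistic is the mean shared-term count over gene pairs; nulls are
    random gene sets of equal size drawn from the annotation universe.
    """
    if not breadth_cutoffs:
        raise ValueError("breadth cutoff list is empty")
    universe = sorted(annotations.universe)
    genes = sorted(set(genes) & set(universe))
    if len(genes) < 2:
        raise ValueError("gene set has < 2 genes in the annotation universe")
    rng = np.random.default_rng(rng_seed)
    results: dict = {}
    categories = sorted(set(annotations.categories.values()))
    null_sets = [
        rng.choice(universe, size=len(genes), replace=False) for _ in range(n_null)
    ]
    for cat in categories:
        terms = annotations.in_category(cat)
        for cutoff in breadth_cutoffs:
            observed = mean_shared_terms(terms, genes, cutoff)
            nulls = np.array(
                [mean_shared_terms(terms, ns, cutoff) for ns in null_sets]
            )
            results[(cat, cutoff)] = NullEnsembleResult(observed, nulls)
    return results


@dataclass
class DiamondResult:
    added: list  # (gene, connectivity p) in order of addition


def _hypergeom_sf(k_s: int, n_total: int, n_seeds: int, degree: int) -> float:
    # P(X >= k_s) for X ~ Hypergeom(N=n_total, K=n_seeds, n=degree)
    return float(stats.hypergeom.sf(k_s - 1, n_total, n_seeds, degree))


def diamond_rank(net: nx.Graph, seeds, n_iter: int) -> list:
    """Iterative seed-set expansion by hypergeometric connectivity.

    At each step the non-seed node with the most significant number of
    links to the current seed set (given its degree) is added.  Ties break
    by higher seed-link count, then lexicographic id.  Returns the ordered
    list of (gene, connectivity p).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    seeds = set(seeds) & set(net.nodes)
    if not seeds:
        raise ValueError("no seed genes present in the network")
    n_total = net.number_of_nodes()
    degree = dict(net.degree())
    ks = {}  # candidate -> links to seed set
    for s in seeds:
        for nb in net.neighbors(s):
            if nb not in seeds:
                ks[nb] = ks.get(nb, 0) + 1
    added = []
    for _ in range(n_iter):
        if not ks:
            log.info("no candidate connected to the seed set; stopping early")
            break
        cands = sorted(ks, key=str)
        pvals = stats.hypergeom.sf(
            np.array([ks[c] for c in cands]) - 1,
            n_total,
            len(seeds),
            np.array([degree[c] for c in cands]),
        )
        order = sorted(
            range(len(cands)), key=lambda i: (pvals[i], -ks[cands[i]], str(cands[i]))
        )
        best = cands[order[0]]
        added.append((best, float(pvals[order[0]])))
        seeds.add(best)
        del ks[best]
        for nb in net.neighbors(best):
            if nb not in seeds:
                ks[nb] = ks.get(nb, 0) + 1
    return added


@dataclass
class RecoveryResult:
    """Bootstrapped seed-withholding recovery versus a random control."""

    recovery_curves: np.ndarray  # n_boot x n_iter cumulative fractions
    control_curves: np.ndarray
    ks_statistic: float
    ks_p: float

    @property
    def mean_recovery(self) -> np.ndarray:
        return self.recovery_curves.mean(axis=0)

    @property
    def mean_control(self) -> np.ndarray:
        return self.control_curves.mean(axis=0)


def _recovery_ranks(net, seed_genes, targets, n_iter):
    """Iteration index (1-based) at which each target is recovered;
    unrecovered targets get n_iter + 1."""
    ranking = [g for g, _ in diamond_rank(net, seed_genes, n_iter)]
    pos = {g: i + 1 for i, g in enumerate(ranking)}
    return np.array([pos.get(t, n_iter + 1) for t in targets], dtype=float)


def diamond_recovery(
    net: nx.Graph,
    genes,
    withhold_frac: float = 0.2,
    n_iter: int = 1000,
    n_boot: int = 1000,
    rng_seed: int = 0,
) -> RecoveryResult:
    """Withhold a fraction of the gene set, expand from the remainder, and
    measure how early the withheld genes are recovered.

    The control recovers random target sets from random seed sets of the
    same sizes.  Recovery-rank distributions (pooled over bootstraps) are
    compared with a one-sided two-sample KS test (alternative: withheld
    genes are recovered earlier than control targets).
    """
    members = _present(net, genes)
    if len(members) < 5:
        raise ValueError("need >= 5 genes for recovery analysis")
    n_withhold = int(np.floor(withhold_frac * len(members)))
    if n_withhold < 1:
        raise ValueError("withhold_frac leaves nothing to recover")
    rng = np.random.default_rng(rng_seed)
    nodes = np.array(sorted(net.nodes))
    rec_ranks, ctl_ranks = [], []
    rec_curves, ctl_curves = [], []
    for _ in range(n_boot):
        withheld = rng.choice(members, size=n_withhold, replace=False)
        seed_genes = sorted(set(members) - set(withheld))
        r = _recovery_ranks(net, seed_genes, withheld, n_iter)
        rec_ranks.append(r)
        rec_curves.append(_cumulative(r, n_iter))

        rand = rng.choice(nodes, size=len(members), replace=False)
        ctl_targets = rand[:n_withhold]
        ctl_seeds = rand[n_withhold:]
        c = _recovery_ranks(net, ctl_seeds, ctl_targets, n_iter)
        ctl_ranks.append(c)
        ctl_curves.append(_cumulative(c, n_iter))
    rec_all = np.concatenate(rec_ranks)
    ctl_all = np.concatenate(ctl_ranks)
    ks = stats.ks_2samp(rec_all, ctl_all, alternative="greater")
    return RecoveryResult(
        np.array(rec_curves), np.array(ctl_curves), float(ks.statistic), float(ks.pvalue)
    )


def _cumulative(ranks: np.ndarray, n_iter: int) -> np.ndarray:
    counts = np.zeros(n_iter)
    for r in ranks:
        if r <= n_iter:
            counts[int(r) - 1] += 1
    return np.cumsum(counts) / len(ranks)
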