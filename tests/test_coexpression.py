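"""Network construction: bicor, soft threshold, TOM, module detection,
eigengenes — each checked against closed forms or brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cordnet.coexpression import (
    adjacency_signed,
    bicor,
    build_partition,
    cluster_modules,
    eigengene_network,
    fit_coexpression_network,
    kme,
    merge_close_modules,
    module_eigengenes,
    pick_soft_threshold,
    scale_free_fit,
    tom_similarity,
    CorrelationMatrix,
)

from conftest import make_study


def tom_bruteforce(a: np.ndarray) -> np.ndarray:
    """O(n^3) triple-loop oracle for the topological overlap matrix."""
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestBicor:
    def test_self_and_anti_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        study = make_study(np.vstack([x, -x, x * 2 + 1]))
        c = bicor(study).values.to_numpy()
        np.testing.assert_allclose(np.diag(c), 1.0)
        assert c[0, 1] == pytest.approx(-1.0, abs=1e-10)
        assert c[0, 2] == pytest.approx(1.0, abs=1e-10)

    def test_close_to_pearson_on_clean_gaussian(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=100)
        x = z + rng.normal(size=100) * 0.8
        y = 0.6 * z + rng.normal(size=100) * 0.8
        study = make_study(np.vstack([x, y]))
        b = bicor(study).values.iloc[0, 1]
        p = np.corrcoef(x, y)[0, 1]
        assert abs(b - p) < 0.05

    def test_robust_to_single_outlier(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=60)
        x = z + rng.normal(size=60) * 0.5
        y = z + rng.normal(size=60) * 0.5
        clean = np.corrcoef(x, y)[0, 1]
        x_out = x.copy()
        x_out[0] = 100 * np.abs(x).max()
        study = make_study(np.vstack([x_out, y]))
        b = bicor(study).values.iloc[0, 1]
        p = np.corrcoef(x_out, y)[0, 1]
        assert abs(b - clean) < 0.1
        assert abs(p - clean) > 0.3

    def test_constant_gene_falls_back(self):
        study = make_study(np.vstack([np.ones(10), np.arange(10.0)]))
        c = bicor(study).values.to_numpy()
        assert c[0, 1] == 0.0
        assert c[0, 0] == 1.0

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError):
            bicor(make_study(np.random.default_rng(0).normal(size=(3, 3))))


class TestAdjacency:
    def test_closed_forms(self):
        c = np.array([[1.0, 1.0, -1.0, 0.0]] * 4)
        c = (c + c.T) / 2  # make symmetric; values still hit the landmarks
        a = adjacency_signed(np.array([[1.0, 0.0], [0.0, 1.0]]), 5)
        assert a[0, 1] == pytest.approx(0.5**5)
        a2 = adjacency_signed(np.array([[1.0, 1.0], [1.0, 1.0]]), 7)
        assert a2[0, 1] == pytest.approx(1.0)
        a3 = adjacency_signed(np.array([[1.0, -1.0], [-1.0, 1.0]]), 3)
        assert a3[0, 1] == pytest.approx(0.0)

    def test_monotone_in_correlation(self):
        cors = np.linspace(-1, 1, 21)
        vals = ((1 + cors) / 2) ** 6
        assert (np.diff(vals) >= 0).all()

    def test_beta_below_one_rejected(self):
        with pytest.raises(ValueError):
            adjacency_signed(np.eye(2), 0.5)


class TestSoftThreshold:
    def test_vacuous_cut_gives_minimum_candidate(self, small_reference):
        # a cut below any attainable fit makes every candidate pass, so the
        # minimum-candidate rule must return beta = 1
        ref, _ = small_reference
        res = pick_soft_threshold(bicor(ref), r2_cut=-1.0)
        assert res.beta == 1 and res.satisfied

    def test_chosen_beta_matches_independent_fit(self, small_reference):
        """The binned scale-free regression agrees with a from-scratch
        recomputation for every candidate."""
        ref, _ = small_reference
        cor = bicor(ref)
        res = pick_soft_threshold(cor)
        c = cor.values.to_numpy()
        for i, beta in enumerate(res.candidates):
            a = ((1 + c) / 2.0) ** beta
            np.fill_diagonal(a, 0.0)
            k = a.sum(axis=1)
            k = k[k > 0]
            edges = np.linspace(k.min(), k.max() + 1e-12, 11)
            counts, _ = np.histogram(k, bins=edges)
            centers = (edges[:-1] + edges[1:]) / 2
            m = counts > 0
            slope, _, r, _, _ = stats.linregress(
                np.log10(centers[m]), np.log10(counts[m] / counts.sum())
            )
            assert res.r_squared[i] == pytest.approx(-np.sign(slope) * r**2)
        passing = res.candidates[res.r_squared > 0.8]
        if len(passing):
            assert res.beta == passing[0] and res.satisfied
        else:
            assert res.beta == res.candidates[np.argmax(res.r_squared)]
            assert not res.satisfied

    def test_mean_connectivity_decreases_with_beta(self, small_reference):
        ref, _ = small_reference
        res = pick_soft_threshold(bicor(ref))
        assert (np.diff(res.mean_connectivity) < 0).all()

    def test_degenerate_correlation_raises(self):
        c = CorrelationMatrix(pd.DataFrame(np.ones((4, 4))), "pearson")
        with pytest.raises(ValueError):
            pick_soft_threshold(c)


class TestTOM:
    def test_uniform_half_adjacency(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(a)
        # one shared neighbor: (0.25 + 0.5) / (1.0 + 1 - 0.5) = 0.5
        off = tom[np.triu_indices(3, k=1)]
        np.testing.assert_allclose(off, 0.5)

    def test_identical_neighborhoods_full_overlap(self):
        a = np.ones((4, 4))
        tom = tom_similarity(a)
        np.testing.assert_allclose(tom, 1.0)

    @pytest.mark.parametrize("n", [4, 6, 8])
    def test_matches_triple_loop_oracle(self, n):
        rng = np.random.default_rng(n)
        a = rng.uniform(0, 1, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        np.testing.assert_allclose(
            tom_similarity(a), tom_bruteforce(a), atol=1e-12
        )

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(0, 1, size=(12, 12))
        a = (a + a.T) / 2
        tom = tom_similarity(a)
        assert ((tom >= 0) & (tom <= 1)).all()
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)

    def test_non_square_raises(self):
        with pytest.raises(ValueError):
            tom_similarity(np.ones((2, 3)))


class TestClusterModules:
    def _blocks(self, rng, sizes, within=0.9):
        mats = []
        labels = []
        for m, size in enumerate(sizes, start=1):
            z = rng.normal(size=50)
            mats.append(
                np.sqrt(within) * z + np.sqrt(1 - within) * rng.normal(size=(size, 50))
            )
            labels += [m] * size
        return np.vstack(mats), np.array(labels)

    def test_two_planted_blocks_recovered_exactly(self):
        rng = np.random.default_rng(0)
        x, truth = self._blocks(rng, (30, 30))
        study = make_study(x)
        tom = tom_similarity(adjacency_signed(bicor(study), 6))
        labels = cluster_modules(tom, study.genes, min_size=20)
        assert sorted(labels.value_counts().to_dict().values()) == [30, 30]
        assert labels.max() == 2
        # blocks map 1:1 onto modules
        ct = pd.crosstab(truth, labels.values)
        assert (ct.gt(0).sum(axis=1) == 1).all()

    def test_noise_matrix_stays_unassigned(self):
        rng = np.random.default_rng(1)
        study = make_study(rng.normal(size=(120, 40)))
        tom = tom_similarity(adjacency_signed(bicor(study), 6))
        labels = cluster_modules(tom, study.genes, min_size=20)
        assert (labels != 0).sum() <= 6  # at most 5% spurious assignments

    def test_min_size_respected(self, small_reference):
        ref, _ = small_reference
        tom = tom_similarity(adjacency_signed(bicor(ref), 6))
        labels = cluster_modules(tom, ref.genes, min_size=20)
        sizes = labels[labels != 0].value_counts()
        assert (sizes >= 20).all()

    def test_fewer_genes_than_min_size(self):
        rng = np.random.default_rng(2)
        study = make_study(rng.normal(size=(5, 10)))
        tom = tom_similarity(adjacency_signed(bicor(study), 2))
        labels = cluster_modules(tom, study.genes, min_size=20)
        assert (labels == 0).all()


class TestEigengenes:
    def test_rank_one_module_recovers_factor(self):
        rng = np.random.default_rng(3)
        e = rng.normal(size=25)
        x = np.outer(np.ones(10), e)  # 10 identical genes, zero noise
        study = make_study(x)
        labels = pd.Series(1, index=study.genes)
        eigen, pve = module_eigengenes(study, labels)
        assert pve[1] == pytest.approx(1.0)
        r = np.corrcoef(eigen.loc[1].to_numpy(), e)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_sign_convention_mean_kme_nonnegative(self, small_reference):
        ref, truth = small_reference
        part = build_partition(ref, truth.labels)
        for m in part.module_ids:
            members = part.members(m)
            assert part.kme.loc[members, m].mean() >= 0

    def test_antiloaded_gene_gets_negative_kme(self):
        rng = np.random.default_rng(4)
        e = rng.normal(size=30)
        x = np.vstack([np.outer(np.ones(9), e), -e[None, :]])
        x += rng.normal(size=x.shape) * 0.01
        study = make_study(x)
        labels = pd.Series(1, index=study.genes)
        eigen, _ = module_eigengenes(study, labels)
        k = kme(study, eigen)
        assert k.iloc[-1, 0] < -0.9
        assert (k.iloc[:9, 0] > 0.9).all()

    def test_kme_matches_direct_correlation(self, small_reference):
        ref, truth = small_reference
        eigen, _ = module_eigengenes(ref, truth.labels)
        k = kme(ref, eigen)
        rng = np.random.default_rng(5)
        for g in rng.choice(len(ref.genes), size=10, replace=False):
            for m in eigen.index:
                direct = np.corrcoef(
                    ref.values()[g], eigen.loc[m].to_numpy()
                )[0, 1]
                assert k.iloc[g][m] == pytest.approx(direct, abs=1e-10)

    def test_small_module_raises(self):
        study = make_study(np.random.default_rng(6).normal(size=(3, 10)))
        labels = pd.Series([1, 2, 2], index=study.genes)
        with pytest.raises(ValueError, match="fewer than 2"):
            module_eigengenes(study, labels)

    def test_propvar_in_unit_interval(self, small_reference):
        ref, truth = small_reference
        part = build_partition(ref, truth.labels)
        for v in part.prop_var_explained.values():
            assert 0.0 <= v <= 1.0


class TestMergeCloseModules:
    def test_same_factor_modules_merge(self):
        rng = np.random.default_rng(7)
        e = rng.normal(size=40)
        x = e + rng.normal(size=(60, 40)) * 0.3  # one factor, split labels
        study = make_study(x)
        labels = pd.Series([1] * 30 + [2] * 30, index=study.genes)
        part = build_partition(study, labels)
        merged = merge_close_modules(part, study, cut_height=0.2)
        assert merged.labels.max() == 1

    def test_orthogonal_modules_unchanged(self, small_reference):
        ref, truth = small_reference
        part = build_partition(ref, truth.labels)
        merged = merge_close_modules(part, ref, cut_height=0.2)
        assert merged.labels.max() == truth.labels.max()

    def test_idempotent(self, small_reference):
        ref, truth = small_reference
        part = build_partition(ref, truth.labels)
        once = merge_close_modules(part, ref, cut_height=0.2)
        twice = merge_close_modules(once, ref, cut_height=0.2)
        assert once.labels.equals(twice.labels)


class TestEigengeneNetwork:
    def test_symmetric_unit_diagonal(self, small_reference):
        ref, truth = small_reference
        eigen, _ = module_eigengenes(ref, truth.labels)
        cor, _ = eigengene_network(eigen)
        v = cor.to_numpy()
        np.testing.assert_allclose(np.diag(v), 1.0)
        np.testing.assert_allclose(v, v.T)

    def test_shared_factor_modules_correlate(self):
        rng = np.random.default_rng(8)
        shared = rng.normal(size=50)
        e1 = 0.8 * shared + 0.6 * rng.normal(size=50)
        e2 = 0.8 * shared + 0.6 * rng.normal(size=50)
        x = np.vstack(
            [e1 + rng.normal(size=(20, 50)) * 0.2,
             e2 + rng.normal(size=(20, 50)) * 0.2]
        )
        study = make_study(x)
        labels = pd.Series([1] * 20 + [2] * 20, index=study.genes)
        eigen, _ = module_eigengenes(study, labels)
        cor, _ = eigengene_network(eigen)
        assert cor.iloc[0, 1] > 0.5

    def test_single_module_raises(self, small_reference):
        ref, truth = small_reference
        eigen, _ = module_eigengenes(ref, truth.labels)
        with pytest.raises(ValueError):
            eigengene_network(eigen.iloc[:1])


class TestEndToEnd:
    def test_planted_modules_recovered(self, small_config, small_reference):
        from sklearn.metrics import adjusted_rand_score

        ref, truth = small_reference
        part, _ = fit_coexpression_network(ref)
        ari = adjusted_rand_score(truth.labels.to_numpy(), part.labels.to_numpy())
        assert ari >= 0.9
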