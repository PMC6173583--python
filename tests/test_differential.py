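"""Module-level DE, consensus calls, severity scoring, enrichment, reversal."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cordnet.containers import ModulePartition
from cordnet.differential import (
    bonferroni,
    consensus_calls,
    curated_enrichment,
    enrichment_robustness,
    gene_statistics,
    mean_rank_set_test,
    module_de,
    reversal_test,
    severity_scores,
    temporal_profiles,
    wilcoxon_rank_sum,
    ModuleDEResult,
)
from cordnet.simulate import (
    SimulationConfig,
    generate_reference_expression,
    generate_test_studies,
    generate_treatment_pair,
)

from conftest import make_study


def wilcoxon_exact_oracle(x, y, alternative="greater"):
    """Exhaustive enumeration of the rank-sum null over all assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    obs = ranks[:n1].sum()
    stats_all = [
        sum(ranks[list(idx)])
        for idx in itertools.combinations(range(len(pooled)), n1)
    ]
    stats_all = np.array(stats_all)
    if alternative == "greater":
        return (stats_all >= obs - 1e-9).mean()
    return (stats_all <= obs + 1e-9).mean()


def fisher_tail_oracle(a, b, c, d):
    """One-sided (greater) hypergeometric tail by explicit summation."""
    n = a + b + c + d
    row = a + b
    col = a + c
    total = 0.0
    for k in range(a, min(row, col) + 1):
        total += (
            math.comb(col, k)
            * math.comb(n - col, row - k)
            / math.comb(n, row)
        )
    return total


class TestGeneStatistics:
    def test_identical_group_means_give_zero_statistic(self):
        x = np.tile([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], (4, 1))
        study = make_study(x, condition=["injured"] * 3 + ["sham"] * 3)
        gs = gene_statistics(study)
        np.testing.assert_allclose(gs.values.to_numpy(), 0.0)
        assert (gs.p_values > 0.99).all()

    def test_matches_textbook_two_sample_t(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5, 12))
        study = make_study(x, condition=["injured"] * 6 + ["sham"] * 6)
        gs = gene_statistics(study)
        for i in range(5):
            a, b = x[i, :6], x[i, 6:]
            sp = np.sqrt(((a.var(ddof=1) * 5) + (b.var(ddof=1) * 5)) / 10)
            t = (a.mean() - b.mean()) / (sp * np.sqrt(1 / 6 + 1 / 6))
            assert gs.values.iloc[i] == pytest.approx(t, rel=1e-10)
            assert gs.p_values.iloc[i] == pytest.approx(
                2 * stats.t.sf(abs(t), df=10), rel=1e-10
            )

    def test_planted_shift_detected_with_power(self):
        hits = 0
        rng = np.random.default_rng(1)
        for _ in range(100):
            a = rng.normal(2.0, 1.0, size=10)
            b = rng.normal(0.0, 1.0, size=10)
            study = make_study(
                np.concatenate([a, b])[None, :],
                condition=["injured"] * 10 + ["sham"] * 10,
            )
            hits += gene_statistics(study).p_values.iloc[0] < 0.01
        assert hits >= 95

    def test_degenerate_group_raises(self):
        study = make_study(np.ones((2, 4)), condition=["injured"] * 3 + ["sham"])
        with pytest.raises(ValueError):
            gene_statistics(study)


class TestMeanRankSetTest:
    def test_matches_exact_enumeration_for_top_k(self):
        values = pd.Series(
            [10.0, 9.0, 8.0, 1.2, 0.7, 0.5, 0.3, 0.2, 0.1, 0.05],
            index=[f"g{i}" for i in range(10)],
        )
        gene_set = ["g0", "g1", "g2"]
        p = mean_rank_set_test(values, gene_set, "up")
        oracle = wilcoxon_exact_oracle(
            values[gene_set].to_numpy(), values.drop(gene_set).to_numpy(), "greater"
        )
        assert p == pytest.approx(oracle, rel=1e-9)

    def test_random_sets_give_uniform_p(self):
        rng = np.random.default_rng(2)
        values = pd.Series(rng.normal(size=300), index=range(300))
        pvals = [
            mean_rank_set_test(
                values, rng.choice(300, size=25, replace=False), "up"
            )
            for _ in range(200)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_one_sided_complementarity(self):
        rng = np.random.default_rng(3)
        values = pd.Series(rng.normal(size=60), index=range(60))
        gene_set = list(range(12))
        up = mean_rank_set_test(values, gene_set, "up")
        down = mean_rank_set_test(values, gene_set, "down")
        assert up + down == pytest.approx(1.0, abs=0.05)

    def test_empty_intersection_raises(self):
        values = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        with pytest.raises(ValueError):
            mean_rank_set_test(values, ["z"], "up")


class TestWilcoxon:
    @pytest.mark.parametrize("n1,n2", [(4, 5), (6, 6), (3, 8)])
    def test_exact_small_sample_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        for alt in ("greater", "less"):
            assert wilcoxon_rank_sum(x, y, alt) == pytest.approx(
                wilcoxon_exact_oracle(x, y, alt), rel=1e-9
            )


class TestModuleDEAndConsensus:
    def test_planted_directions_called_in_every_study(
        self, small_config, small_reference, small_studies
    ):
        _, truth = small_reference
        de = module_de(small_studies, ModulePartition(truth.labels))
        for study_id, sub in de.per_study.groupby("study_id"):
            calls = sub.set_index("module")["call"]
            assert calls[1] == "up"
            assert calls[2] == "down"
        assert de.consensus[1] == "consensus_up"
        assert de.consensus[2] == "consensus_down"
        assert de.consensus[3] == "none"

    def test_null_module_reaches_no_consensus(self):
        """A coexpressed module with no injury effect can be called within a
        single study (the mean-rank test is anti-conservative under
        inter-gene correlation), but its chance calls do not replicate in
        direction across five studies: the consensus label stays 'none'."""
        outcomes = []
        for seed in range(12):
            cfg = SimulationConfig(
                n_genes=300, module_sizes=(40, 30, 30), n_samples_ref=10,
                n_test_studies=5, samples_per_study=20,
                de_effect=(2.0, -2.0, 0.0), sign_flip_module=None,
                curated_target_modules=(0,), curated_size=60, rng_seed=300 + seed,
            )
            _, truth = generate_reference_expression(cfg)
            de = module_de(
                generate_test_studies(cfg, truth), ModulePartition(truth.labels)
            )
            outcomes.append(de.consensus[3])
        assert sum(o == "none" for o in outcomes) >= 11

    @pytest.mark.parametrize(
        "n_up, expected",
        [(5, "consensus_up"), (4, "majority_up"), (3, "none")],
    )
    def test_consensus_rules(self, n_up, expected):
        rows = []
        for s in range(5):
            rows.append(
                {
                    "study_id": f"s{s}",
                    "module": 1,
                    "p_up": 0.001,
                    "p_down": 0.999,
                    "adj_p_up": 0.01,
                    "adj_p_down": 1.0,
                    "call": "up" if s < n_up else "none",
                }
            )
        labels = consensus_calls(ModuleDEResult(pd.DataFrame(rows)))
        assert labels[1] == expected

    def test_consensus_invariant_to_study_order(self, small_studies, small_reference):
        _, truth = small_reference
        part = ModulePartition(truth.labels)
        fwd = module_de(small_studies, part).consensus
        rev = module_de(small_studies[::-1], part).consensus
        pd.testing.assert_series_equal(fwd, rev)



@pytest.fixture(scope="module")
def temporal_setup():
    cfg = SimulationConfig(rng_seed=13, samples_per_study=48)
    _, truth = generate_reference_expression(cfg)
    studies = generate_test_studies(cfg, truth)
    return cfg, truth, studies



class TestTemporalProfiles:
    def test_sign_flipping_module_flagged(self, temporal_setup):
        cfg, truth, studies = temporal_setup
        results, flips = temporal_profiles(studies, ModulePartition(truth.labels))
        assert flips[truth.sign_flip_module]
        assert not flips.drop(truth.sign_flip_module).any()

    def test_constant_direction_module_not_flagged(self, temporal_setup):
        cfg, truth, studies = temporal_setup
        results, flips = temporal_profiles(studies, ModulePartition(truth.labels))
        tps = sorted(results)
        assert results[tps[0]].consensus[1].endswith("up")
        assert results[tps[-1]].consensus[1].endswith("up")
        assert not flips[1]

    def test_missing_timepoints_raise(self, small_reference):
        ref, truth = small_reference
        bad = ref
        bad.sample_meta["timepoint_days"] = np.nan
        with pytest.raises(ValueError, match="time-point"):
            temporal_profiles([bad, bad], ModulePartition(truth.labels))



@pytest.fixture(scope="module")
def severity_setup():
    cfg = SimulationConfig(
        rng_seed=17, de_effect=(6.0, -2.0, 0.0, 0.0, 0.0),
        sign_flip_module=None, n_test_studies=1, samples_per_study=60,
        severity_exclusive=True,
    )
    _, truth = generate_reference_expression(cfg)
    study = generate_test_studies(cfg, truth)[0]
    return truth, study



class TestSeverity:
    def test_score_identity_and_sign(self, severity_setup):
        truth, study = severity_setup
        res = severity_scores(study, ModulePartition(truth.labels))
        g = res.gene_scores
        np.testing.assert_allclose(
            g["score"], g["rho"] * (-np.log10(g["p"])), atol=1e-12
        )
        nonzero = g["score"] != 0
        assert (np.sign(g.loc[nonzero, "score"]) == np.sign(g.loc[nonzero, "rho"])).all()

    def test_coupled_module_is_sole_positive_and_max_rho(self, severity_setup):
        truth, study = severity_setup
        res = severity_scores(study, ModulePartition(truth.labels))
        pos = res.module_enrichment["adj_p_pos"] < 0.05
        assert pos.sum() == 1 and pos[truth.severity_coupled_module]
        assert (
            res.eigengene_correlation["rho"].abs().idxmax()
            == truth.severity_coupled_module
        )

    def test_constant_severity_raises(self, small_reference):
        ref, truth = small_reference
        with pytest.raises(ValueError, match="severity"):
            severity_scores(ref, ModulePartition(truth.labels))


class TestCuratedEnrichment:
    def test_matches_hypergeometric_tail_oracle(self):
        labels = pd.Series(
            [1] * 50 + [0] * 4950, index=[f"g{i}" for i in range(5000)]
        )
        curated = set(labels.index[:10]) | set(labels.index[60:150])
        table = curated_enrichment(ModulePartition(labels), curated, labels.index)
        assert table.loc[1, "p"] == pytest.approx(
            fisher_tail_oracle(10, 40, 90, 4860), rel=1e-9
        )

    def test_module_equal_to_curated_set_is_minimal(self):
        labels = pd.Series([1] * 20 + [0] * 180, index=[f"g{i}" for i in range(200)])
        curated = set(labels.index[:20])
        table = curated_enrichment(ModulePartition(labels), curated, labels.index)
        assert table.loc[1, "p"] == pytest.approx(
            fisher_tail_oracle(20, 0, 0, 180), rel=1e-9
        )
        assert table.loc[1, "p"] < 1e-20

    def test_disjoint_curated_set_not_enriched(self):
        labels = pd.Series([1] * 20 + [0] * 180, index=[f"g{i}" for i in range(200)])
        curated = set(labels.index[50:80])
        table = curated_enrichment(ModulePartition(labels), curated, labels.index)
        assert table.loc[1, "p"] >= 0.5

    def test_planted_target_modules_enriched(self, small_config, small_reference):
        ref, truth = small_reference
        table = curated_enrichment(
            ModulePartition(truth.labels), set(truth.curated_genes), ref.genes
        )
        for m in truth.target_modules:
            assert table.loc[m, "adj_p"] < 0.05


class TestRobustness:
    def test_zero_perturbation_reproduces_base_enrichment(
        self, small_reference
    ):
        ref, truth = small_reference
        part = ModulePartition(truth.labels)
        base = curated_enrichment(part, set(truth.curated_genes), ref.genes)
        rob = enrichment_robustness(
            part, set(truth.curated_genes), ref.genes,
            removal_grid=(0.0,), addition_grid=(0.0,), n_boot=5, rng_seed=0,
        )
        np.testing.assert_allclose(
            rob["removal"]["median_p"][0.0].to_numpy(),
            base["adj_p"].to_numpy(),
        )

    def test_full_removal_reported_as_na(self, small_reference):
        ref, truth = small_reference
        part = ModulePartition(truth.labels)
        rob = enrichment_robustness(
            part, set(truth.curated_genes), ref.genes,
            removal_grid=(0.0, 1.0), addition_grid=(0.0,), n_boot=3, rng_seed=1,
        )
        assert rob["removal"]["median_p"][1.0].isna().all()

    def test_breakdown_monotone_in_signal(self):
        """A module holding more of the curated set survives more removal."""
        breakdowns = []
        for frac in (0.3, 0.55, 0.8):
            cfg = SimulationConfig(
                n_genes=400, module_sizes=(60,), n_samples_ref=10,
                curated_size=80, curated_target_modules=(0,),
                seed_gene_fraction=frac, fp_rate=1 - frac,
                de_effect=(2.0,), sign_flip_module=None, rng_seed=23,
            )
            _, truth = generate_reference_expression(cfg)
            part = ModulePartition(truth.labels)
            rob = enrichment_robustness(
                part, set(truth.curated_genes), truth.labels.index,
                removal_grid=(0.0, 0.2, 0.4, 0.6, 0.8),
                addition_grid=(0.0,), n_boot=20, rng_seed=2,
            )
            breakdowns.append(rob["removal"]["breakdown"].loc[1])
        assert breakdowns[0] <= breakdowns[1] <= breakdowns[2]
        assert breakdowns[2] >= 0.6


class TestReversal:
    def test_negated_injury_reverses_all_consensus_modules(
        self, small_config, small_reference, small_studies
    ):
        _, truth = small_reference
        part = ModulePartition(truth.labels)
        de = module_de(small_studies, part)
        treated, control = generate_treatment_pair(small_config, truth)
        res = reversal_test(treated, control, part, de.consensus)
        assert res.n_consensus == 2
        assert res.n_reversed == 2

    def test_noise_treatment_gives_no_reversals(self, small_config, small_reference, small_studies):
        _, truth = small_reference
        part = ModulePartition(truth.labels)
        de = module_de(small_studies, part)
        treated, control = generate_treatment_pair(small_config, truth, reversal=0.0)
        res = reversal_test(treated, control, part, de.consensus)
        assert res.n_reversed == 0

    def test_eigengene_wilcoxon_matches_exact_enumeration(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=6)
        y = rng.normal(size=6) + 1.0
        assert wilcoxon_rank_sum(x, y, "less") == pytest.approx(
            wilcoxon_exact_oracle(x, y, "less"), rel=1e-9
        )


class TestBonferroni:
    def test_cap_and_scale(self):
        assert bonferroni(0.01, 3) == pytest.approx(0.03)
        assert bonferroni(0.5, 10) == 1.0
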