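"""The population-level enrichment test and its companions."""

import math

import numpy as np
import pandas as pd
import pytest

from slapenrich import (
    AnalysisConfig,
    GeneSet,
    ModelSpec,
    MutationDataset,
    PathwayCollection,
    adjust_pvalues,
    alteration_score,
    core_components,
    differential_enrichment,
    exclusive_coverage,
    expected_count,
    filter_pathways,
    mutex_sort,
    observed_count,
    pathway_pvalue,
    slapenrich,
)
from slapenrich.poisson_binomial import pb_pmf


def _random_dataset(rng, n_genes=20, n_samples=15, density=0.15):
    return MutationDataset(
        [f"g{i}" for i in range(n_genes)],
        [f"s{j}" for j in range(n_samples)],
        (rng.random((n_genes, n_samples)) < density).astype(int),
    )


class TestFilterPathways:
    def test_never_mutated_pathway_excluded(self, toy_dataset):
        coll = PathwayCollection([GeneSet("P", "p", frozenset({"C"}))])
        kept, excluded = filter_pathways(toy_dataset, coll)
        assert len(kept) == 0
        assert "altered in 0 samples" in excluded[0]["reason"]

    def test_single_gene_signal_fails_distinct_gene_criterion(self):
        # one gene mutated in 90% of samples still fails the >=2-genes rule
        ind = np.zeros((3, 10), dtype=int)
        ind[0, :9] = 1
        ds = MutationDataset(["A", "B", "C"], [f"s{j}" for j in range(10)], ind)
        coll = PathwayCollection([GeneSet("P", "p", frozenset({"A", "B"}))])
        kept, excluded = filter_pathways(ds, coll)
        assert len(kept) == 0
        assert "distinct mutated genes" in excluded[0]["reason"]

    def test_matches_bruteforce_recount(self):
        rng = np.random.default_rng(12)
        ds = _random_dataset(rng, n_genes=40, n_samples=30)
        sets = []
        for i in range(20):
            members = rng.choice(40, size=rng.integers(2, 8), replace=False)
            sets.append(GeneSet(f"P{i}", "", frozenset(f"g{m}" for m in members)))
        coll = PathwayCollection(sets)
        config = AnalysisConfig()
        kept, _ = filter_pathways(ds, coll, config)
        need_samples = math.ceil(0.05 * ds.n_samples)
        expected_ids = []
        frame = ds.to_frame()
        for s in sets:
            sub = frame.loc[sorted(s.genes)]
            o = int((sub.sum(axis=0) > 0).sum())
            distinct = int((sub.sum(axis=1) > 0).sum())
            if o >= need_samples and distinct >= 2:
                expected_ids.append(s.id)
        assert kept.ids == expected_ids


class TestCounts:
    def test_observed_toy(self, toy_dataset):
        obs, single, x = observed_count(toy_dataset, GeneSet("P", "p", frozenset({"A", "B"})))
        assert (obs, single) == (2, 1)
        assert x.tolist() == [1, 2, 0]

    def test_pathway_outside_background(self, toy_dataset):
        obs, single, x = observed_count(toy_dataset, GeneSet("P", "p", frozenset({"Z"})))
        assert obs == 0 and single == 0

    def test_random_matrices_match_column_recount(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            ds = _random_dataset(rng)
            members = rng.choice(20, size=5, replace=False)
            gs = GeneSet("P", "p", frozenset(f"g{m}" for m in members))
            obs, single, x = observed_count(ds, gs)
            frame = ds.to_frame().loc[sorted(gs.genes)]
            col = frame.sum(axis=0)
            assert obs == (col >= 1).sum()
            assert single == (col == 1).sum()

    def test_expected_count_is_distribution_mean(self):
        rng = np.random.default_rng(9)
        pi = rng.random(25)
        pmf = pb_pmf(pi)
        assert expected_count(pi) == pytest.approx(
            float(np.dot(np.arange(26), pmf)), abs=1e-9
        )
        assert expected_count([0.2, 0.5, 0.7]) == pytest.approx(1.4)
        assert expected_count([]) == 0.0


class TestScores:
    def test_alteration_score(self):
        assert alteration_score(14, 1.4) == pytest.approx(1.0)
        assert alteration_score(5, 5.0) == 0.0
        assert math.isnan(alteration_score(0, 1.0))
        with pytest.raises(ValueError):
            alteration_score(1, 0.0)

    def test_exclusive_coverage(self):
        assert exclusive_coverage(4, 3) == 75.0
        assert exclusive_coverage(7, 7) == 100.0
        assert math.isnan(exclusive_coverage(0, 0))
        with pytest.raises(ValueError):
            exclusive_coverage(2, 3)

    def test_pathway_pvalue(self):
        assert pathway_pvalue([0.2, 0.5, 0.7], 2) == pytest.approx(0.45, abs=1e-12)
        assert pathway_pvalue([0.2, 0.5, 0.7], 0) == 1.0


class TestAdjustPvalues:
    def test_bh_step_up_hand_example(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03], "bh"), [0.03, 0.03, 0.03]
        )

    def test_bonferroni(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.5, 0.9], "bonferroni"), [0.03, 1.0, 1.0]
        )

    def test_storey_with_unit_pi0_reduces_to_bh(self):
        rng = np.random.default_rng(6)
        p = rng.random(50)
        np.testing.assert_allclose(
            adjust_pvalues(p, "storey", pi0=1.0), adjust_pvalues(p, "bh"), atol=1e-12
        )

    def test_stringency_ordering(self):
        rng = np.random.default_rng(13)
        p = rng.random(30)
        bonf = adjust_pvalues(p, "bonferroni")
        bh = adjust_pvalues(p, "bh")
        assert (bonf >= bh - 1e-12).all()
        assert (bh >= p - 1e-12).all()

    def test_storey_qvalues_below_bh(self):
        rng = np.random.default_rng(14)
        p = np.concatenate([rng.random(50) * 0.01, rng.random(50)])
        q = adjust_pvalues(p, "storey")
        assert (q <= adjust_pvalues(p, "bh") + 1e-12).all()


class TestSlapenrich:
    def test_planted_pathway_tops_table(self, planted_sim):
        ds, lengths, coll, truth = planted_sim
        res = slapenrich(ds, coll, lengths)
        assert res.iloc[0]["pathway_id"] == "PLANTED00"
        assert bool(res.iloc[0]["is_enriched"])
        assert res.iloc[0]["EC"] == 100.0

    def test_duplicate_pathway_gets_identical_statistics(self, planted_sim):
        ds, lengths, coll, _ = planted_sim
        dup = PathwayCollection(
            list(coll) + [GeneSet("DUP", "copy", coll["PLANTED00"].genes)]
        )
        res = slapenrich(ds, dup, lengths).set_index("pathway_id")
        for col in ("E", "O", "pvalue", "EC"):
            assert res.loc["DUP", col] == res.loc["PLANTED00", col]

    def test_invariant_to_gene_and_sample_permutation(self, planted_sim):
        ds, lengths, coll, _ = planted_sim
        rng = np.random.default_rng(0)
        g_perm = rng.permutation(ds.n_genes)
        s_perm = rng.permutation(ds.n_samples)
        mult = None
        if ds.multiplicity is not None:
            mult = ds.multiplicity[np.ix_(g_perm, s_perm)]
        shuffled = MutationDataset(
            [ds.gene_ids[i] for i in g_perm],
            [ds.sample_ids[j] for j in s_perm],
            ds.indicator[np.ix_(g_perm, s_perm)],
            mult,
        )
        a = slapenrich(ds, coll, lengths).set_index("pathway_id").sort_index()
        b = slapenrich(shuffled, coll, lengths).set_index("pathway_id").sort_index()
        # statistics are permutation invariant up to float accumulation order
        pd.testing.assert_frame_equal(a, b, rtol=1e-9, atol=1e-12)

    def test_empty_result_when_nothing_survives(self, toy_dataset, toy_lengths):
        coll = PathwayCollection([GeneSet("P", "p", frozenset({"C"}))])
        with pytest.warns(UserWarning, match="no pathways survive"):
            res = slapenrich(toy_dataset, coll, toy_lengths)
        assert res.empty

    def test_deterministic_output(self, planted_sim):
        ds, lengths, coll, _ = planted_sim
        a = slapenrich(ds, coll, lengths)
        b = slapenrich(ds, coll, lengths)
        pd.testing.assert_frame_equal(a, b)


class TestMutexSort:
    def test_permutation_preserves_content(self, planted_sim):
        ds, _, coll, _ = planted_sim
        gs = coll["PLANTED00"]
        gene_order, sample_order = mutex_sort(ds, gs)
        assert sorted(gene_order) == sorted(ds.genes_present(gs.genes))
        assert sorted(sample_order) == sorted(ds.sample_ids)
        frame = ds.to_frame()
        sub = frame.loc[gene_order, sample_order]
        assert sorted(sub.sum(axis=1)) == sorted(frame.loc[gene_order].sum(axis=1))
        assert sub.to_numpy().sum() == frame.loc[gene_order].to_numpy().sum()

    def test_perfectly_exclusive_matrix_yields_staircase(self):
        ind = np.eye(4, dtype=int)[:, ::-1]  # each sample hits one gene
        ds = MutationDataset(list("ABCD"), [f"s{j}" for j in range(4)], ind)
        gs = GeneSet("P", "p", frozenset("ABCD"))
        gene_order, sample_order = mutex_sort(ds, gs)
        sub = ds.to_frame().loc[gene_order, sample_order].to_numpy()
        assert np.array_equal(sub, np.eye(4, dtype=int))

    def test_idempotent(self, planted_sim):
        ds, _, coll, _ = planted_sim
        gs = coll["PLANTED00"]
        g1, s1 = mutex_sort(ds, gs)
        reordered = MutationDataset(
            ds.gene_ids, s1, ds.to_frame()[s1].to_numpy()
        )
        g2, s2 = mutex_sort(reordered, gs)
        assert g1 == g2 and s1 == s2


class TestCoreComponents:
    def test_pair_sharing_majority_of_genes(self):
        coll = PathwayCollection(
            [
                GeneSet("P1", "", frozenset({"a", "b", "c", "d"})),
                GeneSet("P2", "", frozenset({"a", "b", "c", "e"})),
            ]
        )
        groups = core_components(["P1", "P2"], coll, j_threshold=0.3)
        assert len(groups) == 1
        assert groups[0]["pathways"] == ["P1", "P2"]
        assert groups[0]["core_genes"] == ["a", "b", "c"]

    def test_disjoint_sets_stay_singletons(self):
        coll = PathwayCollection(
            [
                GeneSet("P1", "", frozenset({"a", "b"})),
                GeneSet("P2", "", frozenset({"c", "d"})),
            ]
        )
        groups = core_components(["P1", "P2"], coll)
        assert [g["pathways"] for g in groups] == [["P1"], ["P2"]]
        assert groups[0]["core_genes"] == ["a", "b"]

    def test_no_enriched_sets(self, toy_collection):
        assert core_components([], toy_collection) == []


class TestDifferentialEnrichment:
    def test_pathway_planted_in_one_group_is_flagged(self, planted_sim):
        ds, lengths, coll, _ = planted_sim
        # group A keeps the cohort; group B gets the planted genes wiped
        half = ds.n_samples // 2
        group_a = ds.sample_ids[:half]
        group_b = ds.sample_ids[half:]
        wiped = ds.zero_genes(coll["PLANTED00"].genes)
        hybrid = MutationDataset(
            ds.gene_ids,
            ds.sample_ids,
            np.concatenate(
                [ds.indicator[:, :half], wiped.indicator[:, half:]], axis=1
            ),
        )
        table = differential_enrichment(
            hybrid, {"A": group_a, "B": group_b}, coll, lengths
        )
        row = table[table["pathway_id"] == "PLANTED00"].iloc[0]
        assert bool(row["is_differential"])

    def test_identical_groups_show_no_differences(self, planted_sim):
        ds, lengths, coll, _ = planted_sim
        table = differential_enrichment(
            ds, {"A": ds.sample_ids, "B": ds.sample_ids}, coll, lengths
        )
        assert not table["is_differential"].any()

    def test_empty_group_errors(self, planted_sim):
        ds, lengths, coll, _ = planted_sim
        with pytest.raises(ValueError, match="non-empty"):
            differential_enrichment(ds, {"A": ds.sample_ids, "B": []}, coll, lengths)
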