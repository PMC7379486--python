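"""Unit and property tests for the running-sum enrichment engine."""

import logging

import numpy as np
import pytest

from fibromod import (
    ConfigError,
    EnrichmentResult,
    GeneSet,
    RankedList,
    enrichment_score,
    leading_edge,
    permutation_null,
    run_gsea,
    significance,
)

from conftest import random_instance
from _oracles import ks_two_cdf_es, running_sum_es


def make_list(n):
    return RankedList(
        genes=tuple(f"G{i:03d}" for i in range(n)),
        scores=np.arange(n, 0, -1, dtype=float),
        order="descending",
    )


class TestEnrichmentScore:
    def test_set_at_top_gives_full_score(self):
        ranked = make_list(10)
        top3 = GeneSet.from_iterable("TOP", ranked.genes[:3])
        res = enrichment_score(ranked, top3, weight_p=0)
        assert res.es == pytest.approx(1.0)
        assert res.peak_index == 3

    def test_alternating_hits_unweighted(self, four_gene_list):
        s = GeneSet.from_iterable("S", ["A", "C"])
        res = enrichment_score(four_gene_list, s, weight_p=0)
        np.testing.assert_allclose(res.running_sum, [0.5, 0.0, 0.5, 0.0], atol=1e-15)
        assert res.es == pytest.approx(0.5)
        assert res.peak_index == 1  # earliest index attaining the max

    def test_alternating_hits_weighted(self, four_gene_list):
        s = GeneSet.from_iterable("S", ["A", "C"])
        res = enrichment_score(four_gene_list, s, weight_p=1)
        np.testing.assert_allclose(
            res.running_sum, [2 / 3, 1 / 6, 1 / 2, 0.0], atol=1e-15
        )
        assert res.es == pytest.approx(2 / 3)
        assert res.peak_index == 1

    def test_bottom_hits_negative_es(self, four_gene_list):
        s = GeneSet.from_iterable("S", ["B", "D"])
        res = enrichment_score(four_gene_list, s, weight_p=0)
        np.testing.assert_allclose(res.running_sum, [-0.5, 0.0, -0.5, 0.0], atol=1e-15)
        assert res.es == pytest.approx(-0.5)
        assert res.peak_index == 3  # last index attaining the min

    def test_missing_members_dropped_with_warning(self, four_gene_list, caplog):
        s = GeneSet.from_iterable("S", ["A", "C", "NOT_THERE"])
        with caplog.at_level(logging.WARNING):
            res = enrichment_score(four_gene_list, s, weight_p=0)
        assert res.n_hits == 2
        assert "absent" in caplog.text

    def test_empty_intersection_errors(self, four_gene_list):
        with pytest.raises(ConfigError, match="not represented"):
            enrichment_score(four_gene_list, GeneSet.from_iterable("S", ["X", "Y"]))

    def test_full_coverage_errors(self, four_gene_list):
        s = GeneSet.from_iterable("S", four_gene_list.genes)
        with pytest.raises(ConfigError, match="miss mass"):
            enrichment_score(four_gene_list, s)

    def test_zero_scores_fall_back_to_unweighted(self, caplog):
        ranked = RankedList(
            genes=("A", "B", "C", "D"),
            scores=np.array([1.0, 0.0, 0.0, -1.0]),
            order="descending",
        )
        s = GeneSet.from_iterable("S", ["B", "C"])
        with caplog.at_level(logging.WARNING):
            res = enrichment_score(ranked, s, weight_p=1)
        assert "falling back" in caplog.text
        ref = enrichment_score(ranked, s, weight_p=0)
        assert res.es == pytest.approx(ref.es)

    @pytest.mark.parametrize("weight_p", [0, 1])
    def test_matches_reference_loop(self, weight_p):
        rng = np.random.default_rng(11)
        for _ in range(200):
            ranked, gene_set, mask = random_instance(rng, n_max=40)
            res = enrichment_score(ranked, gene_set, weight_p=weight_p)
            assert res.es == pytest.approx(
                running_sum_es(ranked.scores, mask, weight_p), abs=1e-12
            )
            assert abs(res.running_sum[-1]) < 1e-12
            assert -1.0 <= res.es <= 1.0

    def test_unweighted_equals_classic_ks(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            ranked, gene_set, mask = random_instance(rng, n_max=50)
            res = enrichment_score(ranked, gene_set, weight_p=0)
            assert res.es == pytest.approx(ks_two_cdf_es(mask), abs=1e-12)

    def test_scale_invariance_unweighted(self):
        """A strictly monotone transform of scores cannot change the p=0 ES."""
        rng = np.random.default_rng(21)
        ranked, gene_set, _ = random_instance(rng, n_max=30)
        res = enrichment_score(ranked, gene_set, weight_p=0)
        warped = RankedList(
            genes=ranked.genes,
            scores=np.exp(ranked.scores / 3.0),
            order="descending",
        )
        res2 = enrichment_score(warped, gene_set, weight_p=0)
        assert res2.es == res.es
        assert res2.peak_index == res.peak_index

    @pytest.mark.parametrize("weight_p", [0, 1])
    def test_reversal_antisymmetry_and_leading_edge(self, weight_p):
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 100:
            ranked, gene_set, _ = random_instance(rng, n_max=30)
            res = enrichment_score(ranked, gene_set, weight_p=weight_p)
            rs = res.running_sum
            if np.isclose(rs.max(), -rs.min()):
                continue  # extremum magnitude tied; antisymmetry not required
            rev = RankedList(
                genes=ranked.genes[::-1],
                scores=ranked.scores[::-1],
                order="ascending",
            )
            res_rev = enrichment_score(rev, gene_set, weight_p=weight_p)
            assert res_rev.es == pytest.approx(-res.es, abs=1e-12)
            le = leading_edge(res, ranked)
            le_rev = leading_edge(res_rev, rev)
            assert le.genes == le_rev.genes
            checked += 1


class TestPermutationNull:
    def test_seeded_determinism(self):
        ranked = make_list(30)
        a = permutation_null(ranked, 5, weight_p=1, n_perm=200, seed=9)
        b = permutation_null(ranked, 5, weight_p=1, n_perm=200, seed=9)
        np.testing.assert_array_equal(a, b)
        c = permutation_null(ranked, 5, weight_p=1, n_perm=200, seed=10)
        assert not np.array_equal(a, c)

    @pytest.mark.parametrize("weight_p", [0, 1])
    def test_candidate_shortcut_matches_full_running_sum(self, weight_p):
        """The O(set_size) extremum candidates give the same ES as the
        reference accumulation for the very sets the null sampled."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(10, 60))
            scores = np.sort(rng.normal(size=n))[::-1]
            ranked = RankedList(
                genes=tuple(f"G{i:03d}" for i in range(n)),
                scores=scores,
                order="descending",
            )
            k = int(rng.integers(1, n))
            seed = int(rng.integers(0, 2**31 - 1))
            nulls = permutation_null(ranked, k, weight_p=weight_p,
                                     n_perm=100, seed=seed)
            # reconstruct the sampled positions exactly as the null does
            rng2 = np.random.default_rng(seed)
            positions = np.argsort(
                rng2.random((100, n)), axis=1, kind="stable"
            )[:, :k]
            for row, es_fast in zip(positions, nulls):
                mask = np.zeros(n, dtype=bool)
                mask[row] = True
                assert es_fast == pytest.approx(
                    running_sum_es(scores, mask, weight_p), abs=1e-12
                )

    def test_null_has_both_signs(self):
        ranked = make_list(100)
        nulls = permutation_null(ranked, 10, weight_p=0, n_perm=500, seed=1)
        assert (nulls > 0).any() and (nulls < 0).any()
        assert np.all(np.abs(nulls) <= 1.0)

    def test_bad_arguments(self):
        ranked = make_list(10)
        with pytest.raises(ConfigError, match="n_perm"):
            permutation_null(ranked, 3, n_perm=50)
        with pytest.raises(ConfigError, match="set_size"):
            permutation_null(ranked, 10, n_perm=200)
        with pytest.raises(ConfigError, match="set_size"):
            permutation_null(ranked, 0, n_perm=200)


class TestSignificance:
    def test_add_one_count_on_constructed_null(self):
        rng = np.random.default_rng(0)
        null = np.concatenate([
            rng.uniform(0.05, 0.3, size=100),   # 100 positive nulls
            rng.uniform(-0.3, -0.05, size=99),  # 99 negative nulls
        ])
        p, nes, fdr = significance(0.9, null)
        assert p == pytest.approx(1 / 101)
        assert fdr == pytest.approx(p)
        assert nes == pytest.approx(0.9 / np.mean(null[:100]))

    def test_es_at_median_of_same_sign_nulls(self):
        null = np.concatenate([np.linspace(0.01, 0.99, 99), -np.ones(50) * 0.2])
        es = float(np.median(null[:99]))
        p, _, _ = significance(es, null)
        assert p == pytest.approx(0.51, abs=0.02)

    def test_nes_sign_matches_es_sign(self):
        rng = np.random.default_rng(4)
        null = rng.normal(scale=0.2, size=400)
        for es in (-0.6, 0.6):
            _, nes, _ = significance(es, null)
            assert np.sign(nes) == np.sign(es)

    def test_no_same_sign_mass_warns_p_one(self, caplog):
        with caplog.at_level(logging.WARNING):
            p, nes, fdr = significance(0.5, np.array([-0.1, -0.2]))
        assert p == 1.0
        assert "no same-sign" in caplog.text

    def test_zero_es_reports_p_one(self, caplog):
        with caplog.at_level(logging.WARNING):
            p, nes, fdr = significance(0.0, np.array([0.1, -0.1]))
        assert (p, nes, fdr) == (1.0, 0.0, 1.0)


class TestLeadingEdge:
    def test_full_set_when_at_top(self):
        ranked = make_list(10)
        top3 = GeneSet.from_iterable("TOP", ranked.genes[:3])
        res = enrichment_score(ranked, top3, weight_p=0)
        le = leading_edge(res, ranked)
        assert le.genes == top3.genes

    def test_positive_peak_keeps_members_before_it(self, four_gene_list):
        s = GeneSet.from_iterable("S", ["A", "C"])
        res = enrichment_score(four_gene_list, s, weight_p=0)
        assert leading_edge(res, four_gene_list).genes == frozenset({"A"})

    def test_negative_peak_keeps_members_after_it(self, four_gene_list):
        s = GeneSet.from_iterable("S", ["B", "D"])
        res = enrichment_score(four_gene_list, s, weight_p=0)
        assert leading_edge(res, four_gene_list).genes == frozenset({"D"})

    def test_zero_es_yields_empty_set(self, four_gene_list, caplog):
        res = EnrichmentResult(
            es=0.0, running_sum=np.zeros(4), peak_index=1,
            hit_positions=np.array([1, 3]), weight_p=0, n_hits=2,
        )
        with caplog.at_level(logging.WARNING):
            le = leading_edge(res, four_gene_list)
        assert len(le) == 0


class TestRunGsea:
    def test_composition_and_determinism(self):
        ranked = make_list(200)
        s = GeneSet.from_iterable("S", ranked.genes[:20])
        r1 = run_gsea(ranked, s, weight_p=1, n_perm=199, seed=5)
        r2 = run_gsea(ranked, s, weight_p=1, n_perm=199, seed=5)
        assert r1.es == r2.es
        assert r1.p_nominal == r2.p_nominal
        np.testing.assert_array_equal(r1.es_null, r2.es_null)
        assert r1.leading_edge.genes == r2.leading_edge.genes
        assert r1.p_nominal >= 1 / (r1.n_perm + 1)
        assert len(r1.leading_edge) > 0

    def test_weighted_es_matches_independent_reference(self):
        """Cross-check the weighted statistic against gseapy's preranked engine."""
        gseapy = pytest.importorskip("gseapy")
        import pandas as pd

        rng = np.random.default_rng(8)
        n = 100
        scores = np.sort(rng.normal(size=n))[::-1]
        genes = [f"G{i:03d}" for i in range(n)]
        members = list(rng.choice(genes, size=12, replace=False))
        ranked = RankedList(genes=tuple(genes), scores=scores, order="descending")
        res = enrichment_score(
            ranked, GeneSet.from_iterable("S", members), weight_p=1
        )
        ref = gseapy.prerank(
            rnk=pd.DataFrame({"gene": genes, "score": scores}),
            gene_sets={"S": members}, permutation_num=100, min_size=1,
            max_size=100, weight=1.0, seed=1, threads=1, outdir=None,
            no_plot=True,
        )
        es_ref = float(ref.res2d.loc[ref.res2d["Term"] == "S", "ES"].iloc[0])
        assert res.es == pytest.approx(es_ref, abs=1e-9)
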