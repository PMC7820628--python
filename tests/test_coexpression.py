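import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from toascore.coexpression import (
    GeneRanking,
    coexpression_msr_test,
    expression_similarity_test,
    filter_and_rank,
    mean_squared_rho,
    nearest_genes,
)
from toascore.io import CredibleSet, ValidationError, Variant


def toy_signal(signal_id, pos, ppa=1.0):
    return CredibleSet(
        signal_id, [Variant(f"{signal_id}_rs", "chr1", pos, ppa)]
    )


def gene_pos(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


class TestNearestGenes:
    genes = gene_pos([("chr1", 90, 500, "NEAR"), ("chr1", 200, 600, "FAR")])

    def test_first_nearest_by_tss(self):
        got = nearest_genes([toy_signal("s1", 100)], self.genes, k=1)
        assert got == {"s1": "NEAR"}

    def test_second_nearest(self):
        got = nearest_genes([toy_signal("s1", 100)], self.genes, k=2)
        assert got == {"s1": "FAR"}

    def test_coding_signal_excluded(self):
        got = nearest_genes(
            [toy_signal("s1", 100)], self.genes, k=1,
            coding_scores={"s1": 0.15},
        )
        assert got == {}

    def test_coding_below_cutoff_kept(self):
        got = nearest_genes(
            [toy_signal("s1", 100)], self.genes, k=1,
            coding_scores={"s1": 0.05},
        )
        assert got == {"s1": "NEAR"}

    def test_too_few_genes_dropped_with_warning(self, caplog):
        got = nearest_genes([toy_signal("s1", 100)], self.genes, k=3)
        assert got == {}

    def test_distance_tie_breaks_by_gene_id(self):
        genes = gene_pos([("chr1", 90, 100, "B"), ("chr1", 110, 120, "A")])
        got = nearest_genes([toy_signal("s1", 101)], genes, k=1)
        assert got == {"s1": "A"}  # both 10 bp away; id order decides


class TestFilterAndRank:
    def test_filter_and_rank_order(self):
        tpm = pd.DataFrame(
            {
                "i1": [100.0, 10.0, 0.0],
                "i2": [90.0, 12.0, 0.05],
                "l1": [1.0, 50.0, 0.0],
                "l2": [2.0, 60.0, 0.0],
            },
            index=["gA", "gB", "gDead"],
        )
        st_map = pd.Series({"i1": "islet", "i2": "islet",
                            "l1": "liver", "l2": "liver"})
        ranking = filter_and_rank(tpm, st_map)
        assert "gDead" in ranking.filtered_out
        # gA mean of tissue means = (95 + 1.5)/2 = 48.25; gB = (11+55)/2 = 33
        assert ranking.ranks["gA"] == 1
        assert ranking.ranks["gB"] == 2
        assert sorted(ranking.ranks.index) == ["gA", "gB"]

    def test_tissue_specific_gene_survives_default_filter(self):
        tpm = pd.DataFrame(
            {"i1": [50.0], "i2": [60.0], "l1": [0.0], "l2": [0.0]},
            index=["gIslet"],
        )
        st_map = pd.Series({"i1": "islet", "i2": "islet",
                            "l1": "liver", "l2": "liver"})
        assert "gIslet" not in filter_and_rank(tpm, st_map).filtered_out
        strict = filter_and_rank(tpm, st_map, low_in_all=False)
        assert "gIslet" in strict.filtered_out


def uniform_ranking(n):
    genes = [f"g{i:03d}" for i in range(n)]
    return GeneRanking(
        ranks=pd.Series(np.arange(1, n + 1), index=genes),
        filtered_out=frozenset(),
    )


class TestExpressionSimilarity:
    def test_top_expressed_set_is_enriched(self):
        n = 40
        ranking = uniform_ranking(n)
        # islet expression decreasing with rank -> top genes have low rank sum
        expr = pd.DataFrame(
            {"islet": np.arange(n, 0, -1, dtype=float)},
            index=ranking.genes,
        )
        res = expression_similarity_test(
            ranking.genes[:4], ranking, expr, n_perm=200, seed=1
        )[0]
        assert res.enrichment_factor > 1
        assert res.p_emp <= 5 / 201

    def test_flat_expression_factor_near_one(self):
        n = 40
        ranking = uniform_ranking(n)
        expr = pd.DataFrame({"islet": np.ones(n)}, index=ranking.genes)
        res = expression_similarity_test(
            ranking.genes[10:13], ranking, expr, n_perm=200, seed=1
        )[0]
        # identical expression -> every rank is the average rank
        assert res.enrichment_factor == pytest.approx(1.0, abs=1e-9)
        assert res.p_emp == 1.0

    def test_null_genes_respect_rank_windows(self, monkeypatch):
        from toascore import coexpression as cx

        seen = []
        orig = cx._rank_matched_null

        def spy(rng, query_ranks, background, background_ranks):
            out = orig(rng, query_ranks, background, background_ranks)
            seen.append((query_ranks.copy(), out.copy()))
            return out

        monkeypatch.setattr(cx, "_rank_matched_null", spy)
        n = 400
        ranking = uniform_ranking(n)
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            {"islet": rng.exponential(10, n)}, index=ranking.genes
        )
        query = [ranking.genes[i] for i in (10, 180, 390)]
        expression_similarity_test(query, ranking, expr, n_perm=30, seed=2)
        assert seen
        all_ranks = ranking.ranks
        for query_ranks, null_genes in seen:
            null_ranks = all_ranks.loc[null_genes].to_numpy()
            assert (np.abs(null_ranks - query_ranks) <= 100).all()
            background = np.abs(
                all_ranks.to_numpy()[:, None] - query_ranks[None, :]
            ).min(axis=1) <= 150
            bg_genes = set(np.array(ranking.genes)[background])
            assert set(null_genes) <= bg_genes

    def test_small_universe_matches_exhaustive_enumeration(self):
        """With full window overlap, nulls are uniform 3-subsets: exact p is
        an enumeration over C(30,3) combinations."""
        n = 30
        ranking = uniform_ranking(n)
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(
            {"islet": rng.permutation(np.arange(1, n + 1)).astype(float)},
            index=ranking.genes,
        )
        within = pd.Series(
            stats.rankdata(-expr["islet"].to_numpy()), index=ranking.genes
        )
        query = [ranking.genes[i] for i in (3, 14, 25)]
        obs = within.loc[query].sum()
        sums = [
            within.loc[list(sub)].sum()
            for sub in itertools.combinations(ranking.genes, 3)
        ]
        exact = sum(s <= obs for s in sums) / len(sums)
        n_perm = 3000
        res = expression_similarity_test(
            query, ranking, expr, n_perm=n_perm, seed=6
        )[0]
        band = 3 * math.sqrt(exact * (1 - exact) / n_perm) + 2 / (n_perm + 1)
        assert abs(res.p_emp - exact) <= band

    def test_unranked_gene_rejected(self):
        ranking = uniform_ranking(10)
        expr = pd.DataFrame({"islet": np.ones(10)}, index=ranking.genes)
        with pytest.raises(ValidationError, match="not in ranking"):
            expression_similarity_test(["nope"], ranking, expr, 10, 1)


class TestMsr:
    def samples(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        return rng.normal(size=n)

    def test_identical_profiles_give_one(self):
        x = self.samples()
        expr = pd.DataFrame([x, x * 2 + 1], index=["a", "b"])
        assert mean_squared_rho(expr, ["a", "b"]) == pytest.approx(1.0)

    def test_three_gene_hand_computation(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(3, 15)), index=["a", "b", "c"])
        want = np.mean(
            [
                stats.spearmanr(expr.loc[g1], expr.loc[g2]).statistic ** 2
                for g1, g2 in itertools.combinations(["a", "b", "c"], 2)
            ]
        )
        assert mean_squared_rho(expr, ["a", "b", "c"]) == pytest.approx(want)

    def test_monotone_transformation_invariance(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(3, 20)), index=["a", "b", "c"])
        transformed = np.exp(expr)  # strictly increasing
        assert mean_squared_rho(expr, ["a", "b", "c"]) == pytest.approx(
            mean_squared_rho(transformed, ["a", "b", "c"])
        )

    def test_zero_variance_gene_dropped(self, caplog):
        expr = pd.DataFrame(
            [np.ones(10), np.arange(10.0), np.arange(10.0)[::-1]],
            index=["flat", "up", "down"],
        )
        got = mean_squared_rho(expr, ["flat", "up", "down"])
        assert got == pytest.approx(1.0)  # only (up, down) remains

    def test_null_from_proximal_universe_enumeration(self):
        """Small-universe msr p matches enumeration over all 2-subsets."""
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(6)]
        samples = [f"s{j}" for j in range(10)]
        expr = pd.DataFrame(
            rng.normal(size=(6, 10)), index=genes, columns=samples
        )
        st_map = pd.Series({s: "islet" for s in samples})
        query = ["g0", "g1"]
        obs = mean_squared_rho(expr, query)
        msrs = [
            mean_squared_rho(expr, list(sub))
            for sub in itertools.combinations(genes, 2)
        ]
        exact = sum(m >= obs for m in msrs) / len(msrs)
        n_perm = 2000
        res = coexpression_msr_test(
            query, expr, st_map, genes, n_perm=n_perm, seed=8
        )[0]
        assert res.statistic == pytest.approx(obs)
        band = 3 * math.sqrt(exact * (1 - exact) / n_perm) + 2 / (n_perm + 1)
        assert abs(res.p_emp - exact) <= band

    def test_seeded_determinism(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(8)]
        expr = pd.DataFrame(rng.normal(size=(8, 10)), index=genes)
        st_map = pd.Series({c: "islet" for c in expr.columns})
        kw = dict(gene_set=["g0", "g1", "g2"], expression=expr,
                  sample_tissue=st_map, proximal_universe=genes,
                  n_perm=100, seed=9)
        assert coexpression_msr_test(**kw) == coexpression_msr_test(**kw)
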