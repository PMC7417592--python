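"""Preranked enrichment: ranking statistic, weighted-KS running sum,
permutation null, leading edges and activity scores."""

import numpy as np
import pandas as pd
import pytest

from ascpath.enrichment import (
    RankedGeneList,
    activity_score,
    gsea_preranked,
    leading_edge,
    pseudotime_profile,
    rank_genes,
)
from ascpath.enrichment import _perm_es, _running_extremum


def brute_force_es(scores, hit, weight=1.0):
    """O(N*|S|)-style literal running-sum oracle, independent code path."""
    n = len(scores)
    n_hit = int(sum(hit))
    denom = sum(abs(scores[i]) ** weight for i in range(n) if hit[i])
    running, best, best_i = 0.0, 0.0, 0
    for i in range(n):
        if hit[i]:
            running += (abs(scores[i]) ** weight) / denom if denom > 0 else 0.0
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best):
            best, best_i = running, i
    return best, best_i


def ranked_from(scores, genes=None):
    genes = genes or [f"G{i}" for i in range(len(scores))]
    s = pd.Series(scores, index=genes).sort_values(ascending=False, kind="mergesort")
    return RankedGeneList(scores=s)


class TestRankGenes:
    def table(self):
        return pd.DataFrame(
            {
                "p": [0.0, 1.0, 0.2, 0.01, 0.5],
                "log2fc": [2.0, 1.0, -1.5, -3.0, 0.0],
            },
            index=["up_certain", "null", "down_mild", "down_strong", "no_sign"],
        )

    def test_certain_upregulated_first(self):
        ranked = rank_genes(self.table())
        assert ranked.genes[0] == "up_certain"
        assert ranked.scores.iloc[0] == 1.0

    def test_zero_sign_dropped(self):
        ranked = rank_genes(self.table())
        assert "no_sign" not in ranked.genes

    def test_downregulated_significant_last(self):
        ranked = rank_genes(self.table())
        assert ranked.genes[-1] == "down_strong"

    def test_literal_mode(self):
        ranked = rank_genes(self.table(), mode="literal")
        expected = {"up_certain": 0.0, "null": 1.0, "down_mild": -0.2,
                    "down_strong": -0.01}
        for g, v in expected.items():
            np.testing.assert_allclose(ranked.scores[g], v)

    def test_full_ordering_matches_sort_oracle(self, rng):
        p = rng.random(10)
        fc = rng.normal(0, 2, 10)
        fc[fc == 0] = 1.0
        table = pd.DataFrame({"p": p, "log2fc": fc},
                             index=[f"G{i}" for i in range(10)])
        ranked = rank_genes(table)
        scores = {g: np.sign(fc[i]) * (1 - p[i]) for i, g in enumerate(table.index)}
        oracle = sorted(table.index, key=lambda g: (-scores[g], -abs(fc[list(table.index).index(g)]), g))
        assert list(ranked.genes) == oracle

    def test_duplicate_genes_rejected(self):
        s = pd.Series([1.0, 0.5], index=["A", "A"])
        with pytest.raises(ValueError):
            RankedGeneList(scores=s)


class TestGseaPreranked:
    def test_single_top_gene_gives_unit_es(self, rng):
        ranked = ranked_from(np.linspace(1, 0.1, 20))
        res = gsea_preranked(ranked, [ranked.genes[0]], n_perm=50, seed=1)
        np.testing.assert_allclose(res.es, 1.0)
        assert res.leading_edge == [ranked.genes[0]]

    def test_es_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            scores = np.sort(rng.normal(0, 1, n))[::-1]
            k = int(rng.integers(1, max(2, n // 3)))
            members = rng.choice(n, size=k, replace=False)
            genes = [f"G{i}" for i in range(n)]
            ranked = RankedGeneList(scores=pd.Series(scores, index=genes))
            gene_set = [genes[i] for i in members]
            res = gsea_preranked(ranked, gene_set, n_perm=10, seed=1)
            hit = [g in set(gene_set) for g in genes]
            es_oracle, _ = brute_force_es(list(scores), hit)
            np.testing.assert_allclose(res.es, es_oracle, atol=1e-12)

    def test_permutation_null_matches_full_cumsum(self, rng):
        # the fast hit-position permutation ES must equal the O(N) running sum
        n, k = 40, 7
        scores = np.sort(rng.normal(0, 1, n))[::-1]
        rng2 = np.random.default_rng(5)
        null = _perm_es(scores, k, 200, 1.0, np.random.default_rng(9))
        rng3 = np.random.default_rng(9)
        pos = np.argsort(rng3.random((200, n)), axis=1)[:, :k]
        pos.sort(axis=1)
        for row in range(200):
            hit = np.zeros(n, bool)
            hit[pos[row]] = True
            es, _ = _running_extremum(scores, hit, 1.0)
            np.testing.assert_allclose(null[row], es, atol=1e-12)

    def test_reversed_list_flips_es_sign(self, rng):
        n = 30
        scores = np.linspace(1, -1, n)
        genes = [f"G{i}" for i in range(n)]
        ranked = RankedGeneList(scores=pd.Series(scores, index=genes))
        rev = RankedGeneList(
            scores=pd.Series(-scores[::-1], index=genes[::-1])
        )
        gene_set = genes[:5]
        a = gsea_preranked(ranked, gene_set, n_perm=10, seed=1)
        b = gsea_preranked(rev, gene_set, n_perm=10, seed=1)
        np.testing.assert_allclose(a.es, -b.es, atol=1e-12)

    def test_p_floor_is_one_over_nperm_plus_one(self):
        ranked = ranked_from(np.linspace(1, 0.05, 50))
        res = gsea_preranked(ranked, list(ranked.genes[:8]), n_perm=200, seed=2)
        assert res.p_value >= 1 / 201
        np.testing.assert_allclose(res.p_value, 1 / 201)

    def test_empty_intersection_errors(self):
        ranked = ranked_from([1.0, 0.5])
        with pytest.raises(ValueError):
            gsea_preranked(ranked, ["absent"], n_perm=10, seed=1)


class TestLeadingEdge:
    def test_positive_es_takes_members_before_peak(self, rng):
        scores = np.linspace(1, -1, 20)
        genes = [f"G{i}" for i in range(20)]
        ranked = RankedGeneList(scores=pd.Series(scores, index=genes))
        gene_set = ["G0", "G1", "G2", "G19"]
        res = gsea_preranked(ranked, gene_set, n_perm=10, seed=1)
        assert res.es > 0
        assert set(res.leading_edge) == {"G0", "G1", "G2"}

    def test_leading_edge_subset_matches_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(12, 40))
            scores = np.sort(rng.normal(0, 1, n))[::-1]
            genes = [f"G{i}" for i in range(n)]
            members = rng.choice(n, size=5, replace=False)
            gene_set = [genes[i] for i in members]
            ranked = RankedGeneList(scores=pd.Series(scores, index=genes))
            res = gsea_preranked(ranked, gene_set, n_perm=5, seed=1)
            hit = [g in set(gene_set) for g in genes]
            es, idx = brute_force_es(list(scores), hit)
            if es > 0:
                expected = [genes[i] for i in range(n) if hit[i] and i <= idx]
            elif es < 0:
                expected = [genes[i] for i in range(n) if hit[i] and i >= idx]
            else:
                expected = []
            assert res.leading_edge == expected
            assert set(res.leading_edge) <= set(gene_set)


class TestActivityScore:
    def frame(self):
        return pd.DataFrame(
            [[0.0, 2.0], [0.0, 4.0]], index=["A", "B"], columns=["c1", "c2"]
        )

    def test_zero_cell(self):
        out = activity_score(self.frame(), ["A", "B"])
        assert out["c1"] == 0.0

    def test_single_gene_cube(self):
        out = activity_score(self.frame(), ["A"])
        assert out["c2"] == 8.0

    def test_mean_of_cubes_mode(self):
        out = activity_score(self.frame(), ["A", "B"], mode="mean-of-cubes")
        np.testing.assert_allclose(out["c2"], (8 + 64) / 2)

    def test_ranking_matches_plain_mean(self, rng):
        expr = pd.DataFrame(
            rng.random((10, 30)), index=[f"G{i}" for i in range(10)]
        )
        genes = [f"G{i}" for i in range(4)]
        score = activity_score(expr, genes)
        mean = expr.loc[genes].mean(axis=0)
        assert (score.rank() == mean.rank()).all()

    def test_empty_intersection_errors(self):
        with pytest.raises(ValueError):
            activity_score(self.frame(), ["missing"])


class TestPseudotimeProfile:
    def test_constant_gene_all_ones(self, rng):
        expr = pd.DataFrame(
            np.ones((1, 40)), index=["G0"], columns=[f"c{i}" for i in range(40)]
        )
        pt = pd.Series(rng.random(40), index=expr.columns)
        prof = pseudotime_profile(expr, pt, ["G0"], n_bins=8)
        np.testing.assert_allclose(prof.to_numpy(), 1.0)

    def test_monotone_gene_peaks_last(self):
        cells = [f"c{i}" for i in range(30)]
        pt = pd.Series(np.arange(30, dtype=float), index=cells)
        expr = pd.DataFrame([np.arange(30, dtype=float)], index=["G0"], columns=cells)
        prof = pseudotime_profile(expr, pt, ["G0"], n_bins=6)
        assert prof.iloc[0, -1] == 1.0
        assert (np.diff(prof.iloc[0].to_numpy()) > 0).all()

    def test_row_maxima_are_one(self, rng):
        cells = [f"c{i}" for i in range(50)]
        expr = pd.DataFrame(
            rng.random((5, 50)) + 0.1, index=[f"G{i}" for i in range(5)], columns=cells
        )
        pt = pd.Series(rng.random(50), index=cells)
        prof = pseudotime_profile(expr, pt, list(expr.index), n_bins=10)
        np.testing.assert_allclose(prof.max(axis=1), 1.0)

    def test_too_many_bins_errors(self, rng):
        cells = [f"c{i}" for i in range(5)]
        expr = pd.DataFrame(np.ones((1, 5)), index=["G0"], columns=cells)
        pt = pd.Series(np.arange(5.0), index=cells)
        with pytest.raises(ValueError):
            pseudotime_profile(expr, pt, ["G0"], n_bins=10)
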