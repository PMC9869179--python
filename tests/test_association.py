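import numpy as np
import pytest
import scipy.stats

from hifmeta import (
    CorrelationRecord,
    DiffExprRecord,
    ExpressionMatrix,
    ScoreTable,
    adjusted_association,
    compare_groups,
    correlate_with_score,
    preranked_gsea,
    rank_score,
    sharing_counts,
)

from oracles import gsea_es_oracle


def matrix(values, layer="normalized"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(values.shape[0])],
        [f"s{i}" for i in range(values.shape[1])],
        layer,
    )


def scores_for(m, values):
    return ScoreTable(list(m.sample_ids), np.asarray(values, dtype=float),
                      1, "quantile_sum")


class TestCorrelateWithScore:
    def test_perfect_linear_gene(self):
        s = np.array([1.0, 2.0, 3.0, 4.0])
        m = matrix([2.0 ** (2 * s + 1) - 1])  # log2(x+1) = 2s+1, exactly linear
        (rec,) = correlate_with_score(m, scores_for(m, s))
        assert rec.r == pytest.approx(1.0)
        assert rec.direction == "positive"

    def test_constant_gene_omitted(self):
        m = matrix([[3.0, 3.0, 3.0, 3.0], [1.0, 2.0, 4.0, 8.0]])
        recs = correlate_with_score(m, scores_for(m, [1, 2, 3, 4]))
        assert [r.gene_id for r in recs] == ["g1"]

    def test_exclusion(self):
        m = matrix([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        recs = correlate_with_score(m, scores_for(m, [1, 2, 3]), exclude={"g0"})
        assert [r.gene_id for r in recs] == ["g1"]

    def test_sample_mismatch_raises(self):
        m = matrix([[1.0, 2.0, 3.0]])
        table = ScoreTable(["a", "b", "c"], np.zeros(3) + [1, 2, 3], 1,
                           "quantile_sum")
        with pytest.raises(ValueError, match="match"):
            correlate_with_score(m, table)

    def test_affine_score_invariance(self, rng):
        m = matrix(rng.uniform(0, 50, (10, 20)))
        s = rng.normal(size=20)
        base = correlate_with_score(m, scores_for(m, s))
        shifted = correlate_with_score(m, scores_for(m, 3.0 * s - 7.0))
        for a, b in zip(base, shifted):
            assert a.r == pytest.approx(b.r, abs=1e-12)
            assert a.p_value == pytest.approx(b.p_value, rel=1e-9)

    def test_p_matches_scipy_pearson(self, rng):
        m = matrix(rng.uniform(0, 50, (5, 30)))
        s = rng.normal(size=30)
        recs = correlate_with_score(m, scores_for(m, s))
        for rec in recs:
            x = np.log2(m.gene_row(rec.gene_id) + 1)
            ref = scipy.stats.pearsonr(x, s)
            assert rec.r == pytest.approx(ref.statistic, abs=1e-12)
            assert rec.p_value == pytest.approx(ref.pvalue, rel=1e-9)


class TestSharingCounts:
    def rec(self, g, r, p):
        return CorrelationRecord(g, r, p, 10,
                                 "positive" if r >= 0 else "negative")

    def test_single_dataset(self):
        recs = [self.rec("a", 0.9, 1e-8), self.rec("b", 0.8, 1e-7),
                self.rec("c", 0.5, 0.01)]
        out = sharing_counts([recs], 1e-6)
        assert out[("positive", 1)] == 2
        assert out[("negative", 1)] == 0

    def test_directions_never_pooled(self):
        d1 = [self.rec("a", 0.9, 1e-8)]
        d2 = [self.rec("a", -0.9, 1e-8)]
        out = sharing_counts([d1, d2], 1e-6)
        assert out[("positive", 1)] == 1
        assert out[("negative", 1)] == 1
        assert out[("positive", 2)] == 0

    def test_matches_brute_force_tally(self, rng):
        datasets = []
        genes = [f"g{i}" for i in range(30)]
        for _ in range(6):
            datasets.append([
                self.rec(g, float(rng.normal()), float(rng.uniform(1e-9, 1e-3)))
                for g in genes
            ])
        thresh = 1e-6
        out = sharing_counts(datasets, thresh)
        for direction in ("positive", "negative"):
            per_gene = {
                g: sum(
                    any(r.gene_id == g and r.direction == direction
                        and r.p_value <= thresh for r in ds)
                    for ds in datasets
                )
                for g in genes
            }
            for m in range(1, 7):
                assert out[(direction, m)] == sum(
                    1 for c in per_gene.values() if c >= m
                )

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            sharing_counts([], 1e-6)


class TestRankScore:
    def test_examples(self):
        de = [DiffExprRecord("a", 2.0, 0.001), DiffExprRecord("b", -1.0, 0.01),
              DiffExprRecord("c", 1.0, 1.0)]
        ranked = dict(rank_score(de))
        assert ranked["a"] == pytest.approx(6.0)
        assert ranked["b"] == pytest.approx(-2.0)
        assert ranked["c"] == pytest.approx(0.0)  # padj=1 => 0 regardless of fc

    def test_descending_with_lexicographic_ties(self):
        de = [DiffExprRecord("z", 1.0, 0.1), DiffExprRecord("a", 1.0, 0.1)]
        assert [g for g, _ in rank_score(de)] == ["a", "z"]

    def test_ordering_invariant_to_monotone_p_rescale(self, rng):
        # fixed log2fc signs: monotone rescale of -log10 padj preserves order
        de = [DiffExprRecord(f"g{i}", float(abs(rng.normal()) + 0.1),
                             float(rng.uniform(1e-8, 0.9))) for i in range(20)]
        order1 = [g for g, _ in rank_score(de)]
        rescaled = [DiffExprRecord(r.gene_id, r.log2fc, r.padj ** 2) for r in de]
        order2 = [g for g, _ in rank_score(rescaled)]
        assert order1 == order2


class TestPrerankedGsea:
    def test_top_block_es_one(self):
        ranked = [(f"g{i}", 1.0) for i in range(10)]
        res = preranked_gsea(ranked, {"g0", "g1", "g2"}, 1.0, n_perm=50, seed=0)
        assert res.es == pytest.approx(1.0)

    def test_hand_stepped_example(self):
        ranked = [("a", 3.0), ("b", 2.0), ("c", 1.0), ("d", -1.0), ("e", -2.0)]
        res = preranked_gsea(ranked, {"a", "c"}, 1.0, n_perm=50, seed=0)
        assert res.es == pytest.approx(0.75)

    def test_seeded_determinism(self, rng):
        ranked = [(f"g{i}", float(s)) for i, s in enumerate(rng.normal(size=50))]
        gene_set = {f"g{i}" for i in range(0, 50, 7)}
        a = preranked_gsea(ranked, gene_set, 1.0, 200, seed=9)
        b = preranked_gsea(ranked, gene_set, 1.0, 200, seed=9)
        assert (a.p_value, a.nes) == (b.p_value, b.nes)

    def test_p_floor(self, rng):
        ranked = [(f"g{i}", 10.0 - i) for i in range(20)]
        res = preranked_gsea(ranked, {"g0", "g1"}, 1.0, n_perm=100, seed=0)
        assert res.p_value >= 1 / 101

    def test_empty_intersection_raises(self):
        with pytest.raises(ValueError):
            preranked_gsea([("a", 1.0)], {"zzz"}, 1.0, 10, 0)

    def test_es_matches_literal_oracle(self, rng):
        from hifmeta.association import _running_es

        for _ in range(100):
            n = int(rng.integers(10, 60))
            scores = rng.normal(size=n)
            n_hits = int(rng.integers(1, n))
            hit_idx = rng.choice(n, size=n_hits, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[hit_idx] = True
            weight = float(rng.choice([0.0, 0.5, 1.0, 2.0]))
            assert _running_es(scores, mask, weight) == pytest.approx(
                gsea_es_oracle(scores, mask, weight), abs=1e-12
            )


class TestAdjustedAssociation:
    def test_reduces_to_simple_regression(self, rng):
        m = matrix(rng.uniform(0, 50, (1, 40)))
        s = rng.normal(size=40)
        (rec,) = correlate_with_score(m, scores_for(m, s))
        gene = np.log2(m.values[0] + 1)
        coef, p = adjusted_association(gene, s)
        assert p == pytest.approx(rec.p_value, rel=1e-9)

    def test_null_score_coefficient(self, rng):
        pvals = []
        for _ in range(50):
            cov = rng.normal(size=100)
            gene = cov + rng.normal(0, 0.1, 100)
            s = rng.normal(size=100)  # independent of gene
            _, p = adjusted_association(gene, s, cov)
            pvals.append(p)
        assert scipy.stats.kstest(pvals, "uniform").pvalue > 1e-3

    def test_planted_confound_recovery(self, rng):
        import statsmodels.api as sm

        s = rng.normal(size=500)
        cov = rng.normal(size=500)
        gene = s + 2.0 * cov + rng.normal(0, 1.0, 500)
        coef, p = adjusted_association(gene, s, cov)
        fit = sm.OLS(gene, np.column_stack([np.ones(500), s, cov])).fit()
        se = fit.bse[1]
        assert abs(coef - 1.0) < 3 * se
        assert p < 1e-6

    def test_rank_deficient_raises(self, rng):
        s = rng.normal(size=30)
        with pytest.raises(ValueError, match="rank"):
            adjusted_association(rng.normal(size=30), s, np.column_stack([s, s]))

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            adjusted_association([1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                                 np.ones((3, 1)))


class TestCompareGroups:
    def table(self, values):
        return ScoreTable([f"s{i}" for i in range(len(values))],
                          np.asarray(values, dtype=float), 5, "quantile_sum")

    def test_identical_distributions(self):
        t = self.table([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = {f"s{i}": ("a" if i < 3 else "b") for i in range(6)}
        res = compare_groups(t, labels, ("a", "b"))
        assert res.ranksum.p_value == pytest.approx(1.0)

    def test_medians_reported(self):
        t = self.table([1.0, 2.0, 10.0, 20.0])
        labels = {"s0": "lo", "s1": "lo", "s2": "hi", "s3": "hi"}
        res = compare_groups(t, labels, ("hi", "lo"))
        assert res.medians == (15.0, 1.5)

    def test_unknown_group_raises(self):
        t = self.table([1.0, 2.0])
        labels = {"s0": "a", "s1": "b"}
        with pytest.raises(ValueError, match="unknown group"):
            compare_groups(t, labels, ("a", "zzz"))

    def test_empty_group_raises(self):
        t = self.table([1.0, 2.0])
        labels = {"s0": "a", "s1": "a", "ghost": "b"}
        with pytest.raises(ValueError, match="non-empty"):
            compare_groups(t, labels, ("a", "b"))
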