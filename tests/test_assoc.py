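"""Association statistics and gene-set enrichment, cross-checked against
scipy implementations and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epitax.assoc import (anova_association, chisq_association,
                          contingency_chisq, de_rank, fdr_flag, gsea)


class TestContingencyChisq:
    def test_proportional_table_null(self):
        res = contingency_chisq([[10, 20], [5, 10]])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_2x2_hand_arithmetic_and_permutation_oracle(self):
        table = np.array([[25, 15], [18, 26]])
        res = contingency_chisq(table)
        # hand walk of sum (O-E)^2 / E
        row, col, n = table.sum(1), table.sum(0), table.sum()
        e = np.outer(row, col) / n
        assert res.chi2 == pytest.approx(((table - e) ** 2 / e).sum())
        # Monte-Carlo permutation-of-labels oracle (table large enough for the
        # asymptotic chi-square tail to be accurate)
        labels = np.repeat([0, 1], row)
        groups = np.concatenate([np.repeat([0, 1], table[0]),
                                 np.repeat([0, 1], table[1])])
        rng = np.random.default_rng(0)
        count = 0
        for _ in range(4000):
            perm = rng.permutation(groups)
            t = pd.crosstab(labels, perm).to_numpy()
            e = np.outer(t.sum(1), t.sum(0)) / t.sum()
            count += ((t - e) ** 2 / e).sum() >= res.chi2 - 1e-9
        mc_p = count / 4000
        assert res.p == pytest.approx(
            mc_p, abs=0.01 + 4 * np.sqrt(mc_p * (1 - mc_p) / 4000))

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(100):
            t = rng.integers(1, 40, size=(rng.integers(2, 5), rng.integers(2, 5)))
            res = contingency_chisq(t)
            chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
            assert res.chi2 == pytest.approx(chi2, rel=1e-10)
            assert res.p == pytest.approx(p, rel=1e-8)
            assert res.df == df

    def test_zero_margin_names_level(self):
        t = pd.DataFrame([[0, 0], [3, 4]], index=["empty", "full"])
        with pytest.raises(ValueError, match="empty"):
            contingency_chisq(t)

    def test_drop_levels(self):
        labels = ["c1"] * 6 + ["c2"] * 6
        cov = ["low", "low", "high", "NA", "low", "high",
               "high", "high", "NA", "low", "high", "high"]
        res = chisq_association(labels, cov, drop_levels=["NA"])
        assert res.observed.to_numpy().sum() == 10


class TestAnova:
    def test_equal_means_f_zero(self):
        labels = [0] * 4 + [1] * 4
        cov = [1.0, 2.0, 3.0, 4.0] * 2
        res = anova_association(labels, cov)
        assert res.f == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_two_group_f_is_t_squared(self, rng):
        labels = np.repeat([0, 1], [8, 12])
        cov = rng.normal(size=20) + labels
        res = anova_association(labels, cov)
        t = stats.ttest_ind(cov[labels == 0], cov[labels == 1], equal_var=True)
        assert res.f == pytest.approx(t.statistic ** 2)
        assert res.p == pytest.approx(t.pvalue)

    def test_textbook_three_groups(self):
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        cov = [1, 2, 3, 7, 8, 9, 4, 5, 6]
        res = anova_association(labels, cov)
        f, p = stats.f_oneway([1, 2, 3], [7, 8, 9], [4, 5, 6])
        assert res.f == pytest.approx(f)
        assert res.p == pytest.approx(p)

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            anova_association([0, 0, 0], [1.0, 2.0, 3.0])


class TestDeRank:
    def _expr(self, rng, n_genes=50, n=20):
        return pd.DataFrame(rng.normal(size=(n_genes, n)),
                            index=[f"g{i}" for i in range(n_genes)])

    def test_constant_gene_scores_zero(self, rng):
        expr = self._expr(rng)
        expr.iloc[0] = 7.0
        labels = np.repeat([0, 1], 10)
        s = de_rank(expr, labels, 0)
        assert s["g0"] == 0.0

    def test_indicator_gene_ranked_first(self, rng):
        expr = self._expr(rng)
        labels = np.repeat([0, 1], 10)
        expr.iloc[0] = (labels == 0) + rng.normal(0, 1e-3, 20)
        s = de_rank(expr, labels, 0)
        assert s.index[0] == "g0"
        # sd floor caps the statistic near 1/(0.2+0.2)
        assert s["g0"] == pytest.approx(1.0 / 0.4, rel=0.05)

    def test_label_swap_antisymmetry(self, rng):
        expr = self._expr(rng)
        labels = np.repeat([0, 1], 10)
        a = de_rank(expr, labels, 0)
        b = de_rank(expr, labels, 1)
        assert np.allclose(a.sort_index(), -b.sort_index())

    def test_small_group_rejected(self, rng):
        expr = self._expr(rng, n=5)
        with pytest.raises(ValueError):
            de_rank(expr, [0, 1, 1, 1, 1], 0)


def brute_force_es(scores_desc: np.ndarray, hit_positions: np.ndarray,
                   weight: float) -> float:
    """Full running-sum oracle for the weighted KS enrichment score."""
    n = scores_desc.size
    hits = np.zeros(n, dtype=bool)
    hits[hit_positions] = True
    w = np.abs(scores_desc) ** weight * hits
    nr = w.sum()
    if nr == 0:
        w = hits.astype(float)
        nr = w.sum()
    step = np.where(hits, w / nr, -1.0 / (n - hits.sum()))
    run = np.cumsum(step)
    return float(run.max()), float(run.min())


def assert_es_matches(got: float, hi: float, lo: float):
    """The ES is the extremum of larger magnitude; when the positive and
    negative extrema tie in magnitude (common at weight 0, where steps are
    rational), floating-point round-off decides the sign, so either extremum
    is accepted."""
    if abs(hi + lo) < 1e-9:
        assert got == pytest.approx(hi, abs=1e-9) or got == pytest.approx(lo, abs=1e-9)
    elif hi >= -lo:
        assert got == pytest.approx(hi, abs=1e-12)
    else:
        assert got == pytest.approx(lo, abs=1e-12)


class TestGsea:
    def _data(self, seed=0, n_genes=500, n=30):
        rng = np.random.default_rng(seed)
        expr = pd.DataFrame(rng.normal(size=(n_genes, n)),
                            index=[f"g{i}" for i in range(n_genes)])
        labels = np.repeat([0, 1], [n // 2, n - n // 2])
        return rng, expr, labels

    def test_es_matches_brute_force_oracle(self):
        from epitax.assoc import _es_from_positions
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = 120
            scores = np.sort(rng.normal(size=n))[::-1]
            pos = np.sort(rng.choice(n, rng.integers(5, 30), replace=False))
            for wt in (0.0, 1.0):
                got = _es_from_positions(pos, np.abs(scores[pos]) ** wt, n)
                hi, lo = brute_force_es(scores, pos, wt)
                assert_es_matches(got, hi, lo)

    def test_nominal_p_uniform_under_null(self):
        rng, expr, labels = self._data()
        sets = {f"set{i}": [f"g{j}" for j in rng.choice(500, 25, replace=False)]
                for i in range(200)}
        res = gsea(expr, labels, 0, sets, n_perm=200, seed=1)
        assert stats.kstest(res.table["p"], "uniform").pvalue > 0.01
        assert (res.table["ES"].abs() <= 1.0).all()

    def test_oversized_set_skipped(self):
        _, expr, labels = self._data(n_genes=50)
        sets = {"all": [f"g{i}" for i in range(50)],
                "ok": [f"g{i}" for i in range(10)]}
        with pytest.warns(UserWarning, match="all"):
            res = gsea(expr, labels, 0, sets, n_perm=50, seed=0)
        assert res.table.index.tolist() == ["ok"]

    def test_seeded_permutation_reproducibility(self):
        _, expr, labels = self._data()
        sets = {"s": [f"g{i}" for i in range(20)]}
        a = gsea(expr, labels, 0, sets, n_perm=100, seed=3).table
        b = gsea(expr, labels, 0, sets, n_perm=100, seed=3).table
        assert a.equals(b)

    def test_planted_signal_flagged_at_fdr(self):
        flagged = 0
        for seed in range(5):
            rng, expr, labels = self._data(seed=seed)
            members = [f"g{i}" for i in range(20)]
            expr.loc[members, labels == 0] += 1.5
            sets = {"signal": members}
            sets.update({f"null{i}": [f"g{j}" for j in rng.choice(500, 20, replace=False)]
                         for i in range(20)})
            res = gsea(expr, labels, 0, sets, n_perm=200, seed=seed)
            hits = fdr_flag(res, threshold=0.2)
            flagged += "signal" in hits.index
        assert flagged >= 4

    def test_fdr_flag_filters_and_sorts(self):
        table = pd.DataFrame({"ES": [0.5, -0.6], "NES": [1.2, -2.0],
                              "p": [0.1, 0.01], "q": [0.3, 0.1], "size": [10, 12]},
                             index=["a", "b"])
        out = fdr_flag(table, threshold=0.2)
        assert out.index.tolist() == ["b"]
        assert fdr_flag(table, threshold=0.05).empty
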