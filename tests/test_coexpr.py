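import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import pearsonr as scipy_pearsonr

from varex.coexpr import (build_network, cooks_screen, embed_2d, gene_distance,
                          pairwise_correlations, pearson_test, spearman_as89,
                          winsorize)
from varex.errors import InputError


class TestWinsorize:
    def test_worked_example(self):
        np.testing.assert_array_equal(winsorize([1, 2, 3, 100], frac=0.25),
                                      [2, 2, 3, 3])

    def test_zero_fraction_is_identity(self):
        x = np.array([5.0, 1.0, 9.0])
        np.testing.assert_array_equal(winsorize(x, frac=0.0), x)

    def test_order_statistics_properties(self):
        """Winsorizing clamps exactly the tails: interior order statistics
        are untouched, outputs stay within [x_(k+1), x_(n-k)], and the
        transform is idempotent and monotone."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.standard_cauchy(40)
            k = int(0.1 * 40)
            w = winsorize(x, 0.1)
            srt = np.sort(x)
            assert w.min() == srt[k] and w.max() == srt[-k - 1]
            np.testing.assert_array_equal(np.sort(w)[k:-k], srt[k:-k])
            np.testing.assert_array_equal(winsorize(w, 0.1), w)
            order = np.argsort(x, kind="mergesort")
            assert np.all(np.diff(w[order]) >= 0)

    def test_matches_scipy_mstats(self):
        from scipy.stats.mstats import winsorize as scipy_winsorize

        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 37)
        np.testing.assert_allclose(winsorize(x, 0.1),
                                   np.asarray(scipy_winsorize(x, (0.1, 0.1))))

    def test_invalid_inputs(self):
        with pytest.raises(InputError):
            winsorize([], 0.05)
        with pytest.raises(InputError):
            winsorize([1.0, 2.0], 0.4)


class TestPearsonTest:
    def test_perfect_correlation(self):
        r, t, p = pearson_test([1, 2, 3], [1, 2, 3])
        assert (r, p) == (1.0, 0.0)

    def test_worked_example(self):
        """x=[1,2,3,4], y=[2,1,4,3]: r = 0.6 exactly, p ~ 0.40."""
        r, t, p = pearson_test([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6, abs=1e-12)
        assert p == pytest.approx(0.40, abs=0.01)

    def test_sign_equivariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, (2, 20))
        r1, _, p1 = pearson_test(x, y)
        r2, _, p2 = pearson_test(x, -y)
        assert r2 == pytest.approx(-r1)
        assert p2 == pytest.approx(p1)

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        for n in (5, 10, 50):
            x, y = rng.normal(0, 1, (2, n))
            r, t, p = pearson_test(x, y)
            ref = scipy_pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, (2, 15))
        r1, _, p1 = pearson_test(x, y)
        r2, _, p2 = pearson_test(3 * x + 7, 0.5 * y - 2)
        assert r2 == pytest.approx(r1, abs=1e-12)
        assert p2 == pytest.approx(p1, rel=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(InputError):
            pearson_test([1, 1, 1], [1, 2, 3])


def _exact_two_sided_oracle(x, y):
    """Independent enumeration: mass of rank permutations with |r| >= |r_obs|."""
    n = len(x)
    rx = np.argsort(np.argsort(x)) + 1.0
    ry = np.argsort(np.argsort(y)) + 1.0
    r_obs = np.corrcoef(rx, ry)[0, 1]
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        hits += abs(r) >= abs(r_obs) - 1e-12
        total += 1
    return hits / total


class TestSpearmanAs89:
    def test_monotone_n4_exact(self):
        res = spearman_as89([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.rs == pytest.approx(1.0)
        assert res.p == pytest.approx(2 / 24)
        assert res.method == "exact"

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for n in (4, 5, 6, 7):
            for _ in range(5):
                x = rng.permutation(n).astype(float)
                y = rng.permutation(n).astype(float)
                res = spearman_as89(x, y, method="exact")
                assert res.p == pytest.approx(_exact_two_sided_oracle(x, y),
                                              abs=1e-12)

    def test_edgeworth_matches_reference_values(self):
        """AS 89 Edgeworth branch against p-values from R 4.3.3
        cor.test(method='spearman', exact=TRUE), whose C code implements
        the same algorithm."""
        cases = [  # (n, S, reference two-sided p)
            (10, 136, 0.6319673639), (10, 78, 0.1228031876),
            (10, 180, 0.8114169531), (12, 170, 0.1926121839),
            (12, 254, 0.7327754460), (12, 326, 0.6671505360),
            (15, 532, 0.8625847745), (15, 732, 0.2649417048),
            (15, 560, 1.0), (20, 990, 0.2754340015),
            (20, 1306, 0.9417174960), (20, 1194, 0.6672619873),
        ]
        from varex.coexpr import _spearman_p_as89

        for n, s, ref in cases:
            assert _spearman_p_as89(n, float(s)) == pytest.approx(ref, abs=5e-3)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(6)
        ps = [spearman_as89(rng.normal(0, 1, 12), rng.normal(0, 1, 12)).p
              for _ in range(300)]
        # coarse uniformity: quartile occupancy
        counts, _ = np.histogram(ps, bins=4, range=(0, 1))
        assert counts.min() > 0.25 * 300 * 0.5

    def test_ties_fall_back_to_t_approx(self):
        res = spearman_as89([1, 1, 2, 3, 4], [5, 4, 3, 2, 1])
        assert res.method == "t-approx"

    def test_too_short_rejected(self):
        with pytest.raises(InputError):
            spearman_as89([1, 2, 3], [3, 2, 1])


class TestCooksScreen:
    def test_gross_outlier_flagged_alone(self):
        x = np.array([1, 2, 3, 4, 10], dtype=float)
        y = np.array([1, 2, 3, 4, 0], dtype=float)
        screen = cooks_screen(x, y)
        assert screen.flags.tolist() == [False, False, False, False, True]

    def test_collinear_data_has_zero_distances(self):
        x = np.arange(6, dtype=float)
        screen = cooks_screen(x, 2 * x + 1)
        np.testing.assert_allclose(screen.distances, 0.0)
        assert not screen.flags.any()

    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm
        from statsmodels.stats.outliers_influence import OLSInfluence

        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 25)
        y = 2 * x + rng.normal(0, 1, 25)
        mine = cooks_screen(x, y).distances
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        ref = OLSInfluence(ols).cooks_distance[0]
        np.testing.assert_allclose(mine, ref, rtol=1e-8)

    def test_affine_invariance_of_flags(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 20)
        y = x + rng.normal(0, 0.5, 20)
        base = cooks_screen(x, y)
        scaled = cooks_screen(5 * x - 3, -2 * y + 11)
        np.testing.assert_allclose(base.distances, scaled.distances, rtol=1e-9)

    def test_constant_x_rejected(self):
        with pytest.raises(InputError):
            cooks_screen([1.0] * 5, [1, 2, 3, 4, 5])


class TestGeneDistance:
    def test_perfect_correlation_of_either_sign_is_zero(self):
        r = pd.DataFrame([[1.0, -1.0], [-1.0, 1.0]],
                         index=["a", "b"], columns=["a", "b"])
        d = gene_distance(r)
        assert d.loc["a", "b"] == 0.0

    def test_uncorrelated_is_distance_one(self):
        r = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]],
                         index=["a", "b"], columns=["a", "b"])
        assert gene_distance(r).loc["a", "b"] == 1.0

    def test_triangle_inequality_can_fail(self):
        """1 - r^2 is not a metric: counterexample triple."""
        r = pd.DataFrame([[1.0, 0.9, 0.0],
                          [0.9, 1.0, 0.6],
                          [0.0, 0.6, 1.0]],
                         index=list("abc"), columns=list("abc"))
        d = gene_distance(r)
        assert d.loc["a", "c"] > d.loc["a", "b"] + d.loc["b", "c"]

    def test_out_of_range_rejected(self):
        r = pd.DataFrame([[1.0, 1.2], [1.2, 1.0]],
                         index=["a", "b"], columns=["a", "b"])
        with pytest.raises(InputError):
            gene_distance(r)


@pytest.fixture(scope="module")
def module_distance():
    n = 40
    r = np.zeros((n, n))
    r[:20, :20] = 0.9
    r[20:, 20:] = 0.9
    np.fill_diagonal(r, 1.0)
    names = [f"G{i}" for i in range(n)]
    return gene_distance(pd.DataFrame(r, index=names, columns=names))


class TestEmbed2d:
    def test_same_seed_identical(self, module_distance):
        a = embed_2d(module_distance, perplexity=10, seed=3)
        b = embed_2d(module_distance, perplexity=10, seed=3)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_planted_modules_separate(self, module_distance):
        emb = embed_2d(module_distance, perplexity=10, seed=0).to_numpy()
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(emb))
        within = np.r_[d[:20, :20][np.triu_indices(20, 1)],
                       d[20:, 20:][np.triu_indices(20, 1)]]
        across = d[:20, 20:].ravel()
        assert within.mean() < across.mean()

    def test_duplicated_gene_pair_are_mutual_neighbors(self):
        rng = np.random.default_rng(5)
        m = 20
        r = np.clip((rng.random((m, m)) - 0.5) * 0.6, -1, 1)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        r[0, 1] = r[1, 0] = 1.0  # twin pair
        names = [f"H{i}" for i in range(m)]
        emb = embed_2d(gene_distance(pd.DataFrame(r, index=names,
                                                  columns=names)),
                       perplexity=5, seed=0).to_numpy()
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(emb))
        np.fill_diagonal(d, np.inf)
        assert np.argmin(d[0]) == 1 and np.argmin(d[1]) == 0

    def test_infeasible_perplexity_rejected(self, module_distance):
        with pytest.raises(InputError):
            embed_2d(module_distance, perplexity=13.1)


class TestBuildNetwork:
    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p_adj"])

    def test_strong_significant_negative_edge(self):
        net = build_network(self._pairs([("A", "B", -0.8, 0.001)]))
        assert len(net.edges) == 1
        edge = net.edges.iloc[0]
        assert (edge["weight"], edge["sign"]) == (0.8, "-")

    def test_weak_correlation_never_an_edge(self):
        net = build_network(self._pairs([("A", "B", 0.3, 1e-9)]))
        assert len(net.edges) == 0

    def test_no_self_edges(self):
        net = build_network(self._pairs([("A", "A", 0.99, 1e-9)]))
        assert len(net.edges) == 0


def test_pairwise_correlations_integration():
    rng = np.random.default_rng(9)
    f = rng.normal(0, 1, 60)
    expr = pd.DataFrame({
        "P": -f + rng.normal(0, 0.5, 60),
        "Q": f + rng.normal(0, 0.5, 60),
        "R": rng.normal(0, 1, 60),
    }).T
    expr.columns = [f"s{i}" for i in range(60)]
    pairs = pairwise_correlations(expr)
    pq = pairs[(pairs.gene_a == "P") & (pairs.gene_b == "Q")].iloc[0]
    assert pq["r"] < -0.5
    assert pq["p_adj"] < 0.05
    assert {"rs", "p_spearman", "n_influential"} <= set(pairs.columns)
    net = build_network(pairs, weight_threshold=0.5)
    assert {"P", "Q"} == set(net.edges.iloc[0][["gene_a", "gene_b"]])


@given(st.integers(0, 2 ** 31 - 1))
def test_winsorize_commutes_with_permutation(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, 30)
    perm = rng.permutation(30)
    np.testing.assert_allclose(winsorize(x, 0.1)[perm],
                               winsorize(x[perm], 0.1))
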