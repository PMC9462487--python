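import numpy as np
import pandas as pd
import pytest
from scipy.stats import f_oneway

from varex.de import (anova_genotype, de_call, genotype_groups,
                      genotype_stratified_de, nb_wald_test, normalize_log,
                      size_factors)
from varex.errors import ContrastError, InputError, NormalizationError
from varex.io import CountsMatrix, GenotypeMatrix, VariantRecord


def _cm(counts, genes=None, samples=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    return CountsMatrix(genes, samples, counts)


class TestSizeFactors:
    def test_doubled_sample_worked_example(self):
        """[10,20,30] vs [20,40,60] -> s = [1/sqrt(2), sqrt(2)] exactly."""
        cm = _cm([[10, 20], [20, 40], [30, 60]])
        s = size_factors(cm)
        np.testing.assert_allclose(s, [2 ** -0.5, 2 ** 0.5], rtol=1e-12)
        ln = normalize_log(cm, s)
        np.testing.assert_allclose(ln["s0"], ln["s1"], rtol=1e-12)

    def test_identical_samples_equal_factors(self):
        cm = _cm([[5, 5, 5], [9, 9, 9]])
        np.testing.assert_allclose(size_factors(cm), 1.0)

    def test_zero_containing_gene_excluded_from_median(self):
        with_zero = _cm([[10, 20], [20, 40], [0, 1000]])
        without = _cm([[10, 20], [20, 40]])
        np.testing.assert_allclose(size_factors(with_zero),
                                   size_factors(without))

    def test_no_reference_genes_raises(self):
        with pytest.raises(NormalizationError):
            size_factors(_cm([[0, 5], [5, 0]]))

    def test_scale_equivariance(self, small_counts):
        """Scaling one sample's counts by c multiplies its size factor by c
        relative to every other sample (the overall geometric-mean anchor
        redistributes, so ratios are the equivariant quantity)."""
        s = size_factors(small_counts)
        scaled = small_counts.counts.copy()
        scaled[:, 2] *= 3
        s2 = size_factors(_cm(scaled))
        np.testing.assert_allclose(s2[2] / np.delete(s2, 2),
                                   3 * s[2] / np.delete(s, 2), rtol=1e-12)


class TestNormalizeLog:
    def test_zero_count_maps_to_zero(self):
        ln = normalize_log(_cm([[0, 4]]), np.array([1.0, 4.0]))
        assert ln.iloc[0, 0] == 0.0
        assert ln.iloc[0, 1] == 1.0  # count == s -> log2(2)

    def test_doubling_sample_preserves_normalized_profile(self):
        """Doubling one sample's counts and recomputing size factors leaves
        the normalized expression profile unchanged: every sample's
        normalized counts shift by the same global 2^(1/m) geometric-mean
        constant, so all between-sample contrasts are untouched."""
        cm = _cm([[10, 30], [20, 50], [40, 80]])
        norm1 = cm.counts / size_factors(cm)
        doubled = cm.counts.copy()
        doubled[:, 0] *= 2
        cm2 = _cm(doubled)
        norm2 = cm2.counts / size_factors(cm2)
        np.testing.assert_allclose(norm2, norm1 * 2 ** 0.5, rtol=1e-12)


class TestNbWaldTest:
    def _two_group(self, n=8, seed=0, mu_b=None):
        rng = np.random.default_rng(seed)
        mu_a, alpha = 100.0, 0.1
        mu_b = mu_b or mu_a
        r = 1 / alpha
        a = rng.negative_binomial(r, r / (r + mu_a), (20, n))
        b = rng.negative_binomial(r, r / (r + mu_b), (20, n))
        cm = _cm(np.hstack([a, b]))
        groups = pd.Series(["A"] * n + ["B"] * n, index=cm.samples)
        return cm, groups

    def test_label_swap_negates_log2fc(self):
        cm, groups = self._two_group(mu_b=300)
        fwd = nb_wald_test(cm, groups, sizefactors=np.ones(16))
        swapped = groups.map({"A": "Z", "B": "A"})  # reverses sorted order
        rev = nb_wald_test(cm, swapped, sizefactors=np.ones(16))
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], rtol=1e-6)
        np.testing.assert_allclose(fwd["p"], rev["p"], rtol=1e-6)

    def test_matches_statsmodels_glm(self):
        """IRLS NB fit agrees with the statsmodels GLM oracle."""
        import statsmodels.api as sm

        cm, groups = self._two_group(mu_b=250, seed=3)
        alpha = 0.08
        res = nb_wald_test(cm, groups, sizefactors=np.ones(16), alpha=alpha)
        x = np.column_stack([np.ones(16), np.r_[np.zeros(8), np.ones(8)]])
        for i in range(5):
            glm = sm.GLM(cm.counts[i], x,
                         family=sm.families.NegativeBinomial(alpha=alpha)).fit()
            assert res["log2fc"][i] == pytest.approx(
                glm.params[1] / np.log(2), rel=1e-5)
            assert res["se_log2fc"][i] == pytest.approx(
                glm.bse[1] / np.log(2), rel=1e-4)

    def test_all_zero_gene_null_and_excluded_from_family(self):
        cm, groups = self._two_group()
        counts = cm.counts.copy()
        counts[0] = 0
        res = nb_wald_test(_cm(counts), groups, sizefactors=np.ones(16))
        assert np.isnan(res["p"][0])
        assert res["p_adj"].notna().sum() == 19

    def test_single_level_rejected(self):
        cm, groups = self._two_group()
        with pytest.raises(InputError):
            nb_wald_test(cm, pd.Series("A", index=cm.samples))

    def test_small_group_named_in_error(self):
        cm, groups = self._two_group()
        groups.iloc[:7] = "B"
        with pytest.raises(ContrastError, match="'A'"):
            nb_wald_test(cm, groups)


class TestGenotypeStratifiedDe:
    def _study(self):
        rng = np.random.default_rng(4)
        dosage = np.array([0] * 4 + [1] * 6 + [2] * 6 + [-1] * 2)[:, None]
        gm = GenotypeMatrix([f"s{i}" for i in range(18)],
                            [VariantRecord("1", 1, "rsT", "C", "T")], dosage)
        # only the first gene carries the genotype effect; the flat genes
        # anchor the size factors
        mu = np.tile(200.0, (6, 18))
        mu[0] = 200 * 2.0 ** (-1.0 * np.clip(dosage[:, 0], 0, None))
        counts = rng.poisson(mu)
        return _cm(counts), gm

    def test_negative_effect_recovered(self):
        cm, gm = self._study()
        res = genotype_stratified_de(cm, gm, "rsT", ("HET", "ALT-HOMO"))
        assert res.loc[0, "log2fc"] < -0.5
        assert res.loc[1:, "log2fc"].abs().max() < 0.5

    def test_missing_dosage_samples_excluded(self):
        cm, gm = self._study()
        labels = genotype_groups(gm, "rsT")
        assert len(labels) == 16 and "s16" not in labels.index

    def test_small_contrast_group_named(self):
        cm, gm = self._study()
        gm.dosage[gm.dosage == 2] = 1
        with pytest.raises(ContrastError, match="ALT-HOMO"):
            genotype_stratified_de(cm, gm, "rsT", ("HET", "ALT-HOMO"))


class TestAnova:
    def test_worked_example(self):
        """Groups [1,2,3]/[2,3,4]/[3,4,5]: F = 3 exactly, p from F(2,6)."""
        values = pd.Series([1, 2, 3, 2, 3, 4, 3, 4, 5], index=range(9),
                           dtype=float)
        groups = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3, index=range(9))
        res = anova_genotype(values, groups)
        assert res.F == pytest.approx(3.0, abs=1e-12)
        assert (res.df_between, res.df_within) == (2, 6)
        assert res.p == pytest.approx(0.125, abs=1e-3)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 1, 30)
        g = rng.choice(["x", "y", "z"], 30)
        res = anova_genotype(pd.Series(v, index=range(30)),
                             pd.Series(g, index=range(30)))
        ref = f_oneway(v[g == "x"], v[g == "y"], v[g == "z"])
        assert res.F == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_all_equal_gives_f_zero_p_one(self):
        values = pd.Series([2.0] * 8, index=range(8))
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=range(8))
        res = anova_genotype(values, groups)
        assert (res.F, res.p) == (0.0, 1.0)

    def test_zero_within_variance_unequal_means(self):
        values = pd.Series([1.0, 1.0, 5.0, 5.0], index=range(4))
        groups = pd.Series(["a", "a", "b", "b"], index=range(4))
        res = anova_genotype(values, groups)
        assert res.p == 0.0 and res.degenerate

    def test_single_group_rejected(self):
        with pytest.raises(InputError):
            anova_genotype(pd.Series([1.0, 2.0], index=range(2)),
                           pd.Series(["a", "a"], index=range(2)))

    def test_permutation_null_is_uniform(self):
        """Randomly permuted labels give approximately uniform p-values."""
        from scipy.stats import kstest

        rng = np.random.default_rng(42)
        v = pd.Series(rng.normal(0, 1, 24), index=range(24))
        labels = np.repeat(["a", "b", "c"], 8)
        ps = []
        for _ in range(1000):
            g = pd.Series(rng.permutation(labels), index=range(24))
            ps.append(anova_genotype(v, g).p)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestDeCall:
    @pytest.mark.parametrize("p_adj,log2fc,flag", [
        (0.04, 1.5, True),
        (0.04, 0.5, False),   # fold change 1.41 < 2
        (0.06, 3.0, False),
    ])
    def test_threshold_rule(self, p_adj, log2fc, flag):
        df = pd.DataFrame({"p_adj": [p_adj], "log2fc": [log2fc]})
        assert de_call(df, fdr=0.05, fc=2.0).iloc[0] == flag
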