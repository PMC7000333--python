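"""Normalization, differential expression and PCA unit tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pkdrx import expression as expr
from pkdrx import simulate as sim


def _df(mat, genes=None, samples=None):
    mat = np.asarray(mat)
    genes = genes or [f"g{i}" for i in range(mat.shape[0])]
    samples = samples or [f"s{i}" for i in range(mat.shape[1])]
    return pd.DataFrame(mat, index=genes, columns=samples)


# ---------------------------------------------------------------- CPM


class TestCPM:
    def test_definition_at_unit_library(self):
        counts = _df([[2], [999_998]], samples=["s0"])
        counts["s1"] = [2, 999_998]  # need >= 2 samples
        cpm = expr.compute_cpm(counts)
        assert cpm.loc["g0", "s0"] == pytest.approx(2.0)

    def test_zero_count_gives_zero(self):
        cpm = expr.compute_cpm(_df([[0, 0], [10, 10]]))
        assert (cpm.loc["g0"] == 0).all()

    def test_three_gene_hand_example(self):
        # counts 10/20/70 in a 100-read library scale to 1e5/2e5/7e5
        cpm = expr.compute_cpm(_df([[10, 10], [20, 20], [70, 70]]))
        assert cpm["s0"].tolist() == pytest.approx([1e5, 2e5, 7e5])

    def test_columns_sum_to_one_million(self, toy_counts):
        cpm = expr.compute_cpm(toy_counts)
        assert cpm.sum(axis=0).to_numpy() == pytest.approx([1e6] * 4)

    def test_zero_library_names_sample(self):
        counts = _df([[0, 5], [0, 5]])
        with pytest.raises(expr.ExpressionError, match="s0"):
            expr.compute_cpm(counts)

    def test_duplicate_gene_ids_rejected(self):
        counts = _df([[1, 1], [2, 2]], genes=["g", "g"])
        with pytest.raises(expr.ExpressionError, match="duplicate gene"):
            expr.compute_cpm(counts)


# ---------------------------------------------------------------- TMM


def _tmm_oracle_pair(counts, sample, ref, trim_m=0.3, trim_a=0.05):
    """Direct evaluation of the trimmed weighted mean of M-values for one
    sample against the reference, independent of the implementation."""
    y_s = counts[sample].to_numpy(float)
    y_r = counts[ref].to_numpy(float)
    n_s, n_r = y_s.sum(), y_r.sum()
    ok = (y_s > 0) & (y_r > 0)
    y_s, y_r = y_s[ok], y_r[ok]
    m = np.log2((y_s / n_s) / (y_r / n_r))
    a = 0.5 * np.log2((y_s / n_s) * (y_r / n_r))
    w = 1.0 / ((n_s - y_s) / (n_s * y_s) + (n_r - y_r) / (n_r * y_r))
    n = len(m)
    drop_m, drop_a = int(np.floor(n * trim_m)), int(np.floor(n * trim_a))
    by_m = np.argsort(m)
    keep_m = set(by_m[drop_m : n - drop_m])
    by_a = np.argsort(a)
    keep_a = set(by_a[drop_a : n - drop_a])
    keep = sorted(keep_m & keep_a)
    return float(np.sum(w[keep] * m[keep]) / np.sum(w[keep]))


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        counts = _df(np.tile([[10], [50], [200]], (1, 3)))
        f = expr.tmm_factors(counts)
        assert f.to_numpy() == pytest.approx([1, 1, 1])

    def test_pure_depth_scaling_gives_unit_factors(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(200, size=40)
        counts = _df(np.column_stack([base, base * 2]))
        f = expr.tmm_factors(counts)
        assert f.to_numpy() == pytest.approx([1, 1])

    def test_invariant_under_global_depth_rescaling(self, toy_counts):
        f1 = expr.tmm_factors(toy_counts)
        f2 = expr.tmm_factors(toy_counts * 3)
        assert f1.to_numpy() == pytest.approx(f2.to_numpy())

    def test_asymmetric_de_toy_matches_brute_force(self):
        # 20 genes, a handful strongly up in s1: factors must match the
        # independently evaluated trimmed weighted-mean formula
        rng = np.random.default_rng(7)
        base = rng.integers(50, 500, size=20).astype(float)
        other = base.copy()
        other[:4] *= 8  # asymmetric DE
        counts = _df(np.column_stack([base, other]).astype(int))
        f = expr.tmm_factors(counts, reference="s0")
        lf = _tmm_oracle_pair(counts, "s1", "s0")
        expected_s1 = 2 ** (lf / 2)  # after geometric-mean centering
        assert f["s1"] == pytest.approx(expected_s1, rel=1e-9)
        assert f["s0"] == pytest.approx(1 / expected_s1, rel=1e-9)

    def test_geometric_mean_is_one(self, toy_counts):
        f = expr.tmm_factors(toy_counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_all_zero_sample_errors(self):
        counts = _df([[0, 5], [0, 7]])
        with pytest.raises(expr.ExpressionError, match="zero"):
            expr.tmm_factors(counts)


# ---------------------------------------------------------------- noise filter


class TestNoiseFilter:
    @pytest.mark.parametrize(
        "row, retained",
        [
            ([3, 3, 3, 3], True),    # always above threshold
            ([1, 1, 3, 3], True),    # low in exactly 50%: strictly-more-than rule
            ([1, 1, 1, 3], False),   # low in 75%
            ([0, 0, 0, 0], False),   # all zeros
        ],
    )
    def test_strictly_more_than_half_rule(self, row, retained):
        cpm = _df([row, [10, 10, 10, 10]])
        kept = expr.noise_filter(cpm, threshold=2.0, fraction=0.5)
        assert ("g0" in kept) is retained

    def test_threshold_zero_keeps_everything(self):
        cpm = _df([[0, 0], [5, 5]])
        assert list(expr.noise_filter(cpm, threshold=0.0)) == ["g0", "g1"]


# ---------------------------------------------------------------- BH FDR


class TestBH:
    def test_single_p_unchanged(self):
        assert expr.bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        # sorted p*m/i = .04, .04, .04, .04 -> all adjusted to 0.04
        assert expr.bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_equal_stay_equal(self):
        assert expr.bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(3)
        p = rng.uniform(size=200)
        ours = expr.bh_fdr(p)
        theirs = statsmodels.multipletests(p, method="fdr_bh")[1]
        assert ours == pytest.approx(theirs)

    def test_rejects_out_of_range(self):
        with pytest.raises(expr.ExpressionError):
            expr.bh_fdr([0.5, 1.5])

    def test_shrinking_a_p_value_never_loses_discoveries(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=50)
        alpha = 0.1
        before = (expr.bh_fdr(p) <= alpha).sum()
        p2 = p.copy()
        p2[10] = p2[10] / 10
        after = (expr.bh_fdr(p2) <= alpha).sum()
        assert after >= before


# ---------------------------------------------------------------- moderated t


class TestDifferentialExpression:
    def _null_expr(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        mat = rng.normal(8, 1, size=(n, 8))
        return _df(mat, samples=[f"s{i}" for i in range(8)])

    def test_identical_groups_give_zero_t_unit_p(self):
        mat = self._null_expr()
        mat.iloc[0] = 5.0  # constant gene, same values in both groups
        tab = expr.differential_expression(mat, ["s0", "s1", "s2", "s3"], ["s4", "s5", "s6", "s7"])
        assert tab.iloc[0]["log2fc"] == 0
        assert tab.iloc[0]["t"] == 0
        assert tab.iloc[0]["p"] == pytest.approx(1.0)

    def test_antisymmetric_in_contrast_order(self):
        mat = self._null_expr(seed=2)
        a, b = ["s0", "s1", "s2", "s3"], ["s4", "s5", "s6", "s7"]
        t1 = expr.differential_expression(mat, a, b)
        t2 = expr.differential_expression(mat, b, a)
        assert t1["log2fc"].to_numpy() == pytest.approx(-t2["log2fc"].to_numpy())
        assert t1["t"].to_numpy() == pytest.approx(-t2["t"].to_numpy())
        assert t1["p"].to_numpy() == pytest.approx(t2["p"].to_numpy())

    def test_null_p_values_uniform(self):
        ps = []
        for seed in range(4):
            mat = self._null_expr(seed=seed, n=300)
            tab = expr.differential_expression(mat, ["s0", "s1", "s2", "s3"], ["s4", "s5", "s6", "s7"])
            ps.append(tab["p"].to_numpy())
        ks = stats.kstest(np.concatenate(ps), "uniform")
        assert ks.pvalue > 0.01

    def test_small_group_rejected(self):
        mat = self._null_expr()
        with pytest.raises(expr.ExpressionError, match="fewer than 2"):
            expr.differential_expression(mat, ["s0"], ["s1", "s2"])

    def test_planted_shift_detected(self):
        mat = self._null_expr(seed=9)
        mat.iloc[:10, :4] += 5.0
        tab = expr.differential_expression(mat, ["s0", "s1", "s2", "s3"], ["s4", "s5", "s6", "s7"])
        top10 = set(tab.sort_values("p").index[:10])
        assert top10 == {f"g{i}" for i in range(10)}


# ---------------------------------------------------------------- PCA


class TestPCA:
    def test_rank_one_data_has_full_first_component(self):
        u = np.array([1.0, 2.0, 3.0])
        v = np.array([1.0, -1.0, 0.5, 2.0])
        mat = _df(np.outer(u, v))
        res = expr.pca(mat)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self, toy_counts):
        res = expr.pca(expr.compute_cpm(toy_counts, log=True))
        assert res.variance_fraction.sum() == pytest.approx(1.0)

    def test_loadings_match_eigendecomposition(self):
        rng = np.random.default_rng(4)
        mat = _df(rng.normal(size=(3, 6)))
        res = expr.pca(mat)
        x = mat.to_numpy().T
        x = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(x.T @ x)
        order = np.argsort(evals)[::-1]
        for i in range(2):  # top components, distinct eigenvalues
            dot = abs(res.loadings.iloc[:, i].to_numpy() @ evecs[:, order[i]])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_constant_matrix_rejected(self):
        mat = _df(np.full((4, 3), 7.0))
        with pytest.raises(expr.ExpressionError, match="constant"):
            expr.pca(mat)

    def test_top_loading_genes_rank_one(self):
        u = np.array([0.1, 5.0, -0.2])
        v = np.array([1.0, 2.0, 3.0, 4.0])
        res = expr.pca(_df(np.outer(u, v)))
        top = expr.top_loading_genes(res, component=1, n=1)
        assert top["up"] == ["g1"] or top["down"] == ["g1"]

    def test_bad_component_and_n_rejected(self):
        res = expr.pca(_df(np.random.default_rng(0).normal(size=(5, 4))))
        with pytest.raises(expr.ExpressionError, match="component"):
            expr.top_loading_genes(res, component=99)
        with pytest.raises(expr.ExpressionError, match="exceeds"):
            expr.top_loading_genes(res, component=1, n=50)

    def test_stage_monotone_signal_top_genes_track_severity(self):
        # planted monotone disease-severity signal: the genes loading most on
        # PC1 must rank-correlate strongly with the severity phenotype
        rng = np.random.default_rng(6)
        n_samples = 15
        severity = np.linspace(1.2, 9.0, n_samples)  # 2KW/BW-like, increasing
        signal = np.zeros((60, n_samples))
        signal[:20] = np.outer(rng.uniform(0.5, 1.5, 20), np.linspace(0, 2, n_samples))
        signal[20:40] = np.outer(rng.uniform(0.5, 1.5, 20), np.linspace(0, -2, n_samples))
        mat = _df(signal + rng.normal(0, 0.3, size=signal.shape))
        res = expr.pca(mat)
        top = expr.top_loading_genes(res, component=1, n=20)
        rhos = [
            abs(stats.spearmanr(mat.loc[g].to_numpy(), severity)[0])
            for g in (top["up"] + top["down"])
        ]
        assert np.mean(rhos) > 0.6
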