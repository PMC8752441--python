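import numpy as np
import pandas as pd
import pytest

from traitenv.trait_structure import (
    cluster_traits,
    correlation_matrix,
    latitude_fit,
    pca_traits,
    significant_axes,
)


def _pearson_oracle(x, y):
    """Directly coded Pearson formula (independent of pandas)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xd = x - x.mean()
    yd = y - y.mean()
    return np.sum(xd * yd) / np.sqrt(np.sum(xd**2) * np.sum(yd**2))


class TestCorrelationMatrix:
    def test_self_correlation_one(self, rng):
        df = pd.DataFrame({"a": np.exp(rng.normal(0, 1, 20))})
        corr = correlation_matrix(df)
        assert corr.loc["a", "a"] == 1.0

    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        df = pd.DataFrame({"a": x, "b": -2 * x})
        corr = correlation_matrix(df, log_scale=False)
        assert corr.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_formula_oracle(self, rng):
        df = pd.DataFrame(np.exp(rng.normal(0, 1, (5, 3))), columns=list("abc"))
        corr = correlation_matrix(df, log_scale=True)
        logs = np.log(df.to_numpy())
        for i, a in enumerate("abc"):
            for j, b in enumerate("abc"):
                expect = abs(_pearson_oracle(logs[:, i], logs[:, j]))
                assert corr.loc[a, b] == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="'a'"):
            correlation_matrix(df, log_scale=False)

    def test_pairwise_complete(self, rng):
        df = pd.DataFrame(np.exp(rng.normal(0, 1, (30, 3))), columns=list("abc"))
        df.loc[:4, "a"] = np.nan
        corr = correlation_matrix(df)
        sub = df.dropna()
        expect = abs(
            _pearson_oracle(np.log(sub["a"]), np.log(sub["b"]))
        )
        assert corr.loc["a", "b"] == pytest.approx(expect, abs=1e-12)


class TestClusterTraits:
    def _corr(self, mat, names):
        return pd.DataFrame(mat, index=names, columns=names)

    def test_identical_traits_merge_at_zero(self):
        corr = self._corr([[1.0, 1.0], [1.0, 1.0]], ["a", "b"])
        tree = cluster_traits(corr)
        assert tree.merge_heights[0] == pytest.approx(0.0)
        assert tree.groups["a"] == tree.groups["b"]

    def test_uncorrelated_traits_stay_separate_at_cut_one(self):
        corr = self._corr([[1.0, 0.0], [0.0, 1.0]], ["a", "b"])
        tree = cluster_traits(corr, cut=1.0)
        assert tree.merge_heights[0] == pytest.approx(1.0)
        assert tree.groups["a"] != tree.groups["b"]

    def test_block_structure_hand_traced(self):
        # within-block |r| = 0.8, across = 0; complete linkage:
        # (a,b) at 0.2, (c,d) at 0.2, final merge at max distance 1.0
        corr = self._corr(
            [
                [1.0, 0.8, 0.0, 0.0],
                [0.8, 1.0, 0.0, 0.0],
                [0.0, 0.0, 1.0, 0.8],
                [0.0, 0.0, 0.8, 1.0],
            ],
            list("abcd"),
        )
        tree = cluster_traits(corr, cut=1.0)
        np.testing.assert_allclose(sorted(tree.merge_heights), [0.2, 0.2, 1.0])
        assert tree.groups["a"] == tree.groups["b"]
        assert tree.groups["c"] == tree.groups["d"]
        assert tree.groups["a"] != tree.groups["c"]
        assert tree.n_groups == 2

    def test_merge_heights_monotone_and_bounded(self, small_world, rng):
        obs, _, _, truth = small_world
        cols = list(truth.config.trait_names)
        corr = correlation_matrix(
            obs[cols].dropna(), signed_traits=[truth.config.signed_trait]
        )
        tree = cluster_traits(corr)
        h = tree.merge_heights
        assert (np.diff(h) >= -1e-12).all()
        assert (h >= -1e-12).all() and (h <= 1.0 + 1e-12).all()

    def test_trait_order_invariance(self, rng):
        df = pd.DataFrame(np.exp(rng.normal(0, 1, (50, 5))), columns=list("abcde"))
        corr = correlation_matrix(df)
        t1 = cluster_traits(corr)
        perm = ["d", "b", "e", "a", "c"]
        t2 = cluster_traits(corr.loc[perm, perm])
        part1 = {frozenset(t for t in t1.groups if t1.groups[t] == g)
                 for g in set(t1.groups.values())}
        part2 = {frozenset(t for t in t2.groups if t2.groups[t] == g)
                 for g in set(t2.groups.values())}
        assert part1 == part2


class TestPcaTraits:
    def test_rank_one_case(self):
        x = np.exp(np.random.default_rng(0).normal(0, 1, 30))
        df = pd.DataFrame({"a": x, "b": x**2})  # perfectly correlated in log
        res = pca_traits(df)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_case(self, rng):
        p, n = 4, 20000
        df = pd.DataFrame(
            np.exp(rng.normal(0, 1, (n, p))), columns=[f"t{j}" for j in range(p)]
        )
        res = pca_traits(df)
        np.testing.assert_allclose(
            res.explained_variance_ratio, np.full(p, 1 / p), atol=0.02
        )

    def test_matches_eigen_oracle(self, rng):
        df = pd.DataFrame(
            np.exp(rng.normal(0, 1, (50, 5))), columns=[f"t{j}" for j in range(5)]
        )
        res = pca_traits(df)
        corr = np.corrcoef(np.log(df.to_numpy()).T)
        eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
        np.testing.assert_allclose(
            res.explained_variance_ratio, eig / eig.sum(), atol=1e-10
        )
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-12)

    def test_scores_uncorrelated(self, rng):
        df = pd.DataFrame(
            np.exp(rng.normal(0, 1, (80, 6))), columns=[f"t{j}" for j in range(6)]
        )
        res = pca_traits(df)
        c = np.corrcoef(res.scores.to_numpy().T)
        np.testing.assert_allclose(c - np.eye(len(c)), 0.0, atol=1e-10)

    def test_sign_convention(self, rng):
        df = pd.DataFrame(
            np.exp(rng.normal(0, 1, (60, 4))), columns=[f"t{j}" for j in range(4)]
        )
        res = pca_traits(df)
        L = res.loadings.to_numpy()
        for k in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, k])), k] > 0

    def test_missing_values_rejected(self):
        df = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="missing"):
            pca_traits(df)


class TestSignificantAxes:
    def test_alpha_domain_checked(self, rng):
        df = pd.DataFrame(np.exp(rng.normal(0, 1, (30, 3))), columns=list("abc"))
        with pytest.raises(ValueError, match="alpha"):
            significant_axes(df, alpha=1.5)

    def test_small_n_perm_warns(self, rng):
        df = pd.DataFrame(np.exp(rng.normal(0, 1, (30, 3))), columns=list("abc"))
        with pytest.warns(UserWarning, match="n_perm"):
            significant_axes(df, n_perm=50, seed=0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pure_noise_keeps_at_most_one_axis(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            np.exp(rng.normal(0, 1, (100, 6))), columns=[f"t{j}" for j in range(6)]
        )
        k = significant_axes(df, n_perm=199, seed=seed)
        assert k <= 1

    def test_rank_two_signal_keeps_two_axes(self):
        rng = np.random.default_rng(3)
        n = 300
        f1 = rng.normal(0, 1, n)
        f2 = rng.normal(0, 1, n)
        cols = {}
        for j in range(6):
            base = f1 if j < 3 else f2
            cols[f"t{j}"] = np.exp(base + rng.normal(0, 0.05, n))
        k = significant_axes(pd.DataFrame(cols), n_perm=199, alpha=0.05, seed=0)
        assert k == 2


class TestLatitudeFit:
    def test_exact_linearity(self):
        lat = np.linspace(-60, 60, 100)
        scores = 2.0 * np.abs(lat)
        fit_all, fit_bin = latitude_fit(scores, lat)
        assert fit_all.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit_bin.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit_all.slope == pytest.approx(2.0, abs=1e-10)

    def test_null_case(self, rng):
        lat = rng.uniform(-70, 70, 5000)
        scores = rng.normal(0, 1, 5000)
        fit_all, _ = latitude_fit(scores, lat)
        assert fit_all.r2 < 0.01

    def test_binning_averages_noise(self):
        rng = np.random.default_rng(4)
        lat = rng.uniform(0, 70, 4000)
        signal = 0.1 * lat
        scores = signal + rng.normal(0, 0.5 * signal.std(), 4000)
        fit_all, fit_bin = latitude_fit(scores, lat)
        assert fit_bin.r2 > fit_all.r2
        # direct least-squares oracle on all rows
        X = np.column_stack([np.ones(4000), lat])
        beta, *_ = np.linalg.lstsq(X, scores, rcond=None)
        pred = X @ beta
        ss_res = np.sum((scores - pred) ** 2)
        ss_tot = np.sum((scores - scores.mean()) ** 2)
        assert fit_all.r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)
        assert fit_all.slope == pytest.approx(beta[1], abs=1e-10)

    def test_too_few_latitudes(self):
        with pytest.raises(ValueError, match="3 distinct"):
            latitude_fit([1.0, 2.0], [0.0, 10.0])
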