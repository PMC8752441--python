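import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traitenv.partition import (
    RidgeSpec,
    cv_holdout_r2,
    display_shares,
    partition_table,
    partition_total,
    partition_variance,
    reduce_block,
)


class TestRidgeSpec:
    def test_invalid_parameters(self):
        with pytest.raises(ValueError, match="repetitions"):
            RidgeSpec(repetitions=0)
        with pytest.raises(ValueError, match="fold"):
            RidgeSpec(inner_folds=1)
        with pytest.raises(ValueError, match="lambdas"):
            RidgeSpec(lambdas=[-1.0])


class TestReduceBlock:
    def test_clipping_to_column_count(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (40, 5)), columns=list("abcde"))
        scores, rmap = reduce_block(df, n_components=20)
        assert scores.shape == (40, 5)
        # 5 components capture all block variance (standardized: p)
        assert rmap.explained_variance.sum() == pytest.approx(5.0, abs=1e-8)

    def test_scores_uncorrelated(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (60, 8)))
        scores, _ = reduce_block(df, n_components=4)
        c = np.corrcoef(scores.to_numpy().T)
        np.testing.assert_allclose(c - np.eye(4), 0.0, atol=1e-10)

    def test_captured_variance_matches_eigen_oracle(self, rng):
        n, p, k = 220, 107, 20
        base = rng.normal(0, 1, (n, 5))
        df = pd.DataFrame(
            base @ rng.normal(0, 1, (5, p)) + rng.normal(0, 0.5, (n, p))
        )
        scores, rmap = reduce_block(df, n_components=k)
        X = df.to_numpy()
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(np.cov(Xs.T)))[::-1]
        assert rmap.explained_variance.sum() == pytest.approx(
            eig[:k].sum(), abs=1e-8
        )
        assert scores.to_numpy().var(axis=0, ddof=1).sum() == pytest.approx(
            eig[:k].sum(), abs=1e-8
        )

    def test_constant_column_dropped_with_warning(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (30, 3)), columns=list("abc"))
        df["c"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            scores, rmap = reduce_block(df, n_components=5)
        assert rmap.dropped == ["c"]
        assert scores.shape[1] == 2


def _ols_holdout_oracle(X, y, folds):
    """Hand-coded OLS-based holdout r2 (squared Pearson of concatenated
    out-of-fold predictions)."""
    pred = np.empty_like(y)
    for te in folds:
        tr = np.setdiff1d(np.arange(len(y)), te)
        A = np.column_stack([np.ones(len(tr)), X[tr]])
        beta, *_ = np.linalg.lstsq(A, y[tr], rcond=None)
        pred[te] = np.column_stack([np.ones(len(te)), X[te]]) @ beta
    return np.corrcoef(pred, y)[0, 1] ** 2


class TestCvHoldoutR2:
    def test_noiseless_linear_signal(self, rng):
        n = 200
        X = rng.normal(0, 1, (n, 2))
        y = 2.0 * X[:, 0] - X[:, 1] + 3.0
        spec = RidgeSpec(
            lambdas=np.logspace(-6, 0, 20), repetitions=3, seed=0
        )
        res = cv_holdout_r2(X, y, spec)
        assert res.mean > 0.999

    def test_null_signal(self, rng):
        n = 200
        X = rng.normal(0, 1, (n, 5))
        y = rng.normal(0, 1, n)
        spec = RidgeSpec(
            lambdas=np.logspace(-2, 3, 20), repetitions=20, seed=1
        )
        res = cv_holdout_r2(X, y, spec)
        # squared Pearson of concatenated out-of-fold predictions is
        # upward-biased under the null (fold-mean artifact), so the
        # honest null level sits near 0.05 rather than at 1/n
        assert res.mean < 0.1

    def test_matches_ols_oracle_at_lambda_zero(self):
        rng = np.random.default_rng(5)
        n = 40
        X = rng.normal(0, 1, (n, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(0, 0.5, n)
        folds = [np.arange(i, n, 4) for i in range(4)]  # fixed assignment
        spec = RidgeSpec(
            lambdas=np.array([0.0]), outer_folds=4, inner_folds=2,
            repetitions=1, seed=0,
        )
        res = cv_holdout_r2(X, y, spec, folds_per_repetition=[folds])
        oracle = _ols_holdout_oracle(X, y, folds)
        assert res.per_repetition[0] == pytest.approx(oracle, abs=1e-10)

    def test_infinite_penalty_degenerates_to_zero_with_flag(self, rng):
        n = 60
        X = rng.normal(0, 1, (n, 3))
        y = X[:, 0] + rng.normal(0, 0.1, n)
        spec = RidgeSpec(lambdas=np.array([np.inf]), repetitions=1, seed=0)
        res = cv_holdout_r2(X, y, spec)
        assert res.mean == 0.0
        assert res.degenerate

    def test_small_n_rejected(self, rng):
        X = rng.normal(0, 1, (10, 2))
        y = rng.normal(0, 1, 10)
        with pytest.raises(ValueError, match="too small"):
            cv_holdout_r2(X, y, RidgeSpec())

    def test_deterministic(self, rng):
        X = rng.normal(0, 1, (80, 4))
        y = X[:, 0] + rng.normal(0, 1, 80)
        spec = RidgeSpec(lambdas=np.logspace(-2, 2, 10), repetitions=3, seed=9)
        a = cv_holdout_r2(X, y, spec)
        b = cv_holdout_r2(X, y, spec)
        np.testing.assert_array_equal(a.per_repetition, b.per_repetition)


class TestPartitionVariance:
    def test_printed_row_recovered(self):
        # total 0.40 with single-block fits 0.41 / 0.32 decomposes into
        # joint 0.33, independent climate 0.08, independent soil -0.01
        part = partition_variance(0.40, 0.41, 0.32)
        assert part.joint == pytest.approx(0.33)
        assert part.independent_climate == pytest.approx(0.08)
        assert part.independent_soil == pytest.approx(-0.01)

    def test_fully_redundant_blocks(self):
        part = partition_variance(0.5, 0.5, 0.5)
        assert part == (0.5, 0.0, 0.0)

    def test_uninformative_soil(self):
        part = partition_variance(0.3, 0.3, 0.0)
        assert part.joint == pytest.approx(0.0)
        assert part.independent_climate == pytest.approx(0.3)
        assert part.independent_soil == pytest.approx(0.0)

    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)
    )
    @settings(max_examples=200, deadline=None)
    def test_decomposition_identities(self, r2b, r2c, r2s):
        p = partition_variance(r2b, r2c, r2s)
        assert abs(p.independent_climate + p.independent_soil + p.joint - r2b) < 1e-12
        assert abs(p.independent_climate + p.joint - r2c) < 1e-12
        assert abs(p.independent_soil + p.joint - r2s) < 1e-12
        assert abs(partition_total(*p) - r2b) < 1e-12


class TestDisplayShares:
    def test_equal_split_of_joint(self):
        climate, soil = display_shares(0.47, 0.13, 0.03)
        assert climate == pytest.approx(0.365)
        assert soil == pytest.approx(0.265)
        assert climate + soil == pytest.approx(0.63)

    def test_negative_independent_soil_hidden(self):
        climate, soil = display_shares(0.4, 0.1, -0.05)
        assert soil == pytest.approx(0.2)      # only its joint half
        assert climate == pytest.approx(0.3)   # unaffected


class TestPartitionTable:
    @pytest.fixture
    def blocks(self):
        rng = np.random.default_rng(12)
        n = 60
        latent = rng.normal(0, 1, n)
        other = rng.normal(0, 1, n)
        clim = pd.DataFrame(
            np.outer(latent, rng.uniform(0.5, 1, 4))
            + rng.normal(0, 0.4, (n, 4)),
            columns=[f"clim_{j}" for j in range(4)],
        )
        soil = pd.DataFrame(
            np.outer(other, rng.uniform(0.5, 1, 5))
            + rng.normal(0, 0.4, (n, 5)),
            columns=[f"soil_{j}" for j in range(5)],
        )
        traits = pd.DataFrame(
            {
                "clim_trait": np.exp(latent + rng.normal(0, 0.3, n)),
                "soil_trait": np.exp(other + rng.normal(0, 0.3, n)),
            }
        )
        return traits, clim, soil

    def test_identities_and_driver_recovery(self, blocks):
        traits, clim, soil = blocks
        spec = RidgeSpec(
            lambdas=np.logspace(-3, 3, 15), repetitions=3,
            outer_folds=5, inner_folds=5, n_components=4, seed=0,
        )
        df = partition_table(traits, clim, soil, spec).set_index("trait")
        for trait in df.index:
            row = df.loc[trait]
            total = partition_total(
                row["joint"], row["independent_climate"], row["independent_soil"]
            )
            assert total == pytest.approx(row["r2_both_mean"], abs=1e-12)
            assert row["independent_climate"] + row["joint"] == pytest.approx(
                row["r2_climate_mean"], abs=1e-12
            )
            assert row["independent_soil"] + row["joint"] == pytest.approx(
                row["r2_soil_mean"], abs=1e-12
            )
        # independent blocks: each trait dominated by its own block
        assert (
            df.loc["clim_trait", "independent_climate"]
            > df.loc["clim_trait", "independent_soil"]
        )
        assert (
            df.loc["soil_trait", "independent_soil"]
            > df.loc["soil_trait", "independent_climate"]
        )
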