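"""Hellinger transform, PCA/RDA, VIF, forward selection, richness."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from glacierlake.ordination import (forward_select_rda, hellinger, pca,
                                    pc1_env_regression, rda,
                                    richness_summary, vif, _aic)


class TestHellinger:
    @pytest.mark.parametrize("row, expected", [
        ([1, 1, 1, 1], [0.5, 0.5, 0.5, 0.5]),
        ([4, 0, 0], [1.0, 0.0, 0.0]),
        ([1, 3], [0.5, np.sqrt(3) / 2]),
    ])
    def test_examples(self, row, expected):
        out = hellinger(np.array([row], dtype=float))
        assert np.allclose(out[0], expected, atol=1e-4)

    def test_zero_row_error(self):
        with pytest.raises(ValueError, match="sample index 1"):
            hellinger(np.array([[1.0, 2.0], [0.0, 0.0]]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hnp.arrays(float, (4, 6), elements=st.floats(0, 100)))
    def test_unit_row_sum_of_squares(self, Y):
        Y = Y + 0.01  # avoid zero rows
        H = hellinger(Y)
        assert np.allclose((H ** 2).sum(axis=1), 1.0, atol=1e-10)

    def test_not_idempotent_in_general(self):
        Y = np.array([[1.0, 3.0]])
        H = hellinger(Y)
        assert not np.allclose(hellinger(H), H)


class TestPCA:
    def test_two_clusters_on_pc1(self):
        rng = np.random.default_rng(0)
        Y = np.vstack([rng.normal(0, 0.05, (15, 4)),
                       rng.normal(3, 0.05, (15, 4))])
        res = pca(Y)
        assert res.proportion_explained[0] > 0.9

    def test_eigenvalue_sum_is_total_variance(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(20, 6))
        res = pca(Y)
        assert res.eigenvalues.sum() == pytest.approx(res.total_variance, abs=1e-10)

    def test_isotropic_noise_flat_spectrum(self):
        rng = np.random.default_rng(2)
        res = pca(rng.normal(size=(3000, 4)))
        assert res.eigenvalues[0] / res.eigenvalues[-1] < 1.3


class TestRDA:
    def test_noiseless_linear_fully_constrained(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(30, 1))
        Y = x @ rng.normal(size=(1, 5))
        res = rda(Y, x)
        assert res.constrained_proportion == pytest.approx(1.0, abs=1e-10)

    def test_unrelated_predictor_vs_permutation_null(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(50, 6))
        x = rng.normal(size=(50, 1))
        obs = rda(Y, x).constrained_proportion
        perms = [rda(Y, x[rng.permutation(50)]).constrained_proportion
                 for _ in range(99)]
        # observed proportion behaves like a draw from its own null
        assert obs < np.quantile(perms, 0.99) * 2
        assert obs < 0.2

    def test_eigenvalues_match_pca_of_fitted(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(40, 7))
        X = rng.normal(size=(40, 3))
        res = rda(Y, X)
        Yc = Y - Y.mean(axis=0)
        Xc = X - X.mean(axis=0)
        B, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
        fitted = Xc @ B
        oracle = np.linalg.eigvalsh(fitted.T @ fitted / 39)[::-1][:3]
        assert np.allclose(res.eigenvalues, oracle, atol=1e-10)

    def test_constrained_below_total(self):
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(25, 5))
        X = rng.normal(size=(25, 2))
        res = rda(Y, X)
        assert res.eigenvalues.sum() <= res.total_variance + 1e-12

    def test_collinear_rejected(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(20, 1))
        X = np.hstack([x, 2 * x])
        with pytest.raises(np.linalg.LinAlgError, match="vif"):
            rda(rng.normal(size=(20, 4)), X)


class TestVIF:
    def test_orthogonal_predictors(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(100, 3))
        X = np.linalg.qr(X - X.mean(axis=0))[0]  # centered, exactly orthogonal
        out = vif(X)
        assert all(v == pytest.approx(1.0, abs=1e-8) for v in out.values())

    def test_duplicated_predictor_infinite(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=50)
        out = vif(np.column_stack([x, x, rng.normal(size=50)]))
        assert np.isinf(out["x0"]) and np.isinf(out["x1"])

    def test_exact_correlation_0_9(self):
        """Sample correlation exactly 0.9 -> VIF = 1/(1-0.81) = 5.263."""
        n = 64
        u = np.ones(n) / np.sqrt(n)
        a = np.zeros(n); a[0] = 1.0
        b = np.zeros(n); b[1] = 1.0
        a = a - (a @ u) * u; a /= np.linalg.norm(a)
        b = b - (b @ u) * u - (b @ a) * a; b /= np.linalg.norm(b)
        x1 = a
        x2 = 0.9 * a + np.sqrt(1 - 0.81) * b
        out = vif(np.column_stack([x1, x2]))
        assert out["x0"] == pytest.approx(1 / (1 - 0.81), rel=1e-9)


class TestForwardSelection:
    def test_active_variable_found_first(self):
        """One active predictor among five noise columns, SNR 3, n=60:
        selected first in >=90% of 100 seeded runs."""
        wins = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            X = rng.normal(size=(60, 6))
            signal = X[:, [2]] @ rng.normal(size=(1, 5)) * 3.0
            Y = signal + rng.normal(size=(60, 5))
            res = forward_select_rda(Y, X)
            wins += bool(res.selected_variables
                         and res.selected_variables[0] == "x2")
        assert wins >= 90

    def test_all_noise_selects_nothing_or_little(self):
        rng = np.random.default_rng(123)
        Y = rng.normal(size=(40, 5))
        X = rng.normal(size=(40, 4))
        res = forward_select_rda(Y, X)
        null_aic = _aic(Y, X[:, []])
        assert res.aic <= null_aic + 1e-9
        assert len(res.selected_variables) <= 1

    def test_matches_exhaustive_subsets(self):
        """Greedy first/second picks agree with brute-force best subsets of
        size 1 and (given the first pick) size 2."""
        rng = np.random.default_rng(21)
        X = rng.normal(size=(30, 4))
        Y = X[:, [0]] @ np.ones((1, 3)) * 2 + X[:, [3]] @ np.ones((1, 3)) + \
            rng.normal(size=(30, 3)) * 0.5
        res = forward_select_rda(Y, X)
        best1 = min(range(4), key=lambda j: _aic(Y, X[:, [j]]))
        assert res.selected_variables[0] == f"x{best1}"
        if len(res.selected_variables) >= 2:
            best2 = min((j for j in range(4) if j != best1),
                        key=lambda j: _aic(Y, X[:, [best1, j]]))
            assert res.selected_variables[1] == f"x{best2}"


class TestRegressionAndRichness:
    def test_perfect_line(self):
        x = np.arange(10.0)
        out = pc1_env_regression(2 * x + 1, x)
        assert out["r2"] == pytest.approx(1.0)

    def test_permuted_null(self):
        rng = np.random.default_rng(31)
        x = rng.normal(size=100)
        y = rng.permutation(rng.normal(size=100))
        assert pc1_env_regression(y, x)["r2"] < 0.08

    def test_r2_equals_squared_correlation(self):
        rng = np.random.default_rng(32)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        out = pc1_env_regression(y, x)
        assert out["r2"] == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-12)

    def test_zero_variance_env(self):
        with pytest.raises(ValueError):
            pc1_env_regression(np.arange(5.0), np.ones(5))

    def test_richness_disjoint_and_identical(self):
        Y = np.array([[1, 0, 2, 0], [0, 3, 0, 4]], dtype=float)
        taxa = ["a", "b", "c", "d"]
        out = richness_summary(Y, taxa, ["spring", "summer"])
        assert out["present"] == {"spring": 2, "summer": 2}
        assert out["unique"] == {"spring": 2, "summer": 2}
        out2 = richness_summary(np.vstack([Y[0], Y[0]]), taxa,
                                ["spring", "summer"])
        assert out2["unique"] == {"spring": 0, "summer": 0}

    def test_five_taxon_hand_count(self):
        Y = np.array([
            [1, 1, 0, 0, 1],   # spring
            [0, 1, 1, 0, 0],   # spring
            [0, 1, 1, 1, 0],   # summer
        ], dtype=float)
        taxa = list("abcde")
        out = richness_summary(Y, taxa, ["spring", "spring", "summer"])
        assert out["present"] == {"spring": 4, "summer": 3}
        # spring-only: a, e; summer-only: d
        assert out["unique"] == {"spring": 2, "summer": 1}
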