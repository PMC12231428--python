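"""Correlation-filtered regularised prediction under repeated cross-validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.model_selection import KFold

from ecpredict.errors import ConfigError, DegenerateInputError
from ecpredict.prediction import (
    CVConfig,
    SelectionConfig,
    crossval_predict,
    fit_linear,
    repeat_prediction,
    select_features,
)


class TestSelectFeatures:
    def test_count_at_wholebrain_scale(self, rng):
        x = rng.normal(size=(60, 9_900))
        y = rng.normal(size=60)
        idx = select_features(x, y, 0.05)
        assert idx.size == 990  # 495 per direction

    def test_known_ranking_selects_extremes(self, rng):
        # construct exact sample correlations c_j by mixing the unit y-direction
        # with noise orthogonalized against y
        n, p = 400, 100
        y = rng.normal(size=n)
        yc = (y - y.mean()) / np.linalg.norm(y - y.mean())
        noise = rng.normal(size=(n, p))
        noise = noise - noise.mean(axis=0)
        noise -= yc[:, None] * (yc @ noise)[None, :]
        noise /= np.linalg.norm(noise, axis=0)
        c = np.linspace(-0.9, 0.9, p)
        x = c[None, :] * yc[:, None] + np.sqrt(1 - c**2)[None, :] * noise
        idx = select_features(x, y, 0.05)
        assert set(int(i) for i in idx) == {0, 1, 2, 3, 4, 95, 96, 97, 98, 99}

    def test_ties_break_to_lower_index(self):
        x = np.zeros((20, 10))
        y = np.arange(20.0)
        x[:, 4] = y  # one perfectly correlated feature; rest constant (corr 0)
        idx = select_features(x, y, 0.1)
        # k=1 per direction: top = feature 4; bottom = lowest-index tie (0)
        assert set(idx) == {0, 4}

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        p=st.integers(min_value=30, max_value=400),
        frac=st.floats(min_value=0.02, max_value=0.45),
    )
    def test_selected_count_is_exactly_2k(self, p, frac):
        k = int(np.floor(frac * p))
        if k < 1 or 2 * k >= p:
            return
        rng = np.random.default_rng(p)
        x = rng.normal(size=(30, p))
        y = rng.normal(size=30)
        idx = select_features(x, y, frac)
        assert idx.size == 2 * k
        assert np.unique(idx).size == idx.size

    def test_null_overlap_near_chance(self, rng):
        n, p, frac = 400, 200, 0.05
        x = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        a = select_features(x[: n // 2], y[: n // 2], frac)
        b = select_features(x[n // 2 :], y[n // 2 :], frac)
        overlaps = []
        for _ in range(30):
            perm = rng.permutation(n)
            xa, ya = x[perm[: n // 2]], y[perm[: n // 2]]
            xb, yb = x[perm[n // 2 :]], y[perm[n // 2 :]]
            overlaps.append(
                len(set(select_features(xa, ya, frac)) & set(select_features(xb, yb, frac)))
            )
        # chance overlap of two size-2k subsets of p: (2k)^2/p = 2
        assert np.mean(overlaps) < 6

    def test_degenerate_inputs_raise(self, rng):
        x = rng.normal(size=(20, 50))
        with pytest.raises(DegenerateInputError):
            select_features(x, np.ones(20), 0.1)
        with pytest.raises(ConfigError):
            select_features(x, rng.normal(size=20), 0.01)  # k = 0
        with pytest.raises(ConfigError):
            SelectionConfig(fraction=0.6)


class TestFitLinear:
    def test_ridge_zero_penalty_is_ols(self, rng):
        x = rng.normal(size=(50, 5))
        y = rng.normal(size=50)
        w, b = fit_linear(x, y, "ridge", penalty=0.0)
        x1 = np.column_stack([x, np.ones(50)])
        ols = np.linalg.lstsq(x1, y, rcond=None)[0]
        assert np.allclose(w, ols[:5], atol=1e-8)
        assert np.isclose(b, ols[5], atol=1e-8)

    def test_huge_penalty_predicts_training_mean(self, rng):
        x = rng.normal(size=(50, 5))
        y = rng.normal(size=50) + 3.0
        w, b = fit_linear(x, y, "ridge", penalty=1e12)
        assert np.max(np.abs(w)) < 1e-6
        assert np.isclose(b, y.mean(), atol=1e-6)

    def test_lasso_orthonormal_design_soft_thresholds(self, rng):
        # columns orthonormal: coordinate descent solves w_j = soft(x_j @ y / n, alpha)
        n = 64
        q, _ = np.linalg.qr(rng.normal(size=(n, 2)))
        x = q * np.sqrt(n)  # x.T @ x = n * I
        y = rng.normal(size=n)
        y = y - y.mean()
        alpha = 0.1
        w, _ = fit_linear(x, y, "lasso", penalty=alpha)
        ols = x.T @ y / n
        expected = np.sign(ols) * np.maximum(np.abs(ols) - alpha, 0)
        assert np.allclose(w, expected, atol=1e-3)  # coordinate-descent tolerance

    def test_non_finite_inputs_raise(self):
        from ecpredict.errors import NumericalError

        with pytest.raises(NumericalError):
            fit_linear(np.array([[np.nan]]), np.array([1.0]), "ridge", 1.0)


class TestCrossvalPredict:
    def test_perfect_linear_signal_gives_near_perfect_r(self, rng):
        n, p = 200, 40
        x = rng.normal(size=(n, p))
        w = np.zeros(p)
        w[:4] = [2.0, -2.0, 1.5, -1.5]
        y = x @ w
        r = crossval_predict(x, y, SelectionConfig(0.05), CVConfig(n_repeats=1), seed=0)
        assert r >= 0.99

    def test_null_association_averages_to_zero_across_datasets(self):
        """With y independent of X the prediction correlation centres on zero.

        Within one dataset the CV estimate tracks that sample's chance
        feature-score correlations (repeats share the data), so the zero
        expectation holds across independent datasets, not per dataset.
        """
        means = []
        for d in range(10):
            g = np.random.default_rng(500 + d)
            x = g.normal(size=(120, 60))
            y = g.normal(size=120)
            means.append(
                repeat_prediction(
                    x, y, SelectionConfig(0.05), CVConfig(n_repeats=10, seed=d)
                ).mean_r
            )
        assert abs(np.mean(means)) < 0.1

    def test_same_seed_reproduces(self, rng):
        x = rng.normal(size=(60, 30))
        y = rng.normal(size=60)
        sel, cv = SelectionConfig(0.1), CVConfig(n_repeats=3, seed=9)
        a = repeat_prediction(x, y, sel, cv)
        b = repeat_prediction(x, y, sel, cv)
        assert np.array_equal(a.per_repeat_r, b.per_repeat_r)

    def test_selection_and_fit_ignore_test_fold(self, rng):
        """Corrupting held-out scores never changes what the training fold selects."""
        n, p, seed = 80, 50, 13
        x = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        splitter = KFold(n_splits=10, shuffle=True, random_state=seed)
        train_idx, test_idx = next(splitter.split(x))
        y_corrupt = y.copy()
        y_corrupt[test_idx] = rng.normal(size=test_idx.size) * 100
        sel_clean = select_features(x[train_idx], y[train_idx], 0.1)
        sel_corrupt = select_features(x[train_idx], y_corrupt[train_idx], 0.1)
        assert np.array_equal(sel_clean, sel_corrupt)
        w_clean, b_clean = fit_linear(x[train_idx][:, sel_clean], y[train_idx], "ridge", 1.0)
        w_corrupt, b_corrupt = fit_linear(
            x[train_idx][:, sel_corrupt], y_corrupt[train_idx], "ridge", 1.0
        )
        assert np.array_equal(w_clean, w_corrupt) and b_clean == b_corrupt

    def test_small_folds_rejected(self, rng):
        x = rng.normal(size=(20, 30))
        y = rng.normal(size=20)
        with pytest.raises(ConfigError):
            crossval_predict(x, y, SelectionConfig(0.1), CVConfig(n_folds=10), seed=0)

    def test_single_repeat_mean_equals_value(self, rng):
        x = rng.normal(size=(60, 30))
        y = rng.normal(size=60)
        res = repeat_prediction(x, y, SelectionConfig(0.1), CVConfig(n_repeats=1, seed=2))
        assert res.per_repeat_r.shape == (1,)
        assert res.mean_r == res.per_repeat_r[0]

    def test_mean_r_rises_with_planted_effect_size(self, rng):
        """Average prediction correlation responds monotonically to signal strength."""
        n, p = 150, 40
        means = []
        for strength in (0.0, 0.5, 1.5):
            reps = []
            for rep in range(5):
                g = np.random.default_rng(1000 + rep)
                x = g.normal(size=(n, p))
                y = strength * (x[:, 0] - x[:, 1]) + g.normal(size=n)
                reps.append(
                    repeat_prediction(
                        x, y, SelectionConfig(0.05), CVConfig(n_repeats=2, seed=rep)
                    ).mean_r
                )
            means.append(np.mean(reps))
        assert means[0] < means[1] < means[2]
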