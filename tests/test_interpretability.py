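"""Shapley estimator axioms: linear closed form, dummy, symmetry, local
accuracy against an independent permutation-enumeration oracle."""

import itertools

import numpy as np
import pytest

from grainspec.interpretability import (
    band_window_enrichment,
    shapley_attribute,
    summarize_importance,
)


def brute_force_shapley(f, bg, x):
    """Independent oracle: average marginal contributions over ALL p!
    permutations, with v(S) = mean over background rows of f(x_S, b_~S)."""
    p = x.size
    phi = np.zeros(p)
    for perm in itertools.permutations(range(p)):
        z = bg.copy()
        prev = f(z).mean()
        for j in perm:
            z = z.copy()
            z[:, j] = x[j]
            cur = f(z).mean()
            phi[j] += cur - prev
            prev = cur
    return phi / np.math.factorial(p) if hasattr(np, "math") else phi / np.prod(range(1, p + 1))


def factorial(p):
    out = 1
    for i in range(2, p + 1):
        out *= i
    return out


class TestLinearClosedForm:
    w = np.array([2.0, -1.0, 0.5, 3.0])
    b = 0.7

    def f(self, X):
        return X @ self.w + self.b

    def setup_method(self):
        rng = np.random.default_rng(0)
        self.bg = rng.normal(size=(25, 4))
        self.x = rng.normal(size=4)

    def test_exact_estimator_matches_closed_form(self):
        res = shapley_attribute(self.f, self.bg, self.x[None, :], estimator="exact")
        expected = self.w * (self.x - self.bg.mean(axis=0))
        np.testing.assert_allclose(res.values[0], expected, atol=1e-10)

    def test_sampling_estimator_with_cycled_background_is_exact(self):
        """For a linear model each marginal contribution is w_j (x_j - b_j)
        independent of position, so cycling the whole background reproduces
        the closed form exactly."""
        res = shapley_attribute(self.f, self.bg, self.x[None, :],
                                n_samples=50, seed=1, estimator="sampling")
        expected = self.w * (self.x - self.bg.mean(axis=0))
        np.testing.assert_allclose(res.values[0], expected, atol=1e-10)

    def test_sampling_standard_error_shrinks_with_n(self):
        # nonlinear model so permutations genuinely disagree
        g = lambda X: (X[:, 0] * X[:, 1]) + X[:, 2] ** 2
        ests_small, ests_big = [], []
        for seed in range(12):
            small = shapley_attribute(g, self.bg, self.x[None, :], n_samples=10, seed=seed)
            big = shapley_attribute(g, self.bg, self.x[None, :], n_samples=90, seed=seed)
            ests_small.append(small.values[0])
            ests_big.append(big.values[0])
        sd_small = np.std(ests_small, axis=0).mean()
        sd_big = np.std(ests_big, axis=0).mean()
        assert sd_big < sd_small / 1.5  # expect ~1/3 at 9x the samples


class TestAxioms:
    def test_dummy_feature_gets_zero(self):
        rng = np.random.default_rng(2)
        bg = rng.normal(size=(10, 5))
        bg[:, 3] = 1.5  # constant in background
        x = rng.normal(size=5)
        x[3] = 1.5  # and in the explained point
        f = lambda X: X @ np.array([1.0, 2.0, -1.0, 4.0, 0.5])
        for est in ("exact", "sampling"):
            res = shapley_attribute(f, bg, x[None, :], n_samples=40, seed=3, estimator=est)
            assert res.values[0, 3] == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_axiom_by_enumeration(self):
        rng = np.random.default_rng(4)
        bg = rng.normal(size=(8, 4))
        bg[:, 1] = bg[:, 0]  # exchangeable background for features 0 and 1
        x = rng.normal(size=4)
        x[1] = x[0]
        f = lambda X: (X[:, 0] + X[:, 1]) ** 2 + 0.3 * X[:, 2]
        res = shapley_attribute(f, bg, x[None, :], estimator="exact")
        assert res.values[0, 0] == pytest.approx(res.values[0, 1], abs=1e-10)

    def test_local_accuracy_vs_brute_force(self):
        rng = np.random.default_rng(5)
        bg = rng.normal(size=(6, 4))
        x = rng.normal(size=4)
        f = lambda X: np.tanh(X @ np.array([1.0, -2.0, 0.5, 1.5])) + X[:, 0] * X[:, 3]
        res = shapley_attribute(f, bg, x[None, :], estimator="exact")
        # efficiency: base + sum(phi) = f(x)
        np.testing.assert_allclose(
            res.base_values[0] + res.values[0].sum(), f(x[None, :])[0], atol=1e-8
        )
        # value-by-value agreement with the permutation-enumeration oracle
        phi = np.zeros(4)
        for perm in itertools.permutations(range(4)):
            z = bg.copy()
            prev = f(z).mean()
            for j in perm:
                z = z.copy()
                z[:, j] = x[j]
                cur = f(z).mean()
                phi[j] += cur - prev
                prev = cur
        phi /= factorial(4)
        np.testing.assert_allclose(res.values[0], phi, atol=1e-8)

    def test_sampling_local_accuracy_with_cycled_background(self):
        rng = np.random.default_rng(6)
        bg = rng.normal(size=(10, 6))
        x = rng.normal(size=6)
        f = lambda X: np.sin(X).sum(axis=1)
        res = shapley_attribute(f, bg, x[None, :], n_samples=30, seed=7)
        np.testing.assert_allclose(
            res.base_values[0] + res.values[0].sum(), f(x[None, :])[0], atol=1e-10
        )

    def test_invalid_inputs(self):
        f = lambda X: X.sum(axis=1)
        with pytest.raises(ValueError):
            shapley_attribute(f, np.ones((3, 4)), np.ones((1, 4)), n_samples=0)
        with pytest.raises(ValueError):
            shapley_attribute(f, np.ones((3, 20)), np.ones((1, 20)), estimator="exact")


class TestSummaries:
    def make_attr(self, values, wl=None):
        from grainspec.interpretability import AttributionResult

        values = np.atleast_2d(values)
        return AttributionResult(
            values=values,
            base_values=np.zeros(len(values)),
            explained_class=np.zeros(len(values), dtype=int),
            wavelengths=wl,
        )

    def test_zero_attributions_rank_by_band_order(self):
        attr = self.make_attr(np.zeros((3, 5)))
        s = summarize_importance(attr, k=5)
        assert s.top_k == [0, 1, 2, 3, 4]
        np.testing.assert_array_equal(s.mean_abs, 0.0)

    def test_hand_ranking_by_absolute_value(self):
        s = summarize_importance(self.make_attr([[3.0, -5.0, 1.0]]), k=3)
        assert s.top_k == [1, 0, 2]

    def test_k_equal_bands_is_permutation(self):
        rng = np.random.default_rng(8)
        s = summarize_importance(self.make_attr(rng.normal(size=(4, 7))), k=7)
        assert sorted(s.top_k) == list(range(7))

    def test_k_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            s = summarize_importance(self.make_attr([[1.0, 2.0]]), k=5)
        assert len(s.top_k) == 2


class TestWindowEnrichment:
    wl = np.linspace(400, 1000, 25)

    def summary(self, top):
        from grainspec.interpretability import ImportanceSummary

        return ImportanceSummary(mean_abs=np.zeros(25), top_k=top, wavelengths=self.wl)

    def test_full_cover_gives_one(self):
        rep = band_window_enrichment(self.summary([0, 5, 10]), [(390.0, 1010.0)])
        assert rep["fraction_in_windows"] == 1.0
        assert rep["uniform_baseline"] == 1.0

    def test_disjoint_windows_give_zero(self):
        # bands 0..2 sit at 400-450 nm; windows exclude them
        rep = band_window_enrichment(self.summary([0, 1, 2]), [(900.0, 950.0)])
        assert rep["fraction_in_windows"] == 0.0

    def test_empty_windows_rejected(self):
        with pytest.raises(ValueError):
            band_window_enrichment(self.summary([0]), [])

    def test_planted_linear_signal_enriches_window(self):
        """A model whose weights live only in 580-700 nm concentrates top-k
        importance there far above the uniform baseline."""
        rng = np.random.default_rng(9)
        wl = np.linspace(397, 1003, 64)
        w = np.where((wl >= 580) & (wl <= 700), 3.0, 0.0) * rng.normal(size=64)
        f = lambda X: X @ w
        bg = rng.normal(size=(20, 64))
        xs = rng.normal(size=(5, 64))
        attr = shapley_attribute(f, bg, xs, n_samples=20, seed=10, wavelengths=wl)
        s = summarize_importance(attr, k=10)
        rep = band_window_enrichment(s, [(580.0, 700.0)])
        assert rep["fraction_in_windows"] > rep["uniform_baseline"]
        assert rep["fraction_in_windows"] == 1.0
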