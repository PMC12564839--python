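"""Classifier contracts: attention algebra, trainer behavior, CV stratification,
and finite-difference validation of the network gradients."""

import numpy as np
import pytest

from grainspec import _nn
from grainspec.models import (
    ArchitectureError,
    CNNArch,
    InvalidLabelsError,
    TrainConfig,
    TransformerArch,
    cross_validate,
    scaled_dot_attention,
    train_1dcnn,
    train_cnn_transformer,
    train_plsda,
    train_svm,
)


class TestScaledDotAttention:
    def test_single_key_value_token_returns_v(self):
        Q = np.random.default_rng(0).normal(size=(3, 4))
        K = np.array([[1.0, 2.0, 3.0, 4.0]])
        V = np.array([[5.0, 6.0]])
        out = scaled_dot_attention(Q, K, V)
        np.testing.assert_allclose(out, np.tile(V, (3, 1)))

    def test_uniform_scores_give_column_means(self):
        Q = np.zeros((2, 3))  # all scores equal -> uniform weights
        K = np.random.default_rng(1).normal(size=(5, 3))
        V = np.random.default_rng(2).normal(size=(5, 4))
        out = scaled_dot_attention(Q, K, V)
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (2, 1)))

    def test_two_token_hand_case(self):
        Q = np.array([[1.0, 0.0]])
        K = np.array([[1.0, 0.0], [0.0, 1.0]])
        V = np.array([[1.0, 0.0], [0.0, 1.0]])
        out, w = scaled_dot_attention(Q, K, V, return_weights=True)
        e = np.exp(np.array([1 / np.sqrt(2), 0.0]))
        expected_w = e / e.sum()
        np.testing.assert_allclose(w[0], expected_w)
        np.testing.assert_allclose(out[0], expected_w @ V)

    def test_weight_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        _, w = scaled_dot_attention(
            rng.normal(size=(6, 8)), rng.normal(size=(9, 8)), rng.normal(size=(9, 2)),
            return_weights=True,
        )
        np.testing.assert_allclose(w.sum(axis=-1), 1.0)
        assert np.all(w >= 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            scaled_dot_attention(np.ones((2, 3)), np.ones((2, 4)), np.ones((2, 2)))
        with pytest.raises(ValueError):
            scaled_dot_attention(np.ones((2, 3)), np.ones((4, 3)), np.ones((5, 2)))


def two_gaussians(n=60, seed=0, gap=6.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 4))
    X[: n // 2, 0] += gap
    y = np.array(["pos"] * (n // 2) + ["neg"] * (n - n // 2))
    return X, y


class TestPLSDA:
    def test_separable_classes_perfect_accuracy(self):
        X, y = two_gaussians(seed=1)
        model = train_plsda(X, y, n_components=2)
        assert model.accuracy(X, y) == 1.0

    def test_label_permutation_symmetry(self):
        X, y = two_gaussians(seed=2)
        perm = np.random.default_rng(3).permutation(len(y))
        a = train_plsda(X, y, n_components=2)
        b = train_plsda(X[perm], y[perm], n_components=2)
        np.testing.assert_allclose(a.decision_scores(X), b.decision_scores(X), atol=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidLabelsError):
            train_plsda(np.ones((10, 3)), np.array(["a"] * 10))

    def test_band_count_enforced(self):
        X, y = two_gaussians(seed=4)
        model = train_plsda(X, y, n_components=2)
        with pytest.raises(ValueError, match="bands"):
            model.predict(np.ones((2, 7)))


class TestSVM:
    def test_linearly_separable_toy(self):
        X = np.array([[0.0, 0], [0, 1], [5, 5], [5, 6]])
        y = np.array(["a", "a", "b", "b"])
        model = train_svm(X, y, C=1.0, gamma="scale")
        assert model.accuracy(X, y) == 1.0

    def test_duplication_invariance_of_decision_function(self):
        # hard-margin regime: with no active slack, duplicating every training
        # sample leaves the maximum-margin solution unchanged
        X, y = two_gaussians(seed=5, gap=8.0)
        a = train_svm(X, y, C=1e4, gamma=0.1)
        b = train_svm(np.vstack([X, X]), np.concatenate([y, y]), C=1e4, gamma=0.1)
        np.testing.assert_allclose(a.decision_scores(X), b.decision_scores(X), atol=1e-4)

    def test_snv_preprocessing_helps_svm_on_scattered_spectra(self):
        """Paired over 10 seeds on scatter-corrupted synthetic spectra: the
        RBF-SVM is at least as accurate after SNV as on raw input."""
        from grainspec.acquisition import box_level_split
        from grainspec.preprocessing import snv
        from grainspec.synthetic_data import SceneDesign, make_templates, simulate_dataset

        design = SceneDesign(n_varieties=5, boxes_per_variety=4, grid_rows=3, grid_cols=4)
        wins = []
        for seed in range(10):
            ds = simulate_dataset(make_templates(5, seed=seed), design, seed=seed)
            split = box_level_split(ds, 1, seed=seed)
            tr, te = ds.subset(split.train_idx), ds.subset(split.test_idx)
            raw = train_svm(tr.reflectance, tr.labels, C=10.0, gamma="scale").accuracy(
                te.reflectance, te.labels)
            snv_acc = train_svm(snv(tr.reflectance), tr.labels, C=10.0, gamma="scale").accuracy(
                snv(te.reflectance), te.labels)
            wins.append(snv_acc >= raw)
        assert np.mean(wins) >= 0.9

    def test_nonfinite_input_rejected(self):
        X, y = two_gaussians(seed=6)
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_svm(X, y, C=1.0, gamma=0.1)


def tiny_planted_spectra(n_per=20, bands=32, n_classes=3, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([f"c{i}" for i in range(n_classes)], n_per)
    X = rng.normal(0, 0.05, size=(len(y), bands))
    for i in range(n_classes):
        X[np.asarray(y) == f"c{i}", (4 + 3 * i) % bands] += 1.0
    return X, np.asarray(y)


class TestNetworks:
    def test_zero_epochs_is_random_init_smoke(self):
        X, y = tiny_planted_spectra()
        model = train_1dcnn(X, y, cfg=TrainConfig(epochs=0, seed=0))
        preds = model.predict(X)
        assert set(preds) <= set(np.unique(y))
        assert model.loss_trace == []

    def test_training_reduces_loss(self):
        X, y = tiny_planted_spectra(seed=1)
        model = train_1dcnn(X, y, cfg=TrainConfig(epochs=8, seed=1))
        assert model.loss_trace[-1] < model.loss_trace[0]

    def test_seeded_determinism_both_networks(self):
        X, y = tiny_planted_spectra(seed=2)
        cfg = TrainConfig(epochs=3, seed=5)
        for trainer in (train_1dcnn, train_cnn_transformer):
            a = trainer(X, y, cfg=cfg)
            b = trainer(X, y, cfg=cfg)
            np.testing.assert_array_equal(a.decision_scores(X), b.decision_scores(X))

    def test_cnn_architecture_inventory(self):
        X, y = tiny_planted_spectra(seed=3)
        model = train_1dcnn(X, y, cfg=TrainConfig(epochs=0, seed=0))
        inv = model.network.layer_inventory()
        assert inv == [
            "Conv1d", "BatchNorm1d", "ReLU", "MaxPool1d",
            "Conv1d", "BatchNorm1d", "ReLU", "MaxPool1d",
            "Conv1d", "BatchNorm1d", "ReLU", "MaxPool1d",
            "Flatten", "Dense", "ReLU", "Dropout", "Dense",
        ]
        convs = [l for l in model.network.layers if isinstance(l, _nn.Conv1d)]
        assert [(c.c_out, c.k) for c in convs] == [(8, 5), (16, 3), (16, 3)]

    def test_cnn_transformer_inventory_and_attention_rows(self):
        X, y = tiny_planted_spectra(seed=4)
        model = train_cnn_transformer(
            X, y, tarch=TransformerArch(d_model=16, n_heads=2, patch=2),
            cfg=TrainConfig(epochs=1, seed=0),
        )
        inv = model.network.layer_inventory()
        assert inv[:4] == ["PatchEmbed", "Dense", "PositionalEncoding", "TransformerEncoderLayer"]
        assert inv[4] == "ToChannels"
        model.predict(X[:5])  # forward pass caches attention
        attn = model.network.layers[3].attn.last_attention
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-12)
        assert np.all(attn >= 0)

    def test_uniform_attention_limit_reduces_to_value_means(self):
        """With zeroed query weights every attention row is uniform, so the
        pre-residual attention output is the value mean, identical per token."""
        rng = np.random.default_rng(0)
        attn = _nn.MultiHeadSelfAttention(d_model=8, n_heads=2, rng=rng)
        attn.Wq[...] = 0.0
        x = rng.normal(size=(3, 6, 8))
        out = attn.forward(x, train=False)
        np.testing.assert_allclose(out, np.repeat(out[:, :1, :], 6, axis=1), atol=1e-12)
        np.testing.assert_allclose(attn.last_attention, 1.0 / 6, atol=1e-12)

    def test_too_few_bands_raises_architecture_error(self):
        X, y = tiny_planted_spectra(bands=6, seed=5)
        with pytest.raises(ArchitectureError):
            train_1dcnn(X, y, cfg=TrainConfig(epochs=0, seed=0))

    @pytest.mark.parametrize("build", ["cnn", "transformer"])
    def test_gradients_match_finite_differences(self, build):
        """Backprop oracle: analytic gradients of the full network loss agree
        with central finite differences at randomly probed parameters."""
        rng_data = np.random.default_rng(10)
        X = rng_data.normal(size=(4, 1, 16))
        y = np.array([0, 1, 2, 0])
        rng = np.random.default_rng(0)
        if build == "cnn":
            from grainspec.models import _build_cnn_stack

            net = _nn.Network(_build_cnn_stack(1, 16, 3, CNNArch(), 0.0, rng))
            xin = X
        else:
            net = _nn.Network(
                [
                    _nn.PatchEmbed(2),
                    _nn.Dense(2, 8, rng),
                    _nn.PositionalEncoding(8, 8),
                    _nn.TransformerEncoderLayer(8, 2, 16, 0.0, rng),
                    _nn.ToChannels(),
                    _nn.Flatten(),
                    _nn.Dense(64, 3, rng),
                ]
            )
            xin = X

        def loss_at():
            logits = net.forward(xin, train=True)
            loss, g = _nn.cross_entropy(logits, y)
            return loss, g

        # analytic
        loss, g = loss_at()
        net.backward(g)
        params, grads = net.parameters()
        rng_probe = np.random.default_rng(1)
        eps = 1e-6
        checked = 0
        for p, gr in zip(params, grads):
            flat_p, flat_g = p.ravel(), gr.ravel()
            for idx in rng_probe.choice(flat_p.size, size=min(3, flat_p.size), replace=False):
                orig = flat_p[idx]
                flat_p[idx] = orig + eps
                lp, _ = loss_at()
                flat_p[idx] = orig - eps
                lm, _ = loss_at()
                flat_p[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert fd == pytest.approx(flat_g[idx], rel=1e-4, abs=1e-7)
                checked += 1
        assert checked > 20

    def test_batchnorm_uses_running_stats_in_eval(self):
        bn = _nn.BatchNorm1d(2)
        x = np.random.default_rng(0).normal(2.0, 3.0, size=(16, 2, 5))
        bn.forward(x, train=True)
        out_eval = bn.forward(np.zeros((1, 2, 5)), train=False)
        expected = -bn.run_mean / np.sqrt(bn.run_var + bn.eps)
        np.testing.assert_allclose(out_eval[0, :, 0], expected, atol=1e-9)


class PerfectStub:
    """Oracle classifier: memorises nothing, answers from the true rule."""

    def __init__(self, rule):
        self.rule = rule

    def predict(self, X):
        return self.rule(X)


class TestCrossValidate:
    def make_data(self, n_classes=13, per_class=12, seed=0):
        rng = np.random.default_rng(seed)
        y = np.repeat(np.arange(n_classes), per_class)
        X = y[:, None] + rng.normal(0, 0.01, size=(y.size, 3))
        return X, y

    def test_perfect_stub_scores_one(self):
        X, y = self.make_data()
        cv = cross_validate(lambda A, b: PerfectStub(lambda Z: np.round(Z[:, 0]).astype(int)),
                            X, y, k=4, seed=0)
        assert cv["mean_accuracy"] == 1.0

    def test_majority_stub_scores_chance_on_balanced_data(self):
        X, y = self.make_data()
        cv = cross_validate(lambda A, b: PerfectStub(lambda Z: np.zeros(len(Z), dtype=int)),
                            X, y, k=4, seed=0)
        assert cv["mean_accuracy"] == pytest.approx(1 / 13, abs=1e-9)

    def test_fold_sizes_balanced_within_one_per_class(self):
        X, y = self.make_data(n_classes=5, per_class=11)
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=4, shuffle=True, random_state=0)
        for _, te in skf.split(X, y):
            counts = np.bincount(y[te], minlength=5)
            assert counts.max() - counts.min() <= 1

    def test_small_class_rejected(self):
        X = np.zeros((6, 2))
        y = np.array([0, 0, 0, 0, 1, 1])
        with pytest.raises(InvalidLabelsError):
            cross_validate(lambda A, b: PerfectStub(lambda Z: np.zeros(len(Z))), X, y, k=4)

    def test_group_disjoint_folds(self):
        X, y = self.make_data(n_classes=3, per_class=16)
        groups = np.tile(np.repeat(np.arange(8), 2), 3)  # 8 boxes per class
        from sklearn.model_selection import StratifiedGroupKFold

        sgkf = StratifiedGroupKFold(n_splits=4, shuffle=True, random_state=0)
        for tr, te in sgkf.split(X, y, groups):
            assert not (set(groups[tr]) & set(groups[te]))
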