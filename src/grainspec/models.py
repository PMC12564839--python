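"""The four spectral classifiers: PLS-DA, RBF-SVM, 1D-CNN and CNN-Transformer.

The two networks share one convolutional stack: three conv blocks of
(8 filters, kernel 5), (16, kernel 3), (16, kernel 3), stride 1, each followed
by batch normalization, ReLU and width-2 max pooling, then flatten, one fully
connected layer with dropout, and a linear output layer. The CNN-Transformer
prepends a token embedding of contiguous band patches with sinusoidal
positional encoding and a self-attention encoder, so long-range inter-band
dependencies are mixed into the representation before the local conv motifs
are extracted. Training uses softmax cross-entropy with Adam (lr 0.001),
dropout 0.1, batch size 64; the default budget is 1000 epochs, and short
budgets are accepted everywhere for desk-scale runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.svm import SVC

from . import _nn
from ._nn import Network, softmax
from .feature_selection import PLSCore, one_hot

__all__ = [
    "TrainConfig",
    "CNNArch",
    "TransformerArch",
    "TrainedClassifier",
    "scaled_dot_attention",
    "train_plsda",
    "train_svm",
    "train_1dcnn",
    "train_cnn_transformer",
    "cross_validate",
    "ArchitectureError",
    "InvalidLabelsError",
]

MODEL_KINDS = ("PLS-DA", "SVM", "1D-CNN", "CNN-Transformer")


class ArchitectureError(ValueError):
    """Input too short for the pooling stack, or inconsistent dimensions."""


class InvalidLabelsError(ValueError):
    """Labels unusable for classification (e.g. a single class)."""


@dataclass(frozen=True)
class TrainConfig:
    """Network training hyperparameters (cross-entropy loss, Adam optimizer)."""

    learning_rate: float = 1e-3
    dropout: float = 0.1
    batch_size: int = 64
    epochs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs < 0:
            raise ValueError("learning_rate/batch_size must be positive, epochs >= 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class CNNArch:
    """Convolutional stack shared by both networks."""

    conv_blocks: tuple[tuple[int, int, int], ...] = ((8, 5, 1), (16, 3, 1), (16, 3, 1))
    fc_width: int = 64
    pool: int = 2


@dataclass(frozen=True)
class TransformerArch:
    """Encoder in front of the conv stack (CNN-Transformer only).

    Band patches of ``patch`` contiguous wavelengths are linearly embedded to
    ``d_model`` and mixed by ``n_layers`` post-norm self-attention blocks; the
    patch width shrinks automatically on short inputs so at least 8 tokens
    survive the three pooling stages.
    """

    d_model: int = 64
    n_heads: int = 4
    n_layers: int = 1
    ffn_width: int = 128
    patch: int = 8


def scaled_dot_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray, return_weights: bool = False):
    """softmax(Q K^T / sqrt(d_k)) V.

    Q: (t_q, d_k), K: (t_k, d_k), V: (t_k, d_v). Each weight row is a
    probability distribution over the key tokens.
    """
    Q, K, V = (np.asarray(m, dtype=float) for m in (Q, K, V))
    if Q.ndim != 2 or K.ndim != 2 or V.ndim != 2:
        raise ValueError("Q, K, V must be 2-D matrices")
    if Q.shape[1] != K.shape[1]:
        raise ValueError(f"Q and K must share d_k, got {Q.shape[1]} vs {K.shape[1]}")
    if K.shape[0] != V.shape[0]:
        raise ValueError(f"K and V must share token count, got {K.shape[0]} vs {V.shape[0]}")
    out, weights = _nn.scaled_dot_attention_forward(Q, K, V)
    return (out, weights) if return_weights else out


class TrainedClassifier:
    """A fitted model with its preprocessing/selection provenance.

    ``predict`` accepts exactly the band count the model was trained on.
    ``predict_proba`` returns per-class scores normalised by a softmax for the
    margin-based models (PLS-DA decision values, SVM one-vs-rest votes) and
    true softmax probabilities for the networks.
    """

    def __init__(self, kind, classes, n_bands, predict_fn, score_fn,
                 provenance=None, loss_trace=None, network=None):
        if kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}")
        self.kind = kind
        self.classes_ = np.asarray(classes)
        self.n_bands = int(n_bands)
        self._predict_fn = predict_fn
        self._score_fn = score_fn
        self.provenance = dict(provenance or {})
        self.loss_trace = list(loss_trace or [])
        self.network = network

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_bands:
            raise ValueError(
                f"model was trained on {self.n_bands} bands, got {X.shape[1]}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("input contains non-finite values")
        return X

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Raw per-class scores (logits / decision values), (n, n_classes)."""
        return self._score_fn(self._check(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self.decision_scores(X), axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._predict_fn(self._check(X))

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


# ----------------------------------------------------------------- PLS-DA / SVM


def train_plsda(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int | None = None,
    cv_grid: tuple[int, ...] = (5, 10, 15, 20),
    seed: int = 0,
) -> TrainedClassifier:
    """PLS2 regression on one-hot labels; prediction is the argmax response.

    When ``n_components`` is not given, it is chosen by 4-fold stratified CV
    over ``cv_grid`` (capped at the rank limit).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise InvalidLabelsError("PLS-DA needs at least two classes")
    cap = min(X.shape[0] - 1, X.shape[1])
    if n_components is None:
        grid = sorted({min(k, cap) for k in cv_grid})
        if len(grid) > 1:
            accs = [
                cross_validate(lambda A, b, k=k: train_plsda(A, b, n_components=k),
                               X, y, k=4, seed=seed)["mean_accuracy"]
                for k in grid
            ]
            n_components = grid[int(np.argmax(accs))]
        else:
            n_components = grid[0]
    if n_components > cap:
        raise ValueError(f"n_components {n_components} exceeds rank limit {cap}")
    core = PLSCore(n_components).fit(X, y)
    return TrainedClassifier(
        kind="PLS-DA",
        classes=core.classes_,
        n_bands=X.shape[1],
        predict_fn=core.predict,
        score_fn=core.decision,
        provenance={"n_components": int(n_components)},
    )


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float | None = None,
    gamma=None,
    cv_grid=((1.0, 10.0, 100.0), ("scale", 0.01, 0.1)),
    seed: int = 0,
) -> TrainedClassifier:
    """RBF-kernel maximum-margin classifier, one-vs-one multiclass.

    Unset ``(C, gamma)`` are grid-searched with 4-fold stratified CV.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("input contains non-finite values")
    if np.unique(y).size < 2:
        raise InvalidLabelsError("SVM needs at least two classes")
    if C is None or gamma is None:
        Cs = cv_grid[0] if C is None else (C,)
        gammas = cv_grid[1] if gamma is None else (gamma,)
        best = None
        for c_, g_ in itertools.product(Cs, gammas):
            acc = cross_validate(
                lambda A, b, c=c_, g=g_: train_svm(A, b, C=c, gamma=g),
                X, y, k=4, seed=seed,
            )["mean_accuracy"]
            if best is None or acc > best[0]:
                best = (acc, c_, g_)
        _, C, gamma = best
    svc = SVC(C=C, gamma=gamma, kernel="rbf", decision_function_shape="ovr", random_state=seed)
    svc.fit(X, y)
    return TrainedClassifier(
        kind="SVM",
        classes=svc.classes_,
        n_bands=X.shape[1],
        predict_fn=svc.predict,
        score_fn=svc.decision_function,
        provenance={"C": float(C), "gamma": gamma if isinstance(gamma, str) else float(gamma)},
    )


# -------------------------------------------------------------------- networks


def _build_cnn_stack(c_in: int, length: int, n_classes: int, arch: CNNArch,
                     dropout: float, rng) -> list:
    layers = []
    L, c = length, c_in
    for filters, kernel, _stride in arch.conv_blocks:
        layers += [
            _nn.Conv1d(c, filters, kernel, rng),
            _nn.BatchNorm1d(filters),
            _nn.ReLU(),
            _nn.MaxPool1d(),
        ]
        c, L = filters, L // arch.pool
        if L < 1:
            min_len = arch.pool ** len(arch.conv_blocks)
            raise ArchitectureError(
                f"input of {length} positions is too short for "
                f"{len(arch.conv_blocks)} pooling stages; need >= {min_len}"
            )
    layers += [
        _nn.Flatten(),
        _nn.Dense(c * L, arch.fc_width, rng),
        _nn.ReLU(),
        _nn.Dropout(dropout, rng),
        _nn.Dense(arch.fc_width, n_classes, rng),
    ]
    return layers


def _fit_network(net: Network, X: np.ndarray, y_idx: np.ndarray,
                 cfg: TrainConfig, rng) -> list[float]:
    xin = X[:, None, :]
    n = len(X)
    params, grads = net.parameters()
    opt = _nn.Adam(params, grads, lr=cfg.learning_rate)
    losses = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        total = 0.0
        for s in range(0, n, cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            logits = net.forward(xin[idx], train=True)
            loss, g = _nn.cross_entropy(logits, y_idx[idx])
            net.backward(g)
            opt.step()
            total += loss * len(idx)
        losses.append(total / n)
    return losses


def _network_classifier(kind, net, classes, n_bands, mean, sd, losses, provenance):
    def _prep(X):
        return ((X - mean) / sd)[:, None, :]

    def score_fn(X):
        out = []
        for s in range(0, len(X), 256):
            out.append(net.forward(_prep(X[s : s + 256]), train=False))
        return np.vstack(out)

    def predict_fn(X):
        return classes[np.argmax(score_fn(X), axis=1)]

    return TrainedClassifier(
        kind=kind, classes=classes, n_bands=n_bands,
        predict_fn=predict_fn, score_fn=score_fn,
        provenance=provenance, loss_trace=losses, network=net,
    )


def _train_common(X, y, cfg):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise InvalidLabelsError("need at least two classes")
    y_idx = np.searchsorted(classes, y)
    cfg = cfg or TrainConfig()
    # per-band standardization from training statistics
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return X, y_idx, classes, cfg, mean, sd


def train_1dcnn(
    X: np.ndarray,
    y: np.ndarray,
    arch: CNNArch = CNNArch(),
    cfg: TrainConfig | None = None,
) -> TrainedClassifier:
    """Train the three-block 1D-CNN on spectra (one channel per sample)."""
    X, y_idx, classes, cfg, mean, sd = _train_common(X, y, cfg)
    rng = np.random.default_rng([cfg.seed, 17])
    net = Network(_build_cnn_stack(1, X.shape[1], classes.size, arch, cfg.dropout, rng))
    losses = _fit_network(net, (X - mean) / sd, y_idx, cfg, rng)
    return _network_classifier(
        "1D-CNN", net, classes, X.shape[1], mean, sd, losses,
        {"arch": arch, "config": cfg},
    )


def train_cnn_transformer(
    X: np.ndarray,
    y: np.ndarray,
    arch: CNNArch = CNNArch(),
    tarch: TransformerArch = TransformerArch(),
    cfg: TrainConfig | None = None,
) -> TrainedClassifier:
    """Train the hybrid network: patch embedding + positional encoding +
    self-attention encoder, then the shared conv stack and classifier head."""
    X, y_idx, classes, cfg, mean, sd = _train_common(X, y, cfg)
    rng = np.random.default_rng([cfg.seed, 29])
    n_bands = X.shape[1]
    min_tokens = arch.pool ** len(arch.conv_blocks)
    patch = max(1, min(tarch.patch, n_bands // min_tokens))
    n_tokens = -(-n_bands // patch)
    if n_tokens < min_tokens:
        raise ArchitectureError(
            f"{n_bands} bands give {n_tokens} tokens; need >= {min_tokens}"
        )
    layers = [
        _nn.PatchEmbed(patch),
        _nn.Dense(patch, tarch.d_model, rng),
        _nn.PositionalEncoding(n_tokens, tarch.d_model),
    ]
    layers += [
        _nn.TransformerEncoderLayer(tarch.d_model, tarch.n_heads, tarch.ffn_width,
                                    cfg.dropout, rng)
        for _ in range(tarch.n_layers)
    ]
    layers.append(_nn.ToChannels())
    layers += _build_cnn_stack(tarch.d_model, n_tokens, classes.size, arch, cfg.dropout, rng)
    net = Network(layers)
    losses = _fit_network(net, (X - mean) / sd, y_idx, cfg, rng)
    return _network_classifier(
        "CNN-Transformer", net, classes, n_bands, mean, sd, losses,
        {"arch": arch, "transformer": tarch, "config": cfg, "patch": patch},
    )


# ------------------------------------------------------------ cross-validation


def cross_validate(
    trainer,
    X: np.ndarray,
    y: np.ndarray,
    k: int = 4,
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> dict:
    """Stratified k-fold CV of any trainer callable ``(X, y) -> model``.

    Folds are stratified by label; when ``groups`` (e.g. box ids) are given,
    folds are additionally group-disjoint so no acquisition unit spans folds.
    Returns per-fold and mean/SD accuracies.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise InvalidLabelsError(
            f"smallest class has {counts.min()} samples, fewer than k={k} folds"
        )
    if groups is not None:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(X, y, groups=np.asarray(groups))
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(X, y)
    accs = []
    for tr, te in splits:
        model = trainer(X[tr], y[tr])
        pred = model.predict(X[te])
        accs.append(float(np.mean(pred == y[te])))
    accs = np.asarray(accs)
    return {
        "fold_accuracies": accs.tolist(),
        "mean_accuracy": float(accs.mean()),
        "sd_accuracy": float(accs.std(ddof=1)) if k > 1 else 0.0,
        "k": k,
        "seed": seed,
    }
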