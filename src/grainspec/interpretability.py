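"""Shapley-value attribution of classifier output to wavelengths.

The Shapley value of band j for one spectrum is the band's average marginal
contribution to the explained class score over orderings of the bands, with
absent bands imputed from a background set of training spectra. Two estimators
are provided: a permutation-sampling estimator usable at 224 bands, and an
exact enumeration over all coalitions for small band counts (the oracle the
sampling estimator is validated against). Both satisfy local accuracy:
base value + sum of attributions = model output for the explained spectrum
(the sampling estimator achieves this exactly by cycling the background).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AttributionResult",
    "ImportanceSummary",
    "shapley_attribute",
    "summarize_importance",
    "band_window_enrichment",
]


@dataclass
class AttributionResult:
    """Per-sample, per-band Shapley values for the explained class scores."""

    values: np.ndarray          # (n_explain, n_bands)
    base_values: np.ndarray     # (n_explain,) expected score over background
    explained_class: np.ndarray  # (n_explain,) class index explained per sample
    wavelengths: np.ndarray | None = None
    model_kind: str = "callable"
    estimator: str = "sampling"
    n_samples: int | None = None

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def local_accuracy_residual(self, outputs: np.ndarray) -> np.ndarray:
        """|base + sum(values) - output| per explained sample."""
        return np.abs(self.base_values + self.values.sum(axis=1) - np.asarray(outputs))

    def to_csv(self, path) -> None:
        cols = (
            [f"{w:.2f} nm" for w in self.wavelengths]
            if self.wavelengths is not None
            else [f"band{j}" for j in range(self.n_bands)]
        )
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "explained_class", self.explained_class)
        df.insert(1, "base_value", self.base_values)
        df.to_csv(path, index=False)


@dataclass
class ImportanceSummary:
    """Mean absolute attribution per band with a top-k ranking.

    ``top_k`` is sorted by mean |value| descending; ties break toward the
    shorter wavelength.
    """

    mean_abs: np.ndarray
    top_k: list[int]
    wavelengths: np.ndarray | None = None

    def top_k_wavelengths(self) -> list[float]:
        if self.wavelengths is None:
            raise ValueError("no wavelength axis attached")
        return [float(self.wavelengths[j]) for j in self.top_k]

    def to_json_dict(self) -> dict:
        d = {"mean_abs": self.mean_abs.tolist(), "top_k_band_idx": list(map(int, self.top_k))}
        if self.wavelengths is not None:
            d["top_k_bands"] = [f"{w:.2f} nm" for w in self.top_k_wavelengths()]
        return d


def _score_function(model, explained_output):
    """Normalize (model, target) into f(X) -> (n,) scores plus a class picker."""
    if callable(model) and not hasattr(model, "predict_proba"):
        raw = model
        kind = getattr(model, "__name__", "callable")
    else:
        raw = model.predict_proba
        kind = getattr(model, "kind", type(model).__name__)

    def scores(X):
        out = np.asarray(raw(np.asarray(X, dtype=float)))
        return out[:, None] if out.ndim == 1 else out

    return scores, kind


def shapley_attribute(
    model,
    X_background: np.ndarray,
    X_explain: np.ndarray,
    n_samples: int = 200,
    seed: int = 0,
    explained_output="predicted",
    estimator: str = "sampling",
    max_exact_features: int = 14,
    wavelengths: np.ndarray | None = None,
) -> AttributionResult:
    """Shapley attribution of the explained class score to each band.

    Parameters
    ----------
    model : TrainedClassifier or callable
        Anything exposing ``predict_proba`` (used as the score), or a callable
        returning per-sample scores (1-D) or per-class scores (2-D).
    X_background : (m, p) array
        Reference spectra used to impute absent bands.
    X_explain : (n, p) array
        Spectra to explain.
    n_samples : int
        Number of band permutations per explained spectrum (sampling
        estimator). The background is cycled across permutations so local
        accuracy holds exactly.
    explained_output : "predicted" | int
        Explain the model's predicted class per sample, or one fixed class
        index for all samples.
    estimator : "sampling" | "exact"
        "exact" enumerates all 2^p coalitions (only for small p) and weights
        marginal contributions by the Shapley kernel.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    bg = np.atleast_2d(np.asarray(X_background, dtype=float))
    Xe = np.atleast_2d(np.asarray(X_explain, dtype=float))
    if bg.size == 0:
        raise ValueError("background must be non-empty")
    n, p = Xe.shape
    scores, kind = _score_function(model, explained_output)

    out_explain = scores(Xe)
    if explained_output == "predicted":
        cls = np.argmax(out_explain, axis=1)
    else:
        cls = np.full(n, int(explained_output))
    base_all = scores(bg)  # (m, n_outputs)

    rng = np.random.default_rng([seed, 997])
    values = np.empty((n, p))
    base_values = np.empty(n)

    if estimator == "exact":
        if p > max_exact_features:
            raise ValueError(f"exact estimator limited to {max_exact_features} bands")
        values[:] = _exact_shapley(scores, bg, Xe, cls)
        base_values[:] = base_all.mean(axis=0)[cls]
    elif estimator == "sampling":
        for i in range(n):
            values[i], base_values[i] = _sampling_shapley(
                scores, bg, Xe[i], int(cls[i]), n_samples, rng
            )
    else:
        raise ValueError("estimator must be 'sampling' or 'exact'")

    return AttributionResult(
        values=values,
        base_values=base_values,
        explained_class=cls,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, dtype=float),
        model_kind=kind,
        estimator=estimator,
        n_samples=n_samples,
    )


def _sampling_shapley(scores, bg, x, cls, n_samples, rng):
    """Permutation-sampling estimate for one spectrum.

    Each permutation walks from one background spectrum to ``x`` one band at a
    time; the score increments are the marginal contributions. Background rows
    are cycled (in shuffled order) so the average start score equals the mean
    background score whenever ``n_samples`` is a multiple of the background
    size, making local accuracy exact; otherwise the residual is the sampling
    error of the start scores.
    """
    p = x.size
    m = bg.shape[0]
    bg_order = rng.permutation(m)
    phi = np.zeros(p)
    start_scores = np.empty(n_samples)
    for s in range(n_samples):
        b = bg[bg_order[s % m]]
        perm = rng.permutation(p)
        # states[0] = background, states[t] = background with perm[:t] set to x
        states = np.tile(b, (p + 1, 1))
        mask = np.zeros(p, dtype=bool)
        for t, j in enumerate(perm):
            mask[j] = True
            states[t + 1, mask] = x[mask]
        f = scores(states)[:, cls]
        start_scores[s] = f[0]
        phi[perm] += np.diff(f)
    return phi / n_samples, float(start_scores.mean())


def _exact_shapley(scores, bg, Xe, cls):
    """Exact Shapley values by enumerating all coalitions of bands."""
    n, p = Xe.shape
    m = bg.shape[0]
    n_masks = 1 << p
    masks = np.arange(n_masks)
    sizes = np.array([bin(s).count("1") for s in masks])
    bits = ((masks[:, None] >> np.arange(p)) & 1).astype(bool)  # (n_masks, p)

    fact = np.array([math.factorial(i) for i in range(p + 1)], dtype=float)
    # Shapley kernel weight for adding j to S with |S| = s
    w = fact[: p] * fact[p - 1 :: -1][: p] / fact[p]  # w[s] = s!(p-1-s)!/p!

    values = np.empty((n, p))
    for i in range(n):
        # v(S): mean over background of f(x_S, b_~S)
        X_states = np.where(bits[:, None, :], Xe[i][None, None, :], bg[None, :, :])
        f = scores(X_states.reshape(n_masks * m, p))[:, cls[i]].reshape(n_masks, m)
        v = f.mean(axis=1)
        for j in range(p):
            without = ~bits[:, j]
            S = masks[without]
            values[i, j] = np.sum(w[sizes[S]] * (v[S | (1 << j)] - v[S]))
    return values


def summarize_importance(attr: AttributionResult, k: int = 10) -> ImportanceSummary:
    """Mean |attribution| per band across samples, with the top-k ranking."""
    vals = np.asarray(attr.values)
    if vals.size == 0:
        raise ValueError("empty attribution matrix")
    mean_abs = np.abs(vals.reshape(-1, attr.n_bands)).mean(axis=0)
    if k > attr.n_bands:
        warnings.warn(f"k={k} exceeds {attr.n_bands} bands; clipped")
        k = attr.n_bands
    # descending mean_abs, ties toward lower band index (shorter wavelength)
    order = np.lexsort((np.arange(attr.n_bands), -mean_abs))
    return ImportanceSummary(mean_abs=mean_abs, top_k=order[:k].tolist(), wavelengths=attr.wavelengths)


def band_window_enrichment(
    summary: ImportanceSummary,
    windows: list[tuple[float, float]],
    wavelengths: np.ndarray | None = None,
) -> dict:
    """Fraction of top-k wavelengths inside the union of nm windows, with the
    uniform-selection baseline (fraction of all bands inside the union)."""
    if not windows:
        raise ValueError("windows must be non-empty")
    wl = summary.wavelengths if wavelengths is None else np.asarray(wavelengths)
    if wl is None:
        raise ValueError("a wavelength axis is required")

    def inside(w):
        return any(lo <= w <= hi for lo, hi in windows)

    in_top = [inside(wl[j]) for j in summary.top_k]
    baseline = float(np.mean([inside(w) for w in wl]))
    return {
        "fraction_in_windows": float(np.mean(in_top)),
        "uniform_baseline": baseline,
        "k": len(summary.top_k),
        "windows": [tuple(map(float, w)) for w in windows],
    }
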