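"""Feature-wavelength selection: SPA, CARS, UVE and IVISSA.

All four selectors operate on a (n_samples, n_bands) training matrix and
return a :class:`SelectionResult` with sorted unique band indices, per-band
diagnostics, and a per-iteration trace. CARS, UVE and IVISSA share one inner
model (:class:`PLSCore`, partial least squares on one-hot class indicators)
and one inner criterion (stratified k-fold RMSECV of the one-hot response,
with the argmax misclassification rate recorded alongside), the chemometric
lineage these methods come from.

Selection should be run on the training partition only; leaking the held-out
boxes into band choice inflates test accuracy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SelectionResult",
    "PLSCore",
    "spa",
    "cars",
    "uve",
    "ivissa",
    "reduction_percentage",
    "RankError",
]


class RankError(ValueError):
    """Requested more bands than the matrix rank supports."""


@dataclass
class SelectionResult:
    """Outcome of one selector run."""

    selected_idx: np.ndarray
    scores: np.ndarray
    trace: list
    method_name: str
    seed: int | None
    n_bands: int

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.selected_idx, dtype=int))
        if idx.size and (idx[0] < 0 or idx[-1] >= self.n_bands):
            raise ValueError("selected indices out of range")
        self.selected_idx = idx
        self.scores = np.asarray(self.scores, dtype=float)

    @property
    def n_selected(self) -> int:
        return int(self.selected_idx.size)

    def mask_string(self) -> str:
        """0/1 string of length n_bands for quick diffing of band masks."""
        mask = np.zeros(self.n_bands, dtype=int)
        mask[self.selected_idx] = 1
        return "".join(map(str, mask))

    def selected_wavelengths(self, wavelengths: np.ndarray) -> np.ndarray:
        return np.asarray(wavelengths)[self.selected_idx]

    def to_json(self, path, wavelengths: np.ndarray | None = None) -> None:
        payload = {
            "method": self.method_name,
            "seed": self.seed,
            "n_bands": self.n_bands,
            "selected_idx": self.selected_idx.tolist(),
            "reduction_percent": reduction_percentage(self.n_selected, self.n_bands),
            "scores": self.scores.tolist(),
            "mask": self.mask_string(),
        }
        if wavelengths is not None:
            payload["selected_wavelengths_nm"] = [
                round(float(w), 2) for w in self.selected_wavelengths(wavelengths)
            ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def reduction_percentage(n_selected: int, n_total: int) -> float:
    """Dimensionality reduction achieved by a selection, as a percentage.

    ``100 * (1 - n_selected / n_total)`` reported to two decimals; e.g. keeping
    15 of 224 bands reduces dimensionality by 93.30%.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_selected <= n_total:
        raise ValueError("n_selected must lie in [0, n_total]")
    return round(100.0 * (1.0 - n_selected / n_total), 2)


# --------------------------------------------------------------------- PLS core


def one_hot(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class labels -> (indicator matrix, ordered class array)."""
    classes, inv = np.unique(np.asarray(y), return_inverse=True)
    Y = np.zeros((len(inv), classes.size))
    Y[np.arange(len(inv)), inv] = 1.0
    return Y, classes


class PLSCore:
    """Partial least squares on one-hot class indicators (PLS2).

    The shared inner model of CARS/UVE/IVISSA. A single continuous response is
    also accepted, in which case the model reduces to ordinary PLS regression.
    """

    def __init__(self, n_components: int = 10):
        self.n_components = n_components
        self._pls: PLSRegression | None = None
        self.classes_: np.ndarray | None = None

    @staticmethod
    def _cap_components(requested: int, n_samples: int, n_features: int) -> int:
        return max(1, min(requested, n_samples - 1, n_features))

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PLSCore":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if y.ndim == 1 and not np.issubdtype(y.dtype, np.floating):
            Y, self.classes_ = one_hot(y)
        else:
            Y = y.reshape(len(y), -1).astype(float)
            self.classes_ = None
        k = self._cap_components(self.n_components, *X.shape)
        self._pls = PLSRegression(n_components=k, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # y residual can become constant
            self._pls.fit(X, Y)
        return self

    @property
    def coefficients(self) -> np.ndarray:
        """(n_features, n_targets) regression weights."""
        coef = self._pls.coef_
        # sklearn >= 1.1 stores (n_targets, n_features)
        return coef.T if coef.shape[0] != self._pls.x_weights_.shape[0] else coef

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self._pls.predict(np.asarray(X, dtype=float))

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision(X)
        if self.classes_ is None:
            return scores
        return self.classes_[np.argmax(scores, axis=1)]


def _cv_scores(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    n_components: int = 10,
) -> tuple[float, float]:
    """Stratified k-fold PLS-DA scores: (RMSECV of the one-hot response,
    misclassification rate of the argmax rule).

    RMSECV is the selection criterion — it is continuous, so band subsets are
    rarely tied; the misclassification rate is recorded for diagnostics.
    """
    y = np.asarray(y)
    Y, classes = one_hot(y)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    sq, errs = [], []
    for tr, te in skf.split(X, y):
        model = PLSCore(n_components).fit(X[tr], y[tr])
        pred = model.decision(X[te])
        sq.append(np.mean((pred - Y[te]) ** 2))
        errs.append(np.mean(classes[np.argmax(pred, axis=1)] != y[te]))
    return float(np.sqrt(np.mean(sq))), float(np.mean(errs))


# -------------------------------------------------------------------------- SPA


def _spa_chain(Xc: np.ndarray, start: int, n_select: int) -> tuple[list[int], list[float]]:
    """Greedy successive-projection chain from one start column."""
    R = Xc.copy()
    selected = [start]
    norms = [float(np.linalg.norm(R[:, start]))]
    scale = np.linalg.norm(Xc, axis=0).max()
    for _ in range(n_select - 1):
        v = R[:, selected[-1]]
        nv = v @ v
        if nv <= (1e-12 * scale) ** 2:
            raise RankError("matrix rank exhausted before n_select bands")
        R = R - np.outer(v, (v @ R) / nv)  # project all columns off v
        cand = np.linalg.norm(R, axis=0)
        cand[selected] = -1.0
        j = int(np.argmax(cand))
        if cand[j] <= 1e-12 * scale:
            raise RankError("matrix rank exhausted before n_select bands")
        selected.append(j)
        norms.append(float(cand[j]))
    return selected, norms


def spa(
    X: np.ndarray,
    n_select: int,
    start_band: int | None = None,
    y: np.ndarray | None = None,
    n_folds: int = 5,
    seed: int = 0,
    n_components: int = 10,
    candidate_starts: np.ndarray | None = None,
) -> SelectionResult:
    """Successive Projections Algorithm.

    At each step the band whose column has the largest norm after orthogonal
    projection onto the complement of the already-selected columns is added,
    minimising collinearity in the chosen subset. When labels ``y`` are given
    and no ``start_band`` is fixed, one chain is grown from every candidate
    start and the chain with the lowest inner-CV classification error wins;
    without labels the start with the largest column norm is used.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= n_select <= p:
        raise ValueError("n_select must lie in [1, n_bands]")
    Xc = X  # projections act on the raw columns; center upstream if desired

    if start_band is not None:
        starts = [int(start_band)]
    elif y is None:
        starts = [int(np.argmax(np.linalg.norm(Xc, axis=0)))]
    else:
        starts = list(map(int, candidate_starts)) if candidate_starts is not None else list(range(p))

    trace = []
    best = None
    for s in starts:
        chain, norms = _spa_chain(Xc, s, n_select)
        if y is not None and len(starts) > 1:
            rmsecv, err = _cv_scores(X[:, chain], y, n_folds, seed, n_components)
        else:
            rmsecv = err = 0.0
        trace.append({"start": s, "retained": len(chain), "rmsecv": rmsecv, "cv_error": err})
        if best is None or rmsecv < best[0]:
            best = (rmsecv, chain, norms)
    _, chain, norms = best
    scores = np.zeros(p)
    scores[chain] = norms
    return SelectionResult(np.array(chain), scores, trace, "SPA", seed, p)


# ------------------------------------------------------------------------- CARS


def cars(
    X: np.ndarray,
    y: np.ndarray,
    n_runs: int = 50,
    n_folds: int = 5,
    seed: int = 0,
    n_components: int = 10,
    sample_frac: float = 0.8,
) -> SelectionResult:
    """Competitive Adaptive Reweighted Sampling.

    Each Monte-Carlo run fits the PLS core on a random subset of samples,
    weighs bands by the absolute regression coefficients, retains the top
    fraction given by an exponentially decreasing function (all bands at run
    1, a floor of 2 bands at the final run), then draws the next working set
    by weight (adaptive reweighted sampling, without replacement so the
    retained count follows the schedule exactly). The run whose retained set
    has the lowest inner RMSECV is returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if np.unique(y).size < 2:
        raise ValueError("need >= 2 classes")
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    rng = np.random.default_rng([seed, 211])

    # EDF schedule r_i = a * exp(-k i), fixed by r_1 = 1 and r_N = 2/p
    i = np.arange(1, n_runs + 1)
    a = (p / 2.0) ** (1.0 / (n_runs - 1))
    k = np.log(p / 2.0) / (n_runs - 1)
    ratios = a * np.exp(-k * i)

    retained = np.arange(p)
    trace = []
    results = []
    mean_weights = np.zeros(p)
    for run, r in enumerate(ratios, start=1):
        sub = rng.choice(n, size=max(2, int(round(sample_frac * n))), replace=False)
        model = PLSCore(n_components).fit(X[np.ix_(sub, retained)], y[sub])
        w = np.abs(model.coefficients).sum(axis=1)
        mean_weights[retained] += w / n_runs
        n_keep = int(np.clip(round(r * p), 2, retained.size))
        if run == 1:
            keep = retained  # r_1 = 1: keep everything
        else:
            # EDF: top n_keep by weight; ARS: weighted draw without replacement
            order = np.argsort(w)[::-1][:n_keep]
            pool, pw = retained[order], w[order] + 1e-12
            take = min(n_keep, pool.size)
            keep = pool if take == pool.size else rng.choice(
                pool, size=take, replace=False, p=pw / pw.sum()
            )
        retained = np.sort(keep)
        rmsecv, err = _cv_scores(X[:, retained], y, n_folds, seed, n_components)
        trace.append({"run": run, "retained": retained.size, "rmsecv": rmsecv, "cv_error": err})
        results.append(retained)

    rmse = np.array([t["rmsecv"] for t in trace])
    # exact RMSECV ties (rare) resolve toward the later run / smaller set
    best = len(rmse) - 1 - int(np.argmin(rmse[::-1]))
    return SelectionResult(results[best], mean_weights, trace, "CARS", seed, p)


# -------------------------------------------------------------------------- UVE


def uve(
    X: np.ndarray,
    y: np.ndarray,
    n_noise: int | None = None,
    seed: int = 0,
    n_components: int = 10,
    n_splits: int | None = None,
) -> SelectionResult:
    """Uninformative Variable Elimination.

    Noise columns (uniform, scaled far below the data) are appended, the PLS
    core is refit over resampling splits (leave-one-out for small n, random
    80% subsets otherwise), and each column gets a reliability
    ``c_j = mean(b_j) / SD(b_j)`` over the splits (max over classes). Real
    bands whose |reliability| exceeds the largest noise-column reliability are
    kept; noise columns are never returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if np.unique(y).size < 2:
        raise ValueError("need >= 2 classes")
    n_noise = p if n_noise is None else int(n_noise)
    rng = np.random.default_rng([seed, 307])

    scale = X.std() * 1e-5
    noise = rng.uniform(0.0, 1.0, size=(n, n_noise)) * scale
    Xa = np.hstack([X, noise])

    if n_splits is None:
        n_splits = n if n <= 120 else 50
    coefs = []
    for s in range(n_splits):
        if n_splits == n:  # leave-one-out
            keep = np.delete(np.arange(n), s)
        else:
            keep = rng.choice(n, size=max(2, int(round(0.8 * n))), replace=False)
        if np.unique(y[keep]).size < 2:
            continue
        model = PLSCore(n_components).fit(Xa[keep], y[keep])
        coefs.append(model.coefficients)
    B = np.stack(coefs)  # (splits, p + n_noise, n_targets)
    sd = B.std(axis=0, ddof=1)
    zero_sd = sd == 0
    if zero_sd.any():
        warnings.warn(
            f"{int(zero_sd.sum())} coefficient(s) constant across splits; "
            "reliability set to 0"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(zero_sd, 0.0, B.mean(axis=0) / np.where(zero_sd, 1.0, sd))
    reliability = np.abs(c).max(axis=1)  # max over classes
    cutoff = reliability[p:].max() if n_noise else 0.0
    selected = np.nonzero(reliability[:p] > cutoff)[0]
    trace = [{"retained": int(selected.size), "cutoff": float(cutoff), "n_splits": len(coefs)}]
    return SelectionResult(selected, reliability[:p], trace, "UVE", seed, p)


# ----------------------------------------------------------------------- IVISSA


def ivissa(
    X: np.ndarray,
    y: np.ndarray,
    n_iterations: int = 10,
    n_submodels: int = 30,
    interval_width: int = 8,
    best_frac: float = 0.2,
    n_folds: int = 5,
    seed: int = 0,
    n_components: int = 10,
) -> SelectionResult:
    """Interval-weighted iterative space shrinkage.

    Bands are grouped into contiguous intervals (the last may be shorter,
    never dropped). Each iteration draws random interval subsets with
    inclusion probabilities equal to the current interval weights, scores each
    subset by inner-CV error of the PLS core, and resets each weight to the
    interval's frequency among the best fraction of submodels, shrinking the
    sampling space. Returned bands are the union of intervals with final
    weight above 0.5. This is an interval-weighted shrinkage approximation of
    the published IVISSA family.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    rng = np.random.default_rng([seed, 401])
    edges = list(range(0, p, interval_width)) + [p]
    intervals = [np.arange(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])]
    m = len(intervals)
    weights = np.full(m, 0.5)
    trace = []

    for it in range(n_iterations):
        n_best = max(1, int(round(best_frac * n_submodels)))
        members, errs = [], []
        for _ in range(n_submodels):
            inc = rng.random(m) < weights
            if not inc.any():
                inc[int(np.argmax(weights))] = True
            bands = np.concatenate([intervals[k] for k in np.nonzero(inc)[0]])
            errs.append(_cv_scores(X[:, bands], y, n_folds, seed, n_components)[0])
            members.append(inc)
        order = np.argsort(errs, kind="stable")[:n_best]
        weights = np.stack([members[j] for j in order]).mean(axis=0)
        trace.append(
            {
                "iteration": it + 1,
                "weights": weights.tolist(),
                "best_error": float(errs[order[0]]),
                "retained": int(sum(intervals[k].size for k in np.nonzero(weights > 0.5)[0])),
            }
        )

    if n_iterations == 0:
        selected = np.arange(p)
    else:
        chosen = np.nonzero(weights > 0.5)[0]
        if chosen.size == 0:
            chosen = np.array([int(np.argmax(weights))])
        selected = np.concatenate([intervals[k] for k in chosen])
    scores = np.zeros(p)
    for k, itv in enumerate(intervals):
        scores[itv] = weights[k] if n_iterations else 1.0
    return SelectionResult(selected, scores, trace, "IVISSA", seed, p)
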