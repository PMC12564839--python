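"""Row-wise spectral preprocessing: SG smoothing, baseline correction, SNV,
detrending, and first derivative.

Each function maps a (n_samples, n_bands) matrix to a matrix of the same shape
and never introduces non-finite values on finite input. All operate per
spectrum (per row) and are stateless: nothing is learned from training data,
so the same transform applies to train and test without leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "PreprocessConfig",
    "snv",
    "savitzky_golay",
    "baseline_correct",
    "detrend",
    "first_derivative",
    "apply_preprocess",
    "PREPROCESS_METHODS",
    "DegenerateSpectrumError",
    "PreprocessConfigError",
]

PREPROCESS_METHODS = ("RAW", "SG", "BC", "SNV", "DT", "FD")


class DegenerateSpectrumError(ValueError):
    """A spectrum is constant where a nonzero spread is required."""


class PreprocessConfigError(ValueError):
    """Invalid preprocessing parameters."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Method switch plus the tunables of each preprocessor.

    ``sg_window``/``sg_polyorder`` parameterize Savitzky-Golay smoothing,
    ``dt_order`` the detrending polynomial, ``fd_gap`` the band gap of the
    finite-difference derivative.
    """

    method: str = "SNV"
    sg_window: int = 11
    sg_polyorder: int = 2
    dt_order: int = 2
    fd_gap: int = 1

    def __post_init__(self) -> None:
        if self.method not in PREPROCESS_METHODS:
            raise PreprocessConfigError(
                f"method must be one of {PREPROCESS_METHODS}, got {self.method!r}"
            )
        if self.sg_window % 2 == 0 or self.sg_window < 3:
            raise PreprocessConfigError("sg_window must be odd and >= 3")
        if self.sg_polyorder >= self.sg_window:
            raise PreprocessConfigError("sg_polyorder must be < sg_window")
        if self.fd_gap < 1:
            raise PreprocessConfigError("fd_gap must be >= 1")
        if self.dt_order < 1:
            raise PreprocessConfigError("dt_order must be >= 1")


def _as_matrix(spectra: np.ndarray) -> np.ndarray:
    X = np.asarray(spectra, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise ValueError("spectra must be 1-D or 2-D")
    return X


def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard Normal Variate: per spectrum, subtract the mean and divide by
    the sample standard deviation (divisor n-1).

    Removes per-spectrum multiplicative gain and additive offset exactly:
    ``snv(a*x + b) == snv(x)`` for any ``a > 0``.
    """
    X = _as_matrix(spectra)
    sd = X.std(axis=1, ddof=1)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise DegenerateSpectrumError(
            f"constant spectra (zero SD) at row indices {bad.tolist()}"
        )
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def savitzky_golay(spectra: np.ndarray, window: int = 11, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing: local least-squares polynomial fit per row.

    Edges are handled by fitting the polynomial on the truncated window
    (scipy's ``mode='interp'``). A spectrum that is globally a polynomial of
    degree <= ``polyorder`` passes through unchanged.
    """
    X = _as_matrix(spectra)
    if window % 2 == 0 or window < 3:
        raise PreprocessConfigError("window must be odd and >= 3")
    if polyorder >= window:
        raise PreprocessConfigError("polyorder must be < window")
    if window > X.shape[1]:
        raise PreprocessConfigError("window exceeds the number of bands")
    return savgol_filter(X, window_length=window, polyorder=polyorder, axis=1, mode="interp")


def baseline_correct(spectra: np.ndarray) -> np.ndarray:
    """Remove a linear baseline per spectrum, then shift the minimum to 0.

    The baseline is the least-squares straight line through the spectrum; the
    residual is shifted so every corrected row has minimum exactly 0. The map
    annihilates any added linear drift (``bc(x + a + b*t) == bc(x)``), is
    idempotent, and leaves an already-corrected, trend-free spectrum unchanged.
    """
    X = _as_matrix(spectra)
    n = X.shape[1]
    t = np.arange(n, dtype=float)
    basis = np.vstack([np.ones(n), t]).T  # (n, 2)
    coef, *_ = np.linalg.lstsq(basis, X.T, rcond=None)
    resid = X - (basis @ coef).T
    return resid - resid.min(axis=1, keepdims=True)


def detrend(spectra: np.ndarray, order: int = 2, wavelengths: np.ndarray | None = None) -> np.ndarray:
    """Subtract a least-squares polynomial of the given order per spectrum.

    Fitting is over the wavelength axis when supplied (band index otherwise,
    which gives the same residual for equally spaced grids). A spectrum that
    is itself a polynomial of degree <= ``order`` maps to zeros.
    """
    X = _as_matrix(spectra)
    n = X.shape[1]
    if order < 1:
        raise PreprocessConfigError("order must be >= 1")
    if order >= n:
        raise PreprocessConfigError("order must be < number of bands")
    t = np.asarray(wavelengths, dtype=float) if wavelengths is not None else np.arange(n, dtype=float)
    # scale to [-1, 1] for conditioning
    u = 2.0 * (t - t[0]) / (t[-1] - t[0]) - 1.0
    basis = np.polynomial.polynomial.polyvander(u, order)  # (n, order+1)
    coef, *_ = np.linalg.lstsq(basis, X.T, rcond=None)
    return X - (basis @ coef).T


def first_derivative(
    spectra: np.ndarray, gap: int = 1, wavelengths: np.ndarray | None = None
) -> np.ndarray:
    """Central-difference first derivative with respect to wavelength.

    Interior band ``i`` gets ``(x[i+gap] - x[i-gap]) / (wl[i+gap] - wl[i-gap])``;
    the first/last ``gap`` bands use one-sided differences so the band count is
    preserved. Without a wavelength axis, unit band spacing is assumed.
    """
    X = _as_matrix(spectra)
    n = X.shape[1]
    if gap < 1 or gap >= n:
        raise PreprocessConfigError("gap must satisfy 1 <= gap < n_bands")
    wl = np.asarray(wavelengths, dtype=float) if wavelengths is not None else np.arange(n, dtype=float)
    out = np.empty_like(X)
    # interior: central differences over 2*gap bands
    out[:, gap:-gap or None] = (X[:, 2 * gap :] - X[:, : n - 2 * gap]) / (
        wl[2 * gap :] - wl[: n - 2 * gap]
    )
    # edges: one-sided differences over gap bands
    out[:, :gap] = (X[:, gap : 2 * gap] - X[:, :gap]) / (wl[gap : 2 * gap] - wl[:gap])
    out[:, n - gap :] = (X[:, n - gap :] - X[:, n - 2 * gap : n - gap]) / (
        wl[n - gap :] - wl[n - 2 * gap : n - gap]
    )
    return out


def apply_preprocess(
    spectra: np.ndarray,
    config: PreprocessConfig | str = "SNV",
    wavelengths: np.ndarray | None = None,
) -> np.ndarray:
    """Dispatch on ``config.method``; ``RAW`` is the identity."""
    cfg = PreprocessConfig(method=config) if isinstance(config, str) else config
    X = _as_matrix(spectra)
    if cfg.method == "RAW":
        return X.copy()
    if cfg.method == "SG":
        return savitzky_golay(X, cfg.sg_window, cfg.sg_polyorder)
    if cfg.method == "BC":
        return baseline_correct(X)
    if cfg.method == "SNV":
        return snv(X)
    if cfg.method == "DT":
        return detrend(X, cfg.dt_order, wavelengths)
    if cfg.method == "FD":
        return first_derivative(X, cfg.fd_gap, wavelengths)
    raise PreprocessConfigError(f"unknown method {cfg.method!r}")
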