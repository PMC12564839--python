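"""Core in-memory containers shared across the pipeline.

A *sample* throughout the package is one mean ROI spectrum: the average of all
pixel spectra inside the centered square region of one grid cell of one storage
box. Samples carry provenance (``box_id``, ``cell_id``) so that train/test
splits can be made at the box level, never splitting an acquisition unit.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "SpectralDataset",
    "HypercubeScene",
    "default_wavelengths",
]

#: Default sensor layout: 224 contiguous bands spanning 397-1003 nm (VNIR).
N_BANDS_DEFAULT = 224
WL_MIN_DEFAULT = 397.0
WL_MAX_DEFAULT = 1003.0


def default_wavelengths() -> np.ndarray:
    """224 equally spaced band centers from 397 to 1003 nm."""
    return np.linspace(WL_MIN_DEFAULT, WL_MAX_DEFAULT, N_BANDS_DEFAULT)


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nanometres."""

    values: np.ndarray = field(default_factory=default_wavelengths)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("wavelength grid must be a 1-D array with >= 2 bands")
        if not np.all(np.diff(vals) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "values", vals)

    @property
    def n_bands(self) -> int:
        return self.values.size

    def __len__(self) -> int:
        return self.values.size


@dataclass
class SpectralDataset:
    """Samples x wavelengths reflectance matrix with labels and provenance.

    Attributes
    ----------
    reflectance : (n_samples, n_bands) float array
    wavelengths : WavelengthGrid
    labels : (n_samples,) array of variety identifiers (strings)
    box_id : (n_samples,) int array, globally unique box index
    cell_id : (n_samples,) int array, cell index within the box
    """

    reflectance: np.ndarray
    wavelengths: WavelengthGrid
    labels: np.ndarray
    box_id: np.ndarray
    cell_id: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.reflectance, dtype=float)
        if X.ndim != 2:
            raise ValueError("reflectance must be 2-D (samples x bands)")
        if not isinstance(self.wavelengths, WavelengthGrid):
            self.wavelengths = WavelengthGrid(np.asarray(self.wavelengths))
        if X.shape[1] != self.wavelengths.n_bands:
            raise ValueError(
                f"band mismatch: matrix has {X.shape[1]} columns, "
                f"grid has {self.wavelengths.n_bands}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("reflectance contains non-finite values")
        n = X.shape[0]
        self.reflectance = X
        self.labels = np.asarray(self.labels)
        self.box_id = np.asarray(self.box_id, dtype=int)
        self.cell_id = np.asarray(self.cell_id, dtype=int)
        for name in ("labels", "box_id", "cell_id"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have one entry per sample")
        pairs = set(zip(self.box_id.tolist(), self.cell_id.tolist()))
        if len(pairs) != n:
            raise ValueError("(box_id, cell_id) pairs must be unique")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    def subset(self, idx: np.ndarray) -> "SpectralDataset":
        idx = np.asarray(idx)
        return SpectralDataset(
            self.reflectance[idx],
            self.wavelengths,
            self.labels[idx],
            self.box_id[idx],
            self.cell_id[idx],
        )

    def with_reflectance(self, X: np.ndarray) -> "SpectralDataset":
        """Same provenance, new spectra (e.g. after preprocessing)."""
        return SpectralDataset(X, self.wavelengths, self.labels, self.box_id, self.cell_id)

    # ---------------------------------------------------------------- I/O
    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{w:.2f}" for w in self.wavelengths.values]
        df = pd.DataFrame(self.reflectance, columns=cols)
        df.insert(0, "label", self.labels)
        df.insert(0, "cell_id", self.cell_id)
        df.insert(0, "box_id", self.box_id)
        return df

    def to_csv(self, path) -> None:
        """One row per sample: box_id, cell_id, label, then reflectance columns.

        The header row carries the wavelengths in nm (two decimals).
        """
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectralDataset":
        df = pd.read_csv(path)
        meta = ["box_id", "cell_id", "label"]
        wl = np.array([float(c) for c in df.columns if c not in meta])
        return cls(
            df.drop(columns=meta).to_numpy(dtype=float),
            WavelengthGrid(wl),
            df["label"].to_numpy(dtype=str),
            df["box_id"].to_numpy(),
            df["cell_id"].to_numpy(),
        )

    def to_npz(self, path) -> None:
        """Compact binary container (numpy .npz) of the same fields."""
        np.savez_compressed(
            path,
            reflectance=self.reflectance,
            wavelengths=self.wavelengths.values,
            labels=self.labels.astype(str),
            box_id=self.box_id,
            cell_id=self.cell_id,
        )

    @classmethod
    def from_npz(cls, path) -> "SpectralDataset":
        z = np.load(path, allow_pickle=False)
        return cls(
            z["reflectance"],
            WavelengthGrid(z["wavelengths"]),
            z["labels"],
            z["box_id"],
            z["cell_id"],
        )


@dataclass
class HypercubeScene:
    """A raw line-scan acquisition of one storage box plus its reference frames.

    ``raw``, ``white`` and ``dark`` are (rows, cols, bands) intensity cubes:
    the sample image, the standard white reference board and the closed-shutter
    dark frame. ``grid_layout`` lists the grid-cell rectangles as
    ``(row0, col0, height, width)`` in 0-based, row-major, half-open pixel
    coordinates.
    """

    raw: np.ndarray
    white: np.ndarray
    dark: np.ndarray
    grid_layout: list[tuple[int, int, int, int]]
    wavelengths: WavelengthGrid
    box_id: int = 0
    label: str | None = None

    def __post_init__(self) -> None:
        shapes = {np.asarray(c).shape for c in (self.raw, self.white, self.dark)}
        if len(shapes) != 1:
            raise ValueError("raw, white and dark cubes must share a shape")
        if np.asarray(self.raw).ndim != 3:
            raise ValueError("cubes must be 3-D (rows, cols, bands)")
        if not isinstance(self.wavelengths, WavelengthGrid):
            self.wavelengths = WavelengthGrid(np.asarray(self.wavelengths))
        if np.asarray(self.raw).shape[2] != self.wavelengths.n_bands:
            raise ValueError("cube band count does not match wavelength grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(np.asarray(self.raw).shape)
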