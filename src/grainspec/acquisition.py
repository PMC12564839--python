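"""Radiometric calibration, ROI spectrum extraction, and the box-level split.

Pixel-coordinate convention used everywhere in this package: 0-based,
row-major, rectangles ``(row0, col0, height, width)`` half-open (the pixel at
``row0 + height`` is outside the rectangle).
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np

from .datasets import HypercubeScene, SpectralDataset, WavelengthGrid

__all__ = [
    "DataSplit",
    "radiometric_correct",
    "extract_roi_means",
    "box_level_split",
    "write_envi",
    "read_envi",
    "write_scene",
    "read_scene",
    "DegenerateReferenceError",
    "GeometryError",
    "SplitError",
]


class DegenerateReferenceError(ValueError):
    """White and dark reference coincide on some voxels."""


class GeometryError(ValueError):
    """ROI or grid rectangle extends outside the cube."""


class SplitError(ValueError):
    """A variety has too few boxes for the requested held-out count."""


@dataclass(frozen=True)
class DataSplit:
    """Box-disjoint train/test partition of a :class:`SpectralDataset`."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    held_out_boxes: dict[str, list[int]]
    seed: int | None = None

    def __post_init__(self) -> None:
        tr = set(np.asarray(self.train_idx).tolist())
        te = set(np.asarray(self.test_idx).tolist())
        if tr & te:
            raise ValueError("train and test indices overlap")


def radiometric_correct(scene: HypercubeScene) -> np.ndarray:
    """Reflectance cube ``(raw - dark) / (white - dark)``.

    The standard flat-field correction with a white reference board and a
    closed-shutter dark frame: it maps the dark level to 0 and the white board
    to 1 at every pixel and band, removing uneven illumination.
    """
    raw = np.asarray(scene.raw, dtype=float)
    white = np.asarray(scene.white, dtype=float)
    dark = np.asarray(scene.dark, dtype=float)
    denom = white - dark
    n_bad = int(np.count_nonzero(denom == 0))
    if n_bad:
        raise DegenerateReferenceError(
            f"white equals dark on {n_bad} voxel(s); cannot calibrate"
        )
    out = (raw - dark) / denom
    if not np.all(np.isfinite(out)):
        raise DegenerateReferenceError("calibration produced non-finite values")
    return out


def _roi_rect(cell_rect: tuple[int, int, int, int], roi_size: int) -> tuple[int, int]:
    r0, c0, h, w = cell_rect
    if roi_size > h or roi_size > w:
        raise GeometryError(
            f"ROI of {roi_size} px does not fit in cell of {h}x{w} px"
        )
    return r0 + (h - roi_size) // 2, c0 + (w - roi_size) // 2


def extract_roi_means(
    cube: np.ndarray,
    grid_layout: list[tuple[int, int, int, int]],
    roi_size: int,
    wavelengths: WavelengthGrid | np.ndarray | None = None,
    box_id: int = 0,
    label: str = "unknown",
) -> SpectralDataset:
    """One mean spectrum per grid cell from a centered square ROI.

    For each cell rectangle, a ``roi_size x roi_size`` square is centered
    inside the cell and the per-band mean over its pixels becomes that cell's
    representative spectrum. Cell order follows ``grid_layout``.
    """
    cube = np.asarray(cube, dtype=float)
    if cube.ndim != 3:
        raise GeometryError("cube must be 3-D (rows, cols, bands)")
    rows_px, cols_px, n_bands = cube.shape
    wl = wavelengths if wavelengths is not None else WavelengthGrid(np.arange(n_bands, dtype=float))
    spectra = []
    for rect in grid_layout:
        rr, cc = _roi_rect(rect, roi_size)
        if rr < 0 or cc < 0 or rr + roi_size > rows_px or cc + roi_size > cols_px:
            raise GeometryError(f"ROI of cell {rect} lies outside the cube")
        spectra.append(cube[rr : rr + roi_size, cc : cc + roi_size].reshape(-1, n_bands).mean(axis=0))
    n = len(spectra)
    return SpectralDataset(
        np.asarray(spectra),
        wl if isinstance(wl, WavelengthGrid) else WavelengthGrid(np.asarray(wl)),
        np.asarray([label] * n),
        np.full(n, box_id, dtype=int),
        np.arange(n, dtype=int),
    )


def extract_scene(scene: HypercubeScene, roi_size: int) -> SpectralDataset:
    """Calibrate a scene and extract its ROI mean spectra in one step."""
    cube = radiometric_correct(scene)
    return extract_roi_means(
        cube,
        scene.grid_layout,
        roi_size,
        scene.wavelengths,
        box_id=scene.box_id,
        label=scene.label or "unknown",
    )


def box_level_split(
    dataset: SpectralDataset, test_boxes_per_class: int = 2, seed: int = 0
) -> DataSplit:
    """Hold out whole storage boxes per variety as the independent test set.

    For each variety, ``test_boxes_per_class`` of its boxes are chosen
    uniformly at random; every spectrum from a held-out box goes to test, so
    no acquisition unit is shared between the two sides.
    """
    if test_boxes_per_class < 0:
        raise SplitError("test_boxes_per_class must be >= 0")
    rng = np.random.default_rng(seed)
    held: dict[str, list[int]] = {}
    for label in np.unique(dataset.labels):
        boxes = np.unique(dataset.box_id[dataset.labels == label])
        if boxes.size < test_boxes_per_class:
            raise SplitError(
                f"variety {label!r} has {boxes.size} boxes, "
                f"fewer than test_boxes_per_class={test_boxes_per_class}"
            )
        held[str(label)] = sorted(rng.choice(boxes, size=test_boxes_per_class, replace=False).tolist())
    held_set = {b for bs in held.values() for b in bs}
    mask = np.isin(dataset.box_id, list(held_set))
    return DataSplit(
        train_idx=np.nonzero(~mask)[0],
        test_idx=np.nonzero(mask)[0],
        held_out_boxes=held,
        seed=seed,
    )


# --------------------------------------------------------------------------
# ENVI-style cube I/O: flat binary file + human-readable text header. The
# header declares shape, data type, interleave (BSQ/BIL/BIP) and the
# wavelength list, which is all downstream stages need.
# --------------------------------------------------------------------------

_DTYPE_TO_ENVI = {"uint8": 1, "int16": 2, "int32": 3, "float32": 4, "float64": 5, "uint16": 12}
_ENVI_TO_DTYPE = {v: k for k, v in _DTYPE_TO_ENVI.items()}


def write_envi(path_base: str, cube: np.ndarray, wavelengths: np.ndarray, interleave: str = "bsq") -> None:
    """Write ``<path_base>.raw`` (flat binary) and ``<path_base>.hdr`` (text).

    ``cube`` is (lines, samples, bands) in memory (BIP order); the file is laid
    out per ``interleave``.
    """
    cube = np.ascontiguousarray(cube)
    lines, samples, bands = cube.shape
    interleave = interleave.lower()
    if interleave == "bip":
        data = cube
    elif interleave == "bil":
        data = cube.transpose(0, 2, 1)  # line, band, sample
    elif interleave == "bsq":
        data = cube.transpose(2, 0, 1)  # band, line, sample
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    dtype_code = _DTYPE_TO_ENVI[cube.dtype.name]
    np.ascontiguousarray(data).tofile(path_base + ".raw")
    wl_txt = ", ".join(f"{w:.4f}" for w in np.asarray(wavelengths))
    header = (
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {dtype_code}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        "wavelength = {\n " + wl_txt + " }\n"
    )
    with open(path_base + ".hdr", "w") as fh:
        fh.write(header)


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    # brace-delimited values may span lines
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" in line:
            key, val = line.split("=", 1)
            fields[key.strip().lower()] = val.strip()
    return fields


def read_envi(path_base: str) -> tuple[np.ndarray, np.ndarray]:
    """Read a cube written by :func:`write_envi`; returns (cube, wavelengths).

    The cube is returned as (lines, samples, bands) regardless of the file's
    interleave.
    """
    with open(path_base + ".hdr") as fh:
        fields = _parse_envi_header(fh.read())
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    dtype = np.dtype(_ENVI_TO_DTYPE[int(fields["data type"])])
    interleave = fields.get("interleave", "bsq").lower()
    data = np.fromfile(path_base + ".raw", dtype=dtype)
    if interleave == "bip":
        cube = data.reshape(lines, samples, bands)
    elif interleave == "bil":
        cube = data.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bsq":
        cube = data.reshape(bands, lines, samples).transpose(1, 2, 0)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    wl_match = re.search(r"wavelength\s*=\s*\{([^}]*)\}", open(path_base + ".hdr").read(), re.S)
    wl = (
        np.array([float(t) for t in wl_match.group(1).replace("\n", " ").split(",") if t.strip()])
        if wl_match
        else np.arange(bands, dtype=float)
    )
    return np.ascontiguousarray(cube), wl


def write_scene(dir_path: str, scene: HypercubeScene, interleave: str = "bsq") -> None:
    """Write raw/white/dark cubes plus a grid-layout sidecar under a directory."""
    os.makedirs(dir_path, exist_ok=True)
    wl = scene.wavelengths.values
    write_envi(os.path.join(dir_path, "raw"), np.asarray(scene.raw), wl, interleave)
    write_envi(os.path.join(dir_path, "white"), np.asarray(scene.white), wl, interleave)
    write_envi(os.path.join(dir_path, "dark"), np.asarray(scene.dark), wl, interleave)
    with open(os.path.join(dir_path, "layout.txt"), "w") as fh:
        fh.write(f"box_id = {scene.box_id}\n")
        fh.write(f"label = {scene.label or 'unknown'}\n")
        for rect in scene.grid_layout:
            fh.write("rect = " + " ".join(str(int(v)) for v in rect) + "\n")


def read_scene(dir_path: str) -> HypercubeScene:
    raw, wl = read_envi(os.path.join(dir_path, "raw"))
    white, _ = read_envi(os.path.join(dir_path, "white"))
    dark, _ = read_envi(os.path.join(dir_path, "dark"))
    layout, box_id, label = [], 0, None
    with open(os.path.join(dir_path, "layout.txt")) as fh:
        for line in fh:
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key == "box_id":
                box_id = int(val)
            elif key == "label":
                label = val
            elif key == "rect":
                layout.append(tuple(int(t) for t in val.split()))
    return HypercubeScene(raw, white, dark, layout, WavelengthGrid(wl), box_id=box_id, label=label)
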