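import numpy as np
import pytest

from grainspec.datasets import WavelengthGrid
from grainspec.synthetic_data import (
    NOISELESS,
    NoiseModel,
    SceneDesign,
    make_templates,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def wavelengths() -> WavelengthGrid:
    return WavelengthGrid()


@pytest.fixture(scope="session")
def small_design() -> SceneDesign:
    """Tiny geometry so scene cubes stay a few MB."""
    return SceneDesign(n_varieties=3, boxes_per_variety=3, grid_rows=2, grid_cols=3,
                       roi_size=6, cell_margin=2)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    templates = make_templates(small_design.n_varieties, seed=7)
    return simulate_dataset(templates, small_design, NoiseModel(), seed=7)


def planted_matrix(n=240, p=40, informative=(5, 11, 19, 27, 33), n_classes=3,
                   effect=1.0, noise=0.05, seed=0):
    """Classification matrix where only ``informative`` columns carry signal.

    Every informative column separates the classes strongly: class means are
    redrawn until their spread (max - min) reaches ``effect``, which with the
    default ``noise`` puts at least 20 sigma between the extreme classes. All
    other columns are pure noise. This is the planted-recovery benchmark for
    the selectors.
    """
    rng = np.random.default_rng(seed)
    y = np.repeat(np.arange(n_classes), n // n_classes)
    X = rng.normal(0, noise, size=(y.size, p))
    means = np.empty((n_classes, len(informative)))
    for k in range(len(informative)):
        col = rng.normal(0, effect, size=n_classes)
        while col.max() - col.min() < effect:
            col = rng.normal(0, effect, size=n_classes)
        means[:, k] = col
    for c in range(n_classes):
        X[np.ix_(y == c, list(informative))] += means[c]
    return X, y.astype(str)
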