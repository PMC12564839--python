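"""Simulate the full sampling design and hold out whole boxes for testing.

Generates 13 variety templates, simulates one mean spectrum per grid cell of
every storage box (13 varieties x 10 boxes x 4x7 cells), and splits at the box
level so no acquisition unit appears on both sides.
"""

import numpy as np

from grainspec.acquisition import box_level_split
from grainspec.synthetic_data import SceneDesign, make_templates, simulate_dataset

templates = make_templates(n_varieties=13, seed=1)
dataset = simulate_dataset(templates, SceneDesign(), seed=1)
split = box_level_split(dataset, test_boxes_per_class=2, seed=1)

print(f"spectra: {dataset.n_samples} x {dataset.n_bands} bands "
      f"({dataset.wavelengths.values[0]:.0f}-{dataset.wavelengths.values[-1]:.0f} nm)")
print(f"train/test: {len(split.train_idx)} / {len(split.test_idx)}")
print(f"held-out boxes for V01: {split.held_out_boxes['V01']}")
# 3640 spectra in total; 2912 train and 728 test once 2 boxes per variety are
# reserved. Reflectance stays in [0, 1.2] with the water dips visible near
# 930/970 nm:
wl = dataset.wavelengths.values
mean_spec = dataset.reflectance.mean(axis=0)
print(f"mean reflectance at 550 nm: {mean_spec[np.argmin(np.abs(wl - 550))]:.3f}")
print(f"mean reflectance at 930 nm: {mean_spec[np.argmin(np.abs(wl - 930))]:.3f}")
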