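"""Generator contracts: determinism, sample-count arithmetic, planted signal."""

import numpy as np
import pytest

from grainspec.acquisition import extract_roi_means, radiometric_correct
from grainspec.datasets import WavelengthGrid
from grainspec.synthetic_data import (
    NOISELESS,
    SIGNAL_WINDOWS_NM,
    InvalidDesignError,
    NoiseModel,
    SceneDesign,
    make_templates,
    simulate_dataset,
    simulate_scene,
)


class TestMakeTemplates:
    def test_zero_separation_gives_identical_templates(self, wavelengths):
        tpls = make_templates(5, separation_scale=0.0, seed=3)
        curves = [t.reflectance(wavelengths) for t in tpls]
        for c in curves[1:]:
            np.testing.assert_array_equal(c, curves[0])

    def test_seeded_determinism(self, wavelengths):
        a = make_templates(13, seed=1)
        b = make_templates(13, seed=1)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.reflectance(wavelengths), tb.reflectance(wavelengths))
        c = make_templates(13, seed=2)
        assert any(
            not np.array_equal(ta.reflectance(wavelengths), tc.reflectance(wavelengths))
            for ta, tc in zip(a, c)
        )

    def test_template_range_and_smoothness(self, wavelengths):
        for tpl in make_templates(13, seed=5):
            r = tpl.reflectance(wavelengths)
            assert r.min() >= 0.0 and r.max() <= 1.05
            # band-to-band second difference stays small for a smooth curve
            assert np.abs(np.diff(r, 2)).max() < 5e-3

    def test_invalid_design_rejected(self):
        with pytest.raises(InvalidDesignError):
            make_templates(1)
        with pytest.raises(InvalidDesignError):
            make_templates(5, separation_scale=-0.1)

    def test_between_class_variance_concentrates_in_planted_windows(self, wavelengths):
        """Monte-Carlo: per-band between-class variance is higher inside
        580-700 nm than in the quiet 700-880 nm stretch."""
        tpls = make_templates(13, separation_scale=0.05, seed=11)
        design = SceneDesign(n_varieties=13, boxes_per_variety=8, grid_rows=1, grid_cols=10)
        ds = simulate_dataset(tpls, design, NOISELESS, seed=11)  # ~1000 spectra
        wl = wavelengths.values
        grand = ds.reflectance.mean(axis=0)
        bcv = np.zeros(len(wl))
        for lab in np.unique(ds.labels):
            mu = ds.reflectance[ds.labels == lab].mean(axis=0)
            bcv += (mu - grand) ** 2
        in_win = (wl >= 580) & (wl <= 700)
        out_win = (wl > 700) & (wl < 880)
        assert bcv[in_win].mean() > bcv[out_win].mean()

    def test_planted_window_f_statistic_exceeds_outside(self, wavelengths):
        """Planted-signal contract: per-band between/within F averaged inside
        the signal windows exceeds the average outside."""
        tpls = make_templates(13, seed=2)
        ds = simulate_dataset(tpls, SceneDesign(boxes_per_variety=2), seed=2)
        wl = wavelengths.values
        X, y = ds.reflectance, ds.labels
        grand = X.mean(axis=0)
        between = np.zeros(len(wl))
        within = np.zeros(len(wl))
        for lab in np.unique(y):
            sub = X[y == lab]
            between += len(sub) * (sub.mean(axis=0) - grand) ** 2
            within += ((sub - sub.mean(axis=0)) ** 2).sum(axis=0)
        F = between / np.maximum(within, 1e-30)
        in_win = np.zeros(len(wl), bool)
        for lo, hi in SIGNAL_WINDOWS_NM:
            in_win |= (wl >= lo) & (wl <= hi)
        assert F[in_win].mean() > F[~in_win].mean()


class TestSimulateDataset:
    def test_default_design_sample_count(self):
        tpls = make_templates(13, seed=0)
        ds = simulate_dataset(tpls, SceneDesign(), seed=0)
        assert ds.n_samples == 3640  # 13 varieties x 10 boxes x 28 cells
        assert ds.n_bands == 224

    @pytest.mark.parametrize("design", [
        SceneDesign(n_varieties=2, boxes_per_variety=3, grid_rows=2, grid_cols=2),
        SceneDesign(n_varieties=4, boxes_per_variety=1, grid_rows=1, grid_cols=5),
    ])
    def test_sample_count_arithmetic(self, design):
        tpls = make_templates(design.n_varieties, seed=1)
        ds = simulate_dataset(tpls, design, seed=1)
        assert ds.n_samples == design.n_samples
        assert len(np.unique(ds.box_id)) == design.n_varieties * design.boxes_per_variety

    def test_zero_noise_reproduces_templates(self, small_design, wavelengths):
        tpls = make_templates(small_design.n_varieties, seed=4)
        ds = simulate_dataset(tpls, small_design, NOISELESS, seed=4)
        curves = {t.variety_id: t.reflectance(wavelengths) for t in tpls}
        for i in range(ds.n_samples):
            np.testing.assert_allclose(ds.reflectance[i], curves[str(ds.labels[i])], atol=1e-12)

    def test_seeded_determinism(self, small_design):
        tpls = make_templates(small_design.n_varieties, seed=9)
        a = simulate_dataset(tpls, small_design, seed=9)
        b = simulate_dataset(tpls, small_design, seed=9)
        np.testing.assert_array_equal(a.reflectance, b.reflectance)

    def test_mean_of_replicates_approaches_template(self, wavelengths):
        """Law of large numbers: 200 pure-noise replicates of one template
        average to the template within 3 standard errors per band."""
        tpl = make_templates(2, separation_scale=0.0, seed=0)[0]
        sd = 0.01
        design = SceneDesign(n_varieties=1, boxes_per_variety=10, grid_rows=4, grid_cols=5)
        ds = simulate_dataset([tpl], design, NoiseModel(0, 0, sd, 0), seed=12)
        assert ds.n_samples == 200
        se = sd / np.sqrt(ds.n_samples)
        resid = np.abs(ds.reflectance.mean(axis=0) - tpl.reflectance(wavelengths))
        assert (resid <= 3 * se).mean() > 0.99  # allow a single 3-sigma band
        assert resid.max() <= 5 * se


class TestDatasetIO:
    def test_csv_roundtrip(self, small_dataset, tmp_path):
        path = tmp_path / "ds.csv"
        small_dataset.to_csv(path)
        back = type(small_dataset).from_csv(path)
        np.testing.assert_allclose(back.reflectance, small_dataset.reflectance, atol=1e-9)
        np.testing.assert_array_equal(back.labels.astype(str), small_dataset.labels.astype(str))
        np.testing.assert_array_equal(back.box_id, small_dataset.box_id)
        np.testing.assert_allclose(back.wavelengths.values, small_dataset.wavelengths.values,
                                   atol=5e-3)  # header carries 2-decimal nm

    def test_npz_roundtrip(self, small_dataset, tmp_path):
        path = tmp_path / "ds.npz"
        small_dataset.to_npz(path)
        back = type(small_dataset).from_npz(path)
        np.testing.assert_array_equal(back.reflectance, small_dataset.reflectance)
        np.testing.assert_array_equal(back.cell_id, small_dataset.cell_id)


class TestSimulateScene:
    def test_zero_noise_roundtrip_recovers_template(self, small_design, wavelengths):
        tpl = make_templates(2, seed=3)[0]
        scene = simulate_scene(tpl, small_design, NOISELESS, seed=3)
        ds = extract_roi_means(
            radiometric_correct(scene), scene.grid_layout, small_design.roi_size, wavelengths
        )
        expected = tpl.reflectance(wavelengths)
        for row in ds.reflectance:
            np.testing.assert_allclose(row, expected, atol=1e-12)

    def test_white_exceeds_dark_everywhere(self, small_design):
        tpl = make_templates(2, seed=1)[0]
        scene = simulate_scene(tpl, small_design, seed=1)
        assert np.all(scene.white > scene.dark)

    def test_roi_larger_than_cell_rejected(self):
        tpl = make_templates(2, seed=1)[0]
        bad = SceneDesign(roi_size=20, cell_size=10)
        with pytest.raises(InvalidDesignError):
            simulate_scene(tpl, bad, seed=0)

    def test_two_path_consistency_with_dataset(self, wavelengths):
        """Scene -> calibrate -> ROI means agrees with simulate_dataset for the
        same seed and provenance, up to averaged pixel noise."""
        design = SceneDesign(n_varieties=1, boxes_per_variety=1, grid_rows=2,
                             grid_cols=3, roi_size=6, cell_margin=2)
        noise = NoiseModel(scatter_mult_sd=0.05, scatter_add_sd=0.01,
                           pixel_noise_sd=0.01, baseline_drift_amp=0.01)
        tpl = make_templates(2, seed=21)[0]
        ds_direct = simulate_dataset([tpl], design, noise, seed=21)
        scene = simulate_scene(tpl, design, noise, seed=21, box_id=0)
        ds_scene = extract_roi_means(
            radiometric_correct(scene), scene.grid_layout, design.roi_size, wavelengths
        )
        # scatter parameters identical; both sides add independent pixel noise:
        # direct per band (sd), scene averaged over the ROI (sd/roi)
        tol = 4 * noise.pixel_noise_sd
        assert np.abs(ds_scene.reflectance - ds_direct.reflectance).max() < tol
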