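"""Baseline removal, TIC normalization, peak detection, alignment."""

import numpy as np
import pandas as pd
import pytest

from msiregio import MsiDataset, MzAxis, align_peaks, detect_peaks, \
    remove_baseline, tic_normalize
from msiregio.preprocess import (FeatureMatrix, ModeError, PeakInterval,
                                 mean_spectrum, remove_baseline_dataset)
from msiregio.synth import make_layout, make_peak_panel, simulate_section


def gaussian(x, mu, sigma, area):
    return area / (sigma * np.sqrt(2 * np.pi)) * \
        np.exp(-0.5 * ((x - mu) / sigma) ** 2)


class TestBaseline:
    def test_flat_spectrum_removed_entirely(self):
        assert np.all(remove_baseline(np.full(200, 5.0), width=20) == 0.0)

    def test_peak_on_ramp_recovers_area(self):
        x = np.arange(400, dtype=float)
        peak = gaussian(x, 200.0, 3.0, area=500.0)
        ramp = 0.05 * x + 10.0
        cleaned = remove_baseline(peak + ramp, width=20)
        assert cleaned.sum() == pytest.approx(peak.sum(), rel=0.05)
        assert np.argmax(cleaned) == np.argmax(peak)

    def test_near_idempotent_on_baseline_free_spectrum(self):
        x = np.arange(400, dtype=float)
        spec = gaussian(x, 120.0, 3.0, 300.0) + gaussian(x, 250.0, 3.0, 200.0)
        once = remove_baseline(spec, width=20)
        assert abs(once.sum() - spec.sum()) <= 0.01 * spec.sum()

    def test_centroid_dataset_is_mode_error(self):
        ds = MsiDataset(pixels=[(0, 0)], axis=MzAxis([1000.0], mode="centroid"),
                        intensities=np.array([[1.0]]))
        with pytest.raises(ModeError):
            remove_baseline_dataset(ds)

    def test_width_validated(self):
        with pytest.raises(ValueError):
            remove_baseline(np.ones(10), width=0)


class TestTicNormalize:
    def _two_spectra(self, tics):
        vals = np.array([[t / 2, t / 2] for t in tics], dtype=float)
        return MsiDataset(pixels=[(i, 0) for i in range(len(tics))],
                          axis=MzAxis([1000.0, 1100.0]), intensities=vals)

    def test_definition_forces_common_mean_tic(self):
        out = tic_normalize(self._two_spectra([10.0, 30.0]))
        np.testing.assert_allclose(out.tic(), [20.0, 20.0])

    def test_equal_tics_unchanged(self):
        ds = self._two_spectra([20.0, 20.0])
        out = tic_normalize(ds)
        np.testing.assert_allclose(out.intensities, ds.intensities)

    def test_relative_intensities_preserved(self):
        ds = MsiDataset(pixels=[(0, 0), (1, 0)], axis=MzAxis([1000.0, 1100.0]),
                        intensities=np.array([[1.0, 3.0], [8.0, 2.0]]))
        out = tic_normalize(ds)
        np.testing.assert_allclose(out.intensities[0, 1] / out.intensities[0, 0],
                                   3.0)

    def test_synthetic_tic_variation_removed(self):
        layout = make_layout(30, 30, 0.25, seed=2)
        panel = make_peak_panel(n_peaks=10, n_region_markers=2,
                                n_treatment_markers=1, seed=2)
        ds, _ = simulate_section(layout, panel, group="control",
                                 tic_cv=0.5, noise_sd=0.0, seed=2)
        out = tic_normalize(ds)
        tissue = layout.tissue_mask.ravel()
        tics = out.tic()[tissue]
        assert tics.std() / tics.mean() < 1e-9

    def test_sub_floor_spectra_flagged_not_amplified(self, caplog):
        ds = MsiDataset(pixels=[(0, 0), (1, 0), (2, 0)],
                        axis=MzAxis([1000.0]),
                        intensities=np.array([[100.0], [120.0], [0.001]]))
        with caplog.at_level("WARNING"):
            out = tic_normalize(ds)
        assert out.intensities[2, 0] == 0.001   # untouched, not scaled up
        assert out.metadata["sub_floor_spectra"] == 1
        assert "flagged" in caplog.text

    def test_all_empty_is_an_error(self):
        ds = MsiDataset(pixels=[(0, 0)], axis=MzAxis([1000.0]),
                        intensities=np.zeros((1, 1)))
        with pytest.raises(ValueError, match="empty"):
            tic_normalize(ds)

    def test_joint_normalization_shares_target_across_sections(self):
        a = self._two_spectra([10.0, 10.0])
        b = self._two_spectra([30.0, 30.0])
        b.section_id = "b"
        out_a, out_b = tic_normalize([a, b])
        np.testing.assert_allclose(out_a.tic(), [20.0, 20.0])
        np.testing.assert_allclose(out_b.tic(), [20.0, 20.0])

    def test_pixel_permutation_commutes(self, rng):
        ds = self._two_spectra([10.0, 25.0, 40.0, 55.0])
        perm = rng.permutation(4)
        shuffled = MsiDataset(pixels=ds.pixels[perm], axis=ds.axis,
                              intensities=ds.intensities[perm])
        np.testing.assert_allclose(tic_normalize(shuffled).intensities,
                                   tic_normalize(ds).intensities[perm])


class TestDetectPeaks:
    def _profile_axis(self):
        return MzAxis(np.arange(900.0, 1400.0, 0.1), mode="profile")

    def test_two_gaussians_found_at_their_centers(self):
        axis = self._profile_axis()
        spec = gaussian(axis.values, 1000.0, 0.2, 50.0) + \
            gaussian(axis.values, 1200.0, 0.2, 50.0)
        centers = detect_peaks(spec, axis, smoothing="medium", snr_floor=3.0)
        assert len(centers) == 2
        assert abs(centers[0] - 1000.0) <= 0.1
        assert abs(centers[1] - 1200.0) <= 0.1

    def test_pure_noise_rarely_yields_peaks(self):
        axis = self._profile_axis()
        hits = 0
        for seed in range(40):
            noise = np.abs(np.random.default_rng(seed).normal(0, 1.0,
                                                              len(axis)))
            if len(detect_peaks(noise, axis, snr_floor=3.0)) > 0:
                hits += 1
        assert hits <= 2  # >= 95% clean replicates

    def test_centroid_passthrough(self):
        axis = MzAxis([1000.0, 1100.0, 1200.0], mode="centroid")
        centers = detect_peaks(np.array([5.0, 0.0, 2.0]), axis)
        np.testing.assert_allclose(centers, [1000.0, 1200.0])

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks(np.array([]), MzAxis([1000.0], mode="centroid"))

    def test_unknown_smoothing_strength_rejected(self):
        axis = self._profile_axis()
        with pytest.raises(ValueError, match="smoothing"):
            detect_peaks(np.ones(len(axis)), axis, smoothing="extreme")


def _single_pixel_dataset(axis_values, intensities, mode, section="s",
                          pixel=(0, 0)):
    return MsiDataset(pixels=[pixel], axis=MzAxis(axis_values, mode=mode),
                      intensities=np.asarray([intensities], dtype=float),
                      section_id=section)


class TestAlignPeaks:
    def test_single_profile_point_value_passes_through(self):
        ds = _single_pixel_dataset([999.0, 1000.0, 1001.0], [0, 7.0, 0],
                                   mode="profile")
        fm = align_peaks(ds, [1000.0], halfwidth=0.156)
        assert fm.values[0, 0] == 7.0  # one point in interval, mean = itself

    def test_profile_mean_over_points_in_interval(self):
        axis = [999.95, 1000.0, 1000.05]
        ds = _single_pixel_dataset(axis, [3.0, 6.0, 9.0], mode="profile")
        fm = align_peaks(ds, [1000.0], halfwidth=0.156)
        assert fm.values[0, 0] == pytest.approx(6.0)

    def test_nearby_peaks_land_in_one_column(self):
        a = _single_pixel_dataset([1000.00, 1000.10], [5.0, 0.0],
                                  mode="centroid", section="a")
        b = _single_pixel_dataset([1000.00, 1000.10], [0.0, 4.0],
                                  mode="centroid", section="b")
        fm = align_peaks([a, b], [1000.05], halfwidth=0.156)
        assert fm.values.shape == (2, 1)
        assert fm.values[0, 0] == 5.0 and fm.values[1, 0] == 4.0

    def test_peak_outside_halfwidth_excluded(self):
        ds = _single_pixel_dataset([1000.30], [9.0], mode="centroid")
        fm = align_peaks(ds, [1000.0], halfwidth=0.156)
        assert fm.values[0, 0] == 0.0  # 0.30 > 0.156

    def test_overlapping_intervals_merge_to_stronger_center(self, caplog):
        ds = _single_pixel_dataset([1000.0, 1000.2], [10.0, 1.0],
                                   mode="centroid")
        with caplog.at_level("INFO"):
            fm = align_peaks(ds, [1000.0, 1000.2], halfwidth=0.156)
        assert len(fm.columns) == 1
        assert fm.columns[0].center == 1000.0
        assert "merging" in caplog.text

    def test_dataset_order_does_not_change_values(self):
        a = _single_pixel_dataset([1000.0], [5.0], "centroid", section="a")
        b = _single_pixel_dataset([1000.0], [2.0], "centroid", section="b")
        fm_ab = align_peaks([a, b], [1000.0])
        fm_ba = align_peaks([b, a], [1000.0])
        va = dict(zip(fm_ab.pixel_table["section"], fm_ab.values[:, 0]))
        vb = dict(zip(fm_ba.pixel_table["section"], fm_ba.values[:, 0]))
        assert va == vb


class TestFeatureMatrix:
    def _fm(self):
        pt = pd.DataFrame({"pixel_x": [0, 1], "pixel_y": [0, 0],
                           "section": "s", "group": "control"})
        return FeatureMatrix(values=np.array([[1.0, 2.0], [3.0, 4.0]]),
                             columns=[PeakInterval(1000.0, 0.156),
                                      PeakInterval(1100.0, 0.156)],
                             pixel_table=pt)

    def test_csv_round_trip(self, tmp_path):
        fm = self._fm()
        path = fm.to_csv(tmp_path / "features.csv")
        back = FeatureMatrix.from_csv(path)
        np.testing.assert_allclose(back.values, fm.values)
        assert [c.center for c in back.columns] == [1000.0, 1100.0]

    def test_overlapping_columns_rejected(self):
        pt = pd.DataFrame({"pixel_x": [0], "pixel_y": [0],
                           "section": "s", "group": "g"})
        with pytest.raises(ValueError, match="overlap"):
            FeatureMatrix(values=np.ones((1, 2)),
                          columns=[PeakInterval(1000.0, 0.2),
                                   PeakInterval(1000.1, 0.2)],
                          pixel_table=pt)

    def test_column_count_stable_across_seeds(self):
        """Paper-scale synthetic settings must not produce seed-dependent
        peak-count explosions (column count within +-10% across seeds)."""
        counts = []
        for seed in (1, 2, 3):
            layout = make_layout(24, 24, 0.25, seed=seed)
            panel = make_peak_panel(n_peaks=30, n_region_markers=4,
                                    n_treatment_markers=2, seed=seed)
            ds, _ = simulate_section(layout, panel, group="control", seed=seed)
            norm = tic_normalize(ds)
            mspec, ref = mean_spectrum(norm)
            centers = detect_peaks(mspec, ref.axis)
            counts.append(len(align_peaks(norm, centers).columns))
        assert max(counts) <= 1.1 * min(counts)
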