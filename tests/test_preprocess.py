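import numpy as np
import pytest

from seedcascade import (
    HyperCube,
    PreprocessConfig,
    SpectrumSet,
    airpls_baseline,
    calibrate_reflectance,
    extract_mean_spectra,
    make_band_axis,
    moving_average,
    segment_seeds,
    simulate_hypercube,
    trim_bands,
)
from seedcascade.errors import (
    DegenerateCalibrationError,
    EmptySelectionError,
    InvalidArgumentError,
)
from seedcascade.preprocess import SeedMask


@pytest.fixture()
def nir_axis():
    return make_band_axis("nir", 8, 900.0, 1700.0)


def _cube(values, axis):
    return HyperCube(values, axis)


class TestCalibration:
    def test_reference_endpoints_and_midpoint(self, nir_axis):
        rng = np.random.default_rng(0)
        dark = _cube(rng.uniform(0.0, 0.2, (4, 5, 8)), nir_axis)
        white = _cube(dark.values + rng.uniform(0.5, 1.0, (4, 5, 8)), nir_axis)
        assert np.allclose(calibrate_reflectance(white, dark, white).values, 1.0)
        assert np.allclose(calibrate_reflectance(dark, dark, white).values, 0.0)
        mid = _cube((dark.values + white.values) / 2, nir_axis)
        assert np.allclose(calibrate_reflectance(mid, dark, white).values, 0.5)

    def test_degenerate_reference_names_position(self, nir_axis):
        dark = _cube(np.zeros((2, 2, 8)), nir_axis)
        white = _cube(np.ones((2, 2, 8)), nir_axis)
        white.values[1, 0, 3] = 0.0
        with pytest.raises(DegenerateCalibrationError, match=r"\(1, 0, 3\)"):
            calibrate_reflectance(dark, dark, white)

    def test_calibration_commutes_with_trimming(self, nir_axis):
        rng = np.random.default_rng(1)
        raw = _cube(rng.uniform(0.2, 0.8, (3, 3, 8)), nir_axis)
        dark = _cube(np.full((3, 3, 8), 0.1), nir_axis)
        white = _cube(np.full((3, 3, 8), 0.9), nir_axis)
        interval = (1000.0, 1500.0)
        cal = calibrate_reflectance(raw, dark, white)
        keep = np.flatnonzero(
            (nir_axis.values >= interval[0]) & (nir_axis.values <= interval[1])
        )
        a = cal.values[:, :, keep]
        b = calibrate_reflectance(
            _cube(raw.values[:, :, keep], nir_axis.subset(keep)),
            _cube(dark.values[:, :, keep], nir_axis.subset(keep)),
            _cube(white.values[:, :, keep], nir_axis.subset(keep)),
        ).values
        assert np.allclose(a, b)


class TestSegmentation:
    def test_recovers_planted_footprints_exactly(self, separable_set):
        cube, truth = simulate_hypercube(3, (60, 60), separable_set, rng_seed=7)
        cfg = PreprocessConfig(ref_band_value=1.0)
        mask = segment_seeds(cube, cfg)
        assert mask.n_seeds == 3
        # same partition: match each recovered label to the truth label it covers
        for lab in range(1, 4):
            fp = mask.labels == lab
            truth_labels = np.unique(truth[fp])
            assert truth_labels.size == 1
            assert np.array_equal(fp, truth == truth_labels[0])

    def test_constant_image_finds_nothing(self):
        axis = make_band_axis("thz", 4, 0.3, 2.0)
        cube = HyperCube(np.full((30, 30, 4), 0.7), axis)
        mask = segment_seeds(cube, PreprocessConfig(ref_band_value=1.0))
        assert mask.n_seeds == 0

    def test_reference_band_outside_axis_rejected(self, separable_set):
        cube, _ = simulate_hypercube(1, (30, 30), separable_set, rng_seed=1)
        with pytest.raises(InvalidArgumentError):
            segment_seeds(cube, PreprocessConfig(ref_band_value=99.0))

    def test_mask_label_contract(self):
        with pytest.raises(InvalidArgumentError):
            SeedMask(np.array([[0, 2], [0, 2]]), 2)  # label 1 missing


class TestExtractMeanSpectra:
    def test_matches_brute_force_mean(self, separable_set):
        rng = np.random.default_rng(3)
        axis = separable_set.band_axis
        values = rng.uniform(0, 1, (10, 10, len(axis)))
        labels = np.zeros((10, 10), dtype=int)
        pix = [(1, 1), (1, 2), (2, 1), (7, 8), (3, 3)]
        for r, c in pix:
            labels[r, c] = 1
        sset = extract_mean_spectra(HyperCube(values, axis), SeedMask(labels, 1))
        expected = np.mean([values[r, c] for r, c in pix], axis=0)
        assert np.allclose(sset.spectra[0], expected)

    def test_single_pixel_seed_passthrough(self, separable_set):
        axis = separable_set.band_axis
        values = np.random.default_rng(4).uniform(0, 1, (5, 5, len(axis)))
        labels = np.zeros((5, 5), dtype=int)
        labels[2, 3] = 1
        sset = extract_mean_spectra(HyperCube(values, axis), SeedMask(labels, 1))
        assert np.array_equal(sset.spectra[0], values[2, 3])


class TestMovingAverage:
    def _brute_force(self, row, window):
        half = window // 2
        out = np.empty_like(row)
        for i in range(len(row)):
            lo, hi = max(0, i - half), min(len(row), i + half + 1)
            out[i] = row[lo:hi].mean()
        return out

    def test_window_one_is_identity(self, separable_set):
        out = moving_average(separable_set, 1)
        assert np.allclose(out.spectra, separable_set.spectra)

    def test_constant_rows_unchanged(self):
        axis = make_band_axis("thz", 9, 0.3, 2.0)
        sset = SpectrumSet(np.full((2, 9), 0.4), axis, ["a", "a"])
        assert np.allclose(moving_average(sset, 5).spectra, 0.4)

    @pytest.mark.parametrize("window", [3, 5, 7])
    def test_matches_truncated_window_oracle(self, window):
        rng = np.random.default_rng(11)
        axis = make_band_axis("nir", 9, 900, 1700)
        rows = rng.uniform(0, 1, (6, 9))
        out = moving_average(SpectrumSet(rows, axis, ["x"] * 6), window)
        for i, row in enumerate(rows):
            assert np.allclose(out.spectra[i], self._brute_force(row, window))

    def test_never_extends_value_range(self):
        rng = np.random.default_rng(12)
        axis = make_band_axis("nir", 20, 900, 1700)
        rows = rng.uniform(0, 1, (4, 20))
        out = moving_average(SpectrumSet(rows, axis, ["x"] * 4), 5)
        assert out.spectra.min() >= rows.min() - 1e-12
        assert out.spectra.max() <= rows.max() + 1e-12

    def test_even_window_rejected(self, separable_set):
        with pytest.raises(InvalidArgumentError):
            moving_average(separable_set, 4)


class TestAirPLS:
    def test_zero_spectrum(self):
        baseline, corrected = airpls_baseline(np.zeros(40))
        assert np.allclose(baseline, 0)
        assert np.allclose(corrected, 0)

    def test_smooth_quadratic_fully_absorbed(self):
        t = np.arange(120)
        y = 0.2 + 0.0005 * (t - 50.0) ** 2
        _, corrected = airpls_baseline(y, 1.0, 15)
        assert np.abs(corrected).max() < 0.01 * (y.max() - y.min())

    def test_peak_and_drift_decomposition(self):
        from seedcascade.experiments import airpls_recovery_experiment

        res = airpls_recovery_experiment()
        assert res["rmse_over_amplitude"] < 0.05
        assert res["recovered_apexes"] == res["true_apexes"]

    def test_negative_residual_mass_decreases_with_iterations(self):
        t = np.arange(150)
        y = 0.3 + 0.4 * t / 149 + np.exp(-0.5 * ((t - 70) / 1.5) ** 2)
        masses = []
        for iters in (1, 3, 7, 15):
            _, corrected = airpls_baseline(y, 1.0, iters)
            masses.append(np.abs(corrected[corrected < 0]).sum())
        assert all(b <= a + 1e-9 for a, b in zip(masses, masses[1:]))

    def test_rejects_non_finite(self):
        with pytest.raises(InvalidArgumentError):
            airpls_baseline(np.array([1.0, np.nan, 2.0, 3.0]))


class TestTrimBands:
    def test_printed_nir_interval_keeps_200_bands(self):
        axis = make_band_axis("nir", 256, 874, 1734)
        sset = SpectrumSet(np.zeros((2, 256)), axis, ["a", "b"])
        out = trim_bands(sset, (958.0, 1630.0))
        assert out.n_bands == 200
        assert out.band_axis.values[0] >= 958.0
        assert out.band_axis.values[-1] <= 1630.0

    def test_full_interval_is_identity(self, separable_set):
        out = trim_bands(separable_set, (0.1, 3.0))
        assert out.n_bands == separable_set.n_bands

    def test_matches_membership_scan(self):
        axis = make_band_axis("nir", 10, 900, 1700)
        sset = SpectrumSet(np.zeros((1, 10)), axis, ["a"])
        lo, hi = 1000.0, 1500.0
        out = trim_bands(sset, (lo, hi))
        expected = [j for j, v in enumerate(axis.values) if lo <= v <= hi]
        assert np.allclose(out.band_axis.values, axis.values[expected])

    def test_empty_selection_raises(self, separable_set):
        with pytest.raises(EmptySelectionError):
            trim_bands(separable_set, (5.0, 6.0))
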