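"""Baseline correction, the 3-SD decision surface, and SG smoothing."""

import numpy as np
import pytest
from scipy.signal import savgol_coeffs

from ramanclass.dataset import SpectralDataset
from ramanclass.errors import InsufficientDataError, InvalidConfigError
from ramanclass.preprocess import (
    PreprocessConfig,
    background_correct,
    preprocess,
    remove_outliers,
    smooth,
    smooth_array,
)
from ramanclass.synthetic import PeakSpec, SyntheticConfig, generate_dataset


class TestBackgroundCorrect:
    def test_pure_cubic_baseline_removed(self):
        u = np.linspace(0, 1, 400)
        x = 5.0 - 3.0 * u + 2.0 * u**2 + 0.7 * u**3
        res = background_correct(x, order=3)
        assert np.max(np.abs(res)) < 1e-6 * np.ptp(x)

    def test_constant_maps_to_zero(self):
        res = background_correct(np.full(50, 7.0), order=0)
        assert np.allclose(res, 0.0, atol=1e-9)

    def test_peak_survives_baseline_subtraction(self):
        w = np.linspace(0, 3000, 1700)
        u = w / 3000
        baseline = 4.0 + 2.0 * u - 3.0 * u**2 + 1.5 * u**3
        peak = 2.0 / (1.0 + ((w - 1500) / 15.0) ** 2)
        res = background_correct(baseline + peak, order=3)
        j = np.argmin(np.abs(w - 1500))
        assert res[j] == pytest.approx(2.0, rel=0.05)

    def test_order_too_large_rejected(self):
        with pytest.raises(InvalidConfigError):
            background_correct(np.ones(4), order=4)


class TestRemoveOutliers:
    @staticmethod
    def _brute_force(ds, k):
        """Loop-based reference for the decision-surface filter."""
        removed = []
        for lab in (0, 1):
            idx = [i for i in range(ds.n_spectra) if ds.labels[i] == lab]
            block = ds.intensities[idx]
            mean = block.mean(axis=0)
            sd = block.std(axis=0)
            for i in idx:
                row = ds.intensities[i]
                if any(
                    row[j] > mean[j] + k * sd[j] or row[j] < mean[j] - k * sd[j]
                    for j in range(ds.n_points)
                ):
                    removed.append(i)
        return sorted(removed)

    def test_single_spiked_spectrum_removed(self, rng):
        X = rng.uniform(-1.7, 1.7, size=(201, 40))
        X[57, 13] += 10.0
        ds = SpectralDataset(np.arange(40, dtype=float), X, np.r_[np.ones(101, int), np.zeros(100, int)])
        kept, removed = remove_outliers(ds, k=3.0)
        assert removed.tolist() == [57]
        assert kept.n_spectra == 200

    def test_identical_spectra_none_removed(self):
        X = np.tile([1.0, 2.0, 3.0], (6, 1))
        ds = SpectralDataset([1.0, 2.0, 3.0], X, [0, 0, 0, 1, 1, 1])
        kept, removed = remove_outliers(ds, k=3.0)
        assert removed.size == 0 and kept.n_spectra == 6

    def test_infinite_band_removes_nothing(self, rng):
        X = rng.normal(size=(20, 15))
        ds = SpectralDataset(np.arange(15, dtype=float), X, np.arange(20) % 2)
        _, removed = remove_outliers(ds, k=np.inf)
        assert removed.size == 0

    def test_matches_brute_force_filter(self, rng):
        X = rng.normal(size=(120, 25))
        ds = SpectralDataset(np.arange(25, dtype=float), X, np.arange(120) % 2)
        for k in (1.5, 2.0, 3.0):
            _, removed = remove_outliers(ds, k=k)
            assert removed.tolist() == self._brute_force(ds, k)

    def test_tiny_group_rejected(self):
        ds = SpectralDataset([1.0, 2.0], [[0.0, 0.0], [1.0, 1.0]], [0, 1])
        with pytest.raises(InsufficientDataError):
            remove_outliers(ds)


class TestSmooth:
    def test_constant_spectrum_unchanged(self):
        x = np.full(120, 3.3)
        assert np.allclose(smooth_array(x, 21, 3), x, atol=1e-12)

    def test_linear_ramp_reproduced(self):
        x = np.linspace(0, 5, 200)
        assert np.allclose(smooth_array(x, 91, 3), x, atol=1e-9)

    def test_noise_variance_reduced_to_filter_factor(self, rng):
        # interior variance shrinks by the sum of squared convolution weights
        X = rng.normal(0, 1, size=(400, 301))
        Y = smooth_array(X, 91, 3)
        factor = float((savgol_coeffs(91, 3) ** 2).sum())
        interior = Y[:, 150]
        assert factor < 0.1
        assert interior.var() == pytest.approx(factor, rel=0.2)

    def test_even_window_error_suggests_odd(self):
        with pytest.raises(InvalidConfigError, match="91|89"):
            smooth_array(np.zeros(200), 90, 3)

    def test_commutes_with_global_constant(self, rng):
        x = rng.normal(size=150)
        assert np.allclose(
            smooth_array(x + 5.0, 31, 3), smooth_array(x, 31, 3) + 5.0, atol=1e-9
        )

    def test_dataset_smooth_preserves_shape_and_labels(self, rng):
        ds = SpectralDataset(np.arange(100, dtype=float), rng.normal(size=(4, 100)), [0, 1, 0, 1])
        out = smooth(ds, 31, 3)
        assert out.intensities.shape == (4, 100)
        assert np.array_equal(out.labels, ds.labels)


class TestPipelineOrder:
    def test_stage_order_recorded(self):
        cfg = SyntheticConfig(n_per_class=20, axis_points=200, seed=3)
        ds = generate_dataset(cfg)
        _, log = preprocess(ds, PreprocessConfig())
        assert log["stage_order"] == ["background", "outliers", "smooth"]

    def test_background_stage_skippable(self):
        cfg = SyntheticConfig(n_per_class=20, axis_points=200, seed=3)
        ds = generate_dataset(cfg)
        _, log = preprocess(ds, PreprocessConfig(apply_background=False))
        assert log["stage_order"] == ["outliers", "smooth"]

    def test_injected_outliers_are_filtered(self):
        cfg = SyntheticConfig(n_per_class=150, axis_points=300, seed=8, outlier_rate=0.03)
        ds = generate_dataset(cfg)
        injected = ds.metadata["outlier_rows"]
        assert len(injected) > 0
        _, log = preprocess(ds, PreprocessConfig())
        assert set(injected) <= set(log["removed_outliers"])

    def test_even_window_config_rejected(self):
        with pytest.raises(InvalidConfigError):
            PreprocessConfig(sg_window=90)
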