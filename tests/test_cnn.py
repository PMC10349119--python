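"""Structural, numerical and behavioral checks on the 1-D convolutional net."""

import numpy as np
import pytest

from ramanclass import cnn
from ramanclass.dataset import SpectralDataset, select_region
from ramanclass.errors import InsufficientDataError, InvalidConfigError
from ramanclass.linear import roc_auc


def oracle_lengths(L, n_blocks=3, kernel=3, pool=2):
    """Independent layer-by-layer length bookkeeping."""
    out = [L]
    for _ in range(n_blocks):
        L = L - (kernel - 1)
        if L < 1:
            return None
        out.append(L)
        L = L // pool
        if L < 1:
            return None
        out.append(L)
    return out


def oracle_params(L):
    lengths = oracle_lengths(L)
    conv1 = (3 * 1 + 1) * 64
    conv23 = 2 * (3 * 64 + 1) * 64
    dense1 = lengths[-1] * 64 * 16 + 16
    dense2 = 16 + 1
    return conv1 + conv23 + dense1 + dense2


class TestArchitecture:
    def test_lw_length_arithmetic(self):
        assert cnn.layer_lengths(221) == [221, 219, 109, 107, 53, 51, 25]

    def test_lw_parameter_count(self):
        # 256 + 12352 + 12352 + (1600*16+16) + 17
        assert cnn.parameter_count(221) == 50593

    def test_lengths_and_params_match_oracle_over_range(self):
        for L in range(30, 1201):
            assert cnn.layer_lengths(L) == oracle_lengths(L)
            assert cnn.parameter_count(L) == oracle_params(L)

    def test_too_short_input_names_minimum(self):
        min_len = cnn.min_input_length()
        with pytest.raises(InvalidConfigError, match=str(min_len)):
            cnn.build_cnn(min_len - 1)
        cnn.build_cnn(min_len)  # smallest valid length builds

    def test_model_parameter_arrays_match_count(self):
        net = cnn.build_cnn(221, seed=0)
        total = sum(v.size for v in net.params.values())
        assert total == 50593

    def test_untrained_output_in_open_unit_interval(self, rng):
        net = cnn.build_cnn(64, seed=1)
        p = net.predict_proba(rng.normal(size=(10, 64)))
        assert np.all((p > 0) & (p < 1))


class TestTraining:
    def test_seeded_determinism(self, rng):
        X = rng.normal(size=(40, 50))
        y = np.arange(40) % 2
        tc = cnn.TrainConfig(epochs=3, early_stopping=False)
        a = cnn.CNN1D(50, seed=7).fit(X, y, tc)
        b = cnn.CNN1D(50, seed=7).fit(X, y, tc)
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)

    def test_learns_separable_band(self, hw_effect_dataset):
        hw = select_region(hw_effect_dataset, "HW")
        net = cnn.CNN1D(hw.n_points, seed=0)
        net.fit(hw.intensities, hw.labels, cnn.TrainConfig(epochs=12, early_stopping=False))
        assert roc_auc(net.predict_proba(hw.intensities), hw.labels) >= 0.95
        assert len(net.loss_trace) == 12

    def test_single_class_rejected(self, rng):
        net = cnn.CNN1D(40, seed=0)
        with pytest.raises(InsufficientDataError):
            net.fit(rng.normal(size=(10, 40)), np.ones(10))


class TestGradients:
    def test_matches_central_finite_differences(self, rng):
        # float64 model; 5 spectra x 20 random positions, 1e-3 relative
        net = cnn.CNN1D(60, seed=3, dtype=np.float64)
        X = rng.normal(size=(30, 60))
        y = np.arange(30) % 2
        net.fit(X, y, cnn.TrainConfig(epochs=3, early_stopping=False))
        test = rng.normal(size=(5, 60))
        grads = net.input_gradient(test)
        eps = 1e-5
        for i in range(5):
            for j in rng.choice(60, size=20, replace=False):
                xp, xm = test[i].copy(), test[i].copy()
                xp[j] += eps
                xm[j] -= eps
                fd = (net.predict_proba(xp[None])[0] - net.predict_proba(xm[None])[0]) / (2 * eps)
                if abs(fd) > 1e-12:
                    assert grads[i, j] == pytest.approx(fd, rel=1e-3)

    def test_evaluation_deterministic(self, rng):
        net = cnn.CNN1D(50, seed=0)
        X = rng.normal(size=(8, 50))
        assert np.array_equal(net.predict_proba(X), net.predict_proba(X))
        assert np.array_equal(net.input_gradient(X), net.input_gradient(X))


class TestSaliency:
    def test_zero_weight_model_gives_tied_cdf_half(self, rng):
        net = cnn.CNN1D(60, seed=0)
        for k in net.params:
            net.params[k] = np.zeros_like(net.params[k])
        smap = cnn.vanilla_gradient_saliency(net, rng.normal(size=(6, 60)))
        assert np.allclose(smap.raw_gradients, 0.0)
        assert np.allclose(smap.cdf_values, 0.5)

    def test_cdf_values_uniform_in_unit_interval(self, rng):
        net = cnn.CNN1D(60, seed=2)
        X = rng.normal(size=(15, 60))
        net.fit(X, np.arange(15) % 2, cnn.TrainConfig(epochs=2, early_stopping=False))
        smap = cnn.vanilla_gradient_saliency(net, X)
        v = smap.cdf_values.ravel()
        assert v.min() >= 0.0 and v.max() <= 1.0
        assert v.mean() == pytest.approx(0.5, abs=1e-6)  # rank transform
        # pooled distribution is approximately uniform
        hist, _ = np.histogram(v, bins=4, range=(0, 1))
        assert np.allclose(hist / v.size, 0.25, atol=0.05)

    def test_summary_band_shapes(self, rng):
        net = cnn.CNN1D(60, seed=2)
        ds = SpectralDataset(np.arange(60, dtype=float), rng.normal(size=(9, 60)), np.arange(9) % 2)
        smap = cnn.vanilla_gradient_saliency(net, ds)
        assert smap.mean.shape == (60,)
        assert np.all(smap.lo95 <= smap.mean) and np.all(smap.mean <= smap.hi95)

    def test_empty_test_set_rejected(self):
        net = cnn.CNN1D(60, seed=0)
        with pytest.raises(InsufficientDataError):
            cnn.vanilla_gradient_saliency(net, np.empty((0, 60)))

    def test_per_wavenumber_cdf_variant(self, rng):
        net = cnn.CNN1D(60, seed=4)
        X = rng.normal(size=(12, 60))
        smap = cnn.vanilla_gradient_saliency(net, X, per_wavenumber_cdf=True)
        assert np.allclose(smap.cdf_values.mean(axis=0), 0.5, atol=1e-9)
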