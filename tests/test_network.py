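"""Tests for the two-layer convolutional network and feature encoding."""

import numpy as np
import pytest
import scipy.sparse as sp

from veinfeat.filterbank import FilterBankConfig, build_filter
from veinfeat.network import (
    LogGaborNet,
    binary_hash,
    blockwise_histogram,
    loggabor_conv,
)


def circular_conv_oracle(image, kernel):
    """Brute-force circular spatial-domain convolution (complex kernel)."""
    rows, cols = image.shape
    out = np.zeros((rows, cols), dtype=complex)
    for i in range(rows):
        for j in range(cols):
            acc = 0.0j
            for a in range(rows):
                for b in range(cols):
                    acc += image[a, b] * kernel[(i - a) % rows, (j - b) % cols]
            out[i, j] = acc
    return out


class TestLogGaborConv:
    def test_constant_image_maps_to_zero(self, small_config):
        filt = build_filter(small_config, 1, 0.0)
        out = loggabor_conv(np.full((8, 8), 3.0), filt)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_linearity(self, small_config):
        filt = build_filter(small_config, 2, np.pi / 4)
        rng = np.random.default_rng(0)
        img = rng.random((8, 8))
        np.testing.assert_allclose(loggabor_conv(2.5 * img, filt),
                                   2.5 * loggabor_conv(img, filt),
                                   atol=1e-12)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_spatial_domain_oracle(self, small_config, trial):
        """Frequency-domain filtering equals direct circular convolution
        with the filter's complex spatial kernel."""
        rng = np.random.default_rng(trial)
        img = rng.random((8, 8))
        filt = build_filter(small_config, 1 + trial % 2,
                            (trial % 4) * np.pi / 4)
        expected = np.real(circular_conv_oracle(img, filt.spatial_kernel()))
        np.testing.assert_allclose(loggabor_conv(img, filt), expected,
                                   atol=1e-8)

    def test_shape_mismatch_rejected(self, small_config):
        filt = build_filter(small_config, 1, 0.0)
        with pytest.raises(ValueError):
            loggabor_conv(np.zeros((4, 4)), filt)


class TestBinaryHash:
    def test_all_positive_gives_full_code(self):
        maps = np.ones((3, 2, 2))
        np.testing.assert_array_equal(binary_hash(maps),
                                      np.full((2, 2), 7))

    def test_nonpositive_gives_zero(self):
        """Heaviside(0) = 0: zero responses contribute no bit."""
        maps = np.stack([np.zeros((2, 2)), -np.ones((2, 2))])
        np.testing.assert_array_equal(binary_hash(maps), np.zeros((2, 2)))

    def test_bit_weights_follow_filter_order(self):
        signs = np.array([1.0, -1.0, 1.0])  # k = 1, 2, 3 -> 1 + 0 + 4
        maps = signs[:, None, None] * np.ones((3, 1, 1))
        assert binary_hash(maps)[0, 0] == 5

    def test_range_invariant(self):
        rng = np.random.default_rng(3)
        maps = rng.standard_normal((6, 8, 8))
        code = binary_hash(maps)
        assert code.min() >= 0 and code.max() <= 2 ** 6 - 1


class TestBlockHistogram:
    def test_conservation_per_block(self):
        rng = np.random.default_rng(0)
        encoded = rng.integers(0, 4, size=(4, 4))
        h = blockwise_histogram(encoded, (2, 2), 2).toarray().ravel()
        assert h.reshape(4, 4).sum(axis=1).tolist() == [4, 4, 4, 4]

    def test_uniform_map_is_point_mass(self):
        encoded = np.full((4, 4), 3)
        h = blockwise_histogram(encoded, (2, 2), 2).toarray().ravel()
        expected = np.zeros(16)
        expected[[3, 7, 11, 15]] = 4
        np.testing.assert_array_equal(h, expected)

    def test_hand_worked_4x4(self):
        encoded = np.array([[0, 1, 2, 3],
                            [1, 1, 3, 3],
                            [2, 0, 0, 0],
                            [2, 2, 1, 0]])
        h = blockwise_histogram(encoded, (2, 2), 2).toarray().ravel()
        # row-major blocks: TL {0,1,1,1}, TR {2,3,3,3}, BL {2,0,2,2}, BR {0,0,1,0}
        expected = [1, 3, 0, 0,  0, 0, 1, 3,  1, 0, 3, 0,  3, 1, 0, 0]
        assert h.tolist() == expected

    def test_non_divisible_shape_rejected(self):
        with pytest.raises(ValueError):
            blockwise_histogram(np.zeros((5, 4), dtype=int), (2, 2), 2)


class TestNetwork:
    def test_fit_default_counts(self, fitted_net):
        assert fitted_net.k1_ == 18
        assert fitted_net.k2_ == 18
        assert fitted_net.n_blocks_ == 16
        assert fitted_net.n_features_ == 2 ** 18 * 18 * 16

    def test_layer_map_counts(self, fitted_net, synth_dataset):
        X, _ = synth_dataset
        l1 = fitted_net.layer1(X[0])
        assert l1.shape == (18, 32, 32)
        l2 = fitted_net.layer2(l1[:2])
        assert l2.shape == (2, 18, 32, 32)

    def test_layer2_depends_only_on_parent(self, fitted_net, synth_dataset):
        X, _ = synth_dataset
        l1 = fitted_net.layer1(X[0])
        full = fitted_net.layer2(l1[:3])
        solo = fitted_net.layer2(l1[1:2])
        np.testing.assert_allclose(full[1], solo[0])

    def test_single_filter_composition(self, synth_dataset):
        """K1 = K2 = 1: layer 2 equals applying the two filters in cascade."""
        X, _ = synth_dataset
        net = LogGaborNet(per_scale_counts=(0, 1, 0, 0)).fit(X[:5])
        l1 = net.layer1(X[0])
        l2 = net.layer2(l1)
        assert net.k1_ == net.k2_ == 1
        expected = loggabor_conv(loggabor_conv(X[0], net.layer1_filters_[0]),
                                 net.layer2_filters_[0])
        np.testing.assert_allclose(l2[0, 0], expected, atol=1e-12)

    def test_feature_sum_conservation(self, fitted_net, synth_dataset):
        """Every pixel of every encoded map lands in exactly one histogram
        bin, so the feature total is K1 * pixel count."""
        X, _ = synth_dataset
        f = fitted_net.extract_feature(X[0])
        assert f.shape == (1, fitted_net.n_features_)
        assert f.sum() == 18 * 32 * 32
        assert f.min() >= 0

    @pytest.mark.parametrize("counts", [(1, 1, 1, 1), (0, 3, 2, 0)])
    def test_conservation_random_models(self, synth_dataset, counts):
        X, _ = synth_dataset
        net = LogGaborNet(per_scale_counts=counts).fit(X[:4])
        rng = np.random.default_rng(5)
        for _ in range(3):
            img = rng.random((32, 32))
            f = net.extract_feature(img)
            assert f.sum() == net.k1_ * 32 * 32

    def test_transform_rows_and_determinism(self, fitted_net, synth_dataset):
        X, _ = synth_dataset
        F1 = fitted_net.transform(X[:3])
        F2 = fitted_net.transform(X[:3])
        assert F1.shape == (3, fitted_net.n_features_)
        assert (F1 != F2).nnz == 0

    def test_contrast_inversion_flips_code(self, synth_dataset):
        """I -> -I flips every Heaviside bit at pixels with no exactly-zero
        response, so T -> (2^K2 - 1) - T there."""
        X, _ = synth_dataset
        net = LogGaborNet(per_scale_counts=(1, 1, 1, 1)).fit(X[:5])
        img = X[0]
        for sign in (1.0, -1.0):
            l2 = net.layer2(net.layer1(sign * img))
            code = binary_hash(l2[0])
            if sign == 1.0:
                code_pos, maps_pos = code, l2[0]
            else:
                code_neg = code
        nonzero = np.all(maps_pos != 0.0, axis=0)
        full = 2 ** net.k2_ - 1
        np.testing.assert_array_equal(code_neg[nonzero],
                                      full - code_pos[nonzero])

    def test_fit_is_deterministic(self, synth_dataset):
        X, _ = synth_dataset
        d1 = LogGaborNet().fit(X[:10]).diamond_
        d2 = LogGaborNet().fit(X[:10]).diamond_
        assert d1 == d2

    def test_unfitted_transform_raises(self, synth_dataset):
        X, _ = synth_dataset
        with pytest.raises(RuntimeError):
            LogGaborNet().transform(X[:1])

    def test_hash_group_size_splits_bits(self, synth_dataset):
        X, _ = synth_dataset
        net = LogGaborNet(per_scale_counts=(1, 2, 2, 1),
                          hash_group_size=4).fit(X[:5])
        # K2 = 6 bits -> groups of 4 and 2
        assert net._group_bounds == [(0, 4), (4, 6)]
        f = net.extract_feature(X[0])
        assert f.shape[1] == net.n_features_
        assert f.sum() == net.k1_ * 2 * 32 * 32  # two code maps per parent

    def test_reselect_layer2_keeps_mid_scale_angles(self, synth_dataset):
        """Re-selecting layer 2 on the layer-1 maps reproduces the
        mid-scale orientation sets chosen on raw images."""
        X, _ = synth_dataset
        base = LogGaborNet().fit(X[:30])
        resel = LogGaborNet(reselect_layer2=True).fit(X[:30])
        assert resel.diamond_ == base.diamond_  # layer 1 unaffected
        for s in (1, 2):  # mid scales (0-based indices 1, 2)
            assert resel.diamond2_.angles[s] == base.diamond_.angles[s]

    def test_sklearn_clone_and_get_params(self):
        from sklearn.base import clone

        net = LogGaborNet(m_factor=2.0)
        cloned = clone(net)
        assert cloned.get_params() == net.get_params()

    def test_model_roundtrip(self, fitted_net, synth_dataset, tmp_path):
        X, _ = synth_dataset
        path = tmp_path / "model.zip"
        fitted_net.save(path)
        loaded = LogGaborNet.load(path)
        f1 = fitted_net.extract_feature(X[0])
        f2 = loaded.extract_feature(X[0])
        assert (f1 != f2).nnz == 0
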