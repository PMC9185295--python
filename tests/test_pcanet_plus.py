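"""PCANet+ layers: patch extraction, analytic PCA filter learning,
convolution, pooling, hashing, block histograms, and full feature encoding.

Every numerical operation is checked against an independent brute-force
oracle (nested-loop patch extraction / correlation / pooling, dense
eigendecomposition of the materialized patch matrix)."""

import numpy as np
import pytest

from ofpcanet.exceptions import ConfigError, InputError, StateError
from ofpcanet.pcanet_plus import (
    FilterBank,
    FilterBankLayer,
    LayerConfig,
    block_histograms,
    convolve_bank,
    extract_patches,
    feature_length,
    forward_features,
    hash_chunk,
    learn_pca_filters,
    mean_pool,
    train_filter_bank,
)

# ---------------------------------------------------------------- oracles


def naive_patches(image, k, center=True):
    """Nested-loop zero-padded patch extraction, one column per pixel."""
    img = image if image.ndim == 3 else image[:, :, None]
    h, w, c = img.shape
    pad = (k - 1) // 2
    padded = np.zeros((h + 2 * pad, w + 2 * pad, c))
    padded[pad : pad + h, pad : pad + w] = img
    cols = []
    for i in range(h):
        for j in range(w):
            patch = padded[i : i + k, j : j + k, :].reshape(-1)
            if center:
                patch = patch - patch.mean()
            cols.append(patch)
    return np.stack(cols, axis=1)


def naive_correlate(image, filt):
    """Nested-loop zero-padded correlation of a multi-channel image."""
    img = image if image.ndim == 3 else image[:, :, None]
    h, w, c = img.shape
    k = filt.shape[0]
    pad = (k - 1) // 2
    padded = np.zeros((h + 2 * pad, w + 2 * pad, c))
    padded[pad : pad + h, pad : pad + w] = img
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = np.sum(padded[i : i + k, j : j + k, :] * filt)
    return out


def naive_mean_pool(arr, size):
    """Double-loop mean pooling with symmetric (reflect) border padding."""
    pad = size // 2
    padded = np.pad(arr, pad, mode="symmetric")
    out = np.zeros_like(arr, dtype=np.float64)
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            out[i, j] = padded[i : i + size, j : j + size].mean()
    return out


def _random_orthonormal_layer(k, d, c_in, f_lambda=8, blocks=(2, 2), seed=0):
    """A FilterBankLayer with random orthonormal filters (no training)."""
    rng = np.random.default_rng(seed)
    dim = k * k * c_in
    Q, _ = np.linalg.qr(rng.normal(size=(dim, d)))
    return FilterBankLayer(
        filters=Q.T.reshape(d, k, k, c_in),
        config=LayerConfig(k=k, n_filters=d, f_lambda=f_lambda, blocks=blocks),
    )


# ---------------------------------------------------------------- patches


class TestExtractPatches:
    def test_constant_image_centers_to_zero_in_interior(self):
        """Patch-mean removal nulls every patch not touching the zero-padded
        border (border patches mix the constant with padding zeros)."""
        P = extract_patches(np.full((6, 6), 0.7), k=3)
        interior = P.reshape(9, 6, 6)[:, 1:-1, 1:-1]
        assert np.allclose(interior, 0.0)
        # valid-only extraction (pad=0) nulls every column
        P_valid = extract_patches(np.full((6, 6), 0.7), k=3, pad=0)
        assert np.allclose(P_valid, 0.0)

    def test_3x3_image_k3_gives_9_columns_of_9(self):
        P = extract_patches(np.arange(9.0).reshape(3, 3), k=3)
        assert P.shape == (9, 9)

    def test_multichannel_matches_naive_oracle(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(4, 4, 2))
        P = extract_patches(img, k=3)
        assert P.shape == (18, 16)
        assert np.allclose(P, naive_patches(img, 3), atol=1e-12)

    def test_uncentered_matches_naive_oracle(self):
        rng = np.random.default_rng(1)
        img = rng.normal(size=(5, 6))
        P = extract_patches(img, k=3, center=False)
        assert np.allclose(P, naive_patches(img, 3, center=False), atol=1e-12)

    def test_even_k_rejected(self):
        with pytest.raises(ConfigError):
            extract_patches(np.zeros((6, 6)), k=4)


# ---------------------------------------------------------------- learning


class TestLearnPcaFilters:
    def test_rank_one_patches_recover_direction(self):
        rng = np.random.default_rng(2)
        d = rng.normal(size=9)
        coeffs = rng.normal(size=40)
        P = np.outer(d, coeffs)
        layer = learn_pca_filters(P, 3, k=3, n_channels=1)
        f0 = layer.filters[0].reshape(-1)
        expect = d / np.linalg.norm(d)
        if expect[np.argmax(np.abs(expect))] < 0:
            expect = -expect  # sign convention: largest-|component| positive
        assert np.allclose(f0, expect, atol=1e-10)
        assert np.allclose(layer.eigenvalues[1:], 0.0, atol=1e-8)

    def test_matches_dense_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        P = rng.normal(size=(50, 1000))
        layer = learn_pca_filters(P, 4, k=5, n_channels=2)
        vals, vecs = np.linalg.eigh(P @ P.T)
        order = np.argsort(vals)[::-1]
        for i in range(4):
            v = vecs[:, order[i]]
            f = layer.filters[i].reshape(-1)
            assert min(
                np.max(np.abs(f - v)), np.max(np.abs(f + v))
            ) < 1e-8
        # reconstruction error equals the sum of the discarded eigenvalues
        V = layer.filters.reshape(4, -1).T
        err = np.linalg.norm(P - V @ (V.T @ P)) ** 2
        discarded = vals[order][4:].sum()
        assert abs(err - discarded) / discarded < 1e-6

    def test_duplicating_all_patches_leaves_filters_unchanged(self):
        rng = np.random.default_rng(4)
        P = rng.normal(size=(18, 100))
        a = learn_pca_filters(P, 4, k=3, n_channels=2)
        b = learn_pca_filters(np.concatenate([P, P], axis=1), 4, k=3, n_channels=2)
        assert np.allclose(a.filters, b.filters, atol=1e-10)

    def test_all_zero_patches_rejected(self):
        with pytest.raises(ConfigError, match="degenerate"):
            learn_pca_filters(np.zeros((9, 50)), 2, k=3, n_channels=1)


# ---------------------------------------------------------------- convolution


class TestConvolveBank:
    def test_impulse_response_lays_out_filter(self):
        """Correlation with a delta image reproduces the (flipped) filter
        around the delta position."""
        layer = _random_orthonormal_layer(k=3, d=2, c_in=1, f_lambda=2)
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        out = convolve_bank(img, layer)
        for d in range(2):
            w = layer.filters[d, :, :, 0]
            assert np.allclose(out[3:6, 3:6, d], w[::-1, ::-1], atol=1e-12)

    def test_constant_image_zero_mean_filter(self):
        filt = np.ones((3, 3, 1)) / 9.0
        filt -= filt.mean()
        layer = FilterBankLayer(
            filters=filt[None],
            config=LayerConfig(k=3, n_filters=1, f_lambda=1),
        )
        out = convolve_bank(np.full((8, 8), 0.5), layer)
        assert np.allclose(out[1:-1, 1:-1, 0], 0.0, atol=1e-12)

    def test_matches_naive_correlation_oracle(self):
        rng = np.random.default_rng(5)
        img = rng.normal(size=(10, 7, 3))
        layer = _random_orthonormal_layer(k=5, d=4, c_in=3, f_lambda=4, seed=6)
        out = convolve_bank(img, layer)
        for d in range(4):
            assert np.max(np.abs(out[:, :, d] - naive_correlate(img, layer.filters[d]))) < 1e-10

    def test_channel_mismatch_rejected(self):
        layer = _random_orthonormal_layer(k=3, d=2, c_in=2, f_lambda=2)
        with pytest.raises(InputError):
            convolve_bank(np.zeros((6, 6, 3)), layer)


class TestMeanPool:
    def test_constant_map_unchanged(self):
        m = np.full((7, 7), 3.3)
        assert np.allclose(mean_pool(m, 3), m)

    def test_center_of_1_to_9(self):
        m = np.arange(1.0, 10.0).reshape(3, 3)
        assert mean_pool(m, 3)[1, 1] == pytest.approx(5.0)

    def test_matches_naive_reflect_oracle(self):
        rng = np.random.default_rng(7)
        m = rng.normal(size=(9, 11))
        for size in (3, 5):
            assert np.max(np.abs(mean_pool(m, size) - naive_mean_pool(m, size))) < 1e-12

    def test_stride_subsamples(self):
        rng = np.random.default_rng(8)
        m = rng.normal(size=(8, 8))
        assert np.array_equal(mean_pool(m, 3, 2), mean_pool(m, 3, 1)[::2, ::2])

    def test_pool_size_one_is_identity(self):
        m = np.random.default_rng(9).normal(size=(5, 5))
        assert np.array_equal(mean_pool(m, 1), m)


# ---------------------------------------------------------------- hashing


class TestHashChunk:
    def test_all_positive_maps_give_max_label(self):
        labels = hash_chunk(np.ones((4, 4, 8)))
        assert np.all(labels == 255)

    def test_nonpositive_maps_give_zero(self):
        labels = hash_chunk(-np.ones((4, 4, 8)))
        assert np.all(labels == 0)
        labels = hash_chunk(np.zeros((4, 4, 8)))  # H(0) = 0
        assert np.all(labels == 0)

    def test_single_positive_map_weights_binary(self):
        maps = -np.ones((3, 3, 8))
        maps[1, 1, 2] = 1.0  # f = 3 (1-based) -> 2^(3-1) = 4
        labels = hash_chunk(maps)
        assert labels[1, 1] == 4
        assert labels.sum() == 4

    def test_labels_within_range(self):
        rng = np.random.default_rng(10)
        for f_lambda in (1, 4, 8):
            labels = hash_chunk(rng.normal(size=(12, 12, f_lambda)))
            assert labels.min() >= 0
            assert labels.max() <= 2**f_lambda - 1


class TestBlockHistograms:
    def test_uniform_zero_map_puts_pixel_counts_in_bin_zero(self):
        hist = block_histograms(np.zeros((8, 8), dtype=np.int64), (2, 2), 8)
        hist = hist.reshape(4, 256)
        assert np.all(hist[:, 0] == 16)
        assert np.all(hist[:, 1:] == 0)

    def test_total_mass_equals_pixel_count(self):
        rng = np.random.default_rng(11)
        labels = rng.integers(0, 256, size=(13, 9))
        for blocks in [(1, 1), (2, 2), (3, 2)]:
            hist = block_histograms(labels, blocks, 8)
            assert hist.sum() == 13 * 9
            # per-block conservation
            per_block = hist.reshape(-1, 256).sum(axis=1)
            assert per_block.sum() == 13 * 9

    def test_single_block_matches_naive_bincount(self):
        rng = np.random.default_rng(12)
        labels = rng.integers(0, 16, size=(6, 7))
        hist = block_histograms(labels, (1, 1), 4)
        assert np.array_equal(hist, np.bincount(labels.ravel(), minlength=16))

    def test_more_blocks_than_pixels_rejected(self):
        with pytest.raises(ConfigError):
            block_histograms(np.zeros((2, 2), dtype=np.int64), (4, 4), 2)


# ---------------------------------------------------------------- forward


class TestForwardFeatures:
    def test_feature_length_formula(self):
        """D1=D2=16, F_lambda=8, B=4 -> 4*2*256 per layer = 4096 total."""
        configs = [
            LayerConfig(k=3, n_filters=16, f_lambda=8, blocks=(2, 2)),
            LayerConfig(k=3, n_filters=16, f_lambda=8, blocks=(2, 2)),
        ]
        assert feature_length(configs) == 4096
        bank = FilterBank(
            layers=[
                _random_orthonormal_layer(3, 16, 6, seed=13),
                _random_orthonormal_layer(3, 16, 16, seed=14),
            ]
        )
        rng = np.random.default_rng(15)
        f = forward_features(rng.normal(size=(12, 12, 6)), bank)
        assert f.shape == (4096,)

    def test_zero_tensor_well_defined(self):
        bank = FilterBank(
            layers=[
                _random_orthonormal_layer(3, 8, 2, seed=16),
                _random_orthonormal_layer(3, 8, 8, seed=17),
            ]
        )
        f = forward_features(np.zeros((10, 10, 2)), bank)
        # all labels 0: each block contributes its pixel count to bin 0
        f = f.reshape(-1, 256)
        assert np.all(f[:, 0] == 25)  # 10x10 in 2x2 blocks of 25 px
        assert np.all(f[:, 1:] == 0)

    def test_features_nonnegative_and_mass_conserving(self):
        bank = FilterBank(
            layers=[
                _random_orthonormal_layer(3, 8, 4, seed=18),
                _random_orthonormal_layer(3, 8, 8, seed=19),
            ]
        )
        rng = np.random.default_rng(20)
        f = forward_features(rng.normal(size=(14, 10, 4)), bank)
        assert np.all(f >= 0)
        # each hash map distributes exactly N*M counts over its blocks
        per_map = f.reshape(-1, 4 * 256).sum(axis=1)
        assert np.all(per_map == 140)

    def test_untrained_bank_rejected(self):
        with pytest.raises(StateError):
            forward_features(np.zeros((8, 8, 2)), FilterBank())


# ---------------------------------------------------------------- training


def _toy_tensors(n=3, shape=(12, 12, 4), seed=21):
    rng = np.random.default_rng(seed)
    return [rng.normal(size=shape) for _ in range(n)]


class TestTrainFilterBank:
    CONFIGS = [
        LayerConfig(k=3, n_filters=8, pool_size=3, f_lambda=8),
        LayerConfig(k=3, n_filters=8, pool_size=1, f_lambda=8),
    ]

    def test_training_is_order_invariant(self):
        tensors = _toy_tensors()
        a = train_filter_bank(tensors, self.CONFIGS)
        b = train_filter_bank(tensors[::-1], self.CONFIGS)
        for la, lb in zip(a.layers, b.layers):
            assert np.allclose(la.filters, lb.filters, atol=1e-10)

    def test_streaming_matches_materialized_oracle(self):
        """Scatter accumulated tensor-by-tensor equals the eigendecomposition
        of the fully materialized patch matrix, layer by layer."""
        tensors = _toy_tensors()
        bank = train_filter_bank(tensors, self.CONFIGS)
        # layer 1 oracle
        P1 = extract_patches(tensors, k=3)
        oracle1 = learn_pca_filters(P1, 8, k=3, n_channels=4)
        assert np.allclose(bank.layers[0].filters, oracle1.filters, atol=1e-8)
        # layer 2 oracle: pooled responses of all tensors
        pooled = [
            mean_pool(convolve_bank(t, bank.layers[0]), 3, 1) for t in tensors
        ]
        P2 = extract_patches(pooled, k=3)
        oracle2 = learn_pca_filters(P2, 8, k=3, n_channels=8)
        assert np.allclose(bank.layers[1].filters, oracle2.filters, atol=1e-8)

    def test_filters_orthonormal_within_each_layer(self):
        bank = train_filter_bank(_toy_tensors(), self.CONFIGS)
        for layer in bank.layers:
            V = layer.filters_flat
            assert np.allclose(V @ V.T, np.eye(V.shape[0]), atol=1e-8)

    def test_accepts_iterator_input(self):
        tensors = _toy_tensors()
        a = train_filter_bank(iter(tensors), self.CONFIGS)
        b = train_filter_bank(tensors, self.CONFIGS)
        for la, lb in zip(a.layers, b.layers):
            assert np.array_equal(la.filters, lb.filters)

    def test_constant_training_set_rejected(self):
        with pytest.raises(ConfigError, match="degenerate"):
            train_filter_bank([np.zeros((10, 10, 2))], self.CONFIGS)

    def test_bank_round_trips_through_disk(self, tmp_path):
        bank = train_filter_bank(_toy_tensors(), self.CONFIGS)
        bank.save(tmp_path / "bank")
        loaded = FilterBank.load(tmp_path / "bank")
        for la, lb in zip(bank.layers, loaded.layers):
            assert np.array_equal(la.filters, lb.filters)
            assert la.config == lb.config


class TestLayerConfigValidation:
    def test_filter_count_must_be_multiple_of_chunk(self):
        with pytest.raises(ConfigError):
            LayerConfig(k=3, n_filters=12, f_lambda=8)

    def test_even_filter_size_rejected(self):
        with pytest.raises(ConfigError):
            LayerConfig(k=4, n_filters=8)

    def test_default_pad_is_same_size(self):
        assert LayerConfig(k=7, n_filters=8).pad == 3
        assert LayerConfig(k=9, n_filters=8).pad == 4
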