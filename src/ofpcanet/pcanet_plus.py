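"""Two-layer PCANet+ feature learning over multi-channel images.

Each layer's convolution filters are learned analytically: they are the top
eigenvectors of the scatter matrix of mean-centered local patches, i.e. the
principal components that minimize patch reconstruction error under an
orthonormality constraint.  Layer 1 sees the stacked flow tensors (2T
channels); its mean-pooled responses form the multi-channel input of layer 2.

Feature encoding per layer: response maps are divided into chunks of
``f_lambda`` maps, each chunk is hashed per pixel with a Heaviside step and
binary weights into an integer label map, each label map is partitioned into
non-overlapping blocks, and each block is histogrammed over the
``2**f_lambda`` possible labels.  Features from both layers are concatenated,
giving a vector of length ``sum_l B_l * (D_l / f_lambda) * 2**f_lambda``.

The patch scatter is accumulated as a streaming sum over images, so filter
learning never materializes the full patch matrix of a batch: peak memory
depends on the patch dimension and a single image's size, not on batch size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import eigh
from scipy.ndimage import uniform_filter

from .exceptions import ConfigError, InputError, StateError

_ROW_CHUNK = 64  # row block size for chunked im2col convolution


@dataclass
class LayerConfig:
    """Geometry of one PCANet+ layer.

    ``k``: filter side length (odd).  ``n_filters``: number of PCA filters
    (D), a multiple of ``f_lambda``.  ``pool_size``/``pool_stride``: mean
    pooling applied to the response maps (pool_size 1 = identity).  ``pad``:
    spatial zero padding; None means (k-1)//2 for same-size output.
    ``f_lambda``: hash chunk size.  ``blocks``: (rows, cols) grid of
    non-overlapping histogram blocks per hash map.
    """

    k: int
    n_filters: int
    pool_size: int = 3
    pool_stride: int = 1
    pad: int | None = None
    f_lambda: int = 8
    blocks: tuple[int, int] = (2, 2)

    def __post_init__(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ConfigError(f"filter size k must be odd and positive, got {self.k}")
        if self.f_lambda < 1 or self.f_lambda > 30:
            raise ConfigError(f"f_lambda must be in [1, 30], got {self.f_lambda}")
        if self.n_filters % self.f_lambda != 0:
            raise ConfigError(
                f"n_filters={self.n_filters} must be a multiple of "
                f"f_lambda={self.f_lambda} (chunked hashing)"
            )
        if self.pool_size < 1 or self.pool_size % 2 == 0:
            raise ConfigError(f"pool_size must be odd, got {self.pool_size}")
        if self.pad is None:
            self.pad = (self.k - 1) // 2
        self.blocks = tuple(self.blocks)  # type: ignore[assignment]

    @property
    def n_blocks(self) -> int:
        return self.blocks[0] * self.blocks[1]

    @property
    def n_chunks(self) -> int:
        return self.n_filters // self.f_lambda


@dataclass
class FilterBankLayer:
    """Learned filters of one layer: array (D, k, k, C_in) + its config."""

    filters: np.ndarray
    config: LayerConfig
    eigenvalues: np.ndarray | None = None

    @property
    def n_channels_in(self) -> int:
        return self.filters.shape[3]

    @property
    def filters_flat(self) -> np.ndarray:
        d = self.filters.shape[0]
        return self.filters.reshape(d, -1)


@dataclass
class FilterBank:
    """Ordered PCANet+ layers plus the training-fold identifier."""

    layers: list[FilterBankLayer] = field(default_factory=list)
    trained_on: str | None = None

    @property
    def trained(self) -> bool:
        return len(self.layers) > 0

    def save(self, path: str | Path) -> None:
        """Serialize as an .npz array archive + JSON config sidecar."""
        path = Path(path)
        arrays = {f"filters_{i}": lyr.filters for i, lyr in enumerate(self.layers)}
        np.savez_compressed(path.with_suffix(".npz"), **arrays)
        meta = {
            "trained_on": self.trained_on,
            "layers": [asdict(lyr.config) for lyr in self.layers],
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "FilterBank":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        data = np.load(path.with_suffix(".npz"))
        layers = []
        for i, cfg in enumerate(meta["layers"]):
            cfg["blocks"] = tuple(cfg["blocks"])
            layers.append(
                FilterBankLayer(filters=data[f"filters_{i}"], config=LayerConfig(**cfg))
            )
        return cls(layers=layers, trained_on=meta["trained_on"])


def feature_length(configs: Sequence[LayerConfig]) -> int:
    """Closed-form feature dimension: sum_l B_l (D_l/f_lambda) 2^f_lambda."""
    return sum(c.n_blocks * c.n_chunks * (1 << c.f_lambda) for c in configs)


def _as_3d(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = image[:, :, None]
    if image.ndim != 3:
        raise InputError(f"image must be 2-D or 3-D, got shape {image.shape}")
    return image


def _im2col(image: np.ndarray, k: int, pad: int, step: int = 1) -> np.ndarray:
    """Zero-padded patch matrix of one image, one column per pixel position.

    Column layout: the k x k x C patch at each position flattened in C-order
    (row, column, channel), matching ``FilterBankLayer.filters_flat``.
    Positions are taken every ``step`` pixels in each direction (step > 1 is
    used only to subsample patches for filter learning).
    """
    image = _as_3d(image)
    h, w, c = image.shape
    if h < k or w < k:
        raise InputError(f"image {h}x{w} smaller than filter size {k}")
    padded = np.pad(image, ((pad, pad), (pad, pad), (0, 0)))
    windows = np.lib.stride_tricks.sliding_window_view(padded, (k, k), axis=(0, 1))
    # windows: (H', W', C, k, k) -> reorder to (H', W', k, k, C)
    windows = windows[::step, ::step]
    windows = np.moveaxis(windows, 2, 4)
    hh, ww = windows.shape[:2]
    return windows.reshape(hh * ww, k * k * c).T.copy()


def extract_patches(
    images: np.ndarray | Iterable[np.ndarray],
    k: int,
    *,
    pad: int | None = None,
    step: int = 1,
    center: bool = True,
) -> np.ndarray:
    """Extract the k x k multi-channel patch around every pixel position.

    With the default ``pad=(k-1)//2`` there is one column per pixel per
    image (same-size, zero padding).  Each column is mean-centered by
    subtracting its own mean, the normalization used for filter learning.

    Returns a matrix of shape (k*k*C, n_positions_total).
    """
    if k % 2 == 0:
        raise ConfigError(f"filter size k must be odd, got {k}")
    if pad is None:
        pad = (k - 1) // 2
    if isinstance(images, np.ndarray) and images.ndim <= 3:
        images = [images]
    cols = []
    for img in images:
        P = _im2col(img, k, pad, step=step)
        if center:
            P = P - P.mean(axis=0, keepdims=True)
        cols.append(P)
    if not cols:
        raise InputError("no images supplied")
    return np.concatenate(cols, axis=1)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector signs: largest-|component| entry positive.

    Ties in magnitude resolve to the first (lowest) index, so filters are
    reproducible across eigensolvers.
    """
    out = vectors.copy()
    for j in range(out.shape[1]):
        idx = int(np.argmax(np.abs(out[:, j])))
        if out[idx, j] < 0:
            out[:, j] = -out[:, j]
    return out


def _filters_from_scatter(
    scatter: np.ndarray, d: int, k: int, c_in: int
) -> tuple[np.ndarray, np.ndarray]:
    """Top-d eigenvectors of the patch scatter, reshaped to (d, k, k, c_in)."""
    n = scatter.shape[0]
    if d > n:
        raise ConfigError(f"cannot learn {d} filters from patch dimension {n}")
    if not np.any(scatter):
        raise ConfigError("degenerate input batch: all patches are zero")
    vals, vecs = eigh(scatter, subset_by_index=[n - d, n - 1])
    order = np.argsort(vals)[::-1]  # eigh returns ascending
    vals = vals[order]
    vecs = _fix_signs(vecs[:, order])
    return vecs.T.reshape(d, k, k, c_in), vals


def learn_pca_filters(
    patches: np.ndarray, d: int, *, k: int, n_channels: int
) -> FilterBankLayer:
    """Learn one layer's filters as the top-d principal eigenvectors.

    ``patches`` is a (k*k*C, n) mean-centered patch matrix.  The filters
    minimize the patch reconstruction error ||P - V V^T P||^2 subject to
    V^T V = I, i.e. they are the leading eigenvectors of P P^T, ordered by
    descending eigenvalue with a deterministic sign convention.  Degenerate
    (tied) eigenvalues keep the eigensolver's descending order; the filters
    spanning a tied eigenspace are not unique.
    """
    patches = np.asarray(patches, dtype=np.float64)
    if patches.ndim != 2 or patches.size == 0:
        raise InputError("patches must be a non-empty 2-D matrix")
    if patches.shape[0] != k * k * n_channels:
        raise InputError(
            f"patch dimension {patches.shape[0]} != k*k*C = {k * k * n_channels}"
        )
    scatter = patches @ patches.T
    filters, vals = _filters_from_scatter(scatter, d, k, n_channels)
    return FilterBankLayer(
        filters=filters,
        config=LayerConfig(k=k, n_filters=d, f_lambda=_default_f_lambda(d)),
        eigenvalues=vals,
    )


def _default_f_lambda(d: int) -> int:
    for f in (8, 4, 2, 1):
        if d % f == 0:
            return f
    return 1


def convolve_bank(image: np.ndarray, layer: FilterBankLayer) -> np.ndarray:
    """Same-size correlation of a multi-channel image with a layer's filters.

    Returns response maps of shape (N, M, D).  Correlation (not flipped
    convolution) with zero padding ``layer.config.pad``; patches are NOT
    mean-centered here — centering applies only during filter learning.
    """
    image = _as_3d(image)
    h, w, c = image.shape
    if c != layer.n_channels_in:
        raise InputError(
            f"image has {c} channels but filters expect {layer.n_channels_in}"
        )
    cfg = layer.config
    W = layer.filters_flat  # (D, k*k*C)
    padded = np.pad(image, ((cfg.pad, cfg.pad), (cfg.pad, cfg.pad), (0, 0)))
    out = np.empty((h, w, W.shape[0]), dtype=np.float64)
    # process in row blocks to bound the im2col working set
    for r0 in range(0, h, _ROW_CHUNK):
        r1 = min(r0 + _ROW_CHUNK, h)
        block = padded[r0 : r1 + 2 * cfg.pad, :, :]
        win = np.lib.stride_tricks.sliding_window_view(block, (cfg.k, cfg.k), axis=(0, 1))
        win = np.moveaxis(win, 2, 4)  # (rows, W', k, k, C)
        rows, ww = win.shape[:2]
        P = win.reshape(rows * ww, -1)
        out[r0:r1] = (P @ W.T).reshape(rows, ww, -1)
    return out


def mean_pool(
    response: np.ndarray, pool_size: int, pool_stride: int = 1
) -> np.ndarray:
    """Mean pooling with reflect-padded borders; stride 1 preserves size.

    Accepts a 2-D map or an (N, M, D) stack (pooled per map).
    """
    if pool_size % 2 == 0:
        raise ConfigError(f"pool_size must be odd, got {pool_size}")
    if pool_size == 1 and pool_stride == 1:
        return np.asarray(response, dtype=np.float64)
    arr = np.asarray(response, dtype=np.float64)
    if arr.ndim == 2:
        pooled = uniform_filter(arr, size=pool_size, mode="reflect")
        return pooled[::pool_stride, ::pool_stride]
    pooled = uniform_filter(arr, size=(pool_size, pool_size, 1), mode="reflect")
    return pooled[::pool_stride, ::pool_stride, :]


def hash_chunk(response_maps: np.ndarray) -> np.ndarray:
    """Heaviside hashing of F_lambda response maps into one integer label map.

    ``response_maps``: (N, M, F_lambda).  label(p) = sum_f 2^(f-1) * H(map_f(p))
    with H(x) = 1 iff x > 0 (H(0) = 0).  Labels lie in [0, 2^F_lambda - 1].
    """
    maps = np.asarray(response_maps)
    if maps.ndim != 3:
        raise ConfigError(f"expected (N, M, F_lambda) maps, got shape {maps.shape}")
    f_lambda = maps.shape[2]
    if f_lambda > 30:
        raise ConfigError(f"f_lambda={f_lambda} exceeds 30")
    weights = (1 << np.arange(f_lambda)).astype(np.int64)
    return ((maps > 0).astype(np.int64) * weights).sum(axis=2)


def _block_slices(n: int, parts: int) -> list[slice]:
    """Split [0, n) into ``parts`` near-equal slices; remainder to the last."""
    if parts > n:
        raise ConfigError(f"cannot split {n} pixels into {parts} blocks")
    base = n // parts
    bounds = [i * base for i in range(parts)] + [n]
    return [slice(bounds[i], bounds[i + 1]) for i in range(parts)]


def block_histograms(
    hash_map: np.ndarray, blocks: tuple[int, int], f_lambda: int
) -> np.ndarray:
    """Per-block label histograms of one hash map, concatenated block-major.

    The map is partitioned into a rows x cols grid of non-overlapping blocks
    (remainder pixels go to the last row/column of blocks); each block is
    histogrammed over the 2^f_lambda labels.  The total sum of the returned
    vector equals the map's pixel count.
    """
    hash_map = np.asarray(hash_map)
    n_bins = 1 << f_lambda
    rows, cols = blocks
    if hash_map.min() < 0 or hash_map.max() >= n_bins:
        raise InputError("hash labels out of range for f_lambda")
    out = np.empty(rows * cols * n_bins, dtype=np.float64)
    row_slices = _block_slices(hash_map.shape[0], rows)
    col_slices = _block_slices(hash_map.shape[1], cols)
    i = 0
    for rs in row_slices:
        for cs in col_slices:
            out[i : i + n_bins] = np.bincount(
                hash_map[rs, cs].ravel(), minlength=n_bins
            )
            i += n_bins
    return out


def _encode_layer(pooled: np.ndarray, cfg: LayerConfig) -> np.ndarray:
    """Chunked hash + block histograms of one layer's pooled responses."""
    parts = []
    for t in range(cfg.n_chunks):
        chunk = pooled[:, :, t * cfg.f_lambda : (t + 1) * cfg.f_lambda]
        labels = hash_chunk(chunk)
        parts.append(block_histograms(labels, cfg.blocks, cfg.f_lambda))
    return np.concatenate(parts)


def forward_features(tensor: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Encode one stacked tensor through the trained two-layer PCANet+.

    Layer-1 responses are mean-pooled; the pooled stack is (a) hashed and
    block-histogrammed and (b) fed as a multi-channel image into layer 2,
    which is encoded the same way.  The per-layer encodings are concatenated;
    the output length is ``feature_length([l.config for l in bank.layers])``.
    """
    if not bank.trained:
        raise StateError("filter bank has not been trained")
    tensor = _as_3d(tensor)
    features = []
    current = tensor
    for layer in bank.layers:
        responses = convolve_bank(current, layer)
        pooled = mean_pool(responses, layer.config.pool_size, layer.config.pool_stride)
        features.append(_encode_layer(pooled, layer.config))
        current = pooled
    return np.concatenate(features)


def train_filter_bank(
    tensors: Iterable[np.ndarray],
    configs: Sequence[LayerConfig],
    *,
    learn_step: int = 1,
    trained_on: str | None = None,
) -> FilterBank:
    """Learn the PCANet+ filter bank from a batch of stacked tensors.

    Layer 1 is learned from the mean-centered patches of all input tensors;
    each subsequent layer is learned from the pooled responses of the
    previous layer on the same tensors.  The patch scatter P P^T is
    accumulated one tensor at a time (streaming), so the batch's full patch
    matrix is never materialized.  Training is order-invariant: the scatter
    is a sum over tensors.

    ``learn_step`` subsamples patch positions (every nth pixel in each
    direction) for scatter accumulation only — inference always uses every
    position.  Useful for large frames where adjacent patches are highly
    redundant.
    """
    tensors = list(tensors) if not isinstance(tensors, list) else tensors
    if len(tensors) == 0:
        raise InputError("at least one training tensor required")
    bank = FilterBank(layers=[], trained_on=trained_on)
    current: list[np.ndarray] = [_as_3d(t) for t in tensors]
    for li, cfg in enumerate(configs):
        c_in = current[0].shape[2]
        dim = cfg.k * cfg.k * c_in
        scatter = np.zeros((dim, dim))
        for img in current:
            P = extract_patches(img, cfg.k, pad=cfg.pad, step=learn_step, center=True)
            scatter += P @ P.T
        filters, vals = _filters_from_scatter(scatter, cfg.n_filters, cfg.k, c_in)
        layer = FilterBankLayer(filters=filters, config=cfg, eigenvalues=vals)
        bank.layers.append(layer)
        if li < len(configs) - 1:
            current = [
                mean_pool(convolve_bank(img, layer), cfg.pool_size, cfg.pool_stride)
                for img in current
            ]
    return bank
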