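"""Two-layer Log-Gabor convolutional feature extractor.

The network is a PCANet-style unsupervised pipeline: two cascaded banks of
Log-Gabor convolutions (K1 filters in layer 1, K2 in layer 2, giving K1*K2
signed real-valued maps), a binary-hashing layer that thresholds each
parent's K2 child maps at zero and packs the bits into one integer code map
with weights 2^(k-1), and a block-wise histogram layer that partitions every
code map into B non-overlapping blocks and concatenates the per-block value
histograms into one long sparse nonnegative feature vector of conceptual
length ``2^K2 * K1 * B``.

Training is fully unsupervised: it only runs the per-scale orientation
selection of :mod:`veinfeat.orient_select` on the training images to decide
which candidate orientations each convolutional layer keeps (by default
layer 2 reuses layer 1's selection, so K1 = K2).

:class:`LogGaborNet` wraps the pipeline as a scikit-learn transformer
(``fit`` / ``transform`` on stacks of ROI images, sparse CSR output), so it
composes with sklearn pipelines and model selection.
"""

from __future__ import annotations

import json
import zipfile
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .filterbank import (
    FilterBankConfig,
    FrequencyGrid,
    LogGaborFilter,
    build_filter,
    frequency_grid,
)
from .orient_select import DiamondStructure, select_orientations

__all__ = [
    "LogGaborNet",
    "loggabor_conv",
    "binary_hash",
    "blockwise_histogram",
]


def loggabor_conv(image: np.ndarray, filt: LogGaborFilter) -> np.ndarray:
    """Real part of the circular Log-Gabor convolution of ``image``.

    Computed as ``Re(IFFT(FFT(image) * transfer))``; output shape equals
    input shape.  Constant images map to zero (the filter has no DC).
    """
    image = np.asarray(image, dtype=float)
    if image.shape != filt.shape:
        raise ValueError(
            f"image shape {image.shape} != filter shape {filt.shape}"
        )
    return np.real(np.fft.ifft2(np.fft.fft2(image) * filt.transfer))


def binary_hash(maps: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Pack K2 signed maps into one integer code map.

    Bit k (1-based, weight ``2^(k-1)``) is the Heaviside step of map k:
    1 where the response is strictly positive, 0 otherwise (zero maps to 0).
    Output values lie in [0, 2^K2 - 1].
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 3:
        raise ValueError("expected a stack of 2D maps")
    k2 = maps.shape[0]
    weights = (1 << np.arange(k2, dtype=np.int64))[:, None, None]
    return np.sum((maps > 0) * weights, axis=0)


def blockwise_histogram(encoded: np.ndarray, block_shape: tuple[int, int],
                        n_bits: int) -> sp.csr_matrix:
    """Concatenated per-block histograms of one integer code map.

    The map is partitioned into non-overlapping ``block_shape`` blocks in
    row-major order; each block is histogrammed over bins ``0 .. 2^n_bits-1``
    and the B histograms are concatenated.  Returned as a 1 x (B * 2^n_bits)
    sparse CSR row of raw counts; each block's histogram sums to its pixel
    count.
    """
    encoded = np.asarray(encoded)
    rows, cols = encoded.shape
    br, bc = block_shape
    if rows % br or cols % bc:
        raise ValueError(
            f"block shape {block_shape} does not divide map shape "
            f"{encoded.shape}"
        )
    n_bins = 1 << n_bits
    nbr, nbc = rows // br, cols // bc
    # row-major block index of every pixel
    block_idx = (np.arange(rows)[:, None] // br) * nbc + np.arange(cols)[None, :] // bc
    flat = block_idx.astype(np.int64) * n_bins + encoded.astype(np.int64)
    idx, counts = np.unique(flat.ravel(), return_counts=True)
    n_cols = nbr * nbc * n_bins
    return sp.csr_matrix(
        (counts.astype(np.int64), (np.zeros_like(idx), idx)),
        shape=(1, n_cols),
    )


def _as_image_stack(X: Iterable[np.ndarray] | np.ndarray,
                    expected_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Validate input as an (n, rows, cols) float stack."""
    if isinstance(X, np.ndarray) and X.ndim == 2:
        X = X[None]
    X = np.asarray([np.asarray(im, dtype=float) for im in X])
    if X.ndim != 3 or X.shape[0] == 0:
        raise ValueError("expected a nonempty stack of 2D grayscale images")
    if not np.all(np.isfinite(X)):
        raise ValueError("images contain non-finite values")
    if expected_shape is not None and X.shape[1:] != tuple(expected_shape):
        raise ValueError(
            f"images have shape {X.shape[1:]}, model expects {expected_shape}"
        )
    return X


class LogGaborNet(BaseEstimator, TransformerMixin):
    """Unsupervised two-layer Log-Gabor convolutional feature extractor.

    Parameters
    ----------
    wmin, m_factor, t_factor, sigma_r, n_scales, n_orientations :
        Parameters of the candidate Log-Gabor bank; see
        :class:`veinfeat.filterbank.FilterBankConfig`.
    per_scale_counts :
        How many orientations to retain at each scale (the diamond
        allocation).  Default ``(2, 7, 7, 2)`` keeps K1 = 18 filters.
    block_shape :
        Block size of the histogram layer; must divide ``image_shape``.
        Default 8x8 on 32x32 ROIs gives B = 16 blocks.
    image_shape :
        ROI shape every input image must have.
    reselect_layer2 :
        If True, run a second selection pass over the layer-1 output maps to
        pick layer 2's orientations; by default layer 2 reuses layer 1's
        selection (K1 = K2).
    hash_group_size :
        Bits per code map.  ``None`` packs all K2 bits into one code map per
        parent (the faithful mode, default).  A value g < K2 splits the K2
        maps into consecutive groups of at most g bits, PCANet-style, giving
        smaller histograms.

    Attributes
    ----------
    diamond_ : DiamondStructure
        Retained angles and selection histograms per scale.
    layer1_filters_, layer2_filters_ : list of LogGaborFilter
        The K1 / K2 convolution kernels.
    n_features_ : int
        Conceptual feature length ``2^g * K1 * n_groups * B``.

    Examples
    --------
    >>> net = LogGaborNet().fit(train_rois)
    >>> F = net.transform(test_rois)     # sparse CSR, one row per image
    """

    def __init__(self, wmin: float = 2.0, m_factor: float = 2.2,
                 t_factor: float = 1.3, sigma_r: float = 0.55,
                 n_scales: int = 4, n_orientations: int = 10,
                 per_scale_counts: Sequence[int] = (2, 7, 7, 2),
                 block_shape: tuple[int, int] = (8, 8),
                 image_shape: tuple[int, int] = (32, 32),
                 reselect_layer2: bool = False,
                 hash_group_size: int | None = None):
        self.wmin = wmin
        self.m_factor = m_factor
        self.t_factor = t_factor
        self.sigma_r = sigma_r
        self.n_scales = n_scales
        self.n_orientations = n_orientations
        self.per_scale_counts = per_scale_counts
        self.block_shape = block_shape
        self.image_shape = image_shape
        self.reselect_layer2 = reselect_layer2
        self.hash_group_size = hash_group_size

    # ------------------------------------------------------------------
    def _config(self) -> FilterBankConfig:
        return FilterBankConfig(
            wmin=self.wmin, m_factor=self.m_factor, t_factor=self.t_factor,
            sigma_r=self.sigma_r, n_scales=self.n_scales,
            n_orientations=self.n_orientations,
            image_shape=tuple(self.image_shape),
        )

    def _filters_from_diamond(self, config: FilterBankConfig,
                              diamond: DiamondStructure,
                              grid: FrequencyGrid) -> list[LogGaborFilter]:
        return [
            build_filter(config, s, theta, grid=grid)
            for s in range(1, config.n_scales + 1)
            for theta in diamond.angles[s - 1]
        ]

    def fit(self, X, y=None):
        """Select the per-scale orientations from unlabeled training ROIs."""
        config = self._config()
        rows, cols = config.image_shape
        br, bc = self.block_shape
        if rows % br or cols % bc:
            raise ValueError(
                f"block_shape {self.block_shape} does not divide "
                f"image_shape {config.image_shape}"
            )
        X = _as_image_stack(X, config.image_shape)
        grid = frequency_grid(config.image_shape)
        self.diamond_ = select_orientations(X, config, self.per_scale_counts)
        self.layer1_filters_ = self._filters_from_diamond(
            config, self.diamond_, grid)
        if self.reselect_layer2:
            layer1_maps = [
                loggabor_conv(im, f) for im in X for f in self.layer1_filters_
            ]
            self.diamond2_ = select_orientations(
                layer1_maps, config, self.per_scale_counts)
        else:
            self.diamond2_ = self.diamond_
        self.layer2_filters_ = self._filters_from_diamond(
            config, self.diamond2_, grid)
        self.k1_ = len(self.layer1_filters_)
        self.k2_ = len(self.layer2_filters_)
        g = self.k2_ if self.hash_group_size is None else int(self.hash_group_size)
        if not 1 <= g <= self.k2_:
            raise ValueError("hash_group_size must lie in [1, K2]")
        self._group_bounds = [(i, min(i + g, self.k2_))
                              for i in range(0, self.k2_, g)]
        b = (rows // br) * (cols // bc)
        self.n_blocks_ = b
        self.n_features_ = sum(
            (1 << (hi - lo)) * b for lo, hi in self._group_bounds
        ) * self.k1_
        return self

    # ------------------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "layer1_filters_"):
            raise RuntimeError("LogGaborNet instance is not fitted yet")

    def layer1(self, image: np.ndarray) -> np.ndarray:
        """K1 signed layer-1 maps of one ROI."""
        self._check_fitted()
        return np.stack([loggabor_conv(image, f) for f in self.layer1_filters_])

    def layer2(self, layer1_maps: np.ndarray) -> np.ndarray:
        """(K1, K2) signed layer-2 maps; child k of parent j depends only on
        layer-1 map j."""
        self._check_fitted()
        return np.stack([
            np.stack([loggabor_conv(m, f) for f in self.layer2_filters_])
            for m in layer1_maps
        ])

    def _encode_parent(self, child_maps: np.ndarray) -> list[np.ndarray]:
        """Code maps of one parent's K2 children (one per hash group)."""
        return [binary_hash(child_maps[lo:hi]) for lo, hi in self._group_bounds]

    def extract_feature(self, image: np.ndarray) -> sp.csr_matrix:
        """Sparse feature row of one ROI (layer1 -> layer2 -> hash -> hist)."""
        self._check_fitted()
        image = np.asarray(image, dtype=float)
        if image.shape != tuple(self.image_shape):
            raise ValueError(
                f"ROI shape {image.shape} != model shape {self.image_shape}"
            )
        spectrum = np.fft.fft2(image)
        l2_spectra = [f.transfer for f in self.layer2_filters_]
        segments = []
        for f1 in self.layer1_filters_:
            parent = np.real(np.fft.ifft2(spectrum * f1.transfer))
            parent_spec = np.fft.fft2(parent)
            children = np.stack([
                np.real(np.fft.ifft2(parent_spec * t)) for t in l2_spectra
            ])
            for (lo, hi), code in zip(self._group_bounds,
                                      self._encode_parent(children)):
                segments.append(
                    blockwise_histogram(code, tuple(self.block_shape), hi - lo)
                )
        return sp.hstack(segments, format="csr")

    def transform(self, X) -> sp.csr_matrix:
        """Feature matrix of a stack of ROIs, one sparse CSR row per image."""
        self._check_fitted()
        X = _as_image_stack(X, tuple(self.image_shape))
        return sp.vstack([self.extract_feature(im) for im in X], format="csr")

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Serialize the fitted model (params + diamond) to a zip archive."""
        self._check_fitted()
        meta = {
            "params": {
                k: (list(v) if isinstance(v, (tuple, list)) else v)
                for k, v in self.get_params().items()
            },
            "diamond": self.diamond_.to_dict(),
            "diamond2": self.diamond2_.to_dict(),
            "version": 1,
        }
        with zipfile.ZipFile(Path(path), "w") as zf:
            zf.writestr("model.json", json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "LogGaborNet":
        with zipfile.ZipFile(Path(path)) as zf:
            meta = json.loads(zf.read("model.json"))
        params = meta["params"]
        for key in ("per_scale_counts", "block_shape", "image_shape"):
            params[key] = tuple(params[key])
        model = cls(**params)
        config = model._config()
        grid = frequency_grid(config.image_shape)
        model.diamond_ = DiamondStructure.from_dict(meta["diamond"])
        model.diamond2_ = DiamondStructure.from_dict(meta["diamond2"])
        model.layer1_filters_ = model._filters_from_diamond(
            config, model.diamond_, grid)
        model.layer2_filters_ = model._filters_from_diamond(
            config, model.diamond2_, grid)
        model.k1_ = len(model.layer1_filters_)
        model.k2_ = len(model.layer2_filters_)
        g = model.k2_ if model.hash_group_size is None else int(model.hash_group_size)
        model._group_bounds = [(i, min(i + g, model.k2_))
                               for i in range(0, model.k2_, g)]
        rows, cols = config.image_shape
        br, bc = model.block_shape
        b = (rows // br) * (cols // bc)
        model.n_blocks_ = b
        model.n_features_ = sum(
            (1 << (hi - lo)) * b for lo, hi in model._group_bounds
        ) * model.k1_
        return model
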