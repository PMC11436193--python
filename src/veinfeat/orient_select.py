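"""Adaptive per-scale selection of orientational Log-Gabor filters.

The selection is unsupervised: for each radial scale the full set of
candidate orientations is applied to every training ROI, the magnitude
(|real part|) responses of all pixels across all orientation maps are sorted
in descending order, and each pixel is credited to the orientation at which
it attains its strongest response (its first appearance in the sorted list).
Per-image histograms are normalized and accumulated over the training set so
every image carries equal weight regardless of its dynamic range, and the
``n_S`` highest-weight orientations are retained at scale ``S``.

On natural vascular imagery mid scales carry most oriented energy, so with
counts such as [2, 7, 7, 2] the retained set is "diamond"-shaped: many
orientations at middle scales, few at the extremes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .filterbank import (
    FilterBankConfig,
    LogGaborBank,
    build_bank,
    orientation_angles,
)

__all__ = [
    "OrientationPowerMaps",
    "SortedResponseRecord",
    "OrientationHistogram",
    "DiamondStructure",
    "orientation_power_maps",
    "sort_filter_response",
    "count_most_used_ori",
    "select_orientations",
]


@dataclass(frozen=True)
class OrientationPowerMaps:
    """|Re| responses of one image under all candidate orientations of a scale."""

    maps: np.ndarray  # (n_orientations, rows, cols), all values >= 0
    scale_index: int

    @property
    def n_orientations(self) -> int:
        return self.maps.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.maps.shape[1:]


@dataclass(frozen=True)
class SortedResponseRecord:
    value: float
    row: int
    col: int
    ori: int  # 1-based orientation index


@dataclass(frozen=True)
class OrientationHistogram:
    """Normalized per-orientation usage weights for one scale."""

    weights: np.ndarray  # (n_orientations,), >= 0, sums to 1
    scale_index: int


@dataclass(frozen=True)
class DiamondStructure:
    """Per-scale retained orientation angles chosen by the selection pass."""

    angles: tuple[tuple[float, ...], ...]      # per scale, ascending theta0
    counts: tuple[int, ...]                    # n_S per scale
    weights: tuple[tuple[float, ...], ...]     # full candidate histograms

    @property
    def total(self) -> int:
        return sum(self.counts)

    def to_dict(self) -> dict:
        return {
            "counts": list(self.counts),
            "angles": [list(a) for a in self.angles],
            "weights": [list(w) for w in self.weights],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiamondStructure":
        return cls(
            angles=tuple(tuple(a) for a in d["angles"]),
            counts=tuple(d["counts"]),
            weights=tuple(tuple(w) for w in d["weights"]),
        )


def orientation_power_maps(image: np.ndarray, bank: LogGaborBank,
                           scale_index: int) -> OrientationPowerMaps:
    """Magnitude response maps of ``image`` at one scale's orientations.

    Each map is ``|Re(IFFT(FFT(image) * transfer))|`` — circular filtering,
    output shape equals input shape.
    """
    image = np.asarray(image, dtype=float)
    scale_filters = bank.at_scale(scale_index)
    if not scale_filters:
        raise ValueError(f"bank has no filters at scale {scale_index}")
    if image.shape != scale_filters[0].shape:
        raise ValueError(
            f"image shape {image.shape} does not match bank grid "
            f"{scale_filters[0].shape}"
        )
    spectrum = np.fft.fft2(image)
    maps = np.stack([
        np.abs(np.real(np.fft.ifft2(spectrum * f.transfer)))
        for f in scale_filters
    ])
    return OrientationPowerMaps(maps=maps, scale_index=scale_index)


def sort_filter_response(pow_maps: OrientationPowerMaps
                         ) -> list[SortedResponseRecord]:
    """All (value, row, col, ori) records sorted by value, descending.

    Enumeration order is orientation-major, then row, then col; ties keep
    that order (stable sort), so equal values surface lowest-orientation
    first.
    """
    maps = pow_maps.maps
    n_ori, rows, cols = maps.shape
    values = maps.reshape(-1)
    order = np.argsort(-values, kind="stable")
    ori_idx, row_idx, col_idx = np.unravel_index(order, maps.shape)
    return [
        SortedResponseRecord(value=float(values[o]), row=int(r), col=int(c),
                             ori=int(i) + 1)
        for o, i, r, c in zip(order, ori_idx, row_idx, col_idx)
    ]


def count_most_used_ori(records: Sequence[SortedResponseRecord],
                        n_orientations: int,
                        image_shape: tuple[int, int]) -> OrientationHistogram:
    """Histogram of the orientation each pixel uses most strongly.

    Walking the records in descending-value order, a pixel contributes only
    on its first appearance — i.e. to the orientation of its maximum
    magnitude response.  Weights are normalized to sum to 1.
    """
    rows, cols = image_shape
    seen = np.zeros((rows, cols), dtype=bool)
    counts = np.zeros(n_orientations, dtype=float)
    for rec in records:
        if seen[rec.row, rec.col]:
            continue
        seen[rec.row, rec.col] = True
        counts[rec.ori - 1] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("empty record list")
    return OrientationHistogram(weights=counts / total, scale_index=0)


def _pixel_argmax_histogram(maps: np.ndarray) -> np.ndarray:
    """Fast path: per-pixel argmax histogram, equivalent to the sorted walk."""
    n_ori = maps.shape[0]
    winners = np.argmax(maps, axis=0)  # first max wins = lowest ori index
    counts = np.bincount(winners.ravel(), minlength=n_ori).astype(float)
    return counts / counts.sum()


def select_orientations(train_images: Iterable[np.ndarray],
                        config: FilterBankConfig,
                        per_scale_counts: Sequence[int],
                        bank: LogGaborBank | None = None) -> DiamondStructure:
    """Retain the ``n_S`` most-used candidate orientations at each scale.

    Per-image histograms are normalized before accumulation so each training
    image carries equal weight.  Ties are broken by ascending orientation
    index; retained angles are reported in ascending theta0 order.
    """
    per_scale_counts = list(per_scale_counts)
    if len(per_scale_counts) != config.n_scales:
        raise ValueError(
            f"per_scale_counts has {len(per_scale_counts)} entries, "
            f"expected n_scales = {config.n_scales}"
        )
    if any(n < 0 or n > config.n_orientations for n in per_scale_counts):
        raise ValueError("each per-scale count must lie in [0, n_orientations]")
    images = [np.asarray(im, dtype=float) for im in train_images]
    if not images:
        raise ValueError("training set is empty")
    if bank is None:
        bank = build_bank(config)
    thetas = np.asarray(orientation_angles(config.n_orientations))

    angles: list[tuple[float, ...]] = []
    weights: list[tuple[float, ...]] = []
    for s in range(1, config.n_scales + 1):
        acc = np.zeros(config.n_orientations)
        for im in images:
            pm = orientation_power_maps(im, bank, s)
            acc += _pixel_argmax_histogram(pm.maps)
        acc /= len(images)
        n_s = per_scale_counts[s - 1]
        # highest weight first, ties by ascending orientation index
        order = np.lexsort((np.arange(config.n_orientations), -acc))
        keep = np.sort(order[:n_s])
        angles.append(tuple(float(t) for t in thetas[keep]))
        weights.append(tuple(float(w) for w in acc))
    return DiamondStructure(
        angles=tuple(angles), counts=tuple(per_scale_counts),
        weights=tuple(weights),
    )
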