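"""ROI localization and standardization for near-infrared finger images.

Veins absorb NIR light, so a raw finger image is a bright finger band on a
darker background with dark curvilinear vessels inside.  ROI extraction
finds the upper and lower finger boundaries with a Kirsch compass edge
detector binarized at mean-plus-k-sigma dynamic thresholds, crops the
interior band, and resizes to the network's input size (32x32 by default).
Datasets that ship pre-cropped ROIs bypass the boundary search and are only
resized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

logger = logging.getLogger(__name__)

__all__ = [
    "load_image",
    "kirsch_gradient",
    "threshold_3sigma",
    "extract_roi",
    "resize_roi",
    "RoiParams",
]

# the 8 compass masks: rotations of the north mask, coefficients 5 / -3
_KIRSCH_NORTH = np.array([[5, 5, 5],
                          [-3, 0, -3],
                          [-3, -3, -3]], dtype=float)


def _compass_masks() -> np.ndarray:
    masks = [_KIRSCH_NORTH]
    ring = [(0, 0), (0, 1), (0, 2), (1, 2), (2, 2), (2, 1), (2, 0), (1, 0)]
    m = _KIRSCH_NORTH
    for _ in range(7):
        nxt = m.copy()
        vals = [m[r, c] for r, c in ring]
        vals = vals[-1:] + vals[:-1]  # rotate the outer ring one step
        for (r, c), v in zip(ring, vals):
            nxt[r, c] = v
        masks.append(nxt)
        m = nxt
    return np.stack(masks)


_KIRSCH_MASKS = _compass_masks()


def load_image(path: str | Path) -> np.ndarray:
    """Read a BMP/JPEG/PNG image as grayscale float in [0, 1].

    8-bit and 16-bit inputs are rescaled by their type range; RGB(A) inputs
    are converted with the usual luminance weights.
    """
    import imageio.v3 as iio

    raw = iio.imread(Path(path))
    arr = np.asarray(raw, dtype=float)
    if arr.ndim == 3:
        arr = arr[..., :3] @ np.array([0.2125, 0.7154, 0.0721])
    if np.issubdtype(raw.dtype, np.integer):
        arr = arr / np.iinfo(raw.dtype).max
    return np.clip(arr, 0.0, 1.0)


def kirsch_gradient(image: np.ndarray) -> np.ndarray:
    """Per-pixel maximum response over the 8 Kirsch compass masks.

    Reflective boundary handling; a constant image gives an all-zero map.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    responses = np.stack([
        ndimage.correlate(image, m, mode="reflect") for m in _KIRSCH_MASKS
    ])
    return responses.max(axis=0)


def threshold_3sigma(gradient: np.ndarray,
                     edge_density_ceiling: float = 0.10) -> np.ndarray:
    """Binarize a gradient map at a mean-plus-k-sigma dynamic threshold.

    Three candidate levels ``mu + k sigma`` (k = 1, 2, 3) are tried; the
    smallest k whose edge density does not exceed ``edge_density_ceiling``
    is used (k = 3 if none qualifies).  Higher k always yields a subset of
    lower k's edge set.
    """
    g = np.asarray(gradient, dtype=float)
    mu, sigma = g.mean(), g.std()
    chosen = g > mu + 3 * sigma
    for k in (1, 2, 3):
        edges = g > mu + k * sigma
        if edges.mean() <= edge_density_ceiling:
            chosen = edges
            break
    return chosen


@dataclass(frozen=True)
class RoiParams:
    """Tunables of the ROI localization step."""

    target_shape: tuple[int, int] = (32, 32)
    edge_density_ceiling: float = 0.10
    horizontal_margin: float = 0.05   # fraction of columns trimmed per side
    bypass: bool = False              # input is already a provided ROI


def _boundary_rows(edges: np.ndarray) -> tuple[int, int] | None:
    """Upper/lower finger boundary rows: the strongest near-horizontal edge
    row in the top and bottom halves.  None when no edges exist."""
    rows = edges.shape[0]
    counts = edges.sum(axis=1)
    mid = rows // 2
    if counts[:mid].max(initial=0) == 0 or counts[mid:].max(initial=0) == 0:
        return None
    top = int(np.argmax(counts[:mid]))
    bottom = int(mid + np.argmax(counts[mid:]))
    if bottom - top < 2:
        return None
    return top, bottom


def extract_roi(image: np.ndarray, params: RoiParams = RoiParams()) -> np.ndarray:
    """Localize and standardize the finger-vein ROI of a raw image.

    Finds the finger's upper/lower boundary rows on the thresholded Kirsch
    edge map, crops the interior band plus a horizontal margin, and resizes
    to ``params.target_shape``.  Falls back to the full frame (with a
    warning) when no boundaries are found; with ``params.bypass`` the image
    is treated as a provided ROI and only resized.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if not params.bypass:
        edges = threshold_3sigma(kirsch_gradient(image),
                                 params.edge_density_ceiling)
        bounds = _boundary_rows(edges)
        if bounds is None:
            logger.warning(
                "no finger boundaries found; falling back to the full frame")
        else:
            top, bottom = bounds
            margin = int(round(params.horizontal_margin * image.shape[1]))
            lo, hi = margin, image.shape[1] - margin
            image = image[top + 1:bottom, lo:hi]
            if image.size == 0:
                raise ValueError("degenerate crop box")
    return resize_roi(image, params.target_shape)


def resize_roi(roi: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resize to ``target_shape``, values clipped to [0, 1].

    A same-shape input is returned unchanged (bit-equal).
    """
    roi = np.asarray(roi, dtype=float)
    if roi.size == 0:
        raise ValueError("empty image")
    if roi.shape == tuple(target_shape):
        return roi
    out = _sk_resize(roi, target_shape, order=1, anti_aliasing=True,
                     preserve_range=True)
    return np.clip(out, 0.0, 1.0)
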