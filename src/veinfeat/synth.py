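"""Synthetic labeled vein-like image datasets.

Near-infrared finger imagery shows veins as dark curvilinear strokes on a
brighter, noisy background.  The generator emulates exactly that structure:
each class (finger identity) owns a fixed set of smooth dark polyline
strokes whose geometry is a deterministic function of (class key, global
seed); each sample of the class applies a small rigid jitter (translation,
rotation) and additive Gaussian noise derived from (class key, sample
index, global seed).  Defaults put stroke widths at 2-6 px on a 32x32
frame, so the mid radial scales of the Log-Gabor bank carry most of the
oriented energy.

The generator is the test bed for the whole pipeline: a spec whose strokes
all run along spatial direction alpha concentrates spectral energy at
wave-vector angle alpha + pi/2 (mod pi), which pins down the orientation
the selection stage must retain.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = ["SyntheticSpec", "make_vein_image", "make_dataset", "make_arrays"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic vein dataset generator."""

    n_classes: int = 20
    samples_per_class: int = 6
    image_shape: tuple[int, int] = (32, 32)
    strokes_per_class: tuple[int, int] = (3, 6)     # inclusive count range
    stroke_width: tuple[float, float] = (2.0, 6.0)  # px
    orientation_range: tuple[float, float] = (0.0, np.pi)  # stroke direction
    jitter_translation: float = 1.5   # max |shift| per axis, px
    jitter_rotation: float = 0.05     # max |angle|, radians
    noise_sigma: float = 0.03         # additive Gaussian, gray levels
    background: float = 0.8           # background intensity
    stroke_depth: float = 0.45        # max darkening at a stroke centre
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.samples_per_class < 1:
            raise ValueError("counts must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.strokes_per_class[0] < 1:
            raise ValueError("need at least one stroke per class")


def _class_strokes(class_key: int, spec: SyntheticSpec
                   ) -> list[tuple[np.ndarray, float]]:
    """Deterministic per-class stroke geometry: (dense path points, width)."""
    rng = np.random.default_rng(
        np.random.SeedSequence((spec.seed, int(class_key))))
    rows, cols = spec.image_shape
    lo, hi = spec.strokes_per_class
    n_strokes = int(rng.integers(lo, hi + 1))
    strokes = []
    for _ in range(n_strokes):
        angle = rng.uniform(*spec.orientation_range)
        width = rng.uniform(*spec.stroke_width)
        # anchor near the frame, path runs along `angle` with gentle bends
        cx = rng.uniform(0.2 * cols, 0.8 * cols)
        cy = rng.uniform(0.2 * rows, 0.8 * rows)
        length = rng.uniform(0.8, 1.4) * max(rows, cols)
        t = np.linspace(-0.5, 0.5, 64)
        # low-frequency lateral wobble gives a smooth curvilinear path
        wobble = (rng.uniform(0.02, 0.08) * min(rows, cols)
                  * np.sin(2 * np.pi * rng.uniform(0.5, 1.5) * t
                           + rng.uniform(0, 2 * np.pi)))
        ux, uy = np.cos(angle), np.sin(angle)
        px, py = -uy, ux  # lateral unit vector
        xs = cx + length * t * ux + wobble * px
        ys = cy + length * t * uy + wobble * py
        strokes.append((np.column_stack([ys, xs]), width))
    return strokes


def _render_class_image(class_key: int, spec: SyntheticSpec) -> np.ndarray:
    """Noise-free canonical image of one class."""
    rows, cols = spec.image_shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    grid = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    darkness = np.zeros(rows * cols)
    for points, width in _class_strokes(class_key, spec):
        # distance from every pixel to the dense polyline point set
        d2 = ((grid[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
        dmin = np.sqrt(d2.min(axis=1))
        profile = spec.stroke_depth * np.exp(-(dmin / (0.5 * width)) ** 2)
        darkness = np.maximum(darkness, profile)
    return np.clip(spec.background - darkness.reshape(rows, cols), 0.0, 1.0)


def make_vein_image(class_key: int, sample_index: int,
                    spec: SyntheticSpec) -> np.ndarray:
    """One sample of one class: fixed geometry + per-sample jitter and noise.

    Deterministic in (class_key, sample_index, spec); with zero noise and
    zero jitter all samples of a class are identical.
    """
    base = _render_class_image(class_key, spec)
    rng = np.random.default_rng(np.random.SeedSequence(
        (spec.seed, int(class_key), int(sample_index), 1)))
    img = base
    if spec.jitter_rotation > 0:
        angle = rng.uniform(-spec.jitter_rotation, spec.jitter_rotation)
        img = ndimage.rotate(img, np.degrees(angle), reshape=False,
                             order=1, mode="nearest")
    if spec.jitter_translation > 0:
        shift = rng.uniform(-spec.jitter_translation,
                            spec.jitter_translation, size=2)
        img = ndimage.shift(img, shift, order=1, mode="nearest")
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def make_dataset(spec: SyntheticSpec, root: str | Path) -> Path:
    """Write the full labeled dataset in class-per-folder layout.

    ``root/class_XXX/sample_YY.png`` as 8-bit grayscale PNGs plus a
    ``manifest.json`` recording the spec.  Regeneration with the same spec
    is byte-identical.
    """
    import imageio.v3 as iio

    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for c in range(spec.n_classes):
        cdir = root / f"class_{c:03d}"
        cdir.mkdir(exist_ok=True)
        for s in range(spec.samples_per_class):
            img = make_vein_image(c, s, spec)
            arr = np.round(img * 255).astype(np.uint8)
            iio.imwrite(cdir / f"sample_{s:02d}.png", arr)
    manifest = asdict(spec)
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return root


def make_arrays(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """In-memory dataset: (images stack, integer class labels)."""
    images, labels = [], []
    for c in range(spec.n_classes):
        for s in range(spec.samples_per_class):
            images.append(make_vein_image(c, s, spec))
            labels.append(c)
    return np.stack(images), np.asarray(labels)
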