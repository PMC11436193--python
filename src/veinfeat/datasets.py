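"""Dataset loading (class-per-folder layout) and parameter sweeps.

The on-disk layout is one subfolder per finger identity containing that
finger's BMP/JPEG/PNG samples — the layout public finger-vein databases map
onto naturally and the synthetic generator writes directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import RoiParams, extract_roi, load_image

logger = logging.getLogger(__name__)

__all__ = ["DatasetIndex", "load_dataset", "load_roi_arrays", "run_sweep"]

_IMAGE_SUFFIXES = {".bmp", ".png", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class DatasetIndex:
    """Index of a class-per-folder image tree."""

    entries: tuple[tuple[Path, str], ...]  # (image path, class label)
    root: Path

    @property
    def labels(self) -> list[str]:
        return [label for _, label in self.entries]

    @property
    def paths(self) -> list[Path]:
        return [p for p, _ in self.entries]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def __len__(self) -> int:
        return len(self.entries)


def load_dataset(root: str | Path) -> DatasetIndex:
    """Index a class-per-folder tree in deterministic lexicographic order.

    Empty class folders are dropped with a warning; files that are present
    but unreadable are skipped (and counted) at load time, not here.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    entries: list[tuple[Path, str]] = []
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"dataset root {root} has no class subfolders")
    for cdir in class_dirs:
        files = sorted(
            p for p in cdir.iterdir()
            if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            logger.warning("class folder %s is empty; dropped", cdir.name)
            continue
        entries.extend((f, cdir.name) for f in files)
    if not entries:
        raise ValueError(f"no images found under {root}")
    return DatasetIndex(entries=tuple(entries), root=root)


def load_roi_arrays(index: DatasetIndex,
                    roi_params: RoiParams = RoiParams()
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Load and standardize every indexed image to the target ROI shape.

    Returns ``(images, labels)``; unreadable files are skipped with a logged
    count.
    """
    images, labels = [], []
    skipped = 0
    for path, label in index.entries:
        try:
            raw = load_image(path)
        except Exception as exc:  # unreadable or corrupt file
            logger.warning("skipping unreadable image %s (%s)", path, exc)
            skipped += 1
            continue
        images.append(extract_roi(raw, roi_params))
        labels.append(label)
    if skipped:
        logger.warning("skipped %d unreadable images", skipped)
    if not images:
        raise ValueError("no readable images in dataset")
    return np.stack(images), np.asarray(labels)


_SWEEPABLE = {"wmin", "m_factor", "t_factor", "per_scale_counts"}


def run_sweep(images: np.ndarray, labels: Sequence, model, parameter: str,
              grid: Sequence, train_fraction: float = 0.5,
              n_iterations: int = 1, seed: int = 0) -> pd.DataFrame:
    """Re-run the open-set benchmark over a grid of one model parameter.

    Exactly one parameter of {wmin, m_factor, t_factor, per_scale_counts}
    varies; all other settings are held at the model's.  Returns a table
    with one row per grid value and columns (value, eer, acc).
    """
    from sklearn.base import clone

    from .match_eval import evaluate

    if parameter not in _SWEEPABLE:
        raise ValueError(
            f"sweep parameter must be one of {sorted(_SWEEPABLE)}, "
            f"got {parameter!r}"
        )
    rows = []
    for value in grid:
        net = clone(model).set_params(**{parameter: value})
        report = evaluate(images, labels, net,
                          train_fraction=train_fraction,
                          n_iterations=n_iterations, seed=seed)
        rows.append({"value": str(value), "eer": report.eer,
                     "acc": report.acc})
        logger.info("%s=%s -> EER=%.3f%% ACC=%.3f%%",
                    parameter, value, report.eer, report.acc)
    return pd.DataFrame(rows)
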