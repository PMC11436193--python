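"""Matching and biometric verification metrics.

Feature vectors are compared with plain Euclidean distance (computed on the
sparse representation); identification is 1-nearest-neighbor.  Verification
builds genuine (same finger) and imposter (different finger) distance sets,
sweeps an accept threshold t (accept iff distance <= t) over all distinct
scores, and reports the false acceptance rate FAR(t) = % imposters accepted,
the false rejection rate FRR(t) = % genuines rejected, and the equal error
rate (EER) at the FAR = FRR crossing, linearly interpolated between the two
bracketing thresholds.  The evaluation protocol is open-set: filter
selection (training) and scoring use disjoint finger identities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.metrics import pairwise_distances

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreSet",
    "EvalReport",
    "match_distance",
    "rank1_classify",
    "far_frr",
    "compute_eer",
    "open_set_split",
    "evaluate",
]


@dataclass(frozen=True)
class ScoreSet:
    """Genuine (same identity) and imposter (different identity) distances."""

    genuine: np.ndarray
    imposter: np.ndarray

    def __post_init__(self) -> None:
        for name in ("genuine", "imposter"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size and arr.min() < 0:
                raise ValueError(f"{name} distances must be nonnegative")
            object.__setattr__(self, name, arr)


@dataclass
class EvalReport:
    """Verification/identification metrics averaged over iterations."""

    eer: float                     # percent
    acc: float                     # percent, rank-1 leave-one-out
    thresholds: np.ndarray
    far: np.ndarray                # percent, non-decreasing in t
    frr: np.ndarray                # percent, non-increasing in t
    eer_per_iteration: list[float] = field(default_factory=list)
    acc_per_iteration: list[float] = field(default_factory=list)
    n_iterations: int = 1
    seed: int = 0

    @property
    def roc(self) -> np.ndarray:
        """ROC points (FAR %, 100 - FRR %) over the threshold sweep."""
        return np.column_stack([self.far, 100.0 - self.frr])

    def to_dict(self) -> dict:
        return {
            "eer": self.eer,
            "acc": self.acc,
            "eer_per_iteration": list(self.eer_per_iteration),
            "acc_per_iteration": list(self.acc_per_iteration),
            "n_iterations": self.n_iterations,
            "seed": self.seed,
        }


def _as_row(f) -> sp.csr_matrix:
    if sp.issparse(f):
        return f.tocsr()
    arr = np.asarray(f, dtype=float).reshape(1, -1)
    return sp.csr_matrix(arr)


def match_distance(f_i, f_j) -> float:
    """Euclidean distance between two feature vectors (dense or sparse)."""
    a, b = _as_row(f_i), _as_row(f_j)
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"feature dimensions differ: {a.shape[1]} vs {b.shape[1]}"
        )
    d = a - b
    return float(np.sqrt(d.multiply(d).sum()))


def rank1_classify(gallery_features, gallery_labels: Sequence, probe) -> object:
    """Label of the gallery vector nearest to ``probe`` (1-NN).

    Ties are broken toward the lowest gallery index (argmin's first-minimum
    rule).
    """
    gallery_labels = list(gallery_labels)
    if len(gallery_labels) == 0:
        raise ValueError("empty gallery")
    d = pairwise_distances(_as_row(probe), gallery_features,
                           metric="euclidean").ravel()
    return gallery_labels[int(np.argmin(d))]


def far_frr(scores: ScoreSet, thresholds: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """FAR and FRR (percent) at each accept threshold (accept iff d <= t)."""
    if scores.genuine.size == 0 or scores.imposter.size == 0:
        raise ValueError("both score sets must be nonempty")
    t = np.asarray(thresholds, dtype=float)
    imposter = np.sort(scores.imposter)
    genuine = np.sort(scores.genuine)
    far = 100.0 * np.searchsorted(imposter, t, side="right") / imposter.size
    frr = 100.0 * (1.0 - np.searchsorted(genuine, t, side="right") / genuine.size)
    return far, frr


def compute_eer(scores: ScoreSet
                ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Equal error rate (percent) plus the full threshold sweep.

    Sweeps all distinct scores (plus a below-minimum sentinel) as
    thresholds; the FAR = FRR crossing is located and linearly interpolated
    between the bracketing thresholds.  Returns
    ``(eer, thresholds, far, frr)``.
    """
    if scores.genuine.size == 0 or scores.imposter.size == 0:
        raise ValueError("both score sets must be nonempty")
    all_scores = np.unique(np.concatenate([scores.genuine, scores.imposter]))
    thresholds = np.concatenate([[all_scores[0] - 1.0], all_scores])
    far, frr = far_frr(scores, thresholds)
    diff = far - frr
    idx = int(np.argmax(diff >= 0))  # first threshold with FAR >= FRR
    if idx == 0:
        eer = (far[0] + frr[0]) / 2.0
    else:
        f1, r1 = far[idx - 1], frr[idx - 1]
        f2, r2 = far[idx], frr[idx]
        denom = (r1 - f1) + (f2 - r2)
        lam = 0.5 if denom == 0 else (r1 - f1) / denom
        eer = f1 + lam * (f2 - f1)
    return float(eer), thresholds, far, frr


def open_set_split(class_labels: Sequence, train_fraction: float,
                   seed: int) -> tuple[list, list]:
    """Class-disjoint random split of finger identities.

    All samples (sessions) of one finger stay on the same side; the split is
    a deterministic function of the seed.
    """
    classes = sorted(set(class_labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes for an open-set split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(classes))
    n_train = int(round(train_fraction * len(classes)))
    n_train = min(max(n_train, 1), len(classes) - 1)
    train = sorted(classes[i] for i in order[:n_train])
    test = sorted(classes[i] for i in order[n_train:])
    return train, test


def score_sets(features, labels: Sequence, pair_budget: int = 10 ** 6,
               seed: int = 0) -> ScoreSet:
    """Genuine/imposter distance sets over all sample pairs.

    All intra-class pairs are genuine and all inter-class pairs imposter;
    when the imposter pairing exceeds ``pair_budget`` it is uniformly
    subsampled with the seed.
    """
    labels = np.asarray(labels)
    dist = pairwise_distances(features, metric="euclidean")
    iu, ju = np.triu_indices(len(labels), k=1)
    same = labels[iu] == labels[ju]
    genuine = dist[iu[same], ju[same]]
    imp_i, imp_j = iu[~same], ju[~same]
    if imp_i.size > pair_budget:
        rng = np.random.default_rng(seed)
        keep = rng.choice(imp_i.size, size=pair_budget, replace=False)
        imp_i, imp_j = imp_i[keep], imp_j[keep]
    imposter = dist[imp_i, imp_j]
    return ScoreSet(genuine=genuine, imposter=imposter)


def _rank1_accuracy(features, labels: Sequence) -> float:
    """Leave-one-out rank-1 accuracy (percent): every sample probes the
    rest of the set."""
    labels = np.asarray(labels)
    dist = pairwise_distances(features, metric="euclidean")
    np.fill_diagonal(dist, np.inf)
    nearest = np.argmin(dist, axis=1)
    return 100.0 * float((labels[nearest] == labels).mean())


def evaluate(images: np.ndarray, labels: Sequence, model,
             train_fraction: float = 0.5, n_iterations: int = 5,
             seed: int = 0, pair_budget: int = 10 ** 6) -> EvalReport:
    """Open-set identification/verification benchmark.

    Per iteration: split finger identities, fit ``model`` (an unfitted
    sklearn-style transformer, cloned each time) on the training-identity
    images, extract features of the test-identity images, build
    genuine/imposter score sets, and compute EER and leave-one-out rank-1
    accuracy.  The report averages over iterations; the stored FAR/FRR sweep
    is the last iteration's.
    """
    from sklearn.base import clone

    labels = np.asarray(labels)
    eers, accs = [], []
    thresholds = far = frr = None
    for it in range(n_iterations):
        it_seed = (seed + 1000003 * it) % (2 ** 31)
        train_classes, test_classes = open_set_split(
            labels, train_fraction, it_seed)
        train_mask = np.isin(labels, train_classes)
        net = clone(model).fit(images[train_mask])
        test_mask = ~train_mask
        feats = net.transform(images[test_mask])
        test_labels = labels[test_mask]
        scores = score_sets(feats, test_labels, pair_budget=pair_budget,
                            seed=it_seed)
        eer, thresholds, far, frr = compute_eer(scores)
        acc = _rank1_accuracy(feats, test_labels)
        logger.info("iteration %d: EER=%.3f%% ACC=%.3f%%", it + 1, eer, acc)
        eers.append(eer)
        accs.append(acc)
    return EvalReport(
        eer=float(np.mean(eers)), acc=float(np.mean(accs)),
        thresholds=thresholds, far=far, frr=frr,
        eer_per_iteration=eers, acc_per_iteration=accs,
        n_iterations=n_iterations, seed=seed,
    )
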