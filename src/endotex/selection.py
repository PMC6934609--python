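"""Redundancy-aware training-set selection by clustering first-order statistics.

Video-rate endomicroscopy produces long runs of near-duplicate frames, so
annotating (or training on) every frame is wasteful.  Each frame is
summarized by four first-order statistics of its raw pixel values —
standard deviation, mean, variance and skewness (variance is kept
alongside std, redundantly, as the feature list is defined) — the features
are clustered per class with k-means, and one uniformly random member of
each cluster enters the training set.  Test data is never clustered.

Features are z-scored per dimension before clustering by default: without
standardization the variance column (scale ~1e3) would dominate skewness
(scale ~1).  Constant frames have undefined skewness and are excluded from
clustering (and flagged).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .qc import histogram_skewness
from .synth import Frame


@dataclass(frozen=True)
class SelectionFeature:
    """First-order statistics of one frame's raw pixel values."""

    std: float
    mean: float
    variance: float
    skewness: float | None  # None (undefined) for constant frames

    def as_array(self) -> np.ndarray:
        skew = np.nan if self.skewness is None else self.skewness
        return np.array([self.std, self.mean, self.variance, skew])


def selection_features(frame: Frame | np.ndarray) -> SelectionFeature:
    """Population moments of the raw pixel values."""
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    if pixels.size == 0:
        raise ValueError("empty frame")
    x = pixels.astype(np.float64).ravel()
    mean = float(x.mean())
    var = float(np.mean((x - mean) ** 2))
    return SelectionFeature(
        std=float(np.sqrt(var)),
        mean=mean,
        variance=var,
        skewness=histogram_skewness(pixels) if x.size >= 2 else None,
    )


def feature_matrix(frames: Sequence[Frame]) -> np.ndarray:
    """(n_frames, 4) array of selection features; NaN skewness for constants."""
    return np.stack([selection_features(f).as_array() for f in frames])


def select_by_clustering(
    features: np.ndarray,
    labels: Sequence[str],
    k: int,
    seed: int = 0,
    standardize: bool = True,
) -> np.ndarray:
    """Pick ~k diverse frames per class by k-means on selection features.

    ``features`` is the (n, 4) selection-feature matrix; clustering runs
    per class ("each state") independently with k clusters each, and one
    uniformly random member of every non-empty cluster is selected.  Rows
    with non-finite features (constant frames) are excluded.  Returns the
    sorted global indices of the selected frames.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    selected: list[int] = []
    for class_label in np.unique(labels):
        idx = np.flatnonzero(labels == class_label)
        usable = idx[np.isfinite(features[idx]).all(axis=1)]
        if k > usable.size:
            raise ValueError(
                f"k={k} exceeds the {usable.size} usable frames of class "
                f"{class_label!r}")
        x = features[usable]
        if standardize:
            sd = x.std(axis=0)
            sd[sd == 0] = 1.0
            x = (x - x.mean(axis=0)) / sd
        if k == usable.size:
            selected.extend(usable.tolist())
            continue
        km = KMeans(n_clusters=k, random_state=int(rng.integers(2 ** 31)),
                    n_init=10)
        assign = km.fit_predict(x)
        for cluster in range(k):
            members = usable[assign == cluster]
            if members.size:
                selected.append(int(rng.choice(members)))
    return np.array(sorted(selected), dtype=np.int64)


def select_random(
    labels: Sequence[str], k: int, seed: int = 0,
    usable_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Baseline: k uniformly random frames per class (no clustering)."""
    labels = np.asarray(labels)
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    selected: list[int] = []
    for class_label in np.unique(labels):
        idx = np.flatnonzero(labels == class_label)
        if usable_mask is not None:
            idx = idx[usable_mask[idx]]
        if k > idx.size:
            raise ValueError(f"k={k} exceeds frames of class {class_label!r}")
        selected.extend(rng.choice(idx, size=k, replace=False).tolist())
    return np.array(sorted(selected), dtype=np.int64)


def learning_curve(
    clf_features,
    labels: Sequence[str],
    sel_features: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    sizes: Sequence[int],
    strategy: str,
    make_classifier: Callable,
    n_trials: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy vs per-class training budget k, mean +/- sd over trials.

    For each k in ``sizes`` and each trial, k training frames per class are
    chosen from ``train_idx`` — by per-class k-means on ``sel_features``
    (strategy "cluster") or uniformly at random ("random") — a classifier
    is fitted on their rows of ``clf_features`` and scored on the fixed
    ``test_idx``.  ``make_classifier(X, y, seed)`` must return an object
    with ``predict``.
    """
    if strategy not in ("cluster", "random"):
        raise ValueError("strategy must be 'cluster' or 'random'")
    labels = np.asarray(labels)
    test_y = labels[test_idx]
    rows = []
    for k in sizes:
        accs = []
        for trial in range(n_trials):
            trial_seed = int(np.random.SeedSequence(
                [seed, int(k), trial]).generate_state(1)[0] % (2 ** 31))
            if strategy == "cluster":
                local = select_by_clustering(
                    sel_features[train_idx], labels[train_idx], k, trial_seed)
            else:
                usable = np.isfinite(sel_features[train_idx]).all(axis=1)
                local = select_random(labels[train_idx], k, trial_seed,
                                      usable_mask=usable)
            chosen = train_idx[local]
            clf = make_classifier(clf_features[chosen], labels[chosen],
                                  trial_seed)
            pred = clf.predict(clf_features[test_idx])
            accs.append(100.0 * float(np.mean(pred == test_y)))
        rows.append({"k": int(k), "strategy": strategy,
                     "mean_accuracy": float(np.mean(accs)),
                     "sd_accuracy": float(np.std(accs, ddof=1))
                     if len(accs) > 1 else 0.0,
                     "n_trials": n_trials})
    return pd.DataFrame(rows)
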