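"""Split construction, metrics, majority voting and repeated-run reporting.

Two evaluation regimes are distinguished:

* **cross-subject** — whole subjects (all their frames) are assigned to
  train/validation/test, so test subjects are never seen in training.
  Measures generalization to unseen individuals.
* **cross-sample** — frames are split stratified by class irrespective of
  subject; the same subject may contribute frames to both sides (never the
  same frame).  Measures within-cohort annotation automation, optionally
  with stratified k-fold cross-validation (default 7 folds).

Confusion matrices are oriented rows = predicted, columns = true.  Subject
labels are assigned by majority vote over the subject's frame predictions,
with ties broken by clinical severity (cancer > inflammation > healthy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .synth import CLASSES, SEVERITY_ORDER

SPLITS = ("train", "val", "test")


class SplitLeakageError(RuntimeError):
    """A subject (cross-subject) or frame (cross-sample) spans two splits."""


@dataclass
class EvaluationReport:
    """Frame-level accuracy plus the predicted-by-true confusion matrix."""

    accuracy: float  # percent
    confusion: pd.DataFrame  # rows predicted, columns true
    n_test: int
    per_run: list[float] = field(default_factory=list)
    mean_accuracy: float | None = None
    sd_accuracy: float | None = None
    subject_labels: dict[str, str] = field(default_factory=dict)


def split_cross_subject(
    manifest: pd.DataFrame,
    counts: Mapping[str, tuple[int, int, int]],
    seed: int = 0,
) -> pd.DataFrame:
    """Assign whole subjects to train/val/test; returns annotated copy.

    ``counts[class] = (n_train, n_val, n_test)`` subjects per class.
    Re-seeding rotates subjects between the splits, which is how repeated
    cross-subject runs emulate cross-validation.
    """
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for class_label, (n_train, n_val, n_test) in counts.items():
        subjects = np.sort(
            manifest.loc[manifest["class_label"] == class_label,
                         "subject_id"].unique())
        need = n_train + n_val + n_test
        if need > subjects.size:
            raise ValueError(
                f"requested {need} subjects of class {class_label!r}, "
                f"only {subjects.size} available")
        order = rng.permutation(subjects)
        for s in order[:n_train]:
            assignment[s] = "train"
        for s in order[n_train:n_train + n_val]:
            assignment[s] = "val"
        for s in order[n_train + n_val:need]:
            assignment[s] = "test"
    out = manifest.copy()
    out["split"] = out["subject_id"].map(assignment).fillna("unused")
    validate_split(out, mode="cross_subject")
    return out


def split_cross_sample(
    manifest: pd.DataFrame,
    train_fraction: float = 0.75,
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified-by-class random frame split; returns annotated copy.

    Per class, ``floor((1 - train_fraction) * n)`` frames go to test, the
    remainder to train, so class proportions are preserved within one
    frame.  Subjects may span splits; frames never do.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    split = np.full(len(manifest), "train", dtype=object)
    for class_label in manifest["class_label"].unique():
        idx = np.flatnonzero(
            (manifest["class_label"] == class_label).to_numpy())
        n_test = int(np.floor((1.0 - train_fraction) * idx.size))
        test_rows = rng.permutation(idx)[:n_test]
        split[test_rows] = "test"
    out = manifest.copy()
    out["split"] = split
    validate_split(out, mode="cross_sample")
    return out


def kfold_cross_sample(
    manifest: pd.DataFrame, k: int = 7, seed: int = 0
) -> pd.DataFrame:
    """Stratified k-fold frame partition; adds a ``fold`` column.

    Every frame lands in exactly one test fold; fold sizes differ by at
    most one frame within each class.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = manifest["class_label"].to_numpy()
    if k > np.bincount(pd.factorize(y)[0]).min():
        raise ValueError("k exceeds the size of the smallest class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold = np.empty(len(manifest), dtype=np.int64)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        fold[test_idx] = f
    out = manifest.copy()
    out["fold"] = fold
    return out


def validate_split(manifest: pd.DataFrame, mode: str) -> None:
    """Raise :class:`SplitLeakageError` on train/val/test leakage."""
    tagged = manifest[manifest["split"].isin(SPLITS)]
    if mode == "cross_subject":
        per_subject = tagged.groupby("subject_id")["split"].nunique()
        bad = per_subject[per_subject > 1]
        if len(bad):
            raise SplitLeakageError(
                f"subjects span multiple splits: {list(bad.index)}")
    elif mode == "cross_sample":
        per_frame = tagged.groupby(["subject_id", "frame_index"])[
            "split"].nunique()
        bad = per_frame[per_frame > 1]
        if len(bad):
            raise SplitLeakageError(
                f"frames appear in multiple splits: {list(bad.index)[:5]}")
    else:
        raise ValueError(f"unknown mode {mode!r}")


def confusion_matrix(y_true: Sequence[str],
                     y_pred: Sequence[str]) -> pd.DataFrame:
    """3x3 counts, rows = predicted class, columns = true class."""
    mat = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES),
                       dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        mat.loc[p, t] += 1
    mat.index.name = "predicted"
    mat.columns.name = "true"
    return mat


def evaluate(y_true: Sequence[str], y_pred: Sequence[str]) -> EvaluationReport:
    """Frame-level accuracy (percent) and predicted-by-true confusion."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty test set")
    conf = confusion_matrix(y_true, y_pred)
    acc = 100.0 * float(np.trace(conf.to_numpy())) / y_true.size
    return EvaluationReport(accuracy=acc, confusion=conf, n_test=y_true.size)


def evaluate_model(model, frames, y_true=None) -> EvaluationReport:
    """Predict on frames with any model exposing ``predict`` and score."""
    if y_true is None:
        y_true = [f.class_label for f in frames]
    return evaluate(y_true, model.predict(frames))


def subject_majority_label(
    predictions: Mapping[str, Sequence[str]] | pd.DataFrame,
) -> dict[str, str]:
    """Modal predicted class per subject; ties broken by severity.

    Accepts either a mapping subject -> predicted labels or a DataFrame
    with ``subject_id`` and ``predicted`` columns.  The tie-break order is
    cancer > inflammation > healthy (clinically conservative).
    """
    if isinstance(predictions, pd.DataFrame):
        grouped = {s: g["predicted"].tolist()
                   for s, g in predictions.groupby("subject_id")}
    else:
        grouped = {s: list(v) for s, v in predictions.items()}
    out: dict[str, str] = {}
    for subject, preds in grouped.items():
        if len(preds) == 0:
            raise ValueError(f"subject {subject!r} has no predictions")
        counts = pd.Series(preds).value_counts()
        best = counts.max()
        tied = set(counts[counts == best].index)
        out[subject] = next(c for c in SEVERITY_ORDER if c in tied)
    return out


def repeated_runs(
    run_fn: Callable[[int], float],
    n_runs: int = 10,
    base_seed: int = 0,
) -> tuple[np.ndarray, float, float]:
    """Run a seeded pipeline n times; report accuracies, mean, sample sd."""
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    seeds = [int(s % (2 ** 31)) for s in
             np.random.SeedSequence(base_seed).generate_state(n_runs)]
    accs = np.array([float(run_fn(s)) for s in seeds])
    return accs, float(accs.mean()), float(accs.std(ddof=1))
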