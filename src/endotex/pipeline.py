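"""End-to-end pipeline helpers shared by the CLI, the test-suite and the
reproduction script: QC -> split -> featurize -> train -> evaluate."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import cnn, lbp, qc
from .evaluation import EvaluationReport, evaluate
from .synth import Frame, frames_to_manifest


@dataclass
class PreparedDataset:
    """QC-kept frames with an aligned manifest (and optional LBP features)."""

    frames: list[Frame]
    manifest: pd.DataFrame
    features: sp.csr_matrix | None = None

    @property
    def labels(self) -> np.ndarray:
        return self.manifest["class_label"].to_numpy()


def prepare(frames: Sequence[Frame], threshold: float = -5.0,
            featurize: bool = False) -> PreparedDataset:
    """Apply QC, rebuild the manifest over kept frames, optionally featurize."""
    kept, _, _ = qc.filter_frames(frames, threshold)
    manifest = frames_to_manifest(kept).reset_index(drop=True)
    feats = lbp.featurize_frames(kept) if featurize else None
    return PreparedDataset(frames=list(kept), manifest=manifest,
                           features=feats)


def run_lbp_svm(ds: PreparedDataset, split: pd.Series,
                seed: int = 0) -> tuple[EvaluationReport, lbp.LBPSVMModel]:
    """Train LBP+SVM on the 'train' rows of a split, score the 'test' rows."""
    if ds.features is None:
        ds.features = lbp.featurize_frames(ds.frames)
    split = np.asarray(split)
    train_mask = split == "train"
    test_mask = split == "test"
    model = lbp.train_lbp_svm(ds.features[train_mask],
                              ds.labels[train_mask], seed=seed)
    pred = model.predict_features(ds.features[test_mask])
    return evaluate(ds.labels[test_mask], pred), model


def run_scratch_cnn(
    ds: PreparedDataset,
    split: pd.Series,
    train_cfg: cnn.TrainConfig,
    val_fraction: float = 1.0 / 6.0,
) -> tuple[EvaluationReport, cnn.CNNClassifier]:
    """Train the scratch CNN on a split and score the 'test' rows.

    If the split has no 'val' rows, a validation set of ``val_fraction`` of
    the training rows is carved out (stratified is unnecessary at these
    sizes; the carve-out is seeded).
    """
    split = np.asarray(split, dtype=object).copy()
    rng = np.random.default_rng(train_cfg.seed)
    if not np.any(split == "val"):
        train_rows = np.flatnonzero(split == "train")
        n_val = max(1, int(round(val_fraction * train_rows.size)))
        split[rng.permutation(train_rows)[:n_val]] = "val"

    x = cnn.frames_to_tensor(ds.frames, train_cfg.input_size)
    y = cnn.labels_to_indices(ds.labels)
    tr, va, te = (np.flatnonzero(split == s) for s in ("train", "val", "test"))
    net = cnn.build_scratch_model(input_size=train_cfg.input_size,
                                  seed=train_cfg.seed)
    history = cnn.train_model(net, x[tr], y[tr], x[va], y[va], train_cfg)
    model = cnn.CNNClassifier(net=net, input_size=train_cfg.input_size,
                              history=history)
    probs = net.predict_proba(x[te])
    pred = np.array([cnn.CLASSES[i] for i in probs.argmax(axis=1)])
    return evaluate(ds.labels[te], pred), model
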