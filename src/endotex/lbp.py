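"""Local binary pattern texture features and the linear-SVM classifier.

The LBP code of a pixel is the 8-bit word obtained by thresholding its
eight 3x3 neighbors against the center value,

    LBP(x, y) = sum_{n=0..7} 2^n * s(i_n - i_{x,y}),   s(d) = 1 if d >= 0 else 0,

so ties (neighbor equal to center) contribute a 1 bit.  The neighbor order
is frozen as clockwise from the top-left neighbor:

    n:       0  1  2  3  4  5  6  7
    offset: (-1,-1) (-1,0) (-1,1) (0,1) (1,1) (1,0) (1,-1) (0,-1)

(any fixed order is equally informative — all bits carry the same
significance level — but one must be pinned for reproducible codes).
Because only the intensity *order* within each neighborhood matters, the
code map is invariant under any strictly increasing gray-scale remap.

An image's feature vector is the concatenation of per-patch 256-bin code
histograms: the code map (computed globally, border pixels skipped) is
tiled into non-overlapping N x N patches (default N=8, about one healthy
vesicular crypt), remainder rows/columns dropped, patches in row-major
order.  Histograms are raw counts; a linear SVM classifies the vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.svm import LinearSVC

from .synth import Frame

#: (row, col) offsets of the 8 neighbors, clockwise from top-left; index n
#: is weighted 2^n in the code.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)

N_BINS = 256


@dataclass(frozen=True)
class LBPConfig:
    """Patch-histogram feature configuration (8 neighbors, 256 bins fixed)."""

    patch_size: int = 8

    def __post_init__(self) -> None:
        if self.patch_size < 2:
            raise ValueError("patch_size must be >= 2")


def lbp_code(center: float, neighbors: Sequence[float]) -> int:
    """LBP code of a single pixel from its 8 neighbors in canonical order."""
    if len(neighbors) != 8:
        raise ValueError("exactly 8 neighbor values are required")
    code = 0
    for n, value in enumerate(neighbors):
        if value >= center:
            code |= 1 << n
    return code


def lbp_map(frame: Frame | np.ndarray) -> np.ndarray:
    """Code map over all interior pixels; output shape (H-2, W-2).

    Border pixels are skipped (no padding: padded comparisons would
    fabricate neighbors).
    """
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    if pixels.ndim != 2 or pixels.shape[0] < 3 or pixels.shape[1] < 3:
        raise ValueError("frame must be a 2-D array of at least 3x3 pixels")
    h, w = pixels.shape
    center = pixels[1:h - 1, 1:w - 1]
    codes = np.zeros((h - 2, w - 2), dtype=np.uint8)
    for n, (di, dj) in enumerate(NEIGHBOR_OFFSETS):
        neighbor = pixels[1 + di:h - 1 + di, 1 + dj:w - 1 + dj]
        codes |= (neighbor >= center).astype(np.uint8) << n
    return codes


def _patch_histograms(codes: np.ndarray, patch: int) -> np.ndarray:
    """Concatenated per-patch 256-bin histograms, row-major patch order."""
    hp, wp = codes.shape
    n_rows, n_cols = hp // patch, wp // patch
    if n_rows < 1 or n_cols < 1:
        raise ValueError("code map smaller than one patch")
    trimmed = codes[: n_rows * patch, : n_cols * patch]
    row_ids = np.arange(n_rows * patch) // patch
    col_ids = np.arange(n_cols * patch) // patch
    patch_ids = row_ids[:, None] * n_cols + col_ids[None, :]
    flat = patch_ids.astype(np.int64) * N_BINS + trimmed.astype(np.int64)
    counts = np.bincount(flat.ravel(), minlength=n_rows * n_cols * N_BINS)
    return counts


def extract_features(frame: Frame | np.ndarray,
                     cfg: LBPConfig = LBPConfig()) -> np.ndarray:
    """Feature vector of one frame: length (⌊(H-2)/N⌋·⌊(W-2)/N⌋) x 256."""
    return _patch_histograms(lbp_map(frame), cfg.patch_size)


def featurize_frames(frames: Sequence[Frame],
                     cfg: LBPConfig = LBPConfig()) -> sp.csr_matrix:
    """Stack feature vectors of many frames into a sparse CSR matrix.

    Patch histograms are mostly zero (a patch of N^2 pixels can populate at
    most N^2 of its 256 bins), so sparse storage keeps desk-scale feature
    matrices in memory.
    """
    data: list[np.ndarray] = []
    indices: list[np.ndarray] = []
    indptr = [0]
    n_features = None
    for fr in frames:
        vec = extract_features(fr, cfg)
        if n_features is None:
            n_features = vec.size
        elif vec.size != n_features:
            raise ValueError("frames produce inconsistent feature lengths")
        nz = np.flatnonzero(vec)
        indices.append(nz.astype(np.int32))
        data.append(vec[nz].astype(np.float32))
        indptr.append(indptr[-1] + nz.size)
    return sp.csr_matrix(
        (np.concatenate(data), np.concatenate(indices), np.array(indptr)),
        shape=(len(frames), int(n_features)),
    )


@dataclass
class LBPSVMModel:
    """A trained LBP + linear-SVM classifier."""

    cfg: LBPConfig
    svc: LinearSVC

    def predict_features(self, features: sp.spmatrix | np.ndarray) -> np.ndarray:
        return self.svc.predict(features)

    def predict(self, frames: Sequence[Frame]) -> np.ndarray:
        return self.predict_features(featurize_frames(frames, self.cfg))


def train_lbp_svm(
    features: sp.spmatrix | np.ndarray,
    labels: Sequence[str],
    C: float = 1.0,
    cfg: LBPConfig = LBPConfig(),
    seed: int = 0,
) -> LBPSVMModel:
    """Fit a one-vs-rest linear SVM (hinge loss, C=1 by default).

    Deterministic given inputs and seed (the dual coordinate-descent solver
    shuffles with ``seed``).
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("at least 2 classes are required")
    svc = LinearSVC(C=C, loss="hinge", multi_class="ovr",
                    random_state=seed, max_iter=4000, tol=1e-2)
    svc.fit(features, labels)
    return LBPSVMModel(cfg=cfg, svc=svc)
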