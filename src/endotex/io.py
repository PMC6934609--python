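"""Manifest and frame IO: 8-bit grayscale PNGs plus a CSV manifest."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .synth import Frame


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    required = {"path", "subject_id", "class_label", "frame_index"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    if "is_artifact" in manifest.columns:
        manifest["is_artifact"] = manifest["is_artifact"].astype(bool)
    return manifest


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False)


def load_frames(manifest: pd.DataFrame, root: str | Path) -> list[Frame]:
    """Materialize Frame objects for every manifest row."""
    root = Path(root)
    frames: list[Frame] = []
    for row in manifest.itertuples(index=False):
        pixels = np.asarray(iio.imread(root / row.path))
        if pixels.ndim == 3:  # tolerate RGB PNGs: take one channel
            pixels = pixels[..., 0]
        frames.append(Frame(
            pixels=pixels.astype(np.uint8),
            subject_id=str(row.subject_id),
            class_label=str(row.class_label),
            frame_index=int(row.frame_index),
            is_artifact=bool(getattr(row, "is_artifact", False)),
            scene_id=int(getattr(row, "scene_id", -1)),
        ))
    return frames
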