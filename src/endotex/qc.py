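"""Informative-frame quality control via gray-level-histogram skewness.

Saturated frames pile nearly all their mass at the top of the intensity
range with a thin dark tail, giving a strongly negative (left-skewed)
histogram skewness; frames with skewness at or below an empirical threshold
(default -5) are discarded before training and inference.

The statistic is the population (uncorrected) Fisher-Pearson standardized
third moment g1 = m3 / m2^(3/2), computed over raw pixel values — which is
mathematically identical to the count-weighted moment of the 256-bin
gray-level histogram, without any binning choices.

Note a literal consequence of the keep-rule "skewness > threshold":
underexposed frames have strongly *positive* skewness and therefore pass.
The rule is implemented as stated; see docs/methods.md for discussion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .synth import Frame

DEFAULT_SKEWNESS_THRESHOLD = -5.0


@dataclass(frozen=True)
class QCResult:
    """Outcome of the skewness test for one frame."""

    skewness: float | None  # None when undefined (zero variance)
    keep: bool
    reason: str  # "kept" | "low_skewness" | "zero_variance"


def histogram_skewness(frame: Frame | np.ndarray) -> float | None:
    """Population Fisher-Pearson skewness g1 of the pixel intensities.

    Returns ``None`` (undefined) for zero-variance frames.  Raises on
    frames with fewer than 2 pixels.
    """
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    x = pixels.astype(np.float64).ravel()
    if x.size < 2:
        raise ValueError("frame must contain at least 2 pixels")
    d = x - x.mean()
    m2 = np.mean(d ** 2)
    if m2 == 0.0:
        return None
    m3 = np.mean(d ** 3)
    return float(m3 / m2 ** 1.5)


def filter_frames(
    frames: Sequence[Frame],
    threshold: float = DEFAULT_SKEWNESS_THRESHOLD,
) -> tuple[list[Frame], list[Frame], list[QCResult]]:
    """Partition frames into (kept, discarded) by the skewness test.

    A frame is kept iff its skewness is defined and strictly greater than
    ``threshold``.  Zero-variance frames are discarded with reason
    ``zero_variance``.  Input order is preserved within both outputs.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    kept: list[Frame] = []
    discarded: list[Frame] = []
    results: list[QCResult] = []
    for fr in frames:
        g1 = histogram_skewness(fr)
        if g1 is None:
            results.append(QCResult(None, False, "zero_variance"))
            discarded.append(fr)
        elif g1 > threshold:
            results.append(QCResult(g1, True, "kept"))
            kept.append(fr)
        else:
            results.append(QCResult(g1, False, "low_skewness"))
            discarded.append(fr)
    return kept, discarded, results
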