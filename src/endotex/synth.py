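"""Synthetic endomicroscopy-like frame sequences.

Confocal laser endomicroscopy of the colon wall shows a field of vesicular
crypts: in healthy mucosa a quasi-regular lattice of dark round crypt lumens
with bright fluorescent rims; under inflammation the lumens enlarge and grow
irregular while the background signal rises; under dysplasia ("cancer") the
lattice breaks down into disordered, elongated and fused structures.  Frames
are acquired at video rate while the probe moves slowly, so consecutive
frames are near-duplicates of the same scene, and a fraction of frames are
non-informative (sensor saturation, signal loss).

This module renders that statistical structure procedurally: per-class
lumen geometry, per-subject appearance effects (brightness offset, lattice
spacing, lattice rotation), temporal redundancy groups (one base scene,
several jittered noisy exposures), and saturated/underexposed artifact
frames.  It makes no attempt at photorealism — only the texture statistics
that the downstream classifiers exploit are modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CLASSES: tuple[str, ...] = ("healthy", "inflammation", "cancer")

#: Severity order used for deterministic tie-breaking in majority votes.
SEVERITY_ORDER: tuple[str, ...] = ("cancer", "inflammation", "healthy")

MANIFEST_COLUMNS = [
    "path",
    "subject_id",
    "class_label",
    "frame_index",
    "is_artifact",
    "scene_id",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic acquisition campaign.

    Defaults describe the desk-scale cohort the test-suite and the
    reproduction script run on: 9 subjects per class, 75 texture frames per
    subject (~2,000 informative frames), frames of 290 rows x 292 columns,
    5 near-duplicate frames per base scene, and ~5% artifact frames.
    """

    #: either one count for every class or a mapping class -> count, so
    #: unequal cohorts (as in real campaigns) are representable
    n_subjects_per_class: int | Mapping[str, int] = 9
    frames_per_subject: int = 75
    height: int = 290
    width: int = 292
    artifact_fraction: float = 0.05
    redundancy_group_size: int = 5
    jitter_px: int = 2
    noise_sd: float = 8.0
    seed: int = 0

    def subjects_for(self, class_label: str) -> int:
        if isinstance(self.n_subjects_per_class, int):
            return self.n_subjects_per_class
        return int(self.n_subjects_per_class.get(class_label, 0))

    def __post_init__(self) -> None:
        for name in ("frames_per_subject", "height", "width",
                     "redundancy_group_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        counts = ([self.n_subjects_per_class]
                  if isinstance(self.n_subjects_per_class, int)
                  else list(self.n_subjects_per_class.values()))
        if not counts or min(counts) < 1:
            raise ValueError("n_subjects_per_class must be >= 1")
        if not (0.0 <= self.artifact_fraction < 1.0):
            raise ValueError("artifact_fraction must be in [0, 1)")
        if self.jitter_px < 0:
            raise ValueError("jitter_px must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class Frame:
    """One grayscale frame plus its acquisition metadata."""

    pixels: np.ndarray  # uint8, shape (height, width)
    subject_id: str
    class_label: str
    frame_index: int
    is_artifact: bool = False
    scene_id: int = -1  # base-scene ordinal within the subject; -1 for artifacts


# Per-class texture parameters.  Lumen spacing is ~8-16 px so an 8x8 patch
# spans roughly one healthy crypt; inflammation enlarges lumens and raises
# background signal; cancer elongates, disorders, and fuses them.
_CLASS_TEXTURE = {
    "healthy": dict(spacing=12.0, sigma=1.8, depth=70.0, rim=28.0,
                    pos_jitter=0.08, aniso=(1.0, 1.15), radius_jitter=0.10,
                    background=125.0),
    "inflammation": dict(spacing=15.0, sigma=3.4, depth=85.0, rim=14.0,
                         pos_jitter=0.25, aniso=(1.0, 1.5), radius_jitter=0.45,
                         background=152.0),
    "cancer": dict(spacing=13.0, sigma=2.1, depth=75.0, rim=22.0,
                   pos_jitter=0.55, aniso=(2.5, 4.2), radius_jitter=0.35,
                   background=112.0),
}


@dataclass(frozen=True)
class _SubjectEffect:
    """Systematic per-subject appearance variation.

    Drawn once per subject: makes frames of the same class differ between
    subjects, so generalizing to unseen subjects is strictly harder than
    generalizing to unseen frames of known subjects.
    """

    brightness: float      # additive intensity offset
    spacing_mult: float    # lattice spacing multiplier
    rotation: float        # lattice rotation, radians


def _draw_subject_effect(rng: np.random.Generator) -> _SubjectEffect:
    return _SubjectEffect(
        brightness=float(rng.uniform(-18.0, 18.0)),
        spacing_mult=float(rng.uniform(0.85, 1.20)),
        rotation=float(rng.uniform(0.0, np.pi)),
    )


def _render_scene(rng: np.random.Generator, height: int, width: int,
                  class_label: str, effect: _SubjectEffect) -> np.ndarray:
    """Render one noiseless base scene on a canvas (float64)."""
    p = _CLASS_TEXTURE[class_label]
    spacing = p["spacing"] * effect.spacing_mult * rng.uniform(0.92, 1.08)
    background = (p["background"] + effect.brightness + rng.uniform(-6.0, 6.0))
    img = np.full((height, width), background, dtype=np.float64)

    # Rotated lattice covering the canvas with margin.
    c, s = np.cos(effect.rotation), np.sin(effect.rotation)
    margin = 3.0 * spacing
    # Enumerate lattice indices whose points can fall inside the canvas.
    reach = int(np.ceil((np.hypot(height, width) / 2 + margin) / spacing)) + 1
    cy, cx = height / 2.0, width / 2.0
    ii, jj = np.meshgrid(np.arange(-reach, reach + 1),
                         np.arange(-reach, reach + 1), indexing="ij")
    ys = cy + spacing * (ii * c - jj * s)
    xs = cx + spacing * (ii * s + jj * c)
    inside = ((ys > -margin) & (ys < height + margin)
              & (xs > -margin) & (xs < width + margin))
    ys, xs = ys[inside], xs[inside]

    jit = p["pos_jitter"] * spacing
    ys = ys + rng.normal(0.0, jit, ys.shape)
    xs = xs + rng.normal(0.0, jit, xs.shape)

    depth, rim = p["depth"], p["rim"]
    for y0, x0 in zip(ys, xs):
        sig_minor = p["sigma"] * (1.0 + p["radius_jitter"] * rng.standard_normal())
        sig_minor = max(sig_minor, 0.8)
        ratio = rng.uniform(*p["aniso"])
        sig_major = sig_minor * ratio
        theta = rng.uniform(0.0, np.pi)
        half = int(np.ceil(3.0 * sig_major * 1.9)) + 1
        iy0, iy1 = int(np.floor(y0)) - half, int(np.floor(y0)) + half + 1
        ix0, ix1 = int(np.floor(x0)) - half, int(np.floor(x0)) + half + 1
        iy0c, iy1c = max(iy0, 0), min(iy1, height)
        ix0c, ix1c = max(ix0, 0), min(ix1, width)
        if iy0c >= iy1c or ix0c >= ix1c:
            continue
        yy, xx = np.meshgrid(np.arange(iy0c, iy1c) - y0,
                             np.arange(ix0c, ix1c) - x0, indexing="ij")
        ct, st = np.cos(theta), np.sin(theta)
        u = yy * ct + xx * st
        v = -yy * st + xx * ct
        d2 = (u / sig_major) ** 2 + (v / sig_minor) ** 2
        lumen = np.exp(-0.5 * d2)
        halo = np.exp(-0.5 * d2 / (1.9 ** 2))
        # Bright fluorescent rim around a dark lumen: the halo adds signal,
        # the sharper lumen profile carves the dark center out of it.
        img[iy0c:iy1c, ix0c:ix1c] += rim * halo - (depth + rim) * lumen
    return img


def generate_subject(class_label: str, subject_seed: int,
                     cfg: SynthConfig) -> list[Frame]:
    """Generate one subject's informative-frame sequence.

    Frames come in redundancy groups: each group shares one base scene and
    differs only by a small translation (<= ``cfg.jitter_px``) and fresh
    additive Gaussian noise, emulating video-rate near-duplicates.  Subject
    identity (brightness, lattice spacing, rotation) is drawn from
    ``subject_seed`` so repeated calls are bit-identical.
    """
    if class_label not in CLASSES:
        raise ValueError(f"unknown class_label {class_label!r}")
    rng = np.random.default_rng(subject_seed)
    effect = _draw_subject_effect(rng)
    pad = cfg.jitter_px
    n_scenes = -(-cfg.frames_per_subject // cfg.redundancy_group_size)

    frames: list[Frame] = []
    idx = 0
    for scene_id in range(n_scenes):
        canvas = _render_scene(rng, cfg.height + 2 * pad, cfg.width + 2 * pad,
                               class_label, effect)
        group = min(cfg.redundancy_group_size, cfg.frames_per_subject - idx)
        for _ in range(group):
            dy = int(rng.integers(-cfg.jitter_px, cfg.jitter_px + 1)) if pad else 0
            dx = int(rng.integers(-cfg.jitter_px, cfg.jitter_px + 1)) if pad else 0
            view = canvas[pad + dy:pad + dy + cfg.height,
                          pad + dx:pad + dx + cfg.width]
            noisy = view + rng.normal(0.0, cfg.noise_sd, view.shape)
            pixels = np.clip(noisy, 0, 255).astype(np.uint8)
            frames.append(Frame(pixels=pixels, subject_id="",
                                class_label=class_label, frame_index=idx,
                                is_artifact=False, scene_id=scene_id))
            idx += 1
    return frames


def generate_artifact_frame(kind: str, seed: int, cfg: SynthConfig) -> Frame:
    """Generate one non-informative frame.

    ``saturated``: >= 95% of pixels at intensity >= 250 with a small dark
    remainder — a strongly left-skewed gray-level histogram, the regime the
    skewness filter targets.  ``underexposed``: the mirror image, >= 95% of
    pixels <= 5 with a few bright specks (strongly right-skewed).
    """
    rng = np.random.default_rng(seed)
    h, w = cfg.height, cfg.width
    if kind == "saturated":
        img = np.full((h, w), 255.0)
        img -= np.abs(rng.normal(0.0, 1.2, img.shape))
        minority_value = 5.0
    elif kind == "underexposed":
        img = np.full((h, w), 2.0)
        img += np.abs(rng.normal(0.0, 1.2, img.shape))
        minority_value = 210.0
    else:
        raise ValueError(f"unknown artifact kind {kind!r}")

    # A few blobs of the opposite regime covering ~2% of the frame.
    target = 0.02 * h * w
    covered = 0.0
    while covered < target:
        r = float(rng.uniform(6.0, 14.0))
        y0 = float(rng.uniform(0, h))
        x0 = float(rng.uniform(0, w))
        yy, xx = np.ogrid[:h, :w]
        mask = (yy - y0) ** 2 + (xx - x0) ** 2 < r ** 2
        img[mask] = minority_value + rng.normal(0.0, 2.0, int(mask.sum()))
        covered += float(mask.sum())
    pixels = np.clip(img, 0, 255).astype(np.uint8)
    return Frame(pixels=pixels, subject_id="", class_label="", frame_index=-1,
                 is_artifact=True, scene_id=-1)


def _subject_seed(cfg: SynthConfig, class_idx: int, subj_idx: int) -> int:
    ss = np.random.SeedSequence([cfg.seed, class_idx, subj_idx])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_frames(cfg: SynthConfig) -> list[Frame]:
    """Generate the full in-memory dataset described by ``cfg``.

    Artifact frames (alternating saturated/underexposed regimes, random
    choice) are interleaved into each subject's sequence so that they make
    up approximately ``cfg.artifact_fraction`` of the subject's frames;
    frame indices are re-assigned after interleaving.  Artifact frames keep
    the subject's class label (they occur mid-acquisition) but carry
    ``is_artifact=True`` ground truth.
    """
    all_frames: list[Frame] = []
    af = cfg.artifact_fraction
    n_art = int(round(af * cfg.frames_per_subject / (1.0 - af))) if af > 0 else 0
    for class_idx, class_label in enumerate(CLASSES):
        for subj_idx in range(cfg.subjects_for(class_label)):
            seed = _subject_seed(cfg, class_idx, subj_idx)
            subject_id = f"{class_label[:3]}_{subj_idx:02d}"
            frames = generate_subject(class_label, seed, cfg)
            rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, class_idx, subj_idx, 7]))
            for k in range(n_art):
                kind = "saturated" if rng.random() < 0.5 else "underexposed"
                art = generate_artifact_frame(
                    kind, int(rng.integers(2 ** 31)), cfg)
                art.class_label = class_label
                pos = int(rng.integers(0, len(frames) + 1))
                frames.insert(pos, art)
            for i, fr in enumerate(frames):
                fr.subject_id = subject_id
                fr.frame_index = i
            all_frames.extend(frames)
    return all_frames


def frames_to_manifest(frames: Sequence[Frame],
                       paths: Iterable[str] | None = None) -> pd.DataFrame:
    """Tabulate frame metadata; row order matches the frame sequence."""
    if paths is None:
        paths = ["" for _ in frames]
    return pd.DataFrame(
        {
            "path": list(paths),
            "subject_id": [f.subject_id for f in frames],
            "class_label": [f.class_label for f in frames],
            "frame_index": [f.frame_index for f in frames],
            "is_artifact": [f.is_artifact for f in frames],
            "scene_id": [f.scene_id for f in frames],
        }
    )


def generate_dataset(cfg: SynthConfig, out_dir: str | Path) -> pd.DataFrame:
    """Generate the dataset, write 8-bit PNG frames and a CSV manifest.

    Returns the manifest (also written to ``out_dir/manifest.csv``).
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = generate_frames(cfg)
    paths = []
    for fr in frames:
        name = f"{fr.subject_id}_{fr.frame_index:04d}.png"
        iio.imwrite(out / name, fr.pixels)
        paths.append(name)
    manifest = frames_to_manifest(frames, paths)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
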