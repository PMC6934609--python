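import numpy as np
import pytest

from endotex import SynthConfig, generate_frames


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """A small but structured cohort: 3 subjects/class, 20 frames each."""
    return SynthConfig(n_subjects_per_class=3, frames_per_subject=20,
                       artifact_fraction=0.1, seed=11)


@pytest.fixture(scope="session")
def small_frames(small_cfg):
    return generate_frames(small_cfg)


@pytest.fixture(scope="session")
def small_texture_frames(small_frames):
    return [f for f in small_frames if not f.is_artifact]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
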