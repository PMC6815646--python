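"""Shared fixtures: a small synthetic study and its rendered image sets.

The session-scoped image fixture mirrors the package's default study
conditions (two 40-minute recordings, eight contractions each, 20 dB SNR)
at the scaled CNN's 128-px raster; building it once keeps the training
tests affordable.
"""

from __future__ import annotations

import numpy as np
import pytest

from ehgpipe.pipeline import PipelineConfig, build_image_sets
from ehgpipe.synthetic import SyntheticConfig, generate_record


STUDY_SEED = 42


@pytest.fixture(scope="session")
def study_config() -> PipelineConfig:
    return PipelineConfig(
        synthetic=SyntheticConfig(n_recordings=2, seed=STUDY_SEED),
        epochs=10,
    )


@pytest.fixture(scope="session")
def image_sets(study_config):
    """(60 s images, positional images) for the two-recording synthetic study."""
    full, positional, manifest = build_image_sets(study_config)
    return full, positional, manifest


@pytest.fixture(scope="session")
def small_record():
    """One compact synthetic record with its ground truth."""
    cfg = SyntheticConfig(
        n_recordings=1,
        n_contractions_per_recording=4,
        record_duration=1400.0,
        seed=7,
    )
    return generate_record(cfg, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
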