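"""Shared fixtures: small reusable synthetic data, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from icemotion import detector, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20150517)


@pytest.fixture(scope="session")
def falcon_like():
    """Default Falcon II-like detector model: DQE(0) = 0.5."""
    return detector.DetectorModel()


@pytest.fixture(scope="session")
def noise_movie_256(falcon_like):
    """Specimen-free movie at the reference dose: 24 frames of 256^2 px.

    Session-scoped: several statistical-background tests share it.
    """
    cfg = simulate.SimConfig(
        n_pixels=256, n_frames=24, dose_per_frame=2.33, detector=falcon_like, seed=7
    )
    return simulate.noise_movie(cfg), cfg


@pytest.fixture(scope="session")
def nps_256(falcon_like):
    return detector.evaluate_nps((256, 256), falcon_like)
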