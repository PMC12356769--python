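"""Shared fixtures: cached synthetic fields of view.

Scene generation is the dominant cost of the suite, so generated videos are
cached per parameter set for the session. Everything is seeded; no fixture
touches the filesystem except through tmp_path.
"""

from __future__ import annotations

import numpy as np
import pytest

from pixroi import RunConfig
from pixroi.synthetic import generate_video, random_scene

_CACHE: dict = {}


@pytest.fixture(scope="session")
def make_field():
    """Factory returning (dapi, sytox, truth, scene) for a parameter set,
    cached across the session."""

    def _make(**kwargs):
        key = tuple(sorted(kwargs.items()))
        if key not in _CACHE:
            scene = random_scene(**kwargs)
            dapi, sytox, truth = generate_video(scene)
            _CACHE[key] = (dapi, sytox, truth, scene)
        return _CACHE[key]

    return _make


@pytest.fixture(scope="session")
def default_field(make_field):
    """A mid-sized field with both lytic fates at default noise."""
    return make_field(
        n_netotic=3, n_necrotic=2, height=320, width=320, n_frames=61, seed=11
    )


@pytest.fixture()
def cfg():
    return RunConfig()
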