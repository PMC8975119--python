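"""Shared fixtures: small-geometry catalogs, pools and designs.

Expensive artifacts are session-scoped.  The small geometry (640x512
images, 117-px targets, 177-px ring radius) preserves every structural
relation of the full-size setup (disk containment, 2x2 tiling at 256 px)
while keeping image operations cheap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gazestruct import stimgen, synth
from gazestruct.design import build_design

SMALL = dict(width=640, height=512, target_diameter=117, ring_radius=177.0)


@pytest.fixture(scope="session")
def small_catalog():
    return synth.synth_catalog(
        seed=11, size=(SMALL["height"], SMALL["width"]), patch_diameter=SMALL["target_diameter"]
    )


@pytest.fixture(scope="session")
def small_ring():
    return stimgen.ring_locations(
        SMALL["width"], SMALL["height"], SMALL["ring_radius"],
        target_diameter=SMALL["target_diameter"],
    )


@pytest.fixture(scope="session")
def small_pool(small_catalog, small_ring):
    # screening off: design/gaze tests need supply, not salience
    return stimgen.build_pool(
        small_catalog, small_ring, seed=5, n_candidates=400, screen=False
    )


@pytest.fixture(scope="session")
def small_design(small_pool):
    return build_design(small_pool, seed=9)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
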