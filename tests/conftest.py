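"""Shared fixtures: schedules and small seeded phantoms.

Everything is generated programmatically; expensive fixtures are
session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

import cestquant as cq


@pytest.fixture(scope="session")
def schedule():
    return cq.build_default_schedule()


@pytest.fixture(scope="session")
def small_phantom_cfg():
    """A reduced phantom for volume-level tests: 16x16x4, tumor radius 3."""
    return cq.PhantomConfig(
        grid_shape=(16, 16, 4),
        tumor_center=(4.0, 8.0, 2.0),
        tumor_radius=3.0,
        gm_rim_voxels=2,
        noise_sigma=0.0,
        b0_ramp_ppm=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_noiseless_phantom(small_phantom_cfg, schedule):
    return cq.generate_phantom(small_phantom_cfg, schedule)


@pytest.fixture(scope="session")
def small_noiseless_zvol(small_noiseless_phantom, small_phantom_cfg):
    raw, _, _ = small_noiseless_phantom
    mask = np.ones(small_phantom_cfg.grid_shape, dtype=bool)
    return cq.normalize(raw, mask)


@pytest.fixture(scope="session")
def small_noiseless_fits(small_noiseless_zvol):
    return cq.fit_volume(small_noiseless_zvol)
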