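"""Shared fixtures: wavelength grids, endmembers, rendered scenes, and the
full simulated two-sided scan campaign (computed once per session)."""

from __future__ import annotations

import numpy as np
import pytest

import cocoahsi as chs
from cocoahsi.synthetic_data import SceneParams


@pytest.fixture(scope="session")
def wavelengths():
    return chs.default_wavelength_grid()


@pytest.fixture(scope="session")
def endmembers(wavelengths):
    return chs.build_endmembers(wavelengths)


@pytest.fixture(scope="session")
def small_panel():
    """One batch of 10 beans."""
    return chs.sample_reference_panel(1, 10, seed=3)


@pytest.fixture(scope="session")
def noiseless_scene(small_panel, endmembers):
    return chs.render_scene(small_panel, endmembers, SceneParams.noiseless(), seed=5)


@pytest.fixture(scope="session")
def noisy_scene(small_panel, endmembers):
    return chs.render_scene(small_panel, endmembers, SceneParams(), seed=5)


@pytest.fixture(scope="session")
def noiseless_campaign():
    """The full 17 batches x 10 beans x 2 sides study, rendered noiselessly.

    Returns (panel, spectra_table); 340 rows.
    """
    return chs.simulate_dataset(17, 10, scene_params=SceneParams.noiseless(), seed=0)


@pytest.fixture(scope="session")
def noisy_campaign():
    """The same study under the default noise configuration."""
    return chs.simulate_dataset(17, 10, scene_params=SceneParams(), seed=0)


def random_cube(rng, lines=4, samples=5, bands=6, dtype=np.float64):
    data = rng.normal(size=(lines, samples, bands)).astype(dtype)
    wl = np.linspace(1000.0, 1000.0 + 6.0 * (bands - 1), bands)
    return chs.Hypercube(data=data, wavelengths=wl)
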