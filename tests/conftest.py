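"""Shared fixtures: small synthetic scenes reused across test modules."""

import numpy as np
import pytest

from laurdangp.gp import compute_gp
from laurdangp.synthetic import (
    PIXEL_SIZE_UM,
    build_ground_truth,
    group_presets,
    render_dual_channel,
)


@pytest.fixture(scope="session")
def presets():
    return group_presets()


@pytest.fixture(scope="session")
def dm_scene(presets):
    """One noise-free DM field of view: truth, image and GP map."""
    truth = build_ground_truth(
        presets["DM"], image_shape=(256, 256), n_cells=6, seed=7, subject_offset=0.0
    )
    image = render_dual_channel(truth, noise=False, seed=7)
    return {"truth": truth, "image": image, "gp_map": compute_gp(image)}


@pytest.fixture(scope="session")
def dm_scene_noisy(presets):
    """Same construction with Poisson noise on."""
    truth = build_ground_truth(
        presets["DM"], image_shape=(256, 256), n_cells=6, seed=7, subject_offset=0.0
    )
    image = render_dual_channel(truth, noise=True, seed=7)
    return {"truth": truth, "image": image, "gp_map": compute_gp(image)}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def pixel_size():
    return PIXEL_SIZE_UM
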