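"""Shared fixtures: seeded synthetic slides and a trained cascade model.

Everything is generated at test time; session scope amortizes the heavier
renders and the SVM training across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from ki67hotspot import color, synthetic, tissue
from ki67hotspot.pipeline import PipelineConfig, train_default_model

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160)


@pytest.fixture(scope="session")
def cascade_model():
    """Cascade trained on generated texture patches (seeded)."""
    return train_default_model(PipelineConfig(seed=1), n_per_class=60)


@pytest.fixture(scope="session")
def clean_slide():
    """Artifact-free slide at realistic nuclear density."""
    spec = synthetic.SyntheticSpec(
        width_px=512, height_px=512, n_pos_cells=200, n_neg_cells=1000, seed=9
    )
    return synthetic.generate_slide(spec)


@pytest.fixture(scope="session")
def artifact_slide():
    """Slide with one hemorrhage blob, one fold band, one vessel wall and
    a few near-black artifact pixels."""
    spec = synthetic.SyntheticSpec(
        width_px=512,
        height_px=512,
        n_pos_cells=200,
        n_neg_cells=1000,
        hemorrhage_blobs=[((170, 170), 110)],
        fold_bands=[([(320, 380), (430, 460)], 40)],
        vessel_walls=[([(80, 400), (200, 430), (300, 390)], 5)],
        artifact_pixels=30,
        seed=5,
    )
    return synthetic.generate_slide(spec)


@pytest.fixture(scope="session")
def clean_planes(clean_slide):
    return color.color_planes(clean_slide[0].pixels)


@pytest.fixture(scope="session")
def artifact_planes(artifact_slide):
    return color.color_planes(artifact_slide[0].pixels)


@pytest.fixture(scope="session")
def clean_tissue_mask(clean_slide):
    return tissue.build_specimen_map(clean_slide[0]).mask


@pytest.fixture(scope="session")
def artifact_tissue_mask(artifact_slide):
    return tissue.build_specimen_map(artifact_slide[0]).mask
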