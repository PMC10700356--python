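"""Shared synthetic fixtures.

Movies are generated once per session at the smallest scale that still
exercises the estimators: an iSIM-like field for polarity/spacing readouts
and a widefield-like field for tracking.
"""

import numpy as np
import pytest

from edgewater import GeneratorConfig, generate_cell_movie


@pytest.fixture(scope="session")
def isim_movie_depleted():
    """iSIM-like movie, 3 polarized cells with 50% front MPAct depletion."""
    cfg = GeneratorConfig(image_size_px=(512, 512), n_frames=6, n_cells=3,
                          seed=5, speed_um_min=4.0, mpact_front_depletion=0.5,
                          cell_area_um2_range=(42.0, 56.0))
    movie, truth = generate_cell_movie(cfg)
    return cfg, movie, truth


@pytest.fixture(scope="session")
def isim_movie_uniform():
    """iSIM-like movie with a uniformly distributed membrane reporter."""
    cfg = GeneratorConfig(image_size_px=(512, 512), n_frames=6, n_cells=3,
                          seed=5, speed_um_min=4.0,
                          cell_area_um2_range=(42.0, 56.0))
    movie, truth = generate_cell_movie(cfg)
    return cfg, movie, truth


@pytest.fixture(scope="session")
def widefield_movie():
    """Widefield-like tracking movie: 6 live cells plus one dead cell."""
    cfg = GeneratorConfig(image_size_px=(640, 640), pixel_size_um=0.325,
                          psf_sigma_um=0.3, n_frames=16, n_cells=7, seed=11,
                          speed_um_min=9.0, dead_fraction=0.15,
                          cell_area_um2_range=(42.0, 56.0))
    movie, truth = generate_cell_movie(cfg)
    return cfg, movie, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
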