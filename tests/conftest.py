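"""Shared fixtures: pulse, phantom frames and analysis-window helpers.

All RF fixtures are generated at test time from seeded phantoms; recovery
tests read ground truth only from the frame's ``ground_truth`` record.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from qusresp import (PulseSpec, ScattererPopulation, TissuePhantom,
                     make_pulse, synthesize_rf, tile_windows)

logging.getLogger("qusresp").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def pulse():
    return make_pulse(PulseSpec())


def diffuse_phantom(density=25.0, diameter=50.0, extent=(14.0, 12.0),
                    alpha=0.0, spacing=None, jitter=0.0):
    pop = ScattererPopulation(number_density=density,
                              effective_diameter=diameter,
                              regular_spacing=spacing,
                              spacing_jitter=jitter)
    att = {"background": alpha} if alpha else {}
    return TissuePhantom(extent=extent, populations={"background": pop},
                         attenuation=att)


def central_mask(frame, ax_margin=100, lat_margin=5):
    mask = np.zeros(frame.samples.shape, dtype=bool)
    mask[ax_margin:-ax_margin // 2, lat_margin:-lat_margin] = True
    return mask


@pytest.fixture(scope="session")
def frame_factory(pulse):
    """Cached synthesis of analysis-ready frames + sparse window grids."""
    cache = {}

    def make(seed, *, density=25.0, diameter=50.0, extent=(14.0, 12.0),
             alpha=0.0, spacing=None, jitter=0.0, snr_db=30.0,
             overlap=0.5):
        key = (seed, density, diameter, extent, alpha, spacing, jitter,
               snr_db, overlap)
        if key not in cache:
            ph = diffuse_phantom(density, diameter, extent, alpha,
                                 spacing, jitter)
            fr = synthesize_rf(ph, pulse, seed=seed, snr_db=snr_db)
            grid = tile_windows(central_mask(fr), fr, overlap=overlap)
            cache[key] = (fr, grid)
        return cache[key]

    return make
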