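"""Shared fixtures: small, seeded synthetic datasets.

Simulation and fitting here run on a reduced raster (41–61 cells per
side) and small voxel counts so the suite stays fast; the full-size
conditions are exercised by the acceptance tests.
"""

import numpy as np
import pytest

import prfscotoma as pf
from prfscotoma.fitting import FitConfig
from prfscotoma.prf_model import ModelVariant


@pytest.fixture(scope="session")
def small_full_seq():
    """Full-field study-timing sequence on a reduced raster."""
    return pf.build_sequence(
        pf.study_config(scotoma_radius_deg=0.0, grid_resolution=61)
    )


@pytest.fixture(scope="session")
def small_scotoma_seq():
    """2°-scotoma study sequence on the same reduced raster."""
    return pf.build_sequence(
        pf.study_config(scotoma_radius_deg=2.0, grid_resolution=61)
    )


@pytest.fixture(scope="session")
def canonical_fitcfg():
    return FitConfig(variant=ModelVariant.GAUSSIAN_CANONICAL_HRF)


@pytest.fixture(scope="session")
def study_fits(small_full_seq, small_scotoma_seq):
    """Three simulated subjects, fully fitted (6 analyses each).

    Scotoma acquisition at default noise, scotoma-naive fitting with
    the standard fitted-HRF model — the backbone for the reliability
    tests.
    """
    cfg = FitConfig()
    tables = []
    for j in range(3):
        pop = pf.sample_population(150, seed=100 + j)
        pop = pf.calibrate_amplitudes(pop, small_full_seq)
        dataset = pf.simulate_study(
            pop,
            small_scotoma_seq.config,
            noise_sd=1.0,
            base_seed=200 + 10 * j,
            seq=small_scotoma_seq,
        )
        tables.append(pf.fit_population(dataset, cfg, fit_seq=small_full_seq))
    return tables
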