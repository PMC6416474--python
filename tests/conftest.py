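"""Shared fixtures.

The heavy transport solutions (2e6 packets on the 100^3 grids) are
session-scoped and generated in photon batches so that tests can both use
the pooled single-run map and estimate Monte Carlo standard errors from the
batch spread.  Batches with disjoint packet-id ranges tile the photon set of
one run exactly, so the pooled map equals a single 2e6-packet run.
"""

import numpy as np
import pytest

from photodose import (
    DEFAULT_OPTICS,
    SourceSpec,
    VoxelGrid,
    combine_maps,
    run_mc,
)

SEED = 20190314  # fixed for the whole suite
N_PHOTONS = 2_000_000
N_BATCHES = 8

GROUP1_SOURCE = SourceSpec(beam_diameter=1.0, incident_fluence_rate=50.0)


def _batched_run(voxel_size: float):
    grid = VoxelGrid.homogeneous(100, voxel_size, DEFAULT_OPTICS)
    per = N_PHOTONS // N_BATCHES
    return [
        run_mc(grid, GROUP1_SOURCE, per, seed=SEED, photon_offset=b * per)
        for b in range(N_BATCHES)
    ]


@pytest.fixture(scope="session")
def mc_batches_05():
    """Eight 2.5e5-packet batches on the 0.5-mm grid (tumor optics)."""
    return _batched_run(0.05)


@pytest.fixture(scope="session")
def mc_map_05(mc_batches_05):
    """Pooled 2e6-packet fluence map, 0.5-mm voxels, group-1 source."""
    return combine_maps(mc_batches_05)


@pytest.fixture(scope="session")
def mc_batches_025():
    """The same packet set traced on the 0.25-mm grid."""
    return _batched_run(0.025)


@pytest.fixture(scope="session")
def mc_map_025(mc_batches_025):
    return combine_maps(mc_batches_025)


@pytest.fixture(scope="session")
def small_grid():
    """A cheap 40^3 1-mm grid for functional (non-statistical) checks."""
    return VoxelGrid.homogeneous(40, 0.1, DEFAULT_OPTICS)
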