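"""Shared fixtures: a toy topology and a desk-scale five-system ensemble.

The ensemble fixture uses the canonical study design (three systems sharing a
conformational basin, two in distinct basins; long run + two restarts per
system) with shortened durations so the whole suite stays fast.
"""

import numpy as np
import pytest

from mdtop import synthetic
from mdtop.superpose import pairwise_rmsd_matrix
from mdtop.trajectory import SamplingProtocol, build_artificial_trajectory


@pytest.fixture(scope="session")
def topology():
    return synthetic.generate_topology(12, seed=1)


@pytest.fixture(scope="session")
def five_systems(topology):
    spec = synthetic.five_system_spec(
        topology,
        seed=1,
        long_ns=4.0,
        restart_ns=(0.6, 0.6),
        restart_branch_ns=(1.0, 3.0),
        interval_ps=10.0,
    )
    return synthetic.generate_ensemble(topology, spec)


@pytest.fixture(scope="session")
def artificial(five_systems):
    proto = SamplingProtocol(stride_ps=80.0, exclusion=0.10, discard_ns=1.0, seed=7)
    return build_artificial_trajectory(five_systems, proto)


@pytest.fixture(scope="session")
def rmsd_matrix(topology, artificial):
    return pairwise_rmsd_matrix(artificial.coords, topology, "name CA or name CB")


@pytest.fixture(scope="session")
def basin_truth(artificial):
    return artificial.provenance["basin"].to_numpy()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
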