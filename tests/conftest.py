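"""Shared fixtures: the frozen pseudo-domain pair and small ensembles.

The domain pair is generated from a fixed seed so every test run sees the
same "fold"; ensembles are regenerated deterministically per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from tandemsh2 import synthetic_ensemble as syn

DOMAIN_SEED = 7  # the frozen fixture fold


@pytest.fixture(scope="session")
def domain_pair():
    return syn.make_tandem_domains(seed=DOMAIN_SEED)


@pytest.fixture(scope="session")
def multibasin_ensemble(domain_pair):
    """2-basin heterogeneous ensemble of 16 conformers with ground truth."""
    dom_a, dom_b = domain_pair
    dist = syn.default_pose_distribution(
        dom_a, dom_b, mode="multibasin", n_basins=2, angular_spread_deg=12.0, seed=5
    )
    ens, truth = syn.generate_ensemble(dom_a, dom_b, dist, n=16, seed=31)
    return ens, truth, dist


@pytest.fixture(scope="session")
def tandem_conformer(multibasin_ensemble):
    return multibasin_ensemble[0][0]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
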