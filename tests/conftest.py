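"""Shared fixtures: reduced-scale phantom pipeline runs reused across tests.

The reduced runs keep the full acquisition geometry (300 stage positions,
2.9-um camera pixels, 12-bit CCD model) but lower the Monte Carlo photon
budgets and the lambda sweep so five seeded replicates fit in a desk-scale
test session.
"""

from __future__ import annotations

import numpy as np
import pytest

from flotsim import (
    CapillaryTrack,
    PipelineConfig,
    run_pipeline,
)

#: reduced-scale run parameters shared by the replicate fixtures
REDUCED = dict(
    data_photons=600_000,
    w_photons=400_000,
    n_lambdas=8,
    lambda_span=(1.0e-4, 1.0e1),
    maxiter=80,
    verbosity=0,
)

#: even smaller configuration for cheap structural tests
TINY_OVERRIDES = dict(nx=100, ny=12, nz=40)
TINY = dict(
    recipe_overrides=dict(TINY_OVERRIDES, n_positions=100),
    data_photons=200_000,
    w_photons=150_000,
    n_lambdas=6,
    lambda_span=(1.0e-3, 1.0e1),
    maxiter=60,
    verbosity=0,
)


def _run(seed_pair):
    ds, ws = seed_pair
    return run_pipeline(PipelineConfig(data_seed=ds, w_seed=ws, **REDUCED))


@pytest.fixture(scope="session")
def phantom_replicates():
    """Five seeded replicates of the full phantom experiment (reduced MC)."""
    return [_run((100 + i, 200 + i)) for i in range(5)]


@pytest.fixture(scope="session")
def phantom_run(phantom_replicates):
    return phantom_replicates[0]


@pytest.fixture(scope="session")
def phantom_track(phantom_run):
    return CapillaryTrack.from_map(phantom_run.fmap)


@pytest.fixture(scope="session")
def tiny_run():
    return run_pipeline(PipelineConfig(data_seed=11, w_seed=21, **TINY))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
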