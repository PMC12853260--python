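"""Shared fixtures: small ground-truth networks and (expensive) fitted
models reused across the suite via session scoping."""

import numpy as np
import pytest

from nirsgc import synth, tvmar
from nirsgc.gc import conditional_gc


@pytest.fixture(scope="session")
def bivariate_net():
    """x1 white noise, x2(t) = 0.5 x1(t-1) + e2; GC(1->2) = ln 1.25."""
    base = np.zeros((1, 2, 2))
    base[0, 1, 0] = 0.5
    return synth.GroundTruthNetwork(base, np.eye(2))


@pytest.fixture(scope="session")
def quad_net():
    """Stable 4-channel chain network with three true couplings."""
    base = np.zeros((1, 4, 4))
    np.fill_diagonal(base[0], 0.3)
    base[0, 1, 0] = 0.4
    base[0, 2, 1] = 0.25
    base[0, 3, 2] = 0.3
    return synth.GroundTruthNetwork(base, np.eye(4))


@pytest.fixture(scope="session")
def bivariate_data(bivariate_net):
    cfg = synth.ScenarioConfig(
        n_trials=200, n_times=80, onset_index=20, noise_scale=0.0, seed=11
    )
    return synth.generate_trials(bivariate_net, cfg)


@pytest.fixture(scope="session")
def bivariate_fit(bivariate_data):
    return tvmar.fit_stok(bivariate_data, order=3)


@pytest.fixture(scope="session")
def bivariate_gc(bivariate_fit):
    return conditional_gc(bivariate_fit)


@pytest.fixture(scope="session")
def quad_data(quad_net):
    cfg = synth.ScenarioConfig(
        n_trials=200, n_times=80, onset_index=20, noise_scale=0.0, seed=12
    )
    return synth.generate_trials(quad_net, cfg)


@pytest.fixture(scope="session")
def quad_fit(quad_data):
    return tvmar.fit_stok(quad_data, order=3)


@pytest.fixture(scope="session")
def quad_gc(quad_fit):
    return conditional_gc(quad_fit)
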