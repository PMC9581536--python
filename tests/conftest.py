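"""Shared fixtures.

Heavy objects (the synthetic network, its decay histograms and the global
fit) are session-scoped so the unit tests and the acceptance tests share
one computation. Simulation sizes are scaled for an offline single-CPU
run; the generating parameters themselves are the package defaults.
"""

from __future__ import annotations

import numpy as np
import pytest

import fretscape as fs

NETWORK_SEED = 1
N_PHOTONS = 1_000_000


@pytest.fixture(scope="session")
def network_truth():
    return fs.simulate.gen_network(12, seed=NETWORK_SEED)


@pytest.fixture(scope="session")
def decays(network_truth):
    net, truth = network_truth
    return {v: fs.simulate.simulate_decay(truth, v, N_PHOTONS,
                                          seed=100 * NETWORK_SEED + i)
            for i, v in enumerate(net.variant_names)}


@pytest.fixture(scope="session")
def donor_model(decays):
    return fs.fit_donor_only(next(iter(decays.values())), n_components=2)


@pytest.fixture(scope="session")
def global_fit(network_truth, decays, donor_model):
    _, truth = network_truth
    model = fs.GlobalDecayModel(decays, donor_model, n_states=2,
                                forster_radius=truth.forster_radius,
                                shared_no_fret=True)
    return model.fit(n_restarts=6, seed=0)


@pytest.fixture(scope="session")
def toy_bodies():
    return fs.simulate.gen_toy_structures(seed=2, n_snapshots=200)


def align_states(truth, result, variant_names):
    """Match fitted state labels to the generating states by the global
    permutation minimizing the distance RMSE."""
    d_true = np.array([truth.distances[v] for v in variant_names])
    best = None
    for perm in ([0, 1], [1, 0]):
        rmse = float(np.sqrt(np.mean((d_true - result.distances[:, perm]) ** 2)))
        if best is None or rmse < best[0]:
            best = (rmse, perm)
    rmse, perm = best
    frac_err = result.state_fractions[list(perm)] - truth.state_fractions
    return rmse, frac_err, perm
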