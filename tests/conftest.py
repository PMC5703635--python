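"""Shared fixtures and independent oracles for the test suite.

The path-sum oracles enumerate every latent state path on tiny grids; they
share no code with the filtering recursions they check.
"""

import itertools

import numpy as np
import pytest
from scipy.stats import binom

from drifthmm import make_grid


@pytest.fixture(scope="session")
def grid5():
    return make_grid(5)


@pytest.fixture(scope="session")
def grid401():
    return make_grid(401)


def path_sum_log_marginal(traj, matrices, grid, prior_mass):
    """Brute-force marginal likelihood: sum over all grid-state paths.

    ``matrices`` maps each inter-sample gap to its transition matrix rows.
    """
    K = len(traj.times)
    G = grid.n_points
    gaps = np.diff(traj.times)
    em = [binom.pmf(traj.n[k], traj.C[k], grid.points) for k in range(K)]
    total = 0.0
    for path in itertools.product(range(G), repeat=K):
        p = prior_mass[path[0]] * em[0][path[0]]
        for k in range(1, K):
            p *= matrices[gaps[k - 1]][path[k - 1], path[k]] * em[k][path[k]]
        total += p
    return np.log(total)


def path_sum_posteriors(traj, matrices, grid, prior_mass):
    """Brute-force smoothed posteriors P(q(t_k) | all data) by enumeration."""
    K = len(traj.times)
    G = grid.n_points
    gaps = np.diff(traj.times)
    em = [binom.pmf(traj.n[k], traj.C[k], grid.points) for k in range(K)]
    post = np.zeros((K, G))
    for path in itertools.product(range(G), repeat=K):
        p = prior_mass[path[0]] * em[0][path[0]]
        for k in range(1, K):
            p *= matrices[gaps[k - 1]][path[k - 1], path[k]] * em[k][path[k]]
        for k in range(K):
            post[k, path[k]] += p
    return post / post.sum(axis=1, keepdims=True)
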