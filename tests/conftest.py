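"""Shared fixtures: synthetic datasets and a dense GLS oracle for the
Kalman filter/smoother."""

from __future__ import annotations

import numpy as np
import pytest

from condemnwatch.statespace import (DHRModelSpec, build_state_space,
                                     observation_matrix)
from condemnwatch.synthetic import default_config, simulate_condemnation_records


def gls_state_oracle(y: np.ndarray, spec: DHRModelSpec,
                     P0: np.ndarray) -> np.ndarray:
    """Brute-force posterior state means by stacked generalized least squares.

    The unknowns are the initial state and every process-noise increment;
    all states are linear in them, so the joint Gaussian posterior mean is a
    dense weighted least-squares solution.  Independent of the recursive
    filter/smoother implementation it is used to check.
    """
    F, Q, sigma2 = build_state_space(spec)
    n, k = len(y), spec.dim
    q = np.diag(Q)
    noisy = np.where(q > 0)[0]
    m = len(noisy)
    n_unknown = k + m * (n - 1)

    powers = [np.eye(k)]
    for _ in range(n):
        powers.append(F @ powers[-1])
    G = np.zeros((k, m))
    G[noisy, np.arange(m)] = 1.0

    A = np.zeros((n, k, n_unknown))
    for t in range(n):
        A[t][:, :k] = powers[t]
        for s in range(t):
            A[t][:, k + s * m: k + (s + 1) * m] = powers[t - 1 - s] @ G

    Z = observation_matrix(spec, np.arange(n))
    rows, rhs = [], []
    L0 = np.linalg.cholesky(np.linalg.inv(P0))
    prior = np.zeros((k, n_unknown))
    prior[:, :k] = np.eye(k)
    rows.append(L0.T @ prior)
    rhs.append(np.zeros(k))
    if m:
        W = np.diag(1.0 / np.sqrt(q[noisy]))
        for s in range(n - 1):
            blk = np.zeros((m, n_unknown))
            blk[:, k + s * m: k + (s + 1) * m] = np.eye(m)
            rows.append(W @ blk)
            rhs.append(np.zeros(m))
    for t in range(n):
        if np.isfinite(y[t]):
            rows.append((Z[t] @ A[t] / np.sqrt(sigma2))[None, :])
            rhs.append([y[t] / np.sqrt(sigma2)])
    M = np.vstack(rows)
    b = np.concatenate([np.atleast_1d(r) for r in rhs])
    u, *_ = np.linalg.lstsq(M, b, rcond=None)
    return np.array([A[t] @ u for t in range(n)])


@pytest.fixture(scope="session")
def default_dataset():
    """Default five-reason synthetic dataset (records, denominators, truth)."""
    config = default_config(seed=1)
    records, slaughter, truths = simulate_condemnation_records(config)
    return config, records, slaughter, truths


@pytest.fixture(scope="session")
def default_dataset_dir(tmp_path_factory, default_dataset):
    """The same dataset written out as CSV files."""
    from condemnwatch.synthetic import write_dataset

    config, *_ = default_dataset
    out = tmp_path_factory.mktemp("simdata")
    write_dataset(config, out)
    return out
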