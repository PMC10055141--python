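"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.linalg import expm

import netcontrol as nc
from netcontrol.synth import SynthConfig, synth_connectome, synth_state_maps


@pytest.fixture(scope="session")
def fixtures():
    """Named closed-form graphs (triangle, path4, ring4, star4, k4)."""
    return nc.fixture_graphs()


@pytest.fixture(scope="session")
def small_connectome():
    """16-node synthetic geometric connectome for fast unit tests."""
    return synth_connectome(
        SynthConfig(n_nodes=16, target_density=0.4, seed=11)
    )


@pytest.fixture(scope="session")
def study_connectome():
    """Default-scale (68-node, 27% density) synthetic connectome."""
    return synth_connectome(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def study_states(study_connectome):
    return synth_state_maps(study_connectome, k_maps=12, seed=8)


def random_connectome(n: int, seed: int, density: float = 1.0) -> nc.Connectome:
    """Random connected weighted graph (complete by default)."""
    rng = np.random.default_rng(seed)
    a = np.triu(rng.random((n, n)) + 0.05, 1)
    if density < 1.0:
        iu, ju = np.triu_indices(n, 1)
        keep = rng.random(len(iu)) < density
        mask = np.zeros((n, n), dtype=bool)
        mask[iu[keep], ju[keep]] = True
        # keep a spanning path so the graph stays connected
        for i in range(n - 1):
            mask[i, i + 1] = True
        a = a * mask
    a = a + a.T
    return nc.Connectome(adjacency=a)


def transcription_energy(
    a_norm: np.ndarray,
    x0: np.ndarray,
    xT: np.ndarray,
    T: float = 1.0,
    rho: float = 1.0,
    n: int = 400,
) -> float:
    """Independent direct-transcription oracle for the optimal energy.

    Discretizes the control on an n-interval grid (exact zero-order-hold
    state propagation), writes the cost as a quadratic in the stacked
    inputs, and solves the equality-constrained quadratic program with
    the terminal state x(T) = xT enforced exactly via a KKT system.
    """
    N = a_norm.shape[0]
    dt = T / n
    aug = np.zeros((2 * N, 2 * N))
    aug[:N, :N] = a_norm
    aug[:N, N:] = np.eye(N)
    e = expm(aug * dt)
    ad, bd = e[:N, :N], e[:N, N:]
    pows = [np.eye(N)]
    for _ in range(n):
        pows.append(ad @ pows[-1])
    g = np.zeros(((n + 1) * N, n * N))
    xfree = np.zeros((n + 1) * N)
    for k in range(n + 1):
        xfree[k * N : (k + 1) * N] = pows[k] @ x0
        for j in range(k):
            g[k * N : (k + 1) * N, j * N : (j + 1) * N] = pows[k - 1 - j] @ bd
    w = np.full(n + 1, dt)
    w[0] = w[-1] = dt / 2
    sw = np.sqrt(np.repeat(w, N))
    a1 = sw[:, None] * g
    b1 = sw * (np.tile(xT, n + 1) - xfree)
    c = g[n * N :, :]
    d = xT - xfree[n * N :]
    h = 2.0 * (a1.T @ a1 + rho * dt * np.eye(n * N))
    kkt = np.block([[h, c.T], [c, np.zeros((N, N))]])
    sol = np.linalg.solve(kkt, np.concatenate([2.0 * a1.T @ b1, d]))
    u = sol[: n * N]
    return float(dt * np.sum(u**2))
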