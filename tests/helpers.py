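"""Shared oracle helpers for the test suite."""

import numpy as np


def fd_gradient(fn, W, h=1e-6):
    """Central finite-difference gradient of a scalar function of W."""
    g = np.zeros_like(W)
    for idx in np.ndindex(W.shape):
        Wp, Wm = W.copy(), W.copy()
        Wp[idx] += h
        Wm[idx] -= h
        g[idx] = (fn(Wp) - fn(Wm)) / (2 * h)
    return g


def exact_scv_sources(K, N, V, correlations, rng):
    """Sources whose sample moments match their SCV covariances *exactly*.

    Rows are built from an orthonormal basis orthogonal to the constant
    vector, so every cross-moment that should vanish does so to machine
    precision and the IVA-G cost is exactly stationary at the true demixing.
    """
    base = np.vstack([np.ones(V), rng.standard_normal((N * K, V))])
    Q, _ = np.linalg.qr(base.T)
    B = Q[:, 1 : N * K + 1].T * np.sqrt(V)
    S = np.empty((K, N, V))
    for n in range(N):
        C = np.full((K, K), correlations[n])
        np.fill_diagonal(C, 1.0)
        S[:, n, :] = np.linalg.cholesky(C) @ B[n * K : (n + 1) * K]
    return S
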