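"""Threshold-free reference constraints for IVA.

A reference set holds M ≤ N signals on the sample axis.  Reference n is
assigned to component n (the first M components are constrained).  The
regularizer rewards similarity — squared Pearson correlation ε² — between
each reference and its assigned source in every dataset while penalizing
leakage of the reference into all other components:

    J_ref(W) = Σ_{n≤M} Σ_k [ Σ_{m≠n} ε²(r_n, ŝ_m[k]) − ε²(r_n, ŝ_n[k]) ]

and the combined objective is  L_λ = J_IVA + (λ/2)·J_ref.  No correlation
threshold parameter is involved; λ alone balances the two terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ivafusion.iva_core import (
    DEFAULT_RIDGE_SCALE,
    _as_stack,
    _ensemble_array,
    ivag_cost,
    ivag_gradient,
)

#: regularization weight used throughout the reference analyses
DEFAULT_LAMBDA = 100.0


def _zscore(v: np.ndarray, name: str = "signal") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"zero-variance {name} in similarity")
    return (v - v.mean()) / sd


@dataclass
class ReferenceSet:
    """M reference signals, their labels, and the regularization weight λ.

    References are z-scored at construction (population std), so their inner
    products with centered sources reduce to scaled correlations.
    """

    references: np.ndarray  # (M, S) after z-scoring
    labels: list[str] | None = None
    lam: float = DEFAULT_LAMBDA

    def __post_init__(self) -> None:
        refs = np.atleast_2d(np.asarray(self.references, dtype=float))
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        if self.labels is None:
            self.labels = [f"ref-{i}" for i in range(refs.shape[0])]
        if len(self.labels) != refs.shape[0]:
            raise ValueError("one label per reference required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate reference labels")
        self.references = np.stack(
            [_zscore(refs[i], name=f"reference {self.labels[i]!r}") for i in range(refs.shape[0])]
        )

    @property
    def n_references(self) -> int:
        return self.references.shape[0]

    @property
    def n_samples(self) -> int:
        return self.references.shape[1]

    def validate_against(self, n_components: int, n_samples: int) -> None:
        if self.n_references > n_components:
            raise ValueError(
                f"more references ({self.n_references}) than components ({n_components})"
            )
        if self.n_samples != n_samples:
            raise ValueError(
                f"reference length {self.n_samples} does not match sample axis {n_samples}"
            )


def similarity_eps2(r: np.ndarray, s: np.ndarray) -> float:
    """Squared Pearson correlation in [0, 1]; affine-invariant and symmetric."""
    r = _zscore(r)
    s = _zscore(s)
    if r.shape != s.shape:
        raise ValueError(f"length mismatch: {r.shape} vs {s.shape}")
    return float(np.dot(r, s) / r.size) ** 2


def _source_stack(W, X) -> tuple[np.ndarray, np.ndarray]:
    Wk = _ensemble_array(W)
    Xs = _as_stack(X)
    Xc = Xs - Xs.mean(axis=2, keepdims=True)
    return Wk @ Xc, Xc


def jref(W, X, R: ReferenceSet) -> float:
    """Evaluate the reference regularizer at W (lower is better)."""
    sources, _ = _source_stack(W, X)
    K, N, S = sources.shape
    R.validate_against(n_components=N, n_samples=S)
    M = R.n_references
    total = 0.0
    # eps2[k, n, m] = ε²(r_n, ŝ_m[k])
    norms = np.linalg.norm(sources, axis=2)  # (K, N)
    inner = sources @ R.references.T / S  # (K, N, M): ⟨ŝ_m, r_n⟩/S
    if np.any(norms == 0):
        raise ValueError("zero-variance signal in similarity")
    corr = inner * S / (norms[:, :, None] * np.sqrt(S))  # corr(ŝ_m[k], r_n)
    eps2 = corr**2  # (K, m, n)
    for n in range(M):
        total += float(eps2[:, :, n].sum() - 2.0 * eps2[:, n, n].sum())
    return total


def jref_gradient(W, X, R: ReferenceSet) -> np.ndarray:
    """Gradient of :func:`jref` with respect to each W[k].

    With z-scored references and centered data, for a source row ``s = w Xc``:
    ``ε²(r, s) = (s·r)² / (S · s·s)`` whose gradient in w is
    ``(2a/(S q))·Xc r − (2a²/(S q²))·Xc sᵀ`` with ``a = s·r``, ``q = s·s``.
    """
    sources, Xc = _source_stack(W, X)
    K, N, S = sources.shape
    R.validate_against(n_components=N, n_samples=S)
    M = R.n_references
    refs = R.references  # (M, S)
    grad = np.zeros((K, N, N))
    # sign[m, n]: +1 leakage term (n ≠ m), −1 own-reference term (n == m ≤ M)
    sign = np.ones((N, M))
    for n in range(M):
        sign[n, n] = -1.0
    for k in range(K):
        Sk = sources[k]  # (N, S)
        A = Sk @ refs.T  # (N, M), a_{mn} = ŝ_m · r_n
        q = np.einsum("ns,ns->n", Sk, Sk)  # (N,)
        U = Xc[k] @ refs.T  # (N, M) columns: Xc r_n
        B = Xc[k] @ Sk.T  # (N, N) columns: Xc ŝ_m
        c1 = sign * 2.0 * A / (S * q[:, None])  # (N, M)
        c2 = (sign * 2.0 * A**2 / (S * q[:, None] ** 2)).sum(axis=1)  # (N,)
        grad[k] = c1 @ U.T - c2[:, None] * B.T
    return grad


def constrained_cost(W, X, R: ReferenceSet, ridge_scale: float = DEFAULT_RIDGE_SCALE) -> float:
    """Combined objective  L_λ = J_IVA + (λ/2)·J_ref."""
    base = ivag_cost(W, X, ridge_scale=ridge_scale)
    if R.lam == 0:
        return base
    return base + 0.5 * R.lam * jref(W, X, R)


def constrained_gradient(W, X, R: ReferenceSet, ridge_scale: float = DEFAULT_RIDGE_SCALE) -> np.ndarray:
    """Gradient of :func:`constrained_cost`."""
    base = ivag_gradient(W, X, ridge_scale=ridge_scale)
    if R.lam == 0:
        return base
    return base + 0.5 * R.lam * jref_gradient(W, X, R)
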