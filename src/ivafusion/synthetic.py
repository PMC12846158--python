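"""Ground-truth multi-task generator.

Emulates, at desk scale, a multi-subject multi-task feature study: K
datasets ``X[k] = A[k] S[k] + noise`` whose source rows share a known
cross-dataset (SCV) correlation structure, mixing columns that act as
subject profiles with injectable group effects, and reference signals of
tunable fidelity to the underlying truth.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ivafusion.data_io import FeatureDataset
from ivafusion.evaluation import GroupLabels


@dataclass
class SyntheticConfig:
    """Geometry, dependence structure and effect injection for one draw.

    ``scv_correlation`` may be a scalar off-diagonal correlation shared by
    all components, a length-N sequence (one off-diagonal value per
    component), or a full (N, K, K) stack; ``None`` uses off-diagonals spaced
    over [0.3, 0.9], which keeps the SCV covariance profiles distinct — a
    requirement for IVA-G identifiability.

    ``profile_correlation`` optionally gives the mixing columns (subject
    profiles) their own cross-dataset correlation, which is what makes the
    transposed analysis well-posed; ``None`` leaves profiles independent
    across datasets.
    """

    K: int = 3
    N: int = 6
    V: int = 5000
    T: int = 120
    scv_correlation: object = None
    effect_sizes: dict | None = None  # component index -> Cohen's d
    reference_fidelity: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0
    profile_correlation: object = None
    patient_fraction: float = 0.5

    def __post_init__(self) -> None:
        if min(self.K, self.N, self.V, self.T) < 1:
            raise ValueError("K, N, V, T must all be >= 1")
        if not (0.0 <= self.reference_fidelity <= 1.0):
            raise ValueError("reference_fidelity must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (0.0 < self.patient_fraction < 1.0):
            raise ValueError("patient_fraction must lie in (0, 1)")


@dataclass
class GroundTruth:
    """Everything needed to score a decomposition of a synthetic draw."""

    A: np.ndarray  # (K, T, N) mixing, columns are subject profiles
    S: np.ndarray  # (K, N, V) sources
    scv_cov_true: np.ndarray  # (N, K, K)
    group_labels: GroupLabels
    injected_components: dict  # component index -> injected Cohen's d
    config: SyntheticConfig


def _correlation_stack(cfg: SyntheticConfig) -> np.ndarray:
    """Normalize ``scv_correlation`` to an (N, K, K) PD stack."""
    K, N = cfg.K, cfg.N
    spec = cfg.scv_correlation
    if spec is None:
        spec = np.linspace(0.3, 0.9, N) if N > 1 else np.array([0.6])
    arr = np.asarray(spec, dtype=float)
    if arr.ndim == 0:
        arr = np.full(N, float(arr))
    if arr.ndim == 1:
        if arr.size != N:
            raise ValueError(f"need one off-diagonal value per component, got {arr.size}")
        stack = np.empty((N, K, K))
        for n in range(N):
            stack[n] = np.full((K, K), arr[n])
            np.fill_diagonal(stack[n], 1.0)
    elif arr.shape == (N, K, K):
        stack = arr.copy()
    else:
        raise ValueError(f"scv_correlation must be scalar, length-N, or (N,K,K); got {arr.shape}")
    for n in range(N):
        if np.min(np.linalg.eigvalsh(stack[n])) <= 0:
            raise ValueError(f"SCV correlation matrix for component {n} is not positive definite")
    for n in range(N if K > 1 else 0):
        for m in range(n + 1, N):
            if np.allclose(stack[n], stack[m]):
                warnings.warn(
                    f"components {n} and {m} share an SCV covariance profile: "
                    "they are not identifiable by IVA-G",
                    stacklevel=3,
                )
    return stack


def generate_scv_sources(cfg: SyntheticConfig, rng: np.random.Generator | None = None):
    """Draw K source matrices whose nth rows form a correlated K-vector.

    For each component n, V iid samples of a K-variate Gaussian with the
    target correlation matrix are drawn; each row is then exactly
    standardized (zero mean, unit variance).  Returns ``(S, scv_cov_true)``
    with S of shape (K, N, V).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    stack = _correlation_stack(cfg)
    K, N, V = cfg.K, cfg.N, cfg.V
    S = np.empty((K, N, V))
    for n in range(N):
        chol = np.linalg.cholesky(stack[n])
        draws = chol @ rng.standard_normal((K, V))  # (K, V)
        draws -= draws.mean(axis=1, keepdims=True)
        draws /= draws.std(axis=1, keepdims=True)
        S[:, n, :] = draws
    return S, stack


def _balanced_labels(cfg: SyntheticConfig) -> GroupLabels:
    n_patients = int(round(cfg.T * cfg.patient_fraction))
    n_patients = min(max(n_patients, 1), cfg.T - 1)
    labels = np.zeros(cfg.T, dtype=int)
    labels[cfg.T - n_patients:] = 1
    return GroupLabels(labels)


def generate_mixing_with_groups(cfg: SyntheticConfig, rng: np.random.Generator | None = None):
    """Gaussian mixing matrices with optional injected group effects.

    Entries are standard normal, so shifting the patient rows of an injected
    column by d gives a population Cohen's d of exactly d.  When
    ``profile_correlation`` is set, each component's profile is drawn jointly
    across datasets with that correlation (scalar, or one value per
    component).
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    K, T, N = cfg.K, cfg.T, cfg.N
    labels = _balanced_labels(cfg)
    effects = dict(cfg.effect_sizes or {})
    if any(idx >= N or idx < 0 for idx in effects):
        raise ValueError("effect component index out of range")
    if any(d != 0 for d in effects.values()) and T < 4:
        raise ValueError("injecting a group effect requires T >= 4")

    if cfg.profile_correlation is None:
        A = rng.standard_normal((K, T, N))
    else:
        rho = np.asarray(cfg.profile_correlation, dtype=float)
        rho = np.full(N, float(rho)) if rho.ndim == 0 else rho
        if rho.size != N:
            raise ValueError("profile_correlation must be scalar or length N")
        A = np.empty((K, T, N))
        for n in range(N):
            R = np.full((K, K), rho[n])
            np.fill_diagonal(R, 1.0)
            if np.min(np.linalg.eigvalsh(R)) <= 0:
                raise ValueError(f"profile correlation for component {n} is not positive definite")
            chol = np.linalg.cholesky(R)
            A[:, :, n] = chol @ rng.standard_normal((K, T))
    patients = labels.labels == 1
    for idx, d in effects.items():
        A[:, patients, idx] += d
    return A, labels


def synthesize_multitask(cfg: SyntheticConfig):
    """Full draw: ``X[k] = A[k] S[k] + noise_sd · ε`` per dataset.

    Returns ``(datasets, truth)`` where datasets are subjects-by-voxels
    :class:`~ivafusion.data_io.FeatureDataset` objects.  Bitwise
    deterministic for a fixed config.
    """
    rng = np.random.default_rng(cfg.seed)
    S, scv_cov = generate_scv_sources(cfg, rng)
    A, labels = generate_mixing_with_groups(cfg, rng)
    datasets = []
    for k in range(cfg.K):
        X = A[k] @ S[k]
        if cfg.noise_sd > 0:
            X = X + cfg.noise_sd * rng.standard_normal(X.shape)
        datasets.append(FeatureDataset(X, task_id=f"task-{k}"))
    truth = GroundTruth(
        A=A,
        S=S,
        scv_cov_true=scv_cov,
        group_labels=labels,
        injected_components=dict(cfg.effect_sizes or {}),
        config=cfg,
    )
    return datasets, truth


def make_noisy_reference(truth: GroundTruth, component: int, fidelity: float,
                         kind: str = "spatial", dataset: int = 0,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Reference with a chosen expected correlation to a true signal.

    Returns the z-scored mixture ``α·z(signal) + √(1−α²)·z(noise)`` with
    α = fidelity, so the expected correlation with the signal equals the
    fidelity.  ``kind='spatial'`` uses the true source row (length V);
    ``kind='behavioral'`` uses the true profile column (length T).
    """
    if not (0.0 <= fidelity <= 1.0):
        raise ValueError("fidelity must lie in [0, 1]")
    if not (0 <= component < truth.config.N):
        raise ValueError(f"component index {component} out of range")
    if kind == "spatial":
        signal = truth.S[dataset][component]
    elif kind == "behavioral":
        signal = truth.A[dataset][:, component]
    else:
        raise ValueError(f"unknown reference kind {kind!r}")
    rng = rng or np.random.default_rng(truth.config.seed + 7919 + component)
    z = (signal - signal.mean()) / signal.std()
    noise = rng.standard_normal(signal.size)
    noise = (noise - noise.mean()) / noise.std()
    mixed = fidelity * z + np.sqrt(1.0 - fidelity**2) * noise
    return (mixed - mixed.mean()) / mixed.std()


def reduced_global_matrices(truth: GroundTruth, reduced, W, view: str = "iva") -> np.ndarray:
    """Global matrices ``G[k] = W[k] F[k] A_true[k]`` for scoring recovery.

    ``view='iva'`` uses the subject-axis reducers and the true mixing A[k];
    ``view='tiva'`` treats the transposed model ``Xᵀ = Sᵀ Aᵀ`` whose mixing
    is S[k]ᵀ.  A joint-ISI of the result near zero means the demixing
    recovered the truth up to permutation and scale.
    """
    from ivafusion.iva_core import _ensemble_array

    Wk = _ensemble_array(W)
    G = np.empty_like(Wk)
    for k in range(Wk.shape[0]):
        mixing = truth.A[k] if view == "iva" else truth.S[k].T
        G[k] = Wk[k] @ (reduced[k].reducer.projection @ mixing)
    return G
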