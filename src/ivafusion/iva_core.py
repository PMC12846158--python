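"""IVA-G: joint demixing of K datasets under a Gaussian SCV model.

The objective minimized here is

    J(W) = (1/2) Σ_n log det Σ̂_n  −  Σ_k log |det W[k]|,

where Σ̂_n is the maximum-likelihood (``1/S``) sample covariance of the nth
source component vector — the K-vector of the nth estimated source across
datasets.  The additive constant ``N·K/2·log(2πe)`` of the Gaussian
log-likelihood is dropped; oracle comparisons must subtract it.

The optimizer is plain full-gradient descent with backtracking line search,
so accepted steps never increase the objective.  SCV covariances are
re-estimated at every cost/gradient evaluation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: relative ridge added to SCV covariance diagonals (scaled by trace/K)
DEFAULT_RIDGE_SCALE = 1e-8


class OptimizationError(RuntimeError):
    """Raised when the optimizer encounters a non-recoverable failure."""


@dataclass
class DemixingEnsemble:
    """K square demixing matrices sharing a common order N."""

    W: np.ndarray  # (K, N, N)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 3 or self.W.shape[1] != self.W.shape[2]:
            raise ValueError(f"W must be (K, N, N), got {self.W.shape}")
        dets = np.abs(np.linalg.det(self.W))
        if np.any(dets <= 1e-12):
            raise ValueError("demixing matrix singular")

    @property
    def dataset_count(self) -> int:
        return self.W.shape[0]

    @property
    def order(self) -> int:
        return self.W.shape[1]


@dataclass
class SCVCovariances:
    """Per-component K-by-K covariances across datasets, plus the ridge used."""

    sigma: np.ndarray  # (N, K, K)
    ridge: np.ndarray  # (N,) ridge actually added to each diagonal


@dataclass
class OptimizerOptions:
    max_iterations: int = 512
    w_change_tolerance: float = 1e-6
    initial_step: float = 0.5
    step_growth: float = 1.25
    step_shrink: float = 0.5
    min_step: float = 1e-12
    seed: int = 0
    init: str = "random-orthogonal"  # or "supplied"
    W0: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.w_change_tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class RunResult:
    """One optimizer run: demixing ensemble, sources and diagnostics."""

    W: DemixingEnsemble
    sources: np.ndarray  # (K, N, S)
    scv_cov: SCVCovariances
    cost_trace: np.ndarray
    converged: bool
    seed: int
    n_iterations: int = 0
    constrained_count: int = 0

    @property
    def final_cost(self) -> float:
        return float(self.cost_trace[-1])


def _as_stack(X) -> np.ndarray:
    """Accept a (K, N, S) array or a list of ReducedDataset / arrays."""
    if isinstance(X, np.ndarray) and X.ndim == 3:
        return X
    mats = [np.asarray(getattr(x, "data", x), dtype=float) for x in X]
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ValueError(f"datasets must share one (N, S) shape, got {sorted(shapes)}")
    return np.stack(mats)


def estimate_scv_covariances(sources, ridge_scale: float = DEFAULT_RIDGE_SCALE) -> SCVCovariances:
    """Sample covariance (``1/S``) of each SCV across datasets, ridged.

    ``sources`` is (K, N, S).  ``sigma[n][j][l]`` is the covariance between
    source n of dataset j and source n of dataset l over the S samples.  A
    ridge of ``ridge_scale * trace/K`` is added to each diagonal, which keeps
    the matrices positive definite in the sample-poor (tIVA) regime.
    """
    s = _as_stack(sources)
    K, N, S = s.shape
    if S < 2:
        raise ValueError(f"need at least 2 samples to estimate covariances, got S={S}")
    if S <= K:
        warnings.warn(
            f"sample count S={S} <= dataset count K={K}: SCV covariances are rank deficient "
            "(sample-poor regime)",
            stacklevel=2,
        )
    centered = s - s.mean(axis=2, keepdims=True)
    # sigma[n] = (1/S) * C_n C_nᵀ with C_n = centered[:, n, :]
    sigma = np.einsum("kns,lns->nkl", centered, centered) / S
    ridge = ridge_scale * np.trace(sigma, axis1=1, axis2=2) / K
    sigma[:, np.arange(K), np.arange(K)] += ridge[:, None]
    return SCVCovariances(sigma=sigma, ridge=ridge)


def _ensemble_array(W) -> np.ndarray:
    if isinstance(W, DemixingEnsemble):
        return W.W
    return np.asarray(W, dtype=float)


def ivag_cost(W, X, ridge_scale: float = DEFAULT_RIDGE_SCALE) -> float:
    """IVA-G objective (constants dropped; see module docstring)."""
    Wk = _ensemble_array(W)
    Xs = _as_stack(X)
    sign, logdet_w = np.linalg.slogdet(Wk)
    if np.any(sign == 0):
        raise OptimizationError("demixing matrix singular")
    sources = Wk @ Xs
    sigma = estimate_scv_covariances(sources, ridge_scale=ridge_scale).sigma
    sign_s, logdet_s = np.linalg.slogdet(sigma)
    if np.any(sign_s <= 0):
        raise OptimizationError("SCV covariance not positive definite after ridge")
    return float(0.5 * logdet_s.sum() - logdet_w.sum())


def ivag_gradient(W, X, ridge_scale: float = DEFAULT_RIDGE_SCALE) -> np.ndarray:
    """Gradient of :func:`ivag_cost` with respect to each W[k].

    Row n of the kth block is ``(1/S)·(Σ̂_n⁻¹ ŝ_n)[k] Xcᵀ − (W[k]⁻ᵀ)_n`` with
    centered data; the ridge's implicit dependence on W is O(ridge) and is
    neglected.
    """
    Wk = _ensemble_array(W)
    Xs = _as_stack(X)
    K, N, S = Xs.shape
    Xc = Xs - Xs.mean(axis=2, keepdims=True)
    sources = Wk @ Xc  # centered sources since Xc rows are zero-mean
    sigma = estimate_scv_covariances(sources, ridge_scale=ridge_scale).sigma
    P = np.linalg.inv(sigma)  # (N, K, K)
    # y[k, n, :] = Σ_l P[n, k, l] * sources[l, n, :]
    y = np.einsum("nkl,lns->kns", P, sources)
    grad = np.einsum("kns,kts->knt", y, Xc) / S
    grad -= np.linalg.inv(Wk).transpose(0, 2, 1)
    return grad


def _random_orthogonal_stack(K: int, N: int, rng: np.random.Generator) -> np.ndarray:
    W = np.empty((K, N, N))
    for k in range(K):
        q, r = np.linalg.qr(rng.standard_normal((N, N)))
        W[k] = q * np.sign(np.diag(r))[None, :]
    return W


def _w_change(W_new: np.ndarray, W_old: np.ndarray) -> float:
    """Rotation-invariant demixing change: rows normalized, compare to identity."""
    new = W_new / np.linalg.norm(W_new, axis=2, keepdims=True)
    old = W_old / np.linalg.norm(W_old, axis=2, keepdims=True)
    cross = np.abs(new @ old.transpose(0, 2, 1))
    diag = np.diagonal(cross, axis1=1, axis2=2)
    return float(np.max(1.0 - diag.min(axis=1)))


def _pin_scale_and_sign(W: np.ndarray, Xc: np.ndarray, constraint) -> np.ndarray:
    """Resolve the BSS scale/sign ambiguity deterministically.

    Rows of each W[k] are L2-normalized.  Constrained rows are flipped so
    the source correlates positively with its reference; unconstrained rows
    so the source has nonnegative skewness (with a deterministic tie-break
    on the first sample for numerically symmetric sources).
    """
    W = W / np.linalg.norm(W, axis=2, keepdims=True)
    sources = W @ Xc
    K, N, S = sources.shape
    n_constrained = 0 if constraint is None else constraint.n_references
    for k in range(K):
        for n in range(N):
            s = sources[k, n]
            if n < n_constrained:
                r = constraint.references[n]
                key = float(np.dot(s - s.mean(), r))
            else:
                key = float(stats.skew(s))
                if key == 0.0:
                    key = float(s[0])
            if key < 0:
                W[k, n] *= -1.0
    return W


def optimize(X, order: int | None = None, opts: OptimizerOptions | None = None,
             constraint=None, ridge_scale: float = DEFAULT_RIDGE_SCALE) -> RunResult:
    """Minimize the (optionally constrained) IVA-G objective.

    Parameters
    ----------
    X:
        List of reduced datasets (or a (K, N, S) array), all with the same
        order and sample count.
    order:
        Expected common order N (validated when given).
    constraint:
        Optional :class:`~ivafusion.constraints.ReferenceSet`; when present
        (and its ``lam`` > 0) the threshold-free regularizer is added to the
        objective.
    """
    from ivafusion import constraints as _constraints

    opts = opts or OptimizerOptions()
    Xs = _as_stack(X)
    K, N, S = Xs.shape
    if order is not None and order != N:
        raise ValueError(f"datasets have order {N}, expected {order}")
    if constraint is not None and constraint.lam == 0:
        constraint = None
    if constraint is not None:
        constraint.validate_against(n_components=N, n_samples=S)

    Xc = Xs - Xs.mean(axis=2, keepdims=True)

    if opts.init == "supplied":
        if opts.W0 is None:
            raise ValueError("init='supplied' requires W0")
        W = np.array(opts.W0, dtype=float, copy=True)
        if W.shape != (K, N, N):
            raise ValueError(f"W0 must be {(K, N, N)}, got {W.shape}")
    else:
        rng = np.random.default_rng(opts.seed)
        W = _random_orthogonal_stack(K, N, rng)

    if constraint is None:
        cost_fn = lambda Wm: ivag_cost(Wm, Xc, ridge_scale=ridge_scale)
        grad_fn = lambda Wm: ivag_gradient(Wm, Xc, ridge_scale=ridge_scale)
    else:
        cost_fn = lambda Wm: _constraints.constrained_cost(Wm, Xc, constraint, ridge_scale=ridge_scale)
        grad_fn = lambda Wm: _constraints.constrained_gradient(Wm, Xc, constraint, ridge_scale=ridge_scale)

    cost = cost_fn(W)
    if not np.isfinite(cost):
        raise OptimizationError("non-finite cost at initialization")
    cost_trace = [cost]
    step = opts.initial_step
    converged = False
    iteration = 0
    for iteration in range(1, opts.max_iterations + 1):
        grad = grad_fn(W)
        accepted = False
        while step >= opts.min_step:
            W_try = W - step * grad
            try:
                cost_try = cost_fn(W_try)
            except OptimizationError:
                cost_try = np.inf
            if np.isfinite(cost_try) and cost_try <= cost:
                accepted = True
                break
            step *= opts.step_shrink
        if not accepted:
            # cannot improve along -grad at the step floor: treat as converged
            converged = True
            break
        change = _w_change(W_try, W)
        W, cost = W_try, cost_try
        cost_trace.append(cost)
        logger.debug("iter=%d cost=%.8f step=%.3e w_change=%.3e", iteration, cost, step, change)
        step = min(step * opts.step_growth, 10.0)
        if not np.isfinite(cost):
            raise OptimizationError(f"non-finite cost at iteration {iteration}")
        if change < opts.w_change_tolerance:
            converged = True
            break

    W = _pin_scale_and_sign(W, Xc, constraint)
    sources = W @ Xc
    scv_cov = estimate_scv_covariances(sources, ridge_scale=ridge_scale)
    return RunResult(
        W=DemixingEnsemble(W),
        sources=sources,
        scv_cov=scv_cov,
        cost_trace=np.asarray(cost_trace),
        converged=converged,
        seed=opts.seed,
        n_iterations=iteration,
        constrained_count=0 if constraint is None else constraint.n_references,
    )


def multi_run(X, order: int | None = None, n_runs: int = 10, base_seed: int = 0,
              opts: OptimizerOptions | None = None, constraint=None):
    """Run :func:`optimize` with seeds ``base_seed .. base_seed+n_runs-1``.

    Failures are recorded per seed without aborting the collection.  Returns
    an (unselected) :class:`~ivafusion.evaluation.RunCollection`.
    """
    from ivafusion.evaluation import RunCollection

    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    template = opts or OptimizerOptions()
    runs, failures = [], {}
    for i in range(n_runs):
        seed = base_seed + i
        run_opts = OptimizerOptions(
            max_iterations=template.max_iterations,
            w_change_tolerance=template.w_change_tolerance,
            initial_step=template.initial_step,
            step_growth=template.step_growth,
            step_shrink=template.step_shrink,
            min_step=template.min_step,
            seed=seed,
            init="random-orthogonal",
        )
        try:
            runs.append(optimize(X, order=order, opts=run_opts, constraint=constraint))
        except (OptimizationError, ValueError) as exc:  # pragma: no cover - rare
            logger.warning("run with seed %d failed: %s", seed, exc)
            failures[seed] = str(exc)
    return RunCollection(runs=runs, failures=failures)


def save_run_result(run: RunResult, out_dir) -> None:
    """Persist a run: matrices as ``.npy``, scalars/metadata as JSON."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.save(out / "demixing.npy", run.W.W)
    np.save(out / "sources.npy", run.sources)
    np.save(out / "scv_covariances.npy", run.scv_cov.sigma)
    meta = {
        "cost_trace": run.cost_trace.tolist(),
        "converged": bool(run.converged),
        "seed": int(run.seed),
        "n_iterations": int(run.n_iterations),
        "constrained_count": int(run.constrained_count),
    }
    (out / "run.json").write_text(json.dumps(meta, indent=2))
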