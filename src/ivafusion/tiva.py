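"""Transposed IVA orchestration.

Datasets are transposed so that voxels become the observed axis (reduced by
PCA) and subjects become the statistical samples.  Estimated sources are then
subject profiles, and the columns of the reduced mixing matrices — mapped
back through the voxel-axis reducer — are spatial maps.  Constraints, when
used, act on the profiles (e.g. behavioral score vectors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ivafusion.constraints import ReferenceSet
from ivafusion.data_io import (
    FeatureDataset,
    ReducedDataset,
    back_project_profiles,
    pca_whiten,
    transpose_for_tiva,
)
from ivafusion.iva_core import OptimizerOptions, RunResult, optimize

logger = logging.getLogger(__name__)


@dataclass
class TivaResult:
    """Profiles, back-projected spatial maps and the underlying run."""

    profiles: np.ndarray  # (K, N, T)
    spatial_maps: list[np.ndarray]  # K matrices (V, N)
    run: RunResult
    reduced: list[ReducedDataset]
    constrained_index: int | None = None

    @property
    def order(self) -> int:
        return self.profiles.shape[1]

    @property
    def dataset_count(self) -> int:
        return self.profiles.shape[0]


def _check_shared_subjects(datasets: list[FeatureDataset]) -> int:
    T = datasets[0].subject_count
    ids = datasets[0].subject_ids
    for ds in datasets[1:]:
        if ds.subject_count != T:
            raise ValueError(
                f"subject axis mismatch: {ds.task_id} has {ds.subject_count} subjects, expected {T}"
            )
        if ds.subject_ids != ids:
            raise ValueError(f"subject order mismatch in {ds.task_id}")
    return T


def _reduce_transposed(datasets: list[FeatureDataset], order: int) -> list[ReducedDataset]:
    reduced = []
    for ds in datasets:
        transposed = transpose_for_tiva(ds) if ds.observed_axis == "subjects" else ds
        reduced.append(pca_whiten(transposed, order))
    return reduced


def run_constrained_tiva(
    datasets: list[FeatureDataset],
    behavioral_reference,
    order: int = 6,
    opts: OptimizerOptions | None = None,
    lam: float = 100.0,
    allow_multiple_references: bool = False,
) -> TivaResult:
    """Constrained tIVA with a behavioral reference on the subject axis.

    The reference protocol is one reference per run: behavioral measures
    typically overlap, so each is applied individually; pass
    ``allow_multiple_references=True`` to override.  ``lam=0`` falls back to
    the unconstrained path (bitwise identical to
    :func:`run_tiva_unconstrained` at the same seed).
    """
    T = _check_shared_subjects(datasets)
    K = len(datasets)
    if T < 3 * K:
        logger.warning(
            "sample-poor regime: %d subjects for %d datasets (fewer than 3 per dataset axis)",
            T, K,
        )
    refs = np.atleast_2d(np.asarray(behavioral_reference, dtype=float))
    if refs.shape[0] > 1 and not allow_multiple_references:
        raise ValueError(
            "constrained tIVA applies one reference per run; "
            "set allow_multiple_references=True to override"
        )
    if refs.shape[1] != T:
        raise ValueError(f"reference length {refs.shape[1]} does not match subject count {T}")

    reduced = _reduce_transposed(datasets, order)
    constraint = None
    constrained_index = None
    if lam > 0:
        constraint = ReferenceSet(references=refs, lam=lam)
        constrained_index = 0
    run = optimize(reduced, order=order, opts=opts, constraint=constraint)
    mixing = np.linalg.inv(run.W.W)  # reduced-space mixing, (K, N, N)
    spatial_maps = [back_project_profiles(mixing[k], reduced[k].reducer) for k in range(K)]
    return TivaResult(
        profiles=run.sources,
        spatial_maps=spatial_maps,
        run=run,
        reduced=reduced,
        constrained_index=constrained_index,
    )


def run_tiva_unconstrained(
    datasets: list[FeatureDataset],
    order: int = 6,
    opts: OptimizerOptions | None = None,
) -> TivaResult:
    """Unconstrained tIVA baseline (the λ=0 special case)."""
    T = _check_shared_subjects(datasets)
    dummy = np.linspace(-1.0, 1.0, T)  # never used: lam=0 short-circuits
    return run_constrained_tiva(datasets, dummy, order=order, opts=opts, lam=0.0)


def match_components(a: TivaResult, b: TivaResult) -> dict:
    """Greedy maximum-|spatial-correlation| pairing of two results' components.

    Spatial maps are concatenated across datasets per component before
    correlating.  Returns ``{"mapping": {a_idx: b_idx}, "correlations":
    {a_idx: |r|}}``.
    """
    if a.dataset_count != b.dataset_count:
        raise ValueError("dataset counts differ")
    for k in range(a.dataset_count):
        if a.spatial_maps[k].shape[0] != b.spatial_maps[k].shape[0]:
            raise ValueError(f"voxel counts differ in dataset {k}")
    N = a.order
    if b.order != N:
        raise ValueError("component counts differ")
    stack_a = np.vstack([m for m in a.spatial_maps])  # (K*V, N)
    stack_b = np.vstack([m for m in b.spatial_maps])
    ca = stack_a - stack_a.mean(axis=0)
    cb = stack_b - stack_b.mean(axis=0)
    norm_a = np.linalg.norm(ca, axis=0)
    norm_b = np.linalg.norm(cb, axis=0)
    corr = np.abs(ca.T @ cb) / np.outer(norm_a, norm_b)
    mapping: dict[int, int] = {}
    correlations: dict[int, float] = {}
    avail_a = set(range(N))
    avail_b = set(range(N))
    work = corr.copy()
    for _ in range(N):
        i, j = np.unravel_index(np.argmax(work), work.shape)
        mapping[int(i)] = int(j)
        correlations[int(i)] = float(corr[i, j])
        avail_a.discard(int(i))
        avail_b.discard(int(j))
        work[i, :] = -np.inf
        work[:, j] = -np.inf
    return {"mapping": mapping, "correlations": correlations}
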