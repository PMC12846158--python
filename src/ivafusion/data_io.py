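"""Loading, validation, PCA whitening, transposition and back-projection.

Feature data are dense real matrices with the observed variables on the rows
and the statistical samples on the columns after reduction.  In the standard
(IVA) orientation a dataset is subjects-by-voxels, the subject axis is
reduced and the voxels are the samples; the transposed (tIVA) orientation
flips both roles.

Conventions used throughout the package:

* covariances are computed with the ``1/S`` (maximum-likelihood) normalizer,
  so whitened data satisfy ``(1/S) X Xᵀ = I`` exactly and the IVA-G cost of
  the identity demixing ensemble on whitened data is exactly zero;
* principal axes have their sign fixed so that the largest-magnitude entry
  of each projection row is positive, which makes reductions reproducible
  across platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

SUBJECT_AXIS = "subjects"
VOXEL_AXIS = "voxels"

_AXIS_FLIP = {SUBJECT_AXIS: VOXEL_AXIS, VOXEL_AXIS: SUBJECT_AXIS}


class DataValidationError(ValueError):
    """Raised when an input matrix violates a structural invariant."""


@dataclass
class FeatureDataset:
    """One task's feature matrix with axis metadata.

    ``data`` has the *observed* axis on the rows (subjects in the IVA
    orientation, voxels in the tIVA orientation) and the sample axis on the
    columns.
    """

    data: np.ndarray
    task_id: str = "task"
    subject_ids: list[str] | None = None
    observed_axis: str = SUBJECT_AXIS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataValidationError(
                f"dataset {self.task_id!r}: expected a 2-D matrix, got ndim={self.data.ndim}"
            )
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise DataValidationError(
                f"dataset {self.task_id!r}: non-finite value at row {bad[0]}, column {bad[1]}"
            )
        if min(self.data.shape) < 2:
            raise DataValidationError(
                f"dataset {self.task_id!r}: both axes need length >= 2, got shape {self.data.shape}"
            )
        if self.observed_axis not in _AXIS_FLIP:
            raise DataValidationError(f"unknown observed_axis {self.observed_axis!r}")
        if self.subject_ids is None:
            n_subj = self.data.shape[0] if self.observed_axis == SUBJECT_AXIS else self.data.shape[1]
            self.subject_ids = [f"sub-{i:04d}" for i in range(n_subj)]

    @property
    def n_observed(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def subject_count(self) -> int:
        return self.data.shape[0] if self.observed_axis == SUBJECT_AXIS else self.data.shape[1]

    @property
    def voxel_count(self) -> int:
        return self.data.shape[1] if self.observed_axis == SUBJECT_AXIS else self.data.shape[0]


@dataclass
class ReductionOperator:
    """Whitening PCA projection together with its pseudo-inverse.

    ``projection`` maps the centered observed axis (length D) to N whitened
    components; ``back_projection`` is its Moore-Penrose pseudo-inverse and
    returns reduced-space quantities to the original observed axis.
    """

    projection: np.ndarray  # (N, D)
    mean_vector: np.ndarray  # (D,)
    back_projection: np.ndarray  # (D, N)
    eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def order(self) -> int:
        return self.projection.shape[0]

    @property
    def observed_dim(self) -> int:
        return self.projection.shape[1]


@dataclass
class ReducedDataset:
    """Whitened N-by-S matrix plus the operator that produced it."""

    data: np.ndarray  # (N, S)
    sample_axis: str
    reducer: ReductionOperator
    task_id: str = "task"

    @property
    def order(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _read_matrix(path) -> np.ndarray:
    """Read a dense matrix from delimited text or a ``.npy`` container."""
    path = str(path)
    if path.endswith(".npy"):
        return np.asarray(np.load(path), dtype=float)
    delimiter = "," if path.endswith(".csv") else None
    try:
        return np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise DataValidationError(f"non-numeric cell while reading {path}: {exc}") from exc


def write_matrix(path, matrix: np.ndarray) -> None:
    """Write a matrix so that a read-back reproduces it bitwise.

    Text output uses ``%.17g`` which round-trips IEEE doubles exactly.
    """
    path = str(path)
    matrix = np.asarray(matrix, dtype=float)
    if path.endswith(".npy"):
        np.save(path, matrix)
        return
    delimiter = "," if path.endswith(".csv") else "\t"
    np.savetxt(path, matrix, fmt="%.17g", delimiter=delimiter)


def load_feature_matrices(paths, layout: str = SUBJECT_AXIS, task_ids=None) -> list[FeatureDataset]:
    """Load K feature matrices and enforce the shared-axis rule.

    Parameters
    ----------
    paths:
        Files holding T-by-V matrices (TSV/CSV/whitespace text or ``.npy``).
    layout:
        ``"subjects"`` — rows are subjects, all files must share T and the
        subject order (IVA case); ``"voxels"`` — rows are voxels, all files
        must share V (tIVA case).
    """
    if layout not in _AXIS_FLIP:
        raise DataValidationError(f"unknown layout {layout!r}")
    if not paths:
        raise DataValidationError("no input files given")
    if task_ids is None:
        task_ids = [f"task-{i}" for i in range(len(paths))]
    datasets = []
    for path, task_id in zip(paths, task_ids):
        matrix = _read_matrix(path)
        datasets.append(FeatureDataset(matrix, task_id=task_id, observed_axis=layout))
    first = datasets[0]
    for ds, path in zip(datasets[1:], list(paths)[1:]):
        if ds.data.shape[0] != first.data.shape[0]:
            axis = "subject axis mismatch" if layout == SUBJECT_AXIS else "voxel axis mismatch"
            raise DataValidationError(
                f"{axis}: {path} has {ds.data.shape[0]} rows, expected {first.data.shape[0]}"
            )
        if ds.data.shape[1] != first.data.shape[1]:
            raise DataValidationError(
                f"sample axis mismatch: {path} has {ds.data.shape[1]} columns, "
                f"expected {first.data.shape[1]}"
            )
    return datasets


def transpose_for_tiva(ds: FeatureDataset) -> FeatureDataset:
    """Transpose a dataset, flipping the observed/sample roles (involution)."""
    return FeatureDataset(
        ds.data.T,
        task_id=ds.task_id,
        subject_ids=list(ds.subject_ids),
        observed_axis=_AXIS_FLIP[ds.observed_axis],
    )


def pca_whiten(ds: FeatureDataset, order: int, rank_tol: float = 1e-10) -> ReducedDataset:
    """Reduce the observed axis to ``order`` whitened components.

    Rows are centered across samples, the top-``order`` principal directions
    of the ``1/S``-normalized row covariance are retained and scaled by the
    inverse square roots of their eigenvalues, so the output rows have zero
    mean and exactly identity sample covariance.

    When the observed dimension exceeds the sample count the eigenproblem is
    solved in the dual (Gram-matrix) space, which keeps the tIVA orientation
    (voxels observed, subjects as samples) cheap.
    """
    X = ds.data
    D, S = X.shape
    if order < 1:
        raise DataValidationError(f"order must be >= 1, got {order}")
    mean = X.mean(axis=1)
    Xc = X - mean[:, None]
    if not np.any(Xc):
        raise DataValidationError("zero-variance input: data has rank 0 after centering")

    if D <= S:
        cov = (Xc @ Xc.T) / S
        eigval, eigvec = np.linalg.eigh(cov)  # ascending
        eigval, eigvec = eigval[::-1], eigvec[:, ::-1]
    else:
        gram = (Xc.T @ Xc) / S
        gval, gvec = np.linalg.eigh(gram)
        gval, gvec = gval[::-1], gvec[:, ::-1]
        keep = gval > rank_tol * max(gval[0], 0.0)
        eigval = gval
        # left singular vectors: u_i = Xc v_i / (S λ_i)^(1/2)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(keep, 1.0 / np.sqrt(np.maximum(gval * S, np.finfo(float).tiny)), 0.0)
        eigvec = Xc @ (gvec * scale[None, :])

    rank = int(np.sum(eigval > rank_tol * max(eigval[0], 0.0)))
    if rank == 0:
        raise DataValidationError("zero-variance input: data has rank 0 after centering")
    if order > rank:
        raise DataValidationError(f"order exceeds data rank: order={order}, rank={rank}")

    eigval = eigval[:order]
    eigvec = eigvec[:, :order]
    # deterministic sign: largest-magnitude entry of each projection row positive
    signs = np.sign(eigvec[np.argmax(np.abs(eigvec), axis=0), np.arange(order)])
    signs[signs == 0] = 1.0
    eigvec = eigvec * signs[None, :]

    projection = (eigvec / np.sqrt(eigval)[None, :]).T  # (N, D)
    back_projection = eigvec * np.sqrt(eigval)[None, :]  # (D, N)
    reducer = ReductionOperator(
        projection=projection,
        mean_vector=mean,
        back_projection=back_projection,
        eigenvalues=eigval.copy(),
    )
    reduced = projection @ Xc
    sample_axis = _AXIS_FLIP[ds.observed_axis]
    return ReducedDataset(data=reduced, sample_axis=sample_axis, reducer=reducer, task_id=ds.task_id)


def back_project_profiles(A_reduced: np.ndarray, reducer: ReductionOperator) -> np.ndarray:
    """Express reduced-space mixing columns in the original observed axis.

    Returns ``back_projection @ A_reduced`` with shape (D, n_columns): mixing
    profiles over subjects in the IVA orientation, spatial maps over voxels
    in the tIVA orientation.
    """
    A_reduced = np.asarray(A_reduced, dtype=float)
    if A_reduced.ndim != 2 or A_reduced.shape[0] != reducer.order:
        raise DataValidationError(
            f"shape mismatch: mixing is {A_reduced.shape}, reducer order is {reducer.order}"
        )
    return reducer.back_projection @ A_reduced


def write_component_volumes(maps: np.ndarray, mask_img, path) -> None:
    """Scatter V-by-N component maps into a binary mask and save as NIfTI.

    ``mask_img`` is a ``nibabel`` spatial image whose nonzero voxels define
    the voxel order (C order of the boolean mask).
    """
    import nibabel as nib

    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    mask = np.asarray(mask_img.dataobj) > 0
    n_in_mask = int(mask.sum())
    if maps.shape[0] != n_in_mask:
        raise DataValidationError(
            f"mask/voxel-count mismatch: maps have {maps.shape[0]} voxels, mask has {n_in_mask}"
        )
    n_components = maps.shape[1]
    volume = np.zeros(mask.shape + (n_components,), dtype=np.float32)
    for j in range(n_components):
        frame = np.zeros(mask.shape, dtype=np.float32)
        frame[mask] = maps[:, j]
        volume[..., j] = frame
    img = nib.Nifti1Image(volume, mask_img.affine, header=None)
    nib.save(img, str(path))


def vectorize_volume(img, mask_img) -> np.ndarray:
    """Extract in-mask voxel values (mask C-order), one column per frame."""
    data = np.asarray(img.dataobj, dtype=float)
    mask = np.asarray(mask_img.dataobj) > 0
    if data.ndim == mask.ndim:
        return data[mask]
    return data[mask, :]
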