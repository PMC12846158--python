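"""Stability selection, model-order scanning and group-difference statistics.

Run-to-run reproducibility is measured with a cross-run joint-ISI: the
Amari-style inter-symbol-interference score of the global matrices
``W_a[k] · W_b[k]⁻¹``, summed elementwise in absolute value across datasets
and normalized to [0, 1].  The most reproducible run of a collection is the
one with the smallest mean distance to all others.

Group statistics follow the pooled-variance convention throughout: Student
two-sample t-tests, Benjamini–Hochberg adjustment, and pooled-SD Cohen's d.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ivafusion.constraints import ReferenceSet, similarity_eps2
from ivafusion.iva_core import OptimizerOptions, multi_run

logger = logging.getLogger(__name__)


@dataclass
class GroupLabels:
    """Binary group membership: 0 = control, 1 = patient."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(int)
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary (0/1)")
        if self.count(0) == 0 or self.count(1) == 0:
            raise ValueError("both groups must be non-empty")

    def count(self, group: int) -> int:
        return int(np.sum(self.labels == group))

    def split(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        values = np.asarray(values, dtype=float)
        return values[self.labels == 0], values[self.labels == 1]


@dataclass
class RunCollection:
    """Repeated seeded runs plus their pairwise cross-joint-ISI."""

    runs: list
    failures: dict = field(default_factory=dict)
    cross_isi: np.ndarray | None = None
    selected_index: int | None = None

    @property
    def selected(self):
        if self.selected_index is None:
            raise ValueError("collection has not been selected yet")
        return self.runs[self.selected_index]


def _demixing_of(run) -> np.ndarray:
    if hasattr(run, "W"):
        W = run.W
    elif hasattr(run, "run"):
        W = run.run.W
    else:
        return np.asarray(run, dtype=float)
    return W.W if hasattr(W, "W") else np.asarray(W, dtype=float)


def joint_isi(G) -> float:
    """Joint inter-symbol interference of K global matrices, in [0, 1].

    With ``ḡ_ij = Σ_k |G[k]_ij|``, returns

        [Σ_i (Σ_j ḡ_ij / max_j ḡ_ij − 1) + Σ_j (Σ_i ḡ_ij / max_i ḡ_ij − 1)]
        / (2N(N−1)).

    Zero iff ḡ is a generalized permutation matrix (one nonzero per row and
    column); one for the all-ones ḡ.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim == 2:
        G = G[None]
    N = G.shape[1]
    if G.shape[2] != N:
        raise ValueError("global matrices must be square")
    if N == 1:
        return 0.0
    gbar = np.abs(G).sum(axis=0)
    row_max = gbar.max(axis=1)
    col_max = gbar.max(axis=0)
    if np.any(row_max == 0) or np.any(col_max == 0):
        raise ValueError("zero row or column in global matrix")
    row_term = (gbar / row_max[:, None]).sum(axis=1) - 1.0
    col_term = (gbar / col_max[None, :]).sum(axis=0) - 1.0
    return float((row_term.sum() + col_term.sum()) / (2.0 * N * (N - 1)))


def cross_joint_isi(a, b) -> float:
    """Symmetrized joint-ISI distance between two demixing solutions.

    Evaluates ``joint_isi({W_a[k] W_b[k]⁻¹})`` and the role-swapped variant
    and returns their mean; zero for ambiguity-equivalent solutions
    (consistent row permutation and rescaling).
    """
    Wa = _demixing_of(a)
    Wb = _demixing_of(b)
    if Wa.shape != Wb.shape:
        raise ValueError(f"shape mismatch: {Wa.shape} vs {Wb.shape}")
    inv_b = np.linalg.inv(Wb)
    inv_a = np.linalg.inv(Wa)
    forward = joint_isi(Wa @ inv_b)
    backward = joint_isi(Wb @ inv_a)
    return 0.5 * (forward + backward)


def select_most_reproducible(runs) -> RunCollection:
    """Pick the run minimizing mean cross-joint-ISI to all other runs.

    Ties break deterministically toward the lowest index.
    """
    if isinstance(runs, RunCollection):
        collection = runs
    else:
        collection = RunCollection(runs=list(runs))
    n = len(collection.runs)
    if n < 2:
        raise ValueError("need at least 2 successful runs to select")
    cross = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            cross[i, j] = cross[j, i] = cross_joint_isi(collection.runs[i], collection.runs[j])
    mean_dist = cross.sum(axis=1) / (n - 1)
    collection.cross_isi = cross
    collection.selected_index = int(np.argmin(mean_dist))
    return collection


def order_scan(datasets, orders, n_runs: int = 10, base_seed: int = 0,
               opts: OptimizerOptions | None = None) -> pd.DataFrame:
    """Scan model orders; report mean cross-ISI of the selected run per order.

    ``datasets`` are FeatureDatasets (reduced per order internally).  Orders
    exceeding the data rank are marked failed without affecting the rest.
    The row minimizing ``mean_cross_isi`` is flagged, but selection is left
    to the caller.
    """
    from ivafusion.data_io import pca_whiten

    orders = list(orders)
    rows = []
    for order in orders:
        try:
            reduced = [pca_whiten(ds, order) for ds in datasets]
            coll = multi_run(reduced, order=order, n_runs=n_runs, base_seed=base_seed, opts=opts)
            coll = select_most_reproducible(coll)
            sel = coll.selected_index
            mean_isi = float(coll.cross_isi[sel].sum() / (len(coll.runs) - 1))
            rows.append({"order": order, "mean_cross_isi": mean_isi,
                         "selected_seed": coll.runs[sel].seed, "failed": False, "error": ""})
        except (ValueError, RuntimeError) as exc:
            rows.append({"order": order, "mean_cross_isi": np.nan,
                         "selected_seed": -1, "failed": True, "error": str(exc)})
    table = pd.DataFrame(rows)
    ok = table.loc[~table["failed"], "mean_cross_isi"]
    table["is_minimizer"] = False
    if len(ok):
        table.loc[ok.idxmin(), "is_minimizer"] = True
    return table


def two_sample_ttest(values, groups: GroupLabels) -> tuple[float, float]:
    """Pooled-variance (Student) two-sample t-test, two-sided.

    Returns ``(t, p)`` for group 1 minus group 0 with n1+n2−2 degrees of
    freedom.
    """
    g0, g1 = groups.split(values)
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each group needs at least 2 observations")
    if g0.std(ddof=1) == 0 and g1.std(ddof=1) == 0:
        if g0.mean() == g1.mean():
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(g1, g0, equal_var=True)
    return float(t), float(p)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def cohens_d(values, groups: GroupLabels) -> float:
    """Pooled-SD standardized mean difference (group 1 minus group 0)."""
    g0, g1 = groups.split(values)
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each group needs at least 2 observations")
    n0, n1 = len(g0), len(g1)
    pooled_var = ((n0 - 1) * g0.var(ddof=1) + (n1 - 1) * g1.var(ddof=1)) / (n0 + n1 - 2)
    if pooled_var == 0:
        if g0.mean() == g1.mean():
            return 0.0
        raise ValueError("zero pooled standard deviation")
    return float((g1.mean() - g0.mean()) / np.sqrt(pooled_var))


def component_stats(profiles: np.ndarray, groups: GroupLabels, alpha: float = 0.05,
                    family: str = "per_task", task_ids=None) -> pd.DataFrame:
    """Two-sample statistics for every component × dataset profile.

    ``profiles`` is (K, N, T): per-subject loadings of each component in each
    dataset.  FDR adjustment is applied within each task (``family=
    'per_task'``, the default) or across all tests (``family='pooled'``).
    Returns a table with columns component, task, t, p, p_adj, d,
    significant.
    """
    profiles = np.asarray(profiles, dtype=float)
    K, N, T = profiles.shape
    if T != len(groups.labels):
        raise ValueError("profile length does not match group labels")
    if task_ids is None:
        task_ids = [f"task-{k}" for k in range(K)]
    records = []
    for k in range(K):
        for n in range(N):
            t, p = two_sample_ttest(profiles[k, n], groups)
            d = cohens_d(profiles[k, n], groups)
            records.append({"component": n, "task": task_ids[k], "t": t, "p": p, "d": d})
    table = pd.DataFrame(records)
    if family == "per_task":
        table["p_adj"] = np.nan
        for task in table["task"].unique():
            sel = table["task"] == task
            table.loc[sel, "p_adj"] = fdr_adjust(table.loc[sel, "p"].to_numpy())
    elif family == "pooled":
        table["p_adj"] = fdr_adjust(table["p"].to_numpy())
    else:
        raise ValueError(f"unknown FDR family {family!r}")
    table["significant"] = table["p_adj"] < alpha
    return table


def reference_correlation_table(result, R: ReferenceSet, task_ids=None) -> pd.DataFrame:
    """|Pearson correlation| between each constrained component and its reference.

    ``result`` is a RunResult or TivaResult; reference n is compared with
    component n of every dataset (absolute value — sign is not identifiable).
    """
    sources = result.sources if hasattr(result, "sources") else result.profiles
    K, N, S = sources.shape
    R.validate_against(n_components=N, n_samples=S)
    if task_ids is None:
        task_ids = [f"task-{k}" for k in range(K)]
    records = []
    for k in range(K):
        for n in range(R.n_references):
            eps2 = similarity_eps2(R.references[n], sources[k, n])
            records.append({
                "task": task_ids[k],
                "reference": R.labels[n],
                "component": n,
                "abs_correlation": float(np.sqrt(eps2)),
            })
    return pd.DataFrame(records)


def average_network_references(network_maps: dict, lam: float = 100.0) -> ReferenceSet:
    """Average each network's maps into a single z-scored reference.

    ``network_maps`` maps a network label to a non-empty list of equal-length
    voxel vectors.  Degenerate (constant) averages raise at construction.
    """
    labels, vectors = [], []
    length = None
    for name, maps in network_maps.items():
        if not maps:
            raise ValueError(f"network {name!r} has no maps")
        maps = [np.asarray(m, dtype=float) for m in maps]
        if length is None:
            length = maps[0].size
        if any(m.size != length for m in maps):
            raise ValueError(f"network {name!r}: map length mismatch")
        labels.append(name)
        vectors.append(np.mean(maps, axis=0))
    return ReferenceSet(references=np.stack(vectors), labels=labels, lam=lam)
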