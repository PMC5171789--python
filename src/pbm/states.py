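"""Spatial dimension reduction and k-means state clustering of time points.

Each time point is a point in ROI space; PCA reduces the spatial dimension to
the smallest number of components reaching a target explained-variance
fraction (default 85%), and k-means groups time points into ``k`` global
states by their reduced spatial configuration.  States are relabelled so that
state 1 is the most occupied — the clustering itself carries no meaningful
state order, and a fixed convention keeps cross-run comparisons stable.
Labels are 1-based throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = ["PcaReduction", "StateModel", "pca_reduce", "fit_states", "state_occupancy"]


@dataclass
class PcaReduction:
    """A fitted PCA basis: ``basis`` is ``(N, d)`` with orthonormal columns."""

    basis: np.ndarray
    mean: np.ndarray
    explained_fraction: float
    d: int

    def transform(self, data: np.ndarray) -> np.ndarray:
        return (np.asarray(data, dtype=float) - self.mean) @ self.basis

    def inverse_transform(self, reduced: np.ndarray) -> np.ndarray:
        return reduced @ self.basis.T + self.mean


@dataclass
class StateModel:
    """A fitted k-means state assignment of time points.

    ``labels`` are 1-based and relabelled so occupancy is non-increasing in
    the state index; ``centroids`` live in the reduced (PCA) space.
    """

    labels: np.ndarray
    k: int
    centroids: np.ndarray
    inertia: float
    restarts_used: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 1 or self.labels.max() > self.k:
            raise ValueError("labels must lie in 1..k")

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]


def pca_reduce(
    data: np.ndarray, retain_fraction: float = 0.85
) -> tuple[PcaReduction, np.ndarray]:
    """Project ``(T, N)`` data onto the fewest components explaining ``retain_fraction``.

    Returns the fitted :class:`PcaReduction` and the ``(T, d)`` reduced matrix.
    """
    if not (0.0 < retain_fraction <= 1.0):
        raise ValueError("retain_fraction must lie in (0, 1]")
    data = np.asarray(data, dtype=float)
    t, n = data.shape
    if t <= n:
        raise ValueError(f"need more time points than ROIs for a full PCA ({t} <= {n})")
    pca = PCA(svd_solver="full").fit(data)
    cumulative = np.cumsum(pca.explained_variance_ratio_)
    d = int(np.searchsorted(cumulative, retain_fraction - 1e-12) + 1)
    d = min(d, cumulative.size)
    reduction = PcaReduction(
        basis=pca.components_[:d].T.copy(),
        mean=pca.mean_.copy(),
        explained_fraction=float(cumulative[d - 1]),
        d=d,
    )
    return reduction, reduction.transform(data)


def fit_states(
    reduced: np.ndarray,
    k: int,
    restarts: int = 20,
    max_iter: int = 1000,
    seed: int | None = None,
) -> StateModel:
    """K-means (Euclidean, k-means++ init, best of ``restarts``) on time points."""
    reduced = np.asarray(reduced, dtype=float)
    if k < 2:
        raise ValueError("k must be at least 2")
    if reduced.shape[0] < k:
        raise ValueError("fewer time points than clusters")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=restarts,
        max_iter=max_iter,
        random_state=seed,
        algorithm="lloyd",
    ).fit(reduced)
    raw_labels = km.labels_
    counts = np.bincount(raw_labels, minlength=k)
    if (counts == 0).any():
        raise ValueError("k-means converged with an empty cluster in every restart")
    # relabel by descending occupancy; ties broken by original cluster index
    order = np.lexsort((np.arange(k), -counts))
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)
    return StateModel(
        labels=rank[raw_labels] + 1,
        k=k,
        centroids=km.cluster_centers_[order],
        inertia=float(km.inertia_),
        restarts_used=restarts,
        seed=seed,
    )


def state_occupancy(
    model: StateModel, boundaries: tuple[int, ...] | None = None
) -> tuple[np.ndarray, pd.DataFrame | None]:
    """Pooled and (if boundaries given) per-subject state occupancy fractions.

    Each row of the per-subject frame sums to 1; the pooled vector sums to 1.
    """
    pooled = model.counts / model.labels.size
    if boundaries is None:
        return pooled, None
    starts = (0,) + tuple(boundaries[:-1])
    rows = []
    for a, b in zip(starts, boundaries):
        seg = model.labels[a:b]
        rows.append(np.bincount(seg, minlength=model.k + 1)[1:] / seg.size)
    frame = pd.DataFrame(rows, columns=[f"state_{s}" for s in range(1, model.k + 1)])
    return pooled, frame
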