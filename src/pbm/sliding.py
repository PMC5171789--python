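"""Sliding-window baseline: windowed connectivity and per-subject window-state
clustering, used as the temporal-sensitivity contrast to the point-based
pipeline.  A window of ``window_length`` time points (default 120, i.e.
86.4 s at TR = 0.72 s) is slid with stride 1; each window yields one
vectorized upper-triangle Pearson connectivity matrix, and the window
vectors are PCA-reduced and k-means clustered per subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .timeseries import RoiTimeSeries

__all__ = ["WindowSeries", "window_connectivity", "window_states"]


@dataclass
class WindowSeries:
    """Vectorized per-window connectivity for one subject."""

    vectors: np.ndarray  # (n_windows, N*(N-1)/2)
    window_length: int
    stride: int
    centers: np.ndarray  # window-center time indices (float for even lengths)
    n_rois: int

    @property
    def n_windows(self) -> int:
        return self.vectors.shape[0]


def window_connectivity(
    ts: RoiTimeSeries | np.ndarray, window_length: int, stride: int = 1
) -> WindowSeries:
    """Per-window Pearson connectivity, upper triangle vectorized.

    With ``T`` time points and stride 1 there are ``T - window_length + 1``
    windows; a window equal to the full series reproduces the static matrix.
    """
    values = ts.values if isinstance(ts, RoiTimeSeries) else np.asarray(ts, dtype=float)
    t, n = values.shape
    if window_length < 3:
        raise ValueError("window_length must be at least 3")
    if window_length > t:
        raise ValueError("window_length exceeds the series length")
    if stride < 1:
        raise ValueError("stride must be at least 1")
    iu = np.triu_indices(n, k=1)
    starts = np.arange(0, t - window_length + 1, stride)
    vectors = np.empty((starts.size, iu[0].size))
    for w, s in enumerate(starts):
        c = np.corrcoef(values[s : s + window_length], rowvar=False)
        vectors[w] = c[iu]
    centers = starts + (window_length - 1) / 2.0
    return WindowSeries(
        vectors=vectors,
        window_length=window_length,
        stride=stride,
        centers=centers,
        n_rois=n,
    )


def window_states(
    series: WindowSeries,
    k: int = 8,
    retain_components: int = 30,
    restarts: int = 20,
    max_iter: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """PCA to ``retain_components`` then k-means on one subject's window vectors.

    Returns 1-based window-state labels (aligned to ``series.centers``),
    relabelled by descending occupancy.  ``k=1`` returns a constant label.
    """
    x = series.vectors
    if k < 1:
        raise ValueError("k must be at least 1")
    if k == 1:
        return np.ones(x.shape[0], dtype=int)
    n_comp = min(retain_components, x.shape[0] - 1, x.shape[1])
    reduced = PCA(n_components=n_comp, svd_solver="full").fit_transform(x)
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=restarts,
        max_iter=max_iter,
        random_state=seed,
        algorithm="lloyd",
    ).fit(reduced)
    counts = np.bincount(km.labels_, minlength=k)
    order = np.lexsort((np.arange(k), -counts))
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)
    return rank[km.labels_] + 1
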