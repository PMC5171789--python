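"""State graphlets, their mapping onto time, and proportional binarization.

An *s-graphlet* is one ROI x ROI Pearson-correlation matrix computed over all
time points assigned to one state, with pairs of ROIs whose centres lie
closer than a distance cutoff (default 15 mm) zeroed to suppress trivially
local connectivity.  A *t-graphlet* is the connectivity matrix attached to a
single time point — here simply a copy of the s-graphlet of the state that
time point belongs to, so an edge's trajectory through time takes at most
``k`` distinct values and is fully described by the state-label sequence.

Proportional binarization keeps the top fraction of eligible (non-masked,
upper-triangle) edges of each graphlet by signed weight.  Because every
t-graphlet is a copy of its s-graphlet, thresholding is done once per
s-graphlet and broadcast over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .states import StateModel
from .timeseries import RoiAtlas

__all__ = [
    "SGraphlet",
    "TGraphletSeries",
    "BinaryEdgeSeries",
    "build_s_graphlets",
    "derive_t_graphlets",
    "proportional_binarize",
]


@dataclass
class SGraphlet:
    """Per-state connectivity: symmetric ``(N, N)`` weights, zero diagonal."""

    state_id: int
    weights: np.ndarray
    n_points: int
    masked: np.ndarray | None = None  # True where the distance cutoff zeroed the pair

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=0):
            raise ValueError("weights must be exactly symmetric")
        self.weights = w

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]


def build_s_graphlets(
    data: np.ndarray,
    model: StateModel,
    atlas: RoiAtlas | None = None,
    distance_cutoff_mm: float = 15.0,
) -> list[SGraphlet]:
    """Pearson correlation per state over that state's time points.

    Correlations are computed in the original ROI space (never the PCA
    space).  With an atlas, ROI pairs closer than ``distance_cutoff_mm`` are
    set to exactly 0; the diagonal is always 0.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[0] != model.labels.size:
        raise ValueError("data rows and state labels disagree in length")
    n = data.shape[1]
    if atlas is not None:
        if len(atlas) != n:
            raise ValueError("atlas size does not match ROI count")
        mask = atlas.short_distance_mask(distance_cutoff_mm)
        np.fill_diagonal(mask, False)  # diagonal handled separately
    else:
        mask = None

    graphlets: list[SGraphlet] = []
    for state in range(1, model.k + 1):
        rows = data[model.labels == state]
        if rows.shape[0] < 3:
            raise ValueError(
                f"state {state} has only {rows.shape[0]} time points; "
                "correlation needs at least 3"
            )
        weights = np.corrcoef(rows, rowvar=False)
        weights = (weights + weights.T) / 2.0  # enforce exact symmetry
        np.fill_diagonal(weights, 0.0)
        if mask is not None:
            weights[mask] = 0.0
        graphlets.append(
            SGraphlet(
                state_id=state,
                weights=weights,
                n_points=int(rows.shape[0]),
                masked=None if mask is None else mask.copy(),
            )
        )
    return graphlets


@dataclass
class TGraphletSeries:
    """Per-time-point state labels referencing the shared s-graphlet set.

    Matrices are never duplicated per time point: the label sequence plus the
    ``k`` s-graphlets fully determine every t-graphlet.
    """

    labels_per_subject: list[np.ndarray]
    graphlets: list[SGraphlet]
    tr_seconds: float | None = None

    def __post_init__(self) -> None:
        ids = {g.state_id for g in self.graphlets}
        for labels in self.labels_per_subject:
            present = set(np.unique(labels).tolist())
            if not present <= ids:
                raise ValueError(f"labels reference states {present - ids} with no s-graphlet")

    @property
    def k(self) -> int:
        return len(self.graphlets)

    @property
    def n_rois(self) -> int:
        return self.graphlets[0].n_rois

    @property
    def n_subjects(self) -> int:
        return len(self.labels_per_subject)

    def edge_trace(self, i: int, j: int, subject: int = 0) -> np.ndarray:
        """The weight of edge (i, j) at every time point of one subject."""
        lookup = np.array([g.weights[i, j] for g in self.graphlets])
        return lookup[self.labels_per_subject[subject] - 1]


def derive_t_graphlets(
    model: StateModel,
    s_graphlets: list[SGraphlet],
    boundaries: tuple[int, ...] | None = None,
    tr_seconds: float | None = None,
) -> TGraphletSeries:
    """Map each time point to its state's s-graphlet (pure lookup)."""
    if boundaries is None:
        labels_per_subject = [model.labels.copy()]
    else:
        starts = (0,) + tuple(boundaries[:-1])
        labels_per_subject = [model.labels[a:b].copy() for a, b in zip(starts, boundaries)]
    return TGraphletSeries(labels_per_subject, list(s_graphlets), tr_seconds=tr_seconds)


@dataclass
class BinaryEdgeSeries:
    """Thresholded edge presence over time.

    Two backings are possible.  Pipeline-derived series store the per-state
    retained-edge table (``retained``, shape ``(k, E)``) plus the per-subject
    label sequences — presence of edge ``e`` at time ``t`` is
    ``retained[label[t]-1, e]``.  Explicit series (synthetic schedules,
    fixtures) store per-subject boolean presence matrices directly.
    """

    edges: np.ndarray  # (E, 2) upper-triangle ROI index pairs
    threshold_fraction: float | None = None
    labels_per_subject: list[np.ndarray] | None = None
    retained: np.ndarray | None = None
    presence_per_subject: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int)
        pipeline = self.retained is not None and self.labels_per_subject is not None
        explicit = self.presence_per_subject is not None
        if pipeline == explicit:
            raise ValueError(
                "provide either (retained + labels_per_subject) or presence_per_subject"
            )
        if pipeline:
            if self.retained.shape[1] != self.n_edges:
                raise ValueError("retained table and edge list disagree")
        else:
            for p in self.presence_per_subject:
                if p.shape[1] != self.n_edges:
                    raise ValueError("presence matrix and edge list disagree")

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def n_subjects(self) -> int:
        if self.presence_per_subject is not None:
            return len(self.presence_per_subject)
        return len(self.labels_per_subject)

    @property
    def subject_lengths(self) -> list[int]:
        if self.presence_per_subject is not None:
            return [p.shape[0] for p in self.presence_per_subject]
        return [len(l) for l in self.labels_per_subject]

    def presence_matrix(self, subject: int) -> np.ndarray:
        """Boolean ``(T_s, E)`` presence matrix for one subject."""
        if self.presence_per_subject is not None:
            return self.presence_per_subject[subject]
        return self.retained[self.labels_per_subject[subject] - 1]

    def presence_indices(self, edge: int) -> list[np.ndarray]:
        """Sorted presence-time indices of one edge, per subject."""
        out = []
        for s in range(self.n_subjects):
            if self.presence_per_subject is not None:
                col = self.presence_per_subject[s][:, edge]
            else:
                col = self.retained[self.labels_per_subject[s] - 1, edge]
            out.append(np.flatnonzero(col))
        return out

    @property
    def ever_present(self) -> np.ndarray:
        """Edges present in at least one state / at least once."""
        if self.retained is not None:
            return self.retained.any(axis=0)
        return np.logical_or.reduce([p.any(axis=0) for p in self.presence_per_subject])

    @classmethod
    def from_presence(
        cls,
        presence_per_subject: list[np.ndarray],
        edges: np.ndarray,
        threshold_fraction: float | None = None,
    ) -> "BinaryEdgeSeries":
        return cls(
            edges=edges,
            threshold_fraction=threshold_fraction,
            presence_per_subject=[np.asarray(p, dtype=bool) for p in presence_per_subject],
        )


def proportional_binarize(series: TGraphletSeries, fraction: float) -> BinaryEdgeSeries:
    """Keep the top ``fraction`` of eligible edges of every graphlet.

    Eligible edges are the upper-triangle ROI pairs not zeroed by the
    distance mask; the mask never inflates the denominator and masked pairs
    can never be present.  Exactly ``round(fraction * E_eligible)`` edges are
    retained per state; ties in weight are broken by the fixed (row-major
    upper-triangle) edge order.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = series.n_rois
    iu = np.triu_indices(n, k=1)
    masked = series.graphlets[0].masked
    if masked is not None:
        eligible = ~masked[iu]
    else:
        eligible = np.ones(iu[0].size, dtype=bool)
    edges = np.column_stack([iu[0][eligible], iu[1][eligible]])
    n_eligible = edges.shape[0]
    m = int(round(fraction * n_eligible))
    if m == 0:
        raise ValueError(
            f"fraction {fraction} keeps zero of {n_eligible} eligible edges"
        )

    retained = np.zeros((series.k, n_eligible), dtype=bool)
    for s, graphlet in enumerate(series.graphlets):
        weights = graphlet.weights[iu][eligible]
        if not np.all(np.isfinite(weights)):
            raise ValueError(f"state {graphlet.state_id} has non-finite edge weights")
        # stable sort on descending weight; ties keep fixed edge order
        order = np.argsort(-weights, kind="stable")
        retained[s, order[:m]] = True
    return BinaryEdgeSeries(
        edges=edges,
        threshold_fraction=fraction,
        labels_per_subject=[l.copy() for l in series.labels_per_subject],
        retained=retained,
    )
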