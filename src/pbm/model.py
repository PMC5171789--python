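"""The point-based dynamic-connectivity model and its fitted results.

:class:`PointBasedModel` bundles the full pipeline behind a statsmodels-like
interface: build the model from per-subject ROI time series (plus optional
motion series and atlas), call :meth:`~PointBasedModel.fit`, and receive a
:class:`PBMResults` carrying the state assignment, per-state s-graphlets,
occupancy, dwell and transition summaries, with methods for thresholded
binarization, burstiness classification, edge-difference testing, and
plotting.

Example
-------
>>> from pbm import PointBasedModel, SimulationSpec, simulate
>>> sim = simulate(SimulationSpec(n_subjects=3, n_rois=20, n_timepoints=400,
...                               k_true=4, seed=7))
>>> model = PointBasedModel(sim.timeseries, atlas=sim.atlas, motion=sim.motion,
...                         k=4, band=None)
>>> res = model.fit(seed=0)
>>> print(res.summary())           # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import burstiness as _burst
from . import graphlets as _graphlets
from . import preprocess as _prep
from . import stats as _stats
from .states import PcaReduction, StateModel, fit_states, pca_reduce, state_occupancy
from .timeseries import MotionSeries, RoiAtlas, RoiTimeSeries

__all__ = ["PointBasedModel", "PBMResults"]


class PointBasedModel:
    """Point-based dynamic functional connectivity model.

    Parameters
    ----------
    timeseries
        One :class:`~pbm.timeseries.RoiTimeSeries` per subject (stage
        ``raw``), or already-z-scored series when ``preprocess=False``.
    atlas
        Optional :class:`~pbm.timeseries.RoiAtlas`; enables the
        short-distance edge mask and network-level summaries.
    motion
        Optional per-subject :class:`~pbm.timeseries.MotionSeries` for
        scrubbing (FD threshold taken from each series).
    k
        Number of global states (default 8).
    retain_fraction
        PCA explained-variance target before clustering (default 0.85).
    band
        Band-pass edges in Hz, or ``None`` to skip filtering (appropriate
        for synthetic data without drift or physiological noise).
    distance_cutoff_mm
        ROI pairs closer than this are zeroed in every s-graphlet.
    """

    def __init__(
        self,
        timeseries: list[RoiTimeSeries],
        atlas: RoiAtlas | None = None,
        *,
        motion: list[MotionSeries] | None = None,
        k: int = 8,
        retain_fraction: float = 0.85,
        restarts: int = 20,
        max_iter: int = 1000,
        band: tuple[float, float] | None = (0.01, 0.1),
        distance_cutoff_mm: float = 15.0,
        preprocess: bool = True,
    ):
        if motion is not None and len(motion) != len(timeseries):
            raise ValueError("need one motion series per subject")
        self.timeseries = list(timeseries)
        self.atlas = atlas
        self.motion = list(motion) if motion is not None else None
        self.k = k
        self.retain_fraction = retain_fraction
        self.restarts = restarts
        self.max_iter = max_iter
        self.band = band
        self.distance_cutoff_mm = distance_cutoff_mm
        self.preprocess = preprocess

    @classmethod
    def from_dataframes(
        cls,
        frames: list[pd.DataFrame],
        tr_seconds: float,
        atlas: pd.DataFrame | RoiAtlas | None = None,
        **kwargs,
    ) -> "PointBasedModel":
        """Build from per-subject time x ROI DataFrames (columns = ROI ids)."""
        series = [
            RoiTimeSeries(
                values=f.to_numpy(dtype=float),
                tr_seconds=tr_seconds,
                subject_id=f"sub-{i:03d}",
                roi_ids=tuple(f.columns),
            )
            for i, f in enumerate(frames)
        ]
        if isinstance(atlas, pd.DataFrame):
            atlas = RoiAtlas(atlas)
        return cls(series, atlas=atlas, **kwargs)

    def fit(self, seed: int | None = None) -> "PBMResults":
        """Preprocess, concatenate, PCA-reduce, cluster, and build graphlets."""
        if self.preprocess:
            prepped = []
            for i, ts in enumerate(self.timeseries):
                mo = self.motion[i] if self.motion is not None else None
                prepped.append(_prep.preprocess_subject(ts, motion=mo, band=self.band))
        else:
            prepped = self.timeseries
        concat = _prep.concatenate_subjects(prepped)
        reduction, reduced = pca_reduce(concat.values, self.retain_fraction)
        states = fit_states(
            reduced, self.k, restarts=self.restarts, max_iter=self.max_iter, seed=seed
        )
        s_graphlets = _graphlets.build_s_graphlets(
            concat.values, states, atlas=self.atlas, distance_cutoff_mm=self.distance_cutoff_mm
        )
        t_series = _graphlets.derive_t_graphlets(
            states, s_graphlets, boundaries=concat.boundaries, tr_seconds=concat.tr_seconds
        )
        return PBMResults(
            model=self,
            concatenated=concat,
            reduction=reduction,
            states=states,
            s_graphlets=s_graphlets,
            t_graphlets=t_series,
            seed=seed,
        )


@dataclass
class PBMResults:
    """Fitted point-based model: states, graphlets, and derived summaries."""

    model: PointBasedModel
    concatenated: _prep.ConcatenatedSeries
    reduction: PcaReduction
    states: StateModel
    s_graphlets: list[_graphlets.SGraphlet]
    t_graphlets: _graphlets.TGraphletSeries
    seed: int | None = None

    # -- basic summaries -------------------------------------------------

    @property
    def labels_per_subject(self) -> list[np.ndarray]:
        return self.t_graphlets.labels_per_subject

    def occupancy(self) -> tuple[np.ndarray, pd.DataFrame]:
        pooled, per_subject = state_occupancy(self.states, self.concatenated.boundaries)
        return pooled, per_subject

    def dwell(self) -> _stats.DwellSummary:
        return _stats.dwell_times(
            self.labels_per_subject, self.concatenated.tr_seconds, k=self.states.k
        )

    def transitions(self) -> _stats.TransitionMatrix:
        return _stats.transition_probabilities(self.labels_per_subject, k=self.states.k)

    def transition_distance_correlation(
        self, n_perm: int = 10_000, seed: int | None = None
    ) -> tuple[float, float]:
        return _stats.transition_distance_correlation(
            self.transitions(), self.s_graphlets, n_perm=n_perm, seed=seed
        )

    def boundary_profile(self, half_width: int = 5) -> tuple[np.ndarray, np.ndarray]:
        return _stats.transition_boundary_profile(
            self.concatenated.values, self.labels_per_subject, half_width=half_width
        )

    # -- temporal-network machinery --------------------------------------

    def binarize(self, fraction: float) -> _graphlets.BinaryEdgeSeries:
        return _graphlets.proportional_binarize(self.t_graphlets, fraction)

    def burstiness(
        self,
        fraction: float = 0.05,
        n_perm: int = 200,
        alpha: float = 0.05,
        seed: int | None = None,
    ) -> _burst.BurstinessResult:
        return _burst.classify_burstiness(
            self.binarize(fraction), n_perm=n_perm, alpha=alpha, seed=seed
        )

    def difference_test(
        self,
        state_a: int,
        state_b: int,
        n_perm: int = 10_000,
        seed: int | None = None,
    ) -> _stats.EdgeDifferenceTest:
        masked = self.s_graphlets[0].masked
        return _stats.sgraphlet_difference_test(
            self.concatenated.values,
            self.states,
            state_a,
            state_b,
            n_perm=n_perm,
            seed=seed,
            masked=masked,
        )

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        """A text summary of the fitted state model and its temporal profile."""
        pooled, _ = self.occupancy()
        dwell = self.dwell()
        tm = self.transitions()
        lines = [
            "Point-based dynamic functional connectivity".center(62),
            "=" * 62,
            f"{'Subjects:':<28}{self.concatenated.n_subjects:>10}",
            f"{'Time points (total):':<28}{self.concatenated.n_timepoints:>10}",
            f"{'ROIs:':<28}{self.concatenated.n_rois:>10}",
            f"{'PCA components (d):':<28}{self.reduction.d:>10}",
            f"{'Explained variance:':<28}{self.reduction.explained_fraction:>10.3f}",
            f"{'States (k):':<28}{self.states.k:>10}",
            f"{'Restarts:':<28}{self.states.restarts_used:>10}",
            f"{'Inertia:':<28}{self.states.inertia:>10.1f}",
            f"{'Mean dwell (scans):':<28}{dwell.mean_scans:>10.2f}",
            f"{'Mean dwell (seconds):':<28}{dwell.mean_seconds:>10.2f}",
            f"{'State transitions:':<28}{tm.n_transitions:>10}",
            "-" * 62,
            "State occupancy (fraction of volumes), states ordered by size:",
        ]
        for s in range(self.states.k):
            lines.append(f"  state {s + 1:<2}  {pooled[s]:>8.3f}")
        lines.append("=" * 62)
        return "\n".join(lines)

    # -- plotting ---------------------------------------------------------

    def plot_states(self, subject: int = 0, ax=None):
        """Step plot of the state sequence for one subject."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 2.5))
        labels = self.labels_per_subject[subject]
        t = np.arange(labels.size) * self.concatenated.tr_seconds
        ax.step(t, labels, where="post", lw=0.8)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("state")
        ax.set_yticks(range(1, self.states.k + 1))
        ax.set_title(f"state sequence, subject {self.concatenated.subject_ids[subject]}")
        return ax

    def plot_sgraphlet(self, state: int, ax=None):
        """Heat map of one state's connectivity matrix."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4))
        g = self.s_graphlets[state - 1]
        im = ax.imshow(g.weights, vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_title(f"s-graphlet {state} (n={g.n_points})")
        ax.figure.colorbar(im, ax=ax, shrink=0.8)
        return ax
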