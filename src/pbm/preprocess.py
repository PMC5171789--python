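"""Preprocessing chain: scrub -> interpolate -> band-pass -> z-score -> concatenate.

Motion scrubbing replaces high-FD volumes with cubic-spline estimates fitted
per ROI on the retained volumes (series length is unchanged).  Filtering is a
zero-phase (forward-backward) Butterworth band-pass, order 2 per pass, the
standard resting-state fMRI choice: it removes scanner drift and
high-frequency physiological noise without the phase distortion that would
shift state boundaries in time.  Z-scoring standardises each ROI column;
concatenation stacks subjects along time while recording boundaries so that
no downstream statistic (dwell runs, inter-contact times) spans two subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfiltfilt

from .timeseries import MotionSeries, RoiTimeSeries

__all__ = [
    "scrub_and_interpolate",
    "bandpass",
    "zscore",
    "ConcatenatedSeries",
    "concatenate_subjects",
    "preprocess_subject",
]


def scrub_and_interpolate(ts: RoiTimeSeries, motion: MotionSeries) -> RoiTimeSeries:
    """Replace volumes with FD above threshold by cubic-spline estimates.

    Flagged volumes strictly inside the retained range are re-estimated per
    ROI with a cubic spline fitted on the retained time points; flagged
    volumes at the series boundary hold the nearest retained value instead
    (cubic extrapolation is unstable).  The returned series has the same
    length, ``stage="scrubbed"``, and ``scrub_fraction`` set to the fraction
    of volumes replaced.
    """
    if ts.stage != "raw":
        raise ValueError(f"scrubbing expects stage='raw', got {ts.stage!r}")
    if motion.fd.shape[0] != ts.n_timepoints:
        raise ValueError(
            f"FD length {motion.fd.shape[0]} does not match series length {ts.n_timepoints}"
        )
    flagged = motion.flagged
    if flagged.all():
        raise ValueError("all volumes exceed the FD threshold; input is unrecoverable")

    values = ts.values.copy()
    kept_idx = np.flatnonzero(~flagged)
    bad_idx = np.flatnonzero(flagged)
    if bad_idx.size:
        lo, hi = kept_idx[0], kept_idx[-1]
        interior = bad_idx[(bad_idx > lo) & (bad_idx < hi)]
        if interior.size:
            spline = CubicSpline(kept_idx, ts.values[kept_idx], axis=0)
            values[interior] = spline(interior)
        # boundary-flagged volumes: hold nearest retained value
        values[bad_idx[bad_idx < lo]] = ts.values[lo]
        values[bad_idx[bad_idx > hi]] = ts.values[hi]

    return ts.with_values(
        values, stage="scrubbed", scrub_fraction=float(flagged.mean())
    )


def bandpass(ts: RoiTimeSeries, low_hz: float = 0.01, high_hz: float = 0.1) -> RoiTimeSeries:
    """Zero-phase Butterworth band-pass (order 2 per pass) of every ROI column."""
    if ts.stage not in ("raw", "scrubbed"):
        raise ValueError(f"bandpass expects stage 'raw' or 'scrubbed', got {ts.stage!r}")
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz must satisfy 0 < low < high < Nyquist={nyquist:.4g} Hz"
        )
    sos = butter(2, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr_seconds, output="sos")
    filtered = sosfiltfilt(sos, ts.values, axis=0)
    return ts.with_values(filtered, stage="filtered")


def zscore(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Standardise each ROI column to mean 0 and (population) SD 1."""
    sd = ts.values.std(axis=0, ddof=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [ts.roi_ids[i] for i in dead[:5]]
        raise ValueError(f"zero-variance ROI column(s): {names}")
    z = (ts.values - ts.values.mean(axis=0)) / sd
    return ts.with_values(z, stage="zscored")


@dataclass
class ConcatenatedSeries:
    """Subject time series stacked along time, with subject boundaries.

    ``boundaries`` holds the cumulative end row of every subject, e.g. two
    subjects of 100 points give ``(100, 200)``.  Downstream pooling (dwell
    runs, inter-contact times) must never bridge a boundary.
    """

    values: np.ndarray
    boundaries: tuple[int, ...]
    subject_ids: tuple[str, ...]
    tr_seconds: float
    roi_ids: tuple[str, ...]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    @property
    def n_subjects(self) -> int:
        return len(self.boundaries)

    def slices(self) -> list[slice]:
        starts = (0,) + self.boundaries[:-1]
        return [slice(a, b) for a, b in zip(starts, self.boundaries)]

    def split(self, vector: np.ndarray) -> list[np.ndarray]:
        """Split a length-``T_total`` vector back into per-subject pieces."""
        vector = np.asarray(vector)
        if vector.shape[0] != self.n_timepoints:
            raise ValueError("vector length does not match concatenated length")
        return [vector[s] for s in self.slices()]


def concatenate_subjects(series: list[RoiTimeSeries]) -> ConcatenatedSeries:
    """Stack z-scored subjects row-wise, recording subject boundaries."""
    if not series:
        raise ValueError("no subjects to concatenate")
    first = series[0]
    for ts in series:
        if ts.stage != "zscored":
            raise ValueError(f"subject {ts.subject_id!r} is not z-scored (stage={ts.stage!r})")
        if ts.roi_ids != first.roi_ids:
            raise ValueError(f"subject {ts.subject_id!r} has a mismatched ROI set/order")
        if ts.tr_seconds != first.tr_seconds:
            raise ValueError("subjects have differing sampling intervals")
    values = np.vstack([ts.values for ts in series])
    boundaries = tuple(np.cumsum([ts.n_timepoints for ts in series]).tolist())
    return ConcatenatedSeries(
        values=values,
        boundaries=boundaries,
        subject_ids=tuple(ts.subject_id for ts in series),
        tr_seconds=first.tr_seconds,
        roi_ids=first.roi_ids,
    )


def preprocess_subject(
    ts: RoiTimeSeries,
    motion: MotionSeries | None = None,
    band: tuple[float, float] | None = (0.01, 0.1),
) -> RoiTimeSeries:
    """Run one subject through scrub -> band-pass -> z-score.

    ``motion=None`` skips scrubbing; ``band=None`` skips filtering (useful for
    synthetic data that contain no drift or physiological noise).
    """
    if motion is not None:
        ts = scrub_and_interpolate(ts, motion)
    if band is not None:
        ts = bandpass(ts, *band)
    return zscore(ts)
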