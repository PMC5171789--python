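"""Core data containers: ROI time series, motion series, and the ROI atlas.

An :class:`RoiTimeSeries` is a plain ``(T, N)`` matrix of signal intensities
(one column per region of interest) together with the sampling interval (TR)
and a ``stage`` flag recording how far along the preprocessing chain
(raw -> scrubbed -> filtered -> zscored) the data have travelled.  The atlas
carries ROI centre coordinates in millimetres and a resting-state-network
label per ROI; both are needed downstream for the short-distance edge mask
and for within-/between-network summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "STAGES",
    "RoiTimeSeries",
    "MotionSeries",
    "RoiAtlas",
    "load_timeseries_csv",
    "load_motion_csv",
]

STAGES = ("raw", "scrubbed", "filtered", "zscored")


@dataclass
class RoiTimeSeries:
    """A ``(T, N)`` ROI signal matrix for one subject (or a concatenation).

    Parameters
    ----------
    values
        Signal intensities, time along axis 0, ROIs along axis 1.
    tr_seconds
        Sampling interval (repetition time) in seconds.
    subject_id
        Identifier carried through the pipeline.
    stage
        One of ``raw``, ``scrubbed``, ``filtered``, ``zscored``.
    roi_ids
        Optional column labels; defaults to ``roi_000`` ... when omitted.
    scrub_fraction
        Fraction of volumes replaced during scrubbing (set by
        :func:`pbm.preprocess.scrub_and_interpolate`).
    """

    values: np.ndarray
    tr_seconds: float
    subject_id: str = "subject"
    stage: str = "raw"
    roi_ids: tuple[str, ...] | None = None
    scrub_fraction: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (time x ROI) matrix")
        t, n = self.values.shape
        if t < 2 or n < 2:
            raise ValueError(f"need at least 2 time points and 2 ROIs, got {t} x {n}")
        if not np.isfinite(self.tr_seconds) or self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be a positive real")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if self.roi_ids is None:
            self.roi_ids = tuple(f"roi_{i:03d}" for i in range(n))
        else:
            self.roi_ids = tuple(str(r) for r in self.roi_ids)
            if len(self.roi_ids) != n:
                raise ValueError("roi_ids length does not match number of columns")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, stage: str, **kwargs) -> "RoiTimeSeries":
        """Return a copy with new values and stage (other metadata kept)."""
        return replace(self, values=values, stage=stage, **kwargs)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.roi_ids))


@dataclass
class MotionSeries:
    """Per-volume framewise displacement (FD, in mm) with a scrub threshold."""

    fd: np.ndarray
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float).ravel()
        if self.fd.size == 0:
            raise ValueError("fd is empty")
        if np.any(~np.isfinite(self.fd)) or np.any(self.fd < 0):
            raise ValueError("fd must be finite and non-negative")
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")

    @property
    def flagged(self) -> np.ndarray:
        """Boolean mask of volumes exceeding the FD threshold."""
        return self.fd > self.threshold


class RoiAtlas:
    """ROI centres (mm) and resting-state-network labels.

    Backed by a DataFrame with columns ``id, x, y, z, network``; ROI order is
    the column order of the companion time-series matrices.
    """

    REQUIRED = ("id", "x", "y", "z", "network")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"atlas table missing columns {missing}")
        table = table.reset_index(drop=True)
        if table["id"].duplicated().any():
            raise ValueError("atlas ROI ids are not unique")
        if table["network"].isna().any():
            raise ValueError("every ROI needs exactly one network label")
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    @property
    def coords(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def networks(self) -> np.ndarray:
        return self.table["network"].to_numpy()

    @property
    def network_names(self) -> list[str]:
        seen: list[str] = []
        for name in self.networks:
            if name not in seen:
                seen.append(name)
        return seen

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean distances between ROI centres, in mm."""
        xyz = self.coords
        diff = xyz[:, None, :] - xyz[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    def short_distance_mask(self, cutoff_mm: float) -> np.ndarray:
        """Boolean ``(N, N)`` mask of pairs closer than ``cutoff_mm`` (incl. diagonal)."""
        return self.distance_matrix() < cutoff_mm

    @classmethod
    def from_csv(cls, path: str | Path) -> "RoiAtlas":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def load_timeseries_csv(
    path: str | Path,
    tr_seconds: float,
    subject_id: str | None = None,
    sep: str | None = None,
) -> RoiTimeSeries:
    """Read one subject's time x ROI table (CSV/TSV with a header row of ROI ids)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep)
    return RoiTimeSeries(
        values=frame.to_numpy(dtype=float),
        tr_seconds=tr_seconds,
        subject_id=subject_id or path.stem,
        roi_ids=tuple(frame.columns),
    )


def load_motion_csv(path: str | Path, threshold: float = 0.5) -> MotionSeries:
    """Read a single-column framewise-displacement series aligned to the volumes."""
    frame = pd.read_csv(path)
    if frame.shape[1] != 1:
        raise ValueError("motion file must contain a single FD column")
    return MotionSeries(fd=frame.iloc[:, 0].to_numpy(dtype=float), threshold=threshold)
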