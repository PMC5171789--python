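"""Seedable generator of multi-subject ROI time series with planted states.

The generator emulates the statistical structure the point-based pipeline
assumes in resting-state data: a latent Markov chain over ``k_true`` global
states (mean dwell set through the self-transition mass; the default 6.3
scans matches the dwell regime typical of low-TR resting-state recordings),
per-state multivariate-Gaussian observations with distinct spatial mean
patterns and covariances, optional gradual (smoothstep) drift of the mean at
state transitions, framewise-displacement spikes with optional signal
corruption at the flagged volumes, and a grid-placed atlas whose minimum ROI
spacing guarantees that the short-distance edge mask is exercised.

Per-state mean offsets default on (``mean_scale`` in z-units): states in
resting-state data differ in their global amplitude configuration, and it is
this spatial configuration the time-point clustering keys on.  Zero-mean
covariance-only states are available by setting ``mean_scale=0``.

``simulate_edge_schedule`` produces binary edge-presence series (bursty,
tonic, periodic, random) for testing the temporal-network machinery
directly; bursty gaps follow a discrete power law with tail exponent
``alpha`` (default 1.8).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timeseries import MotionSeries, RoiAtlas, RoiTimeSeries

__all__ = [
    "SimulationSpec",
    "SimulationResult",
    "simulate",
    "simulate_edge_schedule",
    "make_grid_atlas",
    "DEFAULT_NETWORK_NAMES",
]

# abbreviations conventional for resting-state network parcellations
DEFAULT_NETWORK_NAMES = ("DM", "SM", "Vis", "FP", "Sa", "CO", "Au", "Sub", "DA", "VA")


@dataclass
class SimulationSpec:
    """Parameters of the synthetic resting-state study."""

    n_subjects: int = 20
    n_rois: int = 60
    n_timepoints: int = 1200
    tr_seconds: float = 0.72
    k_true: int = 8
    mean_dwell_scans: float = 6.3  # sets the self-transition mass 1 - 1/dwell
    mean_scale: float = 1.0  # per-state mean offset SD, z-units
    noise_sd: float = 0.0  # extra iid noise on top of the state covariance draw
    cov_mix: float = 0.5  # weight of the random correlation part vs identity
    state_covariances: list[np.ndarray] | None = None
    markov_chain: np.ndarray | None = None
    boundary_drift: str = "abrupt"  # "abrupt" | "gradual"
    ramp_length: int = 0  # points over which the mean blends in gradual mode
    motion_rate: float = 0.012  # expected fraction of FD-flagged volumes
    fd_magnitude: float = 0.8  # FD at spikes, mm (> 0.5 threshold)
    corrupt_motion_points: bool = True  # inject a signal artifact at spikes
    n_networks: int = 6
    min_spacing_mm: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boundary_drift not in ("abrupt", "gradual"):
            raise ValueError("boundary_drift must be 'abrupt' or 'gradual'")
        if self.ramp_length < 0:
            raise ValueError("ramp_length must be >= 0")
        if self.boundary_drift == "gradual" and self.ramp_length == 0:
            self.ramp_length = 4
        if self.mean_dwell_scans <= 1:
            raise ValueError("mean_dwell_scans must exceed 1")
        if self.markov_chain is not None:
            chain = np.asarray(self.markov_chain, dtype=float)
            if chain.shape != (self.k_true, self.k_true):
                raise ValueError("markov_chain must be k_true x k_true")
            if not np.allclose(chain.sum(axis=1), 1.0):
                raise ValueError("markov_chain rows must sum to 1")
            self.markov_chain = chain
        if self.state_covariances is not None:
            covs = [np.asarray(c, dtype=float) for c in self.state_covariances]
            for c in covs:
                if c.shape != (self.n_rois, self.n_rois):
                    raise ValueError("covariances must be n_rois x n_rois")
                if not np.allclose(c, c.T):
                    raise ValueError("covariances must be symmetric")
                if np.linalg.eigvalsh(c).min() < -1e-10:
                    raise ValueError("covariances must be positive semi-definite")
            self.state_covariances = covs


@dataclass
class SimulationResult:
    """All generated inputs plus the ground truth behind them."""

    timeseries: list[RoiTimeSeries]
    motion: list[MotionSeries]
    atlas: RoiAtlas
    labels: list[np.ndarray]  # planted 1-based state labels per subject
    state_means: np.ndarray  # (k, N)
    state_covariances: list[np.ndarray]
    markov_chain: np.ndarray
    spec: SimulationSpec


def _default_chain(k: int, mean_dwell: float) -> np.ndarray:
    stay = 1.0 - 1.0 / mean_dwell
    chain = np.full((k, k), (1.0 - stay) / (k - 1))
    np.fill_diagonal(chain, stay)
    return chain


def _default_covariances(rng: np.random.Generator, k: int, n: int, mix: float) -> list[np.ndarray]:
    covs = []
    rank = max(2, n // 6)
    for _ in range(k):
        a = rng.normal(size=(n, rank))
        m = a @ a.T / rank
        d = np.sqrt(np.diag(m))
        corr = m / np.outer(d, d)
        covs.append(mix * corr + (1.0 - mix) * np.eye(n))
    return covs


def make_grid_atlas(
    n_rois: int,
    min_spacing_mm: float = 12.0,
    n_networks: int = 6,
    network_names: tuple[str, ...] = DEFAULT_NETWORK_NAMES,
) -> RoiAtlas:
    """Atlas on a 3-D lattice with the given minimum centre spacing.

    With spacing below 15 mm, lattice neighbours fall inside the default
    short-distance cutoff, so the edge mask is exercised by construction.
    Networks are contiguous blocks of roughly equal size.
    """
    side = int(np.ceil(n_rois ** (1.0 / 3.0)))
    grid = np.array(
        [
            (x, y, z)
            for x in range(side)
            for y in range(side)
            for z in range(side)
        ][:n_rois],
        dtype=float,
    )
    coords = grid * min_spacing_mm
    names = list(network_names[:n_networks])
    assignments = [names[min(i * n_networks // n_rois, n_networks - 1)] for i in range(n_rois)]
    table = pd.DataFrame(
        {
            "id": [f"roi_{i:03d}" for i in range(n_rois)],
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "network": assignments,
        }
    )
    return RoiAtlas(table)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _mean_path(labels: np.ndarray, means: np.ndarray, drift: str, ramp: int) -> np.ndarray:
    """Per-time-point mean vectors; gradual mode blends across each boundary.

    The smoothstep blend has its steepest slope exactly at the boundary, so
    the successive-point distance rises toward a transition and peaks there.
    """
    path = means[labels - 1].astype(float)
    if drift == "abrupt" or ramp == 0:
        return path
    t_total = labels.size
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1  # first index of new state
    blended = path.copy()
    bounds = np.concatenate([[0], change, [t_total]])
    for idx, b in enumerate(change):
        prev_mu = means[labels[b - 1] - 1]
        next_mu = means[labels[b] - 1]
        # blend weight with its inflection midway between samples b-1 and b,
        # so the largest mean increment falls on the step crossing the boundary;
        # windows are clipped at the neighbouring transitions so short dwell
        # runs never overwrite each other's ramps
        lo = max(bounds[idx], int(np.floor(b - 0.5 - ramp / 2.0)))
        hi = min(bounds[idx + 2], int(np.ceil(b - 0.5 + ramp / 2.0)) + 1)
        for t in range(lo, hi):
            w = _smoothstep(0.5 + (t - b + 0.5) / ramp)
            blended[t] = (1.0 - w) * prev_mu + w * next_mu
    return blended


def simulate(spec: SimulationSpec) -> SimulationResult:
    """Draw the full synthetic study described by ``spec`` (bit-reproducible)."""
    rng = np.random.default_rng(spec.seed)
    k, n = spec.k_true, spec.n_rois
    chain = (
        spec.markov_chain
        if spec.markov_chain is not None
        else _default_chain(k, spec.mean_dwell_scans)
    )
    covs = (
        spec.state_covariances
        if spec.state_covariances is not None
        else _default_covariances(rng, k, n, spec.cov_mix)
    )
    chols = [np.linalg.cholesky(c + 1e-12 * np.eye(n)) for c in covs]
    means = rng.normal(0.0, spec.mean_scale, size=(k, n)) if spec.mean_scale > 0 else np.zeros((k, n))

    atlas = make_grid_atlas(n, spec.min_spacing_mm, spec.n_networks)
    timeseries: list[RoiTimeSeries] = []
    motion: list[MotionSeries] = []
    labels_out: list[np.ndarray] = []

    for s in range(spec.n_subjects):
        labels = np.empty(spec.n_timepoints, dtype=int)
        labels[0] = rng.integers(1, k + 1)
        for t in range(1, spec.n_timepoints):
            labels[t] = rng.choice(k, p=chain[labels[t - 1] - 1]) + 1

        mean_path = _mean_path(labels, means, spec.boundary_drift, spec.ramp_length)
        z = rng.standard_normal((spec.n_timepoints, n))
        values = np.empty_like(z)
        for state in range(1, k + 1):
            rows = labels == state
            values[rows] = z[rows] @ chols[state - 1].T
        values += mean_path
        if spec.noise_sd > 0:
            values += rng.normal(0.0, spec.noise_sd, size=values.shape)

        fd = rng.uniform(0.0, 0.3, size=spec.n_timepoints)
        spikes = rng.random(spec.n_timepoints) < spec.motion_rate
        fd[spikes] = spec.fd_magnitude + rng.exponential(0.2, size=int(spikes.sum()))
        if spec.corrupt_motion_points and spikes.any():
            values[spikes] += rng.normal(0.0, 5.0, size=(int(spikes.sum()), n))

        timeseries.append(
            RoiTimeSeries(
                values=values,
                tr_seconds=spec.tr_seconds,
                subject_id=f"sub-{s:03d}",
                roi_ids=tuple(atlas.ids),
            )
        )
        motion.append(MotionSeries(fd=fd, threshold=0.5))
        labels_out.append(labels)

    return SimulationResult(
        timeseries=timeseries,
        motion=motion,
        atlas=atlas,
        labels=labels_out,
        state_means=means,
        state_covariances=list(covs),
        markov_chain=chain,
        spec=spec,
    )


def simulate_edge_schedule(
    kind: str,
    length: int,
    seed: int | np.random.Generator | None = None,
    *,
    alpha: float = 1.8,
    period: int = 5,
    p: float = 0.1,
) -> np.ndarray:
    """A binary presence series of one edge with the requested temporal law.

    ``bursty``: gaps drawn from a discrete power law ``P(G >= g) = g^(1-alpha)``
    (density exponent ``alpha``, default 1.8); ``tonic``: always present;
    ``periodic``: presence every ``period`` samples; ``random``: Bernoulli(``p``).
    """
    if length < 10:
        raise ValueError("length must be at least 10")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if kind == "tonic":
        return np.ones(length, dtype=bool)
    if kind == "periodic":
        out = np.zeros(length, dtype=bool)
        out[::period] = True
        return out
    if kind == "random":
        return rng.random(length) < p
    if kind == "bursty":
        if alpha <= 1.0:
            raise ValueError("alpha must exceed 1")
        out = np.zeros(length, dtype=bool)
        t = 0
        out[0] = True
        while True:
            gap = int(np.ceil(rng.random() ** (-1.0 / (alpha - 1.0))))
            t += gap
            if t >= length:
                break
            out[t] = True
        return out
    raise ValueError(f"unknown schedule kind {kind!r}")
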