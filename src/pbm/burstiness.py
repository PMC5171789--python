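"""Inter-contact times, the Goh–Barabási burstiness coefficient, and its
permutation-based classification.

For a binarized edge, the inter-contact times (ICTs) are the sample gaps
between consecutive presences, pooled over subjects without ever bridging a
subject boundary.  The burstiness coefficient is

    B = (sigma_tau - mu_tau) / (sigma_tau + mu_tau)

with the population standard deviation and mean of the ICT list.  B lies in
[-1, 1]: regular/tonic contact patterns (constant ICTs) give -1, a
memoryless (Poisson-like) process gives values near 0, and heavy-tailed gap
distributions push B above 0.

Classification uses a max/min-statistic permutation null: each permutation
shuffles the temporal order of the thresholded t-graphlet sequence (one
permutation per subject, applied to all edges jointly, so the cross-edge
structure of the null is preserved), recomputes every edge's B, and records
the maximum and minimum over edges.  An edge is *bursty* if B > 0 and B is
at or above the ``ceil((1 - alpha/2) * n_perm)``-th order statistic of the
max distribution (the 195th of 200 at alpha = 0.05), *tonic/periodic* if
B < 0 and B is at or below the ``floor(alpha/2 * n_perm)``-th order
statistic of the min distribution (the 5th of 200), and *random* otherwise.
The inclusive comparisons matter: an always-present edge has B = -1 in the
data and in every permutation, and is classified tonic under the <=-rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graphlets import BinaryEdgeSeries

__all__ = [
    "IctSet",
    "NullDistribution",
    "BurstinessResult",
    "BetweenWithinResult",
    "extract_icts",
    "burstiness_coefficient",
    "classify_burstiness",
    "rsn_burstiness_summary",
    "between_within_test",
]


@dataclass
class IctSet:
    """Pooled inter-contact times of one edge (never spanning subjects)."""

    icts: np.ndarray
    n_contacts: int
    edge: tuple[int, int] | None = None


def extract_icts(
    presence_per_subject: list[np.ndarray], edge: tuple[int, int] | None = None
) -> IctSet:
    """Differences of consecutive presence indices within each subject, pooled.

    A subject contributes ``max(0, contacts - 1)`` ICTs; a subject where the
    edge appears fewer than twice contributes none, and no gap ever spans a
    subject boundary.
    """
    icts: list[np.ndarray] = []
    n_contacts = 0
    for presence in presence_per_subject:
        idx = np.asarray(presence)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        if np.any(np.diff(idx) <= 0):
            raise ValueError("presence indices must be strictly increasing")
        n_contacts += idx.size
        if idx.size >= 2:
            icts.append(np.diff(idx))
    pooled = np.concatenate(icts) if icts else np.empty(0, dtype=int)
    return IctSet(icts=pooled, n_contacts=n_contacts, edge=edge)


def burstiness_coefficient(icts: np.ndarray | IctSet) -> float:
    """B = (sigma - mu)/(sigma + mu) with population sigma; NaN below 2 ICTs."""
    if isinstance(icts, IctSet):
        icts = icts.icts
    icts = np.asarray(icts, dtype=float)
    if icts.size < 2:
        return float("nan")
    mu = icts.mean()
    sigma = icts.std(ddof=0)
    return float((sigma - mu) / (sigma + mu))


def _moments_to_b(count: np.ndarray, total: np.ndarray, sq_total: np.ndarray) -> np.ndarray:
    """Vectorized B from per-edge ICT count / sum / sum of squares."""
    b = np.full(count.shape, np.nan)
    ok = count >= 2
    mu = np.where(ok, total / np.maximum(count, 1), np.nan)
    var = np.where(ok, sq_total / np.maximum(count, 1) - mu**2, np.nan)
    sigma = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(invalid="ignore"):
        b[ok] = ((sigma - mu) / (sigma + mu))[ok]
    return b


def _ict_moments(columns_per_subject: list[np.ndarray]) -> tuple[np.ndarray, ...]:
    """ICT count/sum/sum-of-squares/contacts per column over subject chunks."""
    n_cols = columns_per_subject[0].shape[1]
    count = np.zeros(n_cols)
    total = np.zeros(n_cols)
    sq_total = np.zeros(n_cols)
    contacts = np.zeros(n_cols)
    for block in columns_per_subject:
        for c in range(n_cols):
            idx = np.flatnonzero(block[:, c])
            contacts[c] += idx.size
            if idx.size >= 2:
                gaps = np.diff(idx)
                count[c] += gaps.size
                total[c] += gaps.sum()
                sq_total[c] += (gaps * gaps).sum()
    return count, total, sq_total, contacts


def _edge_b(series: BinaryEdgeSeries, labels_per_subject: list[np.ndarray] | None = None,
            presence_per_subject: list[np.ndarray] | None = None) -> tuple[np.ndarray, ...]:
    """Per-edge B (and moments) for a binary series, optionally with overridden
    (e.g. permuted) labels or presence matrices.

    Pipeline-backed series are evaluated once per unique *state signature* —
    the subset of states in which an edge survives the threshold.  Edges
    sharing a signature have identical presence series, so their B (and its
    null) is identical; computing per signature and broadcasting is an exact
    shortcut.
    """
    if series.retained is not None:
        labels = labels_per_subject if labels_per_subject is not None else series.labels_per_subject
        uniq, inverse = np.unique(series.retained, axis=1, return_inverse=True)
        blocks = [uniq[l - 1, :] for l in labels]
        count, total, sq_total, contacts = _ict_moments(blocks)
        b = _moments_to_b(count, total, sq_total)
        inverse = np.asarray(inverse).ravel()
        return b[inverse], count[inverse], total[inverse], sq_total[inverse], contacts[inverse]
    presence = presence_per_subject if presence_per_subject is not None else series.presence_per_subject
    count, total, sq_total, contacts = _ict_moments(presence)
    return _moments_to_b(count, total, sq_total), count, total, sq_total, contacts


def order_statistic_cutoffs(n_perm: int, alpha: float) -> tuple[int, int]:
    """1-based ascending order-statistic indices for the max/min null cutoffs.

    Two-tailed at ``alpha``: the max-side index is ``ceil((1 - alpha/2) * n_perm)``
    (195 of 200 at alpha = 0.05) and the min-side index ``floor(alpha/2 * n_perm)``
    (5 of 200), with non-integral products rounded toward the conservative cutoff.
    """
    hi = int(math.ceil((1.0 - alpha / 2.0) * n_perm))
    lo = max(1, int(math.floor((alpha / 2.0) * n_perm)))
    return hi, lo


@dataclass
class NullDistribution:
    """Max- and min-over-edges B values from the temporal-shuffle null."""

    max_values: np.ndarray
    min_values: np.ndarray
    n_perm: int
    alpha: float
    hi_index: int
    lo_index: int
    hi_cutoff: float
    lo_cutoff: float


@dataclass
class BurstinessResult:
    """Per-edge ICT moments, B, and permutation classification."""

    edges: np.ndarray  # (E, 2)
    b: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    n_icts: np.ndarray
    n_contacts: np.ndarray
    classification: np.ndarray  # str: bursty | tonic_periodic | random | undefined
    ever_present: np.ndarray
    null: NullDistribution | None = None
    threshold_fraction: float | None = None

    def to_frame(self, networks: np.ndarray | None = None) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "i": self.edges[:, 0],
                "j": self.edges[:, 1],
                "n_icts": self.n_icts.astype(int),
                "n_contacts": self.n_contacts.astype(int),
                "mu": self.mu,
                "sigma": self.sigma,
                "B": self.b,
                "classification": self.classification,
                "ever_present": self.ever_present,
            }
        )
        if networks is not None:
            networks = np.asarray(networks)
            frame.insert(2, "rsn_i", networks[self.edges[:, 0]])
            frame.insert(3, "rsn_j", networks[self.edges[:, 1]])
        return frame


def classify_burstiness(
    series: BinaryEdgeSeries,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int | None = None,
) -> BurstinessResult:
    """Compute B per edge and classify against the max/min temporal-shuffle null.

    Each permutation applies one random reordering of the time axis per
    subject, simultaneously to all edges; shuffling preserves every edge's
    number of contacts exactly, so the null keeps edge density fixed while
    destroying temporal structure.  Edges with fewer than 2 pooled ICTs are
    ``undefined`` and excluded from the max/min statistics.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)

    b, count, total, sq_total, contacts = _edge_b(series)
    mu = np.where(count >= 1, total / np.maximum(count, 1), np.nan)
    var = sq_total / np.maximum(count, 1) - mu**2
    sigma = np.sqrt(np.maximum(var, 0.0))
    sigma[count < 1] = np.nan

    lengths = series.subject_lengths
    max_values = np.empty(n_perm)
    min_values = np.empty(n_perm)
    pipeline = series.retained is not None
    for p in range(n_perm):
        perms = [rng.permutation(t) for t in lengths]
        if pipeline:
            shuffled = [l[perm] for l, perm in zip(series.labels_per_subject, perms)]
            b_null = _edge_b(series, labels_per_subject=shuffled)[0]
        else:
            shuffled = [m[perm] for m, perm in zip(series.presence_per_subject, perms)]
            b_null = _edge_b(series, presence_per_subject=shuffled)[0]
        if np.all(np.isnan(b_null)):
            raise ValueError("a permutation produced no edge with a defined B")
        max_values[p] = np.nanmax(b_null)
        min_values[p] = np.nanmin(b_null)

    hi_idx, lo_idx = order_statistic_cutoffs(n_perm, alpha)
    hi_cut = float(np.sort(max_values)[hi_idx - 1])
    lo_cut = float(np.sort(min_values)[lo_idx - 1])

    classification = np.full(series.n_edges, "random", dtype=object)
    classification[np.isnan(b)] = "undefined"
    classification[(b > 0) & (b >= hi_cut)] = "bursty"
    classification[(b < 0) & (b <= lo_cut)] = "tonic_periodic"

    return BurstinessResult(
        edges=series.edges,
        b=b,
        mu=mu,
        sigma=sigma,
        n_icts=count,
        n_contacts=contacts,
        classification=classification,
        ever_present=series.ever_present,
        null=NullDistribution(
            max_values=max_values,
            min_values=min_values,
            n_perm=n_perm,
            alpha=alpha,
            hi_index=hi_idx,
            lo_index=lo_idx,
            hi_cutoff=hi_cut,
            lo_cutoff=lo_cut,
        ),
        threshold_fraction=series.threshold_fraction,
    )


def _block_tables(networks: np.ndarray) -> list[str]:
    seen: list[str] = []
    for name in networks:
        if name not in seen:
            seen.append(name)
    return seen


def rsn_burstiness_summary(
    result: BurstinessResult, networks: np.ndarray
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent bursty and percent tonic/periodic edges per RSN-pair block.

    Percentages are over edges present in at least one state within each
    block; within-network blocks sit on the diagonal.  Blocks with no such
    edge are NaN (undefined, not 0).
    """
    networks = np.asarray(networks)
    names = _block_tables(networks)
    idx = {n: i for i, n in enumerate(names)}
    n_net = len(names)
    eligible = np.zeros((n_net, n_net))
    bursty = np.zeros((n_net, n_net))
    tonic = np.zeros((n_net, n_net))
    for e in range(result.edges.shape[0]):
        if not result.ever_present[e]:
            continue
        a = idx[networks[result.edges[e, 0]]]
        b_ = idx[networks[result.edges[e, 1]]]
        a, b_ = min(a, b_), max(a, b_)
        eligible[a, b_] += 1
        if result.classification[e] == "bursty":
            bursty[a, b_] += 1
        elif result.classification[e] == "tonic_periodic":
            tonic[a, b_] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_bursty = np.where(eligible > 0, 100.0 * bursty / eligible, np.nan)
        pct_tonic = np.where(eligible > 0, 100.0 * tonic / eligible, np.nan)
    # mirror into symmetric tables
    for m in (pct_bursty, pct_tonic):
        lower = np.tril_indices(n_net, k=-1)
        m[lower] = m.T[lower]
    return (
        pd.DataFrame(pct_bursty, index=names, columns=names),
        pd.DataFrame(pct_tonic, index=names, columns=names),
    )


@dataclass
class BetweenWithinResult:
    """Difference of mean B between- vs within-RSN edges, with permutation test."""

    delta: float
    p_value: float
    significant: bool
    mean_between: float
    mean_within: float
    n_between: int
    n_within: int
    null_deltas: np.ndarray
    alpha: float


def between_within_test(
    result: BurstinessResult,
    networks: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> BetweenWithinResult:
    """Permutation test of mean B for between- vs within-RSN edges.

    Only edges present in at least one state and with a defined B enter.  The
    null shuffles the within/between designation across edges, preserving
    group sizes; the observed difference is compared two-tailed against the
    ``ceil((1 - alpha/2) * n_perm)``-th order statistic of the null
    differences (the 975th of 1000 at alpha = 0.05).
    """
    networks = np.asarray(networks)
    include = result.ever_present & ~np.isnan(result.b)
    if not include.any():
        raise ValueError("no edge with a defined B is present in any state")
    b = result.b[include]
    between = networks[result.edges[include, 0]] != networks[result.edges[include, 1]]
    n_between = int(between.sum())
    n_within = int((~between).sum())
    if n_between == 0 or n_within == 0:
        raise ValueError("both the between- and within-RSN groups must be nonempty")

    delta = float(b[between].mean() - b[~between].mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for p in range(n_perm):
        shuffled = rng.permutation(between)
        null[p] = b[shuffled].mean() - b[~shuffled].mean()

    hi_idx, lo_idx = order_statistic_cutoffs(n_perm, alpha)
    sorted_null = np.sort(null)
    significant = bool(delta >= sorted_null[hi_idx - 1] or delta <= sorted_null[lo_idx - 1])
    p_value = float((1 + np.sum(np.abs(null) >= abs(delta))) / (1 + n_perm))
    return BetweenWithinResult(
        delta=delta,
        p_value=p_value,
        significant=significant,
        mean_between=float(b[between].mean()),
        mean_within=float(b[~between].mean()),
        n_between=n_between,
        n_within=n_within,
        null_deltas=null,
        alpha=alpha,
    )
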