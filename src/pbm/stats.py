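"""Statistical comparison of s-graphlets and temporal summaries of the state
sequence: edge-wise permutation difference tests with FDR, network-level
summaries, transition probabilities, dwell times, graphlet distances, and the
transition-boundary distance profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from .graphlets import SGraphlet
from .states import StateModel

__all__ = [
    "EdgeDifferenceTest",
    "sgraphlet_difference_test",
    "fdr_adjust",
    "rsn_difference_summary",
    "TransitionMatrix",
    "transition_probabilities",
    "DwellSummary",
    "dwell_times",
    "graphlet_distance",
    "transition_distance_correlation",
    "transition_boundary_profile",
]


@dataclass
class EdgeDifferenceTest:
    """Edge-wise permutation comparison of two s-graphlets.

    ``difference`` and ``p_values`` run over the upper-triangle edges in
    ``edges`` order; ``significant`` is populated by :func:`fdr_adjust` (BH
    over the pooled family of all edges and all tested state pairs).
    Two-tailed p-values are ``(1 + #{|null| >= |obs|}) / (1 + n_perm)`` so a
    permutation p can never be exactly 0.
    """

    state_a: int
    state_b: int
    edges: np.ndarray  # (E, 2)
    difference: np.ndarray  # corr(a) - corr(b), per edge
    p_values: np.ndarray
    n_permutations: int
    significant: np.ndarray | None = None
    alpha: float | None = None


def _cluster_corr(data: np.ndarray, rows: np.ndarray, iu) -> np.ndarray:
    c = np.corrcoef(data[rows], rowvar=False)
    return c[iu]


def sgraphlet_difference_test(
    data: np.ndarray,
    model: StateModel,
    state_a: int,
    state_b: int,
    n_perm: int = 10_000,
    seed: int | None = None,
    masked: np.ndarray | None = None,
) -> EdgeDifferenceTest:
    """Monte-Carlo test of edge-wise connectivity differences between states.

    Each permutation pools the two clusters' time points and re-splits them
    at the original sizes, re-derives the two correlation matrices, and takes
    the edge-wise difference as a draw from the null "the clusters do not
    differ in connectivity".  With ``masked`` (a boolean ``(N, N)`` short-
    distance mask), masked pairs are dropped from the edge family.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    data = np.asarray(data, dtype=float)
    idx_a = np.flatnonzero(model.labels == state_a)
    idx_b = np.flatnonzero(model.labels == state_b)
    if idx_a.size < 3 or idx_b.size < 3:
        raise ValueError("both states need at least 3 time points for correlation")
    n = data.shape[1]
    iu = np.triu_indices(n, k=1)
    if masked is not None:
        keep = ~masked[iu]
        iu = (iu[0][keep], iu[1][keep])
    edges = np.column_stack(iu)

    obs = _cluster_corr(data, idx_a, iu) - _cluster_corr(data, idx_b, iu)

    pooled = np.concatenate([idx_a, idx_b])
    na = idx_a.size
    rng = np.random.default_rng(seed)
    exceed = np.zeros(edges.shape[0], dtype=int)
    abs_obs = np.abs(obs)
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        null = _cluster_corr(data, perm[:na], iu) - _cluster_corr(data, perm[na:], iu)
        exceed += np.abs(null) >= abs_obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    return EdgeDifferenceTest(
        state_a=state_a,
        state_b=state_b,
        edges=edges,
        difference=obs,
        p_values=p,
        n_permutations=n_perm,
    )


def fdr_adjust(tests: list[EdgeDifferenceTest], alpha: float = 0.001) -> None:
    """Benjamini–Hochberg FDR over the pooled family of all edges x state pairs.

    Writes ``significant`` (and ``alpha``) back onto every test in place.
    """
    pooled = np.concatenate([t.p_values for t in tests])
    flags = multipletests(pooled, alpha=alpha, method="fdr_bh")[0]
    offset = 0
    for t in tests:
        t.significant = flags[offset : offset + t.p_values.size]
        t.alpha = alpha
        offset += t.p_values.size


def rsn_difference_summary(
    test: EdgeDifferenceTest, networks: np.ndarray
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent of edges per RSN-pair block significantly larger in one state.

    Returns ``(a_gt_b, b_gt_a)`` symmetric tables; the two summaries are
    disjoint by construction (an edge difference is either positive or
    negative).  Blocks containing no edges are NaN (undefined, not 0).
    """
    if test.significant is None:
        raise ValueError("run fdr_adjust before summarising")
    networks = np.asarray(networks)
    names: list[str] = []
    for nm in networks:
        if nm not in names:
            names.append(nm)
    pos = {nm: i for i, nm in enumerate(names)}
    n_net = len(names)
    total = np.zeros((n_net, n_net))
    larger_a = np.zeros((n_net, n_net))
    larger_b = np.zeros((n_net, n_net))
    for e in range(test.edges.shape[0]):
        a = pos[networks[test.edges[e, 0]]]
        b = pos[networks[test.edges[e, 1]]]
        a, b = min(a, b), max(a, b)
        total[a, b] += 1
        if test.significant[e]:
            if test.difference[e] > 0:
                larger_a[a, b] += 1
            elif test.difference[e] < 0:
                larger_b[a, b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_a = np.where(total > 0, 100.0 * larger_a / total, np.nan)
        pct_b = np.where(total > 0, 100.0 * larger_b / total, np.nan)
    lower = np.tril_indices(n_net, k=-1)
    for m in (pct_a, pct_b):
        m[lower] = m.T[lower]
    return (
        pd.DataFrame(pct_a, index=names, columns=names),
        pd.DataFrame(pct_b, index=names, columns=names),
    )


@dataclass
class TransitionMatrix:
    """Row-stochastic state-transition percentages over change points only.

    Self-transitions are dwell, not transitions, so the diagonal is excluded
    from the events; each defined row sums to 100%.  Rows of states with no
    outgoing transition are NaN (undefined).
    """

    counts: np.ndarray  # (k, k) integer transition counts, zero diagonal
    percent: np.ndarray  # (k, k) percentages, NaN rows where undefined
    k: int

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())


def transition_probabilities(
    labels_per_subject: list[np.ndarray], k: int | None = None
) -> TransitionMatrix:
    """Transition percentages P(a -> b) over time points where the state changes."""
    if k is None:
        k = int(max(np.max(l) for l in labels_per_subject))
    counts = np.zeros((k, k), dtype=int)
    for labels in labels_per_subject:
        labels = np.asarray(labels, dtype=int)
        change = labels[1:] != labels[:-1]
        src = labels[:-1][change] - 1
        dst = labels[1:][change] - 1
        np.add.at(counts, (src, dst), 1)
    row_sums = counts.sum(axis=1)
    percent = np.full((k, k), np.nan)
    defined = row_sums > 0
    percent[defined] = 100.0 * counts[defined] / row_sums[defined, None]
    return TransitionMatrix(counts=counts, percent=percent, k=k)


@dataclass
class DwellSummary:
    """Run lengths (in scans) of consecutive same-state time points."""

    runs: dict[int, list[int]]  # state -> run lengths, pooled across subjects
    tr_seconds: float
    mean_scans: float
    mean_seconds: float

    def per_state_mean_scans(self) -> dict[int, float]:
        return {s: float(np.mean(r)) if r else float("nan") for s, r in self.runs.items()}


def dwell_times(
    labels_per_subject: list[np.ndarray], tr_seconds: float, k: int | None = None
) -> DwellSummary:
    """Run-length encode the state sequence per subject (runs never span subjects)."""
    if k is None:
        k = int(max(np.max(l) for l in labels_per_subject))
    runs: dict[int, list[int]] = {s: [] for s in range(1, k + 1)}
    all_runs: list[int] = []
    for labels in labels_per_subject:
        labels = np.asarray(labels, dtype=int)
        if labels.size == 0:
            raise ValueError("empty label sequence")
        change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [labels.size]])
        for a, b in zip(starts, ends):
            runs[int(labels[a])].append(int(b - a))
            all_runs.append(int(b - a))
    mean_scans = float(np.mean(all_runs))
    return DwellSummary(
        runs=runs,
        tr_seconds=tr_seconds,
        mean_scans=mean_scans,
        mean_seconds=mean_scans * tr_seconds,
    )


def graphlet_distance(a: SGraphlet | np.ndarray, b: SGraphlet | np.ndarray) -> float:
    """Normalized taxicab distance: mean |weight difference| over upper-triangle edges."""
    wa = a.weights if isinstance(a, SGraphlet) else np.asarray(a, dtype=float)
    wb = b.weights if isinstance(b, SGraphlet) else np.asarray(b, dtype=float)
    if wa.shape != wb.shape:
        raise ValueError("graphlets have mismatched shapes")
    iu = np.triu_indices(wa.shape[0], k=1)
    return float(np.abs(wa[iu] - wb[iu]).mean())


def transition_distance_correlation(
    transitions: TransitionMatrix,
    graphlets: list[SGraphlet],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Spearman rank correlation of P(a -> b) with the graphlet distance d(a, b).

    Ordered state pairs (a != b, row defined) are paired with the taxicab
    distance between the corresponding s-graphlets; the p-value permutes the
    pairing.  A negative rho means transitions preferentially reach nearby
    states.
    """
    k = transitions.k
    probs: list[float] = []
    dists: list[float] = []
    weights = {g.state_id: g for g in graphlets}
    for a in range(1, k + 1):
        for b in range(1, k + 1):
            if a == b or np.isnan(transitions.percent[a - 1, b - 1]):
                continue
            probs.append(transitions.percent[a - 1, b - 1])
            dists.append(graphlet_distance(weights[a], weights[b]))
    if len(probs) < 3:
        raise ValueError("need at least 3 transition/distance pairs")
    probs_arr = np.asarray(probs)
    dists_arr = np.asarray(dists)
    rho = float(spearmanr(probs_arr, dists_arr).statistic)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        null = spearmanr(probs_arr, rng.permutation(dists_arr)).statistic
        if abs(null) >= abs(rho):
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return rho, p


def transition_boundary_profile(
    data: np.ndarray,
    labels_per_subject: list[np.ndarray],
    half_width: int = 5,
    boundaries: tuple[int, ...] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean successive-time-point Euclidean distance aligned to state transitions.

    ``d(t) = ||x[t+1] - x[t]||`` is averaged across all transitions at offsets
    ``-half_width .. +half_width``, where offset 0 is the step that crosses
    the transition.  On data whose states drift gradually, the profile rises
    toward the transition and peaks at offset 0.

    ``data`` is the concatenated ``(T_total, N)`` matrix; ``labels_per_subject``
    splits it (their lengths must sum to ``T_total``).
    Returns ``(offsets, profile)``.
    """
    if half_width < 1:
        raise ValueError("half_width must be at least 1")
    data = np.asarray(data, dtype=float)
    lengths = [len(l) for l in labels_per_subject]
    if sum(lengths) != data.shape[0]:
        raise ValueError("label lengths do not sum to the data length")
    offsets = np.arange(-half_width, half_width + 1)
    sums = np.zeros(offsets.size)
    n_obs = np.zeros(offsets.size)
    start = 0
    for labels, t_s in zip(labels_per_subject, lengths):
        block = data[start : start + t_s]
        start += t_s
        step = np.linalg.norm(np.diff(block, axis=0), axis=1)  # step[t] = d(t, t+1)
        trans = np.flatnonzero(np.asarray(labels)[1:] != np.asarray(labels)[:-1])
        if trans.size == 0:
            continue
        for oi, off in enumerate(offsets):
            pos = trans + off
            valid = (pos >= 0) & (pos < step.size)
            sums[oi] += step[pos[valid]].sum()
            n_obs[oi] += valid.sum()
    if n_obs.sum() == 0:
        raise ValueError("no transitions found in any subject")
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(n_obs > 0, sums / n_obs, np.nan)
    return offsets, profile
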