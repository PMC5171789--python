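import numpy as np
import pytest
from scipy.stats import spearmanr

import pbm
from pbm.stats import (
    EdgeDifferenceTest,
    dwell_times,
    fdr_adjust,
    graphlet_distance,
    rsn_difference_summary,
    sgraphlet_difference_test,
    transition_boundary_profile,
    transition_distance_correlation,
    transition_probabilities,
)
from pbm.states import StateModel


def state_model(labels, k):
    labels = np.asarray(labels, dtype=int)
    return StateModel(
        labels=labels, k=k, centroids=np.zeros((k, 1)), inertia=0.0, restarts_used=1
    )


class TestDifferenceTest:
    def test_planted_correlation_difference_detected(self, rng):
        """One ROI pair correlated at ~0.8 in state 1 and ~0 in state 2, 200
        points each: that edge reaches the permutation floor p < 0.001
        (Fisher-z power at this effect and n is ~1)."""
        n = 200
        z = rng.standard_normal((n, 3))
        a = z.copy()
        a[:, 1] = 0.8 * a[:, 0] + np.sqrt(1 - 0.8**2) * rng.standard_normal(n)
        b = rng.standard_normal((n, 3))
        data = np.vstack([a, b])
        labels = np.repeat([1, 2], n)
        test = sgraphlet_difference_test(
            data, state_model(labels, k=2), 1, 2, n_perm=2000, seed=0
        )
        edge01 = np.flatnonzero((test.edges == [0, 1]).all(axis=1))[0]
        assert test.p_values[edge01] < 0.001
        assert test.difference[edge01] > 0.5

    def test_split_half_of_one_state_is_null(self, rng):
        """Splitting a homogeneous state in two flags nothing beyond the FDR level."""
        data = rng.standard_normal((400, 6))
        labels = np.tile([1, 2], 200)
        test = sgraphlet_difference_test(
            data, state_model(labels, k=2), 1, 2, n_perm=500, seed=1
        )
        fdr_adjust([test], alpha=0.05)
        assert test.significant.sum() <= 2

    def test_p_values_never_zero_and_flags_monotone_in_alpha(self, rng):
        data = rng.standard_normal((100, 4))
        labels = np.tile([1, 2], 50)
        test = sgraphlet_difference_test(
            data, state_model(labels, k=2), 1, 2, n_perm=200, seed=2
        )
        assert np.all(test.p_values > 0)
        assert np.all(test.p_values <= 1)
        fdr_adjust([test], alpha=0.01)
        strict = test.significant.copy()
        fdr_adjust([test], alpha=0.2)
        assert np.all(test.significant[strict])  # loosening alpha keeps flags

    def test_small_state_rejected(self, rng):
        data = rng.standard_normal((10, 3))
        labels = np.array([1, 1, 2, 2, 2, 2, 2, 2, 2, 2])
        with pytest.raises(ValueError, match="3 time points"):
            sgraphlet_difference_test(data, state_model(labels, k=2), 1, 2, n_perm=100)


class TestRsnDifferenceSummary:
    def _manual_test(self, edges, diff, sig):
        t = EdgeDifferenceTest(
            state_a=1,
            state_b=2,
            edges=np.asarray(edges),
            difference=np.asarray(diff, dtype=float),
            p_values=np.full(len(edges), 0.5),
            n_permutations=100,
        )
        t.significant = np.asarray(sig, dtype=bool)
        t.alpha = 0.05
        return t

    def test_no_flags_gives_zeros(self):
        networks = np.array(["DM", "DM", "Vis", "Vis"])
        edges = [[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]]
        t = self._manual_test(edges, np.ones(6), [False] * 6)
        a_gt_b, b_gt_a = rsn_difference_summary(t, networks)
        assert (a_gt_b.to_numpy() == 0).all()
        assert (b_gt_a.to_numpy() == 0).all()

    def test_fully_flagged_block_is_100_percent(self):
        networks = np.array(["DM", "DM", "Vis"])
        edges = [[0, 1], [0, 2], [1, 2]]
        t = self._manual_test(edges, [1.0, 1.0, 1.0], [True, True, True])
        a_gt_b, _ = rsn_difference_summary(t, networks)
        assert a_gt_b.loc["DM", "DM"] == 100.0
        assert a_gt_b.loc["DM", "Vis"] == 100.0

    def test_hand_counted_fraction(self):
        """3 of 12 DM-Vis edges flagged larger -> 25.0% in that block."""
        networks = np.array(["DM"] * 3 + ["Vis"] * 4)
        edges = [[i, j] for i in range(3) for j in range(3, 7)]
        sig = [True, True, True] + [False] * 9
        t = self._manual_test(edges, np.ones(12), sig)
        a_gt_b, b_gt_a = rsn_difference_summary(t, networks)
        assert a_gt_b.loc["DM", "Vis"] == pytest.approx(25.0)
        assert b_gt_a.loc["DM", "Vis"] == pytest.approx(0.0)
        # blocks with no edges are undefined, not zero
        assert np.isnan(a_gt_b.loc["DM", "DM"])

    def test_directions_disjoint(self, rng):
        networks = np.array(["A", "B", "A", "B"])
        edges = [[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]]
        diff = rng.standard_normal(6)
        t = self._manual_test(edges, diff, [True] * 6)
        a_gt_b, b_gt_a = rsn_difference_summary(t, networks)
        both = a_gt_b.to_numpy() + b_gt_a.to_numpy()
        assert np.nanmax(both) <= 100.0


class TestTransitions:
    def test_hand_enumerated_sequence(self):
        tm = transition_probabilities([np.array([1, 1, 2, 2, 1])], k=2)
        assert tm.percent[0, 1] == 100.0
        assert tm.percent[1, 0] == 100.0
        assert tm.n_transitions == 2

    def test_constant_labels_are_undefined(self):
        tm = transition_probabilities([np.ones(10, dtype=int)], k=2)
        assert np.isnan(tm.percent).all()

    def test_defined_rows_sum_to_100(self, rng):
        labels = rng.integers(1, 5, size=500)
        tm = transition_probabilities([labels], k=4)
        sums = np.nansum(tm.percent, axis=1)
        defined = tm.counts.sum(axis=1) > 0
        assert np.allclose(sums[defined], 100.0, atol=1e-8)

    def test_counts_conserve_change_points(self, rng):
        seqs = [rng.integers(1, 4, size=200) for _ in range(3)]
        tm = transition_probabilities(seqs, k=3)
        changes = sum(int((s[1:] != s[:-1]).sum()) for s in seqs)
        assert tm.n_transitions == changes

    def test_diagonal_excluded(self, rng):
        labels = rng.integers(1, 4, size=300)
        tm = transition_probabilities([labels], k=3)
        assert np.all(tm.counts.diagonal() == 0)


class TestDwellTimes:
    def test_run_length_encoding(self):
        s = dwell_times([np.array([1, 1, 1, 2, 2])], tr_seconds=0.72)
        assert s.runs[1] == [3]
        assert s.runs[2] == [2]
        assert s.mean_seconds == pytest.approx(s.mean_scans * 0.72)

    def test_alternating_labels(self):
        s = dwell_times([np.array([1, 2, 1, 2])], tr_seconds=1.0)
        assert all(r == 1 for runs in s.runs.values() for r in runs)

    def test_runs_conserve_total_length(self, rng):
        seqs = [rng.integers(1, 4, size=n) for n in (100, 250, 73)]
        s = dwell_times(seqs, tr_seconds=0.72)
        assert sum(r for runs in s.runs.values() for r in runs) == 423

    def test_markov_chain_mean_dwell(self, rng):
        """Stay-probability 0.8 gives geometric dwells with mean 5 scans."""
        t_total = 6000
        labels = np.empty(t_total, dtype=int)
        labels[0] = 1
        for t in range(1, t_total):
            if rng.random() < 0.8:
                labels[t] = labels[t - 1]
            else:
                labels[t] = rng.choice([s for s in (1, 2, 3) if s != labels[t - 1]])
        s = dwell_times([labels], tr_seconds=0.72)
        n_runs = sum(len(r) for r in s.runs.values())
        sem = np.sqrt(0.8 / 0.2**2) / np.sqrt(n_runs)
        assert s.mean_scans == pytest.approx(5.0, abs=3 * sem)


class TestGraphletDistance:
    def _sym(self, rng, n=6):
        a = rng.uniform(-1, 1, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        return a

    def test_identical_graphlets(self, rng):
        a = self._sym(rng)
        assert graphlet_distance(a, a) == 0.0

    def test_constant_shift(self, rng):
        a = self._sym(rng)
        b = a.copy()
        iu = np.triu_indices(6, 1)
        b[iu] += 0.2
        b.T[iu] += 0.2
        assert graphlet_distance(a, b) == pytest.approx(0.2, abs=1e-12)

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(1000):
            a, b, c = (self._sym(rng, 4) for _ in range(3))
            dab, dba = graphlet_distance(a, b), graphlet_distance(b, a)
            assert dab == dba
            assert graphlet_distance(a, c) <= dab + graphlet_distance(b, c) + 1e-12

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            graphlet_distance(self._sym(rng, 4), self._sym(rng, 5))


def make_graphlets(mats):
    from pbm.graphlets import SGraphlet

    return [
        SGraphlet(state_id=i + 1, weights=m, n_points=10) for i, m in enumerate(mats)
    ]


class TestTransitionDistanceCorrelation:
    def _tm(self, percent):
        from pbm.stats import TransitionMatrix

        counts = np.nan_to_num(percent).astype(int)
        return TransitionMatrix(counts=counts, percent=percent, k=percent.shape[0])

    def test_perfect_anti_rank(self, rng):
        """Probabilities decreasing in graphlet distance give rho = -1.

        d(a, b) = d(b, a), so both directions of a state pair get the same
        probability; the tie structure of the two rankings then matches and
        the rank correlation is exactly -1.
        """
        iu = np.triu_indices(3, 1)
        mats = []
        for level in (0.0, 0.1, 0.4):  # pairwise distances 0.1, 0.3, 0.4 (distinct)
            m = np.zeros((3, 3))
            m[iu] = level
            m += m.T
            mats.append(m)
        graphlets = make_graphlets(mats)
        dists = {
            (a, b): graphlet_distance(mats[a], mats[b])
            for a in range(3)
            for b in range(a + 1, 3)
        }
        percent = np.full((3, 3), np.nan)
        for rank, (a, b) in enumerate(sorted(dists, key=dists.get)):
            percent[a, b] = percent[b, a] = 90.0 - 10.0 * rank
        rho, p = transition_distance_correlation(
            self._tm(percent), graphlets, n_perm=500, seed=0
        )
        assert rho == pytest.approx(-1.0)

    def test_independent_pairing_is_null(self, rng):
        mats = [np.zeros((4, 4)) for _ in range(4)]
        iu = np.triu_indices(4, 1)
        for m in mats:
            v = rng.uniform(-1, 1, size=iu[0].size)
            m[iu] = v
            m += m.T
        percent = np.full((4, 4), np.nan)
        off = ~np.eye(4, dtype=bool)
        percent[off] = rng.uniform(1, 99, size=off.sum())
        rho, p = transition_distance_correlation(
            self._tm(percent), make_graphlets(mats), n_perm=500, seed=1
        )
        assert p > 0.01

    def test_too_few_pairs_rejected(self, rng):
        percent = np.full((2, 2), np.nan)
        percent[0, 1] = 100.0
        mats = [np.zeros((3, 3)), np.ones((3, 3)) - np.eye(3)]
        with pytest.raises(ValueError, match="3"):
            transition_distance_correlation(self._tm(percent), make_graphlets(mats))


class TestBoundaryProfile:
    def test_gradual_drift_peaks_at_transition(self):
        """On gradually drifting states, the successive-point distance rises
        toward the transition and peaks at the crossing step."""
        sim = pbm.simulate(
            pbm.SimulationSpec(
                n_subjects=8,
                n_rois=15,
                n_timepoints=900,
                k_true=3,
                mean_dwell_scans=25.0,
                boundary_drift="gradual",
                ramp_length=6,
                mean_scale=3.0,
                motion_rate=0.0,
                seed=77,
            )
        )
        data = np.vstack([ts.values for ts in sim.timeseries])
        offsets, profile = transition_boundary_profile(data, sim.labels, half_width=5)
        mid = np.flatnonzero(offsets == 0)[0]
        assert profile[mid] == profile.max()
        assert profile[mid - 3] < profile[mid - 2] < profile[mid - 1] < profile[mid]
        assert profile[mid + 1] > profile[mid + 2]

    def test_iid_data_random_labels_flat(self, rng):
        data = rng.standard_normal((4000, 10))
        labels = rng.integers(1, 4, size=4000)
        offsets, profile = transition_boundary_profile(data, [labels], half_width=4)
        assert profile.std() / profile.mean() < 0.02

    def test_no_transitions_rejected(self, rng):
        data = rng.standard_normal((50, 5))
        with pytest.raises(ValueError, match="transition"):
            transition_boundary_profile(data, [np.ones(50, dtype=int)], half_width=2)
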