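import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from brainte.cohort import (
    NETWORKS,
    SubjectTimeSeries,
    SyntheticTruth,
    default_dwell_matrix,
    generate_state_centroids,
    generate_subject_series,
)
from brainte.states import (
    UNASSIGNABLE,
    BrainStateSet,
    ami,
    assign_frames,
    choose_k,
    correlation_distance,
    explained_variance,
    extract_states,
    label_states,
    run_kmeans,
    select_stable_partition,
    subject_centroids,
    _standardize_rows,
)


def _planted_frames(parcellation, n_frames, noise_frac, seed, k=4, amplitude=1.0):
    cents = generate_state_centroids(parcellation, k, amplitude, seed=seed)
    rng = np.random.default_rng(seed)
    labels = rng.integers(k, size=n_frames)
    data = cents[labels] + rng.normal(0.0, noise_frac * amplitude, (n_frames, cents.shape[1]))
    return data, labels, cents


def _agreement(found, truth, k):
    # Hungarian matching of cluster labels against ground truth
    conf = np.zeros((k, k))
    np.add.at(conf, (found, truth), 1)
    rows, cols = linear_sum_assignment(-conf)
    return conf[rows, cols].sum() / len(found)


class TestCorrelationDistance:
    def test_self_distance_zero(self):
        v = np.array([1.0, 5.0, -2.0, 0.3])
        assert correlation_distance(v, v) == pytest.approx(0.0, abs=1e-12)

    def test_antipodal_distance_two(self):
        v = np.array([1.0, 5.0, -2.0, 0.3])
        assert correlation_distance(v, -v) == pytest.approx(2.0, abs=1e-12)

    def test_reversed_sequence(self):
        # hand check: r([1,2,3],[3,2,1]) = -1, so distance = 2
        assert correlation_distance([1, 2, 3], [3, 2, 1]) == pytest.approx(2.0)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            correlation_distance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_range(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            d = correlation_distance(rng.normal(size=6), rng.normal(size=6))
            assert 0.0 <= d <= 2.0


class TestRunKmeans:
    def test_distinct_frames_perfect_partition(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(3, 8))
        data = np.repeat(base, 2, axis=0)  # frames > k with 3 exact pairs
        part = run_kmeans(data, 3, n_replicates=5, seed=0)
        assert part.within_cluster_distance_total == pytest.approx(0.0, abs=1e-9)
        assert len(np.unique(part.labels[::2])) == 3
        np.testing.assert_array_equal(part.labels[::2], part.labels[1::2])

    def test_planted_recovery(self, parcellation):
        data, truth_labels, _ = _planted_frames(parcellation, 5000, 0.3, seed=2)
        part = run_kmeans(data, 4, n_replicates=10, seed=0)
        assert _agreement(part.labels, truth_labels, 4) >= 0.99

    def test_two_seeds_high_ami(self, parcellation):
        data, _, _ = _planted_frames(parcellation, 3000, 0.3, seed=4)
        p1 = run_kmeans(data, 4, n_replicates=10, seed=1)
        p2 = run_kmeans(data, 4, n_replicates=10, seed=2)
        assert ami(p1.labels, p2.labels) >= 0.99

    def test_deterministic(self, parcellation):
        data, _, _ = _planted_frames(parcellation, 500, 0.4, seed=6)
        a = run_kmeans(data, 4, n_replicates=3, seed=5)
        b = run_kmeans(data, 4, n_replicates=3, seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.centroids, b.centroids)

    def test_objective_nonincreasing_in_replicates(self, parcellation):
        # replicate streams are nested: the first m of n replicates coincide
        data, _, _ = _planted_frames(parcellation, 800, 0.6, seed=8)
        objs = [
            run_kmeans(data, 5, n_replicates=m, seed=3).within_cluster_distance_total
            for m in (1, 2, 4, 8)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))

    def test_centroid_is_restandardized_member_mean(self, parcellation):
        data, _, _ = _planted_frames(parcellation, 400, 0.3, seed=9)
        part = run_kmeans(data, 4, n_replicates=3, seed=0)
        xs = _standardize_rows(data)
        for j in range(4):
            m = xs[part.labels == j].mean(axis=0)
            m = m - m.mean()
            m = m / np.linalg.norm(m)
            np.testing.assert_allclose(part.centroids[j], m, atol=1e-10)

    def test_needs_more_frames_than_clusters(self):
        with pytest.raises(ValueError):
            run_kmeans(np.random.default_rng(0).normal(size=(3, 5)), 3, seed=0)


class TestStablePartition:
    def test_identical_partitions(self, parcellation):
        data, _, _ = _planted_frames(parcellation, 300, 0.3, seed=1)
        p = run_kmeans(data, 4, n_replicates=2, seed=0)
        chosen, mat = select_stable_partition([p, p, p])
        np.testing.assert_allclose(mat, 1.0, atol=1e-12)
        assert chosen is p

    def test_outvoted_random_partition(self, parcellation):
        data, _, _ = _planted_frames(parcellation, 300, 0.3, seed=1)
        good = [run_kmeans(data, 4, n_replicates=2, seed=s) for s in range(9)]
        rng = np.random.default_rng(0)
        noisy = good[0].__class__(
            labels=rng.integers(4, size=300),
            centroids=good[0].centroids,
            within_cluster_distance_total=np.inf,
        )
        chosen, mat = select_stable_partition(good + [noisy])
        assert any(chosen is p for p in good)
        # direct oracle: AMI row sums identify the winner
        sums = mat.sum(axis=1)
        assert np.argmax(sums) != 9

    def test_ami_label_permutation_invariant(self, parcellation):
        data, _, _ = _planted_frames(parcellation, 300, 0.3, seed=2)
        p = run_kmeans(data, 4, n_replicates=2, seed=0)
        permuted = (p.labels + 1) % 4
        assert ami(p.labels, permuted) == pytest.approx(1.0, abs=1e-12)

    def test_requires_two_partitions(self, parcellation):
        data, _, _ = _planted_frames(parcellation, 100, 0.3, seed=3)
        p = run_kmeans(data, 2, n_replicates=1, seed=0)
        with pytest.raises(ValueError):
            select_stable_partition([p])


class TestChooseK:
    def test_planted_k_recovered(self, parcellation):
        data, _, _ = _planted_frames(parcellation, 2000, 0.5, seed=12)
        k_star, ev = choose_k(data, k_range=range(2, 9), n_replicates=5, seed=0)
        assert k_star == 4

    def test_huge_threshold_returns_first_k(self, parcellation):
        data, _, _ = _planted_frames(parcellation, 300, 0.5, seed=12)
        k_star, _ = choose_k(data, k_range=range(2, 6), gain_threshold=1.0, n_replicates=2, seed=0)
        assert k_star == 2

    def test_explained_variance_nondecreasing(self, parcellation):
        data, _, _ = _planted_frames(parcellation, 1000, 0.5, seed=13)
        _, ev = choose_k(data, k_range=range(2, 9), n_replicates=5, seed=1)
        vals = [ev[k] for k in sorted(ev)]
        assert all(b >= a - 1e-6 for a, b in zip(vals, vals[1:]))
        assert all(0.0 <= v <= 1.0 for v in vals)

    def test_no_elbow_warns_and_returns_max(self, parcellation):
        data, _, _ = _planted_frames(parcellation, 400, 0.5, seed=14)
        with pytest.warns(RuntimeWarning, match="max of range"):
            k_star, _ = choose_k(
                data, k_range=range(2, 5), gain_threshold=0.0, n_replicates=2, seed=0
            )
        assert k_star == 4


class TestLabelStates:
    def test_binary_dmn_indicator(self, parcellation):
        c = parcellation.indicator("DMN")[None, :]
        assert label_states(c, parcellation) == ("DMN+",)

    def test_negated_indicator(self, parcellation):
        c = -parcellation.indicator("DMN")[None, :]
        assert label_states(c, parcellation) == ("DMN-",)

    def test_tie_breaks_lexicographically(self, small_parcellation):
        # equal weight on CER and DAT regions: exact tie, CER < DAT
        c = (small_parcellation.indicator("DAT") + small_parcellation.indicator("CER"))[None, :]
        with pytest.warns(RuntimeWarning, match="tie"):
            labels = label_states(c, small_parcellation)
        assert labels == ("CER+",)

    def test_zero_centroid_error(self, parcellation):
        with pytest.raises(ValueError, match="all-zero"):
            label_states(np.zeros((1, 86)), parcellation)

    def test_planted_centroids_named_by_home_network(self, parcellation):
        c = generate_state_centroids(parcellation, 4, 1.0, seed=0)
        assert label_states(c, parcellation) == ("DMN+", "DMN-", "VIS+", "VIS-")


class TestAssignFrames:
    def _states(self, parcellation):
        cents = generate_state_centroids(parcellation, 4, 1.0, seed=0)
        return BrainStateSet(k=4, group_centroids=cents, labels=("DMN+", "DMN-", "VIS+", "VIS-"))

    def test_exact_centroid_frame(self, parcellation):
        states = self._states(parcellation)
        data = np.vstack([states.group_centroids[2], states.group_centroids[0]])
        series = SubjectTimeSeries("s", data)
        np.testing.assert_array_equal(assign_frames(series, states), [2, 0])

    def test_anticorrelated_pair_flips(self, parcellation):
        cents = generate_state_centroids(parcellation, 2, 1.0, seed=0)
        states = BrainStateSet(k=2, group_centroids=cents, labels=("DMN+", "DMN-"))
        series = SubjectTimeSeries("s", np.vstack([-cents[0], -cents[1]]))
        np.testing.assert_array_equal(assign_frames(series, states), [1, 0])

    def test_group_labels_passthrough(self, parcellation):
        states = self._states(parcellation)
        series = SubjectTimeSeries("s", np.random.default_rng(0).normal(size=(5, 86)))
        labels = np.array([0, 1, 2, 3, 0])
        np.testing.assert_array_equal(assign_frames(series, states, group_labels=labels), labels)

    def test_zero_variance_frame_sentinel(self, parcellation):
        states = self._states(parcellation)
        data = np.vstack([states.group_centroids[0], np.zeros(86)])
        with pytest.warns(RuntimeWarning, match="unassignable"):
            labels = assign_frames(SubjectTimeSeries("s", data), states)
        assert labels[1] == UNASSIGNABLE and labels[0] == 0


class TestSubjectCentroids:
    def test_single_state_subject_imputes_rest(self, parcellation):
        cents = generate_state_centroids(parcellation, 4, 1.0, seed=0)
        states = BrainStateSet(k=4, group_centroids=cents, labels=("a", "b", "c", "d"))
        data = np.tile(cents[1], (6, 1))
        series = SubjectTimeSeries("s", data)
        with pytest.warns(RuntimeWarning, match="imputed"):
            sc = subject_centroids(series, np.ones(6, dtype=int), states)
        np.testing.assert_allclose(sc.centroids[1], cents[1])
        assert sc.imputed_states == frozenset({0, 2, 3})
        for j in sc.imputed_states:
            np.testing.assert_array_equal(sc.centroids[j], cents[j])

    def test_frames_per_state_sums_to_frame_count(self, parcellation, truth):
        draw = generate_subject_series(truth, 60, 0.05, seed=3)
        states = BrainStateSet(
            k=4, group_centroids=truth.true_centroids, labels=("a", "b", "c", "d")
        )
        labels = assign_frames(draw.series, states)
        sc = subject_centroids(draw.series, labels, states)
        assert sc.frames_per_state.sum() == 60

    def test_noiseless_subject_recovers_perturbed_centroids(self, parcellation):
        cents = generate_state_centroids(parcellation, 4, 1.0, seed=0)
        truth = SyntheticTruth(
            true_centroids=cents,
            dwell_matrix=default_dwell_matrix(4, stay=0.4),
            noise_sd=1e-13,
            seed=0,
        )
        draw = generate_subject_series(truth, 200, subject_perturbation_sd=0.1, seed=4)
        states = BrainStateSet(k=4, group_centroids=cents, labels=("a", "b", "c", "d"))
        sc = subject_centroids(draw.series, draw.labels, states)
        offset = draw.raw.mean(axis=0)  # removed by per-region demeaning
        for j in range(4):
            if j in sc.imputed_states:
                continue
            np.testing.assert_allclose(sc.centroids[j] + offset, draw.centroids_used[j], atol=1e-9)


class TestExtractStates:
    def test_pipeline_recovers_planted_states(self, cohort_draw, parcellation, truth):
        result = extract_states(
            cohort_draw.series, parcellation, k=4, n_replicates=5, stability_runs=3, seed=0
        )
        assert result.k_selected == 4
        assert set(result.states.labels) == {"DMN+", "DMN-", "VIS+", "VIS-"}
        # match each recovered centroid to its best planted counterpart
        for c in result.states.group_centroids:
            rs = [
                np.corrcoef(c, t)[0, 1] for t in truth.true_centroids
            ]
            assert max(rs) >= 0.95

    def test_partition_restriction_matches_subject_labels(self, cohort_draw, parcellation):
        result = extract_states(
            cohort_draw.series, parcellation, k=4, n_replicates=3, stability_runs=2, seed=1
        )
        for s in cohort_draw.series:
            sl = result.frame_slices[s.subject_id]
            np.testing.assert_array_equal(
                result.subject_labels[s.subject_id], result.partition.labels[sl]
            )
            np.testing.assert_array_equal(
                assign_frames(s, result.states, group_labels=result.subject_labels[s.subject_id]),
                result.partition.labels[sl],
            )

    def test_region_permutation_equivariance(self, parcellation):
        data, _, _ = _planted_frames(parcellation, 400, 0.3, seed=21)
        rng = np.random.default_rng(0)
        perm = rng.permutation(86)
        part = run_kmeans(data, 4, n_replicates=3, seed=7)
        part_p = run_kmeans(data[:, perm], 4, n_replicates=3, seed=7)
        np.testing.assert_array_equal(part.labels, part_p.labels)
        np.testing.assert_allclose(part.centroids[:, perm], part_p.centroids, atol=1e-12)
        permuted_parc = type(parcellation)(
            region_names=tuple(parcellation.region_names[i] for i in perm),
            networks=tuple(parcellation.networks[i] for i in perm),
        )
        cents = generate_state_centroids(parcellation, 4, 1.0, seed=0)
        assert label_states(cents, parcellation) == label_states(cents[:, perm], permuted_parc)

    def test_explained_variance_helper_bounds(self, parcellation):
        data, labels, _ = _planted_frames(parcellation, 300, 0.4, seed=22)
        xs = _standardize_rows(data)
        ev = explained_variance(xs, labels, 4)
        assert 0.0 < ev < 1.0
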