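"""Frame selection, pooling, k-means, validity curve and centroid matching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.cluster import KMeans as SkKMeans
from sklearn.metrics import adjusted_rand_score

import capdyn as cd
from capdyn.clustering import (
    ClusteringError,
    CapSolution,
    compute_cvi,
    find_elbow,
    round_half_away_from_zero,
)

from conftest import make_ts


class TestSelectTopFrames:
    def test_printed_counts_for_155_frames(self):
        rng = np.random.default_rng(0)
        series = rng.standard_normal(155)
        assert cd.select_top_frames(series, 0.20).indices.size == 31
        assert cd.select_top_frames(series, 0.30).indices.size == 47

    def test_enumerable_example(self):
        sel = cd.select_top_frames(np.array([1.0, 5.0, 3.0, 2.0, 4.0]), 0.4)
        assert sel.indices.tolist() == [1, 4]
        assert sel.seed_values.tolist() == [5.0, 4.0]

    def test_ties_break_toward_earlier_frame(self):
        sel = cd.select_top_frames(np.array([2.0, 2.0, 2.0, 1.0]), 0.5)
        assert sel.indices.tolist() == [0, 1]

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_invalid_fraction(self, fraction):
        with pytest.raises(ClusteringError):
            cd.select_top_frames(np.zeros(10), fraction)

    @given(st.integers(10, 400), st.floats(0.05, 1.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_count_law_and_dominance(self, t, fraction):
        rng = np.random.default_rng(t)
        series = rng.standard_normal(t)
        sel = cd.select_top_frames(series, fraction)
        assert sel.indices.size == round_half_away_from_zero(fraction * t)
        unselected = np.setdiff1d(np.arange(t), sel.indices)
        if unselected.size:
            assert series[sel.indices].min() >= series[unselected].max()


class TestPoolFrames:
    def _cohort(self):
        rng = np.random.default_rng(1)
        flags = np.array([False, False, True, False])
        return [
            make_ts(rng.standard_normal((155, 4)), subject=f"sub-{i}",
                    noise_flags=flags)
            for i in range(2)
        ]

    def test_counts_and_noise_columns_dropped(self):
        subs = self._cohort()
        sel = [cd.select_top_frames(ts.seed_series, 0.2, ts.subject_id)
               for ts in subs]
        pooled = cd.pool_frames(subs, sel)
        assert pooled.data.shape == (62, 3)
        assert pooled.component_ids == ("c01", "c02", "c04")

    def test_provenance_round_trip_bitwise(self):
        subs = self._cohort()
        sel = [cd.select_top_frames(ts.seed_series, 0.2, ts.subject_id)
               for ts in subs]
        pooled = cd.pool_frames(subs, sel)
        keep = ~subs[0].noise_flags
        by_id = {ts.subject_id: ts for ts in subs}
        for i, (sid, f) in enumerate(zip(pooled.subject_index, pooled.frame_index)):
            assert np.array_equal(pooled.data[i], by_id[sid].data[f][keep])

    def test_inconsistent_component_sets_rejected(self):
        rng = np.random.default_rng(2)
        a = make_ts(rng.standard_normal((20, 3)), subject="a")
        b = make_ts(rng.standard_normal((20, 4)), subject="b")
        sel = [cd.select_top_frames(ts.seed_series, 0.5, ts.subject_id)
               for ts in (a, b)]
        with pytest.raises(ClusteringError, match="component set"):
            cd.pool_frames([a, b], sel)


class TestKMeans:
    def test_zero_noise_clusters_separated_with_zero_objective(self):
        a = np.array([1.0, 0.0, 0.0, 1.0])
        b = np.array([0.0, 1.0, 1.0, 0.0])
        x = np.vstack([a, a, a, b, b, b])
        sol = cd.kmeans_cluster(x, 2, n_init=8, rng_seed=0)
        assert sol.objective == pytest.approx(0.0, abs=1e-12)
        assert len(set(sol.labels[:3])) == 1 and len(set(sol.labels[3:])) == 1
        assert sol.labels[0] != sol.labels[3]

    def test_matches_sklearn_on_euclidean_instance(self):
        """Independent cross-check: same objective as scikit-learn KMeans."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal((60, 4))
        ours = cd.kmeans_cluster(x, 3, metric="euclidean", n_init=200, rng_seed=0)
        sk = SkKMeans(n_clusters=3, n_init=50, random_state=0).fit(x)
        assert ours.objective == pytest.approx(sk.inertia_, rel=1e-6)

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        centers = rng.standard_normal((3, 5)) * 4
        x = np.repeat(centers, 20, axis=0) + 0.1 * rng.standard_normal((60, 5))
        perm = rng.permutation(60)
        sol_a = cd.kmeans_cluster(x, 3, n_init=20, rng_seed=1)
        sol_b = cd.kmeans_cluster(x[perm], 3, n_init=20, rng_seed=2)
        match = cd.match_centroids(sol_a, sol_b)
        assert np.all(match["correlation"] > 0.999)

    def test_correlation_metric_invariant_to_frame_rescaling(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((40, 6))
        y = x.copy()
        y[7] = 3.0 * y[7] + 2.0  # positive affine change to one frame
        sol_x = cd.kmeans_cluster(x, 3, n_init=10, rng_seed=3)
        sol_y = cd.kmeans_cluster(y, 3, n_init=10, rng_seed=3)
        assert np.array_equal(sol_x.labels, sol_y.labels)

    def test_validation_errors(self):
        with pytest.raises(ClusteringError):
            cd.kmeans_cluster(np.zeros((3, 2)), 5)
        with pytest.raises(ClusteringError):
            cd.kmeans_cluster(np.zeros((5, 2)), 1)


class TestCvi:
    def _solution(self, centroids, labels, metric="euclidean"):
        return CapSolution(k=centroids.shape[0], centroids=centroids,
                           labels=np.asarray(labels), objective=0.0,
                           metric=metric, n_init=1, rng_seed=0)

    def test_point_masses_give_zero(self):
        x = np.array([[0.0, 0.0], [0.0, 0.0], [4.0, 0.0], [4.0, 0.0]])
        sol = self._solution(np.array([[0.0, 0.0], [4.0, 0.0]]), [0, 0, 1, 1])
        assert compute_cvi(x, sol) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        # within distances all 1, centroid separation 4 -> 1/4
        x = np.array([[1.0, 0.0], [-1.0, 0.0], [5.0, 0.0], [3.0, 0.0]])
        sol = self._solution(np.array([[0.0, 0.0], [4.0, 0.0]]), [0, 0, 1, 1])
        assert compute_cvi(x, sol) == pytest.approx(0.25)

    def test_doubling_separation_halves_cvi(self):
        x1 = np.array([[1.0, 0.0], [-1.0, 0.0], [5.0, 0.0], [3.0, 0.0]])
        x2 = np.array([[1.0, 0.0], [-1.0, 0.0], [9.0, 0.0], [7.0, 0.0]])
        s1 = self._solution(np.array([[0.0, 0.0], [4.0, 0.0]]), [0, 0, 1, 1])
        s2 = self._solution(np.array([[0.0, 0.0], [8.0, 0.0]]), [0, 0, 1, 1])
        assert compute_cvi(x2, s2) == pytest.approx(compute_cvi(x1, s1) / 2)

    def test_k1_undefined(self):
        sol = self._solution(np.zeros((1, 2)), [0, 0])
        with pytest.raises(ClusteringError):
            compute_cvi(np.zeros((2, 2)), sol)


class TestElbow:
    def test_sharp_knee_found(self):
        ks = list(range(2, 11))
        cvi = [1.0 - 0.2 * (k - 2) if k <= 5 else 0.4 - 0.01 * (k - 5) for k in ks]
        assert find_elbow(ks, cvi, "chord") == 5
        assert find_elbow(ks, cvi, "line") == 5

    def test_linear_curve_falls_back_with_warning(self):
        ks = list(range(2, 11))
        cvi = [1.0 - 0.05 * (k - 2) for k in ks]
        with pytest.warns(RuntimeWarning, match="curvature"):
            assert find_elbow(ks, cvi, "chord") == 2

    def test_too_few_points(self):
        with pytest.raises(ClusteringError):
            find_elbow([2, 3], [1.0, 0.5])


class TestCentroidTools:
    def test_top_components_ranked(self):
        out = cd.top_components(np.array([0.1, 0.9, 0.5]),
                                ["c1", "c2", "c3"], ["n1", "n2", "n3"], n=2)
        assert out["component_id"].tolist() == ["c2", "c3"]
        assert out["network"].tolist() == ["n2", "n3"]

    def test_ties_resolve_by_component_order(self):
        out = cd.top_components(np.zeros(4), ["a", "b", "c", "d"],
                                ["n"] * 4, n=2)
        assert out["component_id"].tolist() == ["a", "b"]

    def test_match_identical_solutions_under_permutation(self):
        rng = np.random.default_rng(6)
        c = rng.standard_normal((4, 8))
        sol_a = CapSolution(4, c, np.zeros(4, int), 0.0, "correlation", 1, 0)
        perm = [2, 0, 3, 1]
        sol_b = CapSolution(4, c[perm], np.zeros(4, int), 0.0, "correlation", 1, 0)
        match = cd.match_centroids(sol_a, sol_b)
        assert np.allclose(match["correlation"], 1.0)
        assert match.set_index("state_a")["state_b"].to_dict() == {
            i: perm.index(i) for i in range(4)
        }

    def test_negated_solution_matches_at_minus_one(self):
        rng = np.random.default_rng(7)
        c = rng.standard_normal((3, 8))
        sol_a = CapSolution(3, c, np.zeros(3, int), 0.0, "correlation", 1, 0)
        sol_b = CapSolution(3, -c, np.zeros(3, int), 0.0, "correlation", 1, 0)
        match = cd.match_centroids(sol_a, sol_b)
        assert np.allclose(match["correlation"], -1.0)


class TestRecovery:
    def test_label_recovery_on_benchmark(self, benchmark_recovery):
        """Clustering the pooled top-20% frames at the planted k recovers the
        planted partition with adjusted Rand index > 0.7."""
        ari = adjusted_rand_score(
            benchmark_recovery["true_labels"], benchmark_recovery["solution"].labels
        )
        assert ari > 0.7

    def test_top_components_match_planted_pattern(self, benchmark_recovery):
        """Each recovered centroid's strongest components coincide with the
        matched planted pattern's strongest components."""
        coh = benchmark_recovery["cohort"]
        sol = benchmark_recovery["solution"]
        patterns = coh.truth.pattern_set.patterns
        planted = CapSolution(5, patterns, np.zeros(5, int), 0.0,
                              "correlation", 1, 0)
        match = cd.match_centroids(sol, planted).set_index("state_a")
        for j in range(5):
            pj = int(match.loc[j, "state_b"])
            top_rec = set(np.argsort(-sol.centroids[j])[:10])
            top_true = set(np.argsort(-patterns[pj])[:10])
            assert len(top_rec & top_true) >= 7

    def test_separate_group_clustering_recovers_shared_states(
        self, benchmark_recovery
    ):
        """TD-only and ASD-only clustering yield matching centroids: the
        planted group difference is in occupancy, not pattern shape."""
        coh = benchmark_recovery["cohort"]
        proc = benchmark_recovery["processed"]
        gmap = dict(zip(coh.participants["participant_id"],
                        coh.participants["group"]))
        sols = {}
        for g in ("TD", "ASD"):
            sub = [ts for ts in proc if gmap[ts.subject_id] == g]
            sel = [cd.select_top_frames(ts.seed_series, 0.2, ts.subject_id)
                   for ts in sub]
            sols[g] = cd.kmeans_cluster(cd.pool_frames(sub, sel), 5,
                                        n_init=20, rng_seed=1)
        match = cd.match_centroids(sols["TD"], sols["ASD"])
        assert np.all(match["correlation"] > 0.8)
        assert match["correlation"].mean() > 0.85
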