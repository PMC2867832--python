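import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acetclust.clustering import (
    ClusterResult,
    DistanceMatrix,
    build_distance_matrix,
    cross_tabulate_clusterings,
    k_medoids,
    kolmogorov_distance,
    label_clusters,
    profile_center_of_mass,
)
from acetclust.profiles import BinnedProfile, CumulativeProfile, cumulative_normalize

from oracles import brute_force_medoids, is_swap_optimal

TABLE1_CELLS = [[513, 417, 552], [387, 711, 635], [246, 366, 654]]


def cdf(pid, values):
    return CumulativeProfile(pid, tuple(values))


def random_cdf(pid, rng, n_bins=11):
    scores = rng.uniform(0, 10, size=n_bins)
    return cumulative_normalize(BinnedProfile(pid, tuple(scores), n_bins=n_bins))


class TestKolmogorovDistance:
    def test_identity(self, rng):
        a = random_cdf("a", rng)
        assert kolmogorov_distance(a, a) == 0.0

    def test_point_mass_vs_uniform(self):
        a = cdf("a", [0.0] * 10 + [1.0])
        b = cdf("b", [(i + 1) / 11 for i in range(11)])
        assert kolmogorov_distance(a, b) == pytest.approx(10 / 11)

    def test_loop_oracle(self, rng):
        for _ in range(25):
            a, b = random_cdf("a", rng), random_cdf("b", rng)
            brute = max(abs(x - y) for x, y in zip(a.cdf, b.cdf))
            assert kolmogorov_distance(a, b) == pytest.approx(brute)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            kolmogorov_distance(cdf("a", [1.0]), cdf("b", [0.5, 1.0]))


class TestDistanceMatrix:
    def test_identical_profiles_zero_matrix(self, rng):
        base = random_cdf("x", rng)
        dm = build_distance_matrix(
            [cdf(f"p{i}", base.cdf) for i in range(3)]
        )
        assert np.all(dm.d == 0)

    def test_duplicate_ids_error(self, rng):
        with pytest.raises(ValueError, match="duplicate"):
            build_distance_matrix([random_cdf("a", rng), random_cdf("a", rng)])

    def test_matches_pairwise_calls(self, rng):
        profiles = [random_cdf(f"p{i}", rng) for i in range(8)]
        dm = build_distance_matrix(profiles)
        for i, j in itertools.combinations(range(8), 2):
            assert dm.d[i, j] == pytest.approx(
                kolmogorov_distance(profiles[i], profiles[j])
            )

    def test_metric_properties(self, rng):
        profiles = [random_cdf(f"p{i}", rng) for i in range(15)]
        d = build_distance_matrix(profiles).d
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert np.all((d >= 0) & (d <= 1))
        for i, j, k in itertools.permutations(range(15), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


def euclidean_dm(points, ids=None):
    points = np.asarray(points, dtype=float)
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    ids = ids or tuple(f"p{i}" for i in range(n))
    return DistanceMatrix(tuple(ids), d)


class TestKMedoids:
    def test_two_tight_groups(self):
        points = [[0, 0], [0.1, 0], [0, 0.1], [10, 10], [10.1, 10], [10, 10.1]]
        dm = euclidean_dm(points)
        result = k_medoids(dm, k=2)
        groups = {}
        for pid, c in result.assignment.items():
            groups.setdefault(c, set()).add(pid)
        assert set(map(frozenset, groups.values())) == {
            frozenset({"p0", "p1", "p2"}),
            frozenset({"p3", "p4", "p5"}),
        }
        _, best_obj = brute_force_medoids(dm.d, 2)
        assert result.objective == pytest.approx(best_obj)

    def test_equidistant_ties_deterministic(self):
        n = 5
        d = np.ones((n, n)) - np.eye(n)
        dm = DistanceMatrix(tuple(f"p{i}" for i in range(n)), d)
        result = k_medoids(dm, k=2)
        assert result.medoid_ids == ("p0", "p1")
        assert result.objective == pytest.approx(3.0)

    def test_k1_is_one_median(self, rng):
        points = rng.uniform(0, 1, size=(9, 2))
        dm = euclidean_dm(points)
        result = k_medoids(dm, k=1)
        totals = dm.d.sum(axis=1)
        assert result.medoid_ids == (dm.ids[int(np.argmin(totals))],)
        assert result.objective == pytest.approx(float(totals.min()))

    def test_k_equals_n_degenerate(self, rng):
        dm = euclidean_dm(rng.uniform(0, 1, size=(4, 2)))
        result = k_medoids(dm, k=4)
        assert result.objective == 0.0
        assert set(result.medoid_ids) == set(dm.ids)

    def test_k_too_large_errors(self, rng):
        dm = euclidean_dm(rng.uniform(0, 1, size=(3, 2)))
        with pytest.raises(ValueError, match="exceeds"):
            k_medoids(dm, k=4)

    def test_medoid_assigned_to_own_cluster(self, rng):
        dm = euclidean_dm(rng.uniform(0, 1, size=(12, 2)))
        result = k_medoids(dm, k=3)
        for ci, mid in enumerate(result.medoid_ids):
            assert result.assignment[mid] == ci

    def test_swap_optimality_always(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 9))
            k = int(rng.integers(2, 4))
            dm = euclidean_dm(rng.uniform(0, 1, size=(n, 2)))
            result = k_medoids(dm, k=k)
            idx = {pid: i for i, pid in enumerate(dm.ids)}
            medoids = [idx[m] for m in result.medoid_ids]
            assert is_swap_optimal(dm.d, medoids)
            assert result.objective == pytest.approx(
                dm.d[medoids].min(axis=0).sum()
            )


class TestLabelClusters:
    @staticmethod
    def result_for(profiles, k=3):
        dm = build_distance_matrix(
            {pid: cumulative_normalize(bp) for pid, bp in profiles.items()}
        )
        return k_medoids(dm, k=k)

    def test_archetype_labels(self, rng):
        profiles = {}
        for i in range(4):
            up = np.exp(-0.5 * ((np.arange(11) - 3) / 1.0) ** 2)
            down = np.exp(-0.5 * ((np.arange(11) - 8) / 1.0) ** 2)
            mid = np.exp(-0.5 * ((np.arange(11) - 5.5) / 1.0) ** 2)
            profiles[f"u{i}"] = BinnedProfile(f"u{i}", tuple(up + rng.uniform(0, 0.01, 11)))
            profiles[f"c{i}"] = BinnedProfile(f"c{i}", tuple(mid + rng.uniform(0, 0.01, 11)))
            profiles[f"d{i}"] = BinnedProfile(f"d{i}", tuple(down + rng.uniform(0, 0.01, 11)))
        result = label_clusters(self.result_for(profiles), profiles)
        for pid in profiles:
            expected = {"u": "upstream", "c": "centered", "d": "downstream"}[pid[0]]
            assert result.label_of(pid) == expected

    def test_center_of_mass(self):
        assert profile_center_of_mass(np.array([0, 0, 1.0])) == 2.0
        assert profile_center_of_mass(np.zeros(11)) == 5.0

    def test_tie_broken_to_lower_cluster_index(self):
        result = ClusterResult(
            k=3,
            medoid_ids=("a", "b", "c"),
            assignment={"a": 0, "b": 1, "c": 2},
            objective=0.0,
        )
        flat = BinnedProfile("x", tuple([1.0] * 11))
        profiles = {"a": flat, "b": flat, "c": flat}
        labeled = label_clusters(result, profiles)
        assert labeled.labels == {0: "upstream", 1: "centered", 2: "downstream"}

    def test_k_not_3_unlabeled(self, rng):
        dm = euclidean_dm(rng.uniform(0, 1, size=(6, 2)))
        result = k_medoids(dm, k=2)
        profiles = {pid: BinnedProfile(pid, tuple([1.0] * 11)) for pid in dm.ids}
        assert label_clusters(result, profiles).labels is None


def synthetic_result(label_lists):
    """ClusterResult from explicit per-cluster promoter-id lists."""
    assignment, medoids = {}, []
    for ci, ids in enumerate(label_lists):
        medoids.append(ids[0])
        for pid in ids:
            assignment[pid] = ci
    labels = dict(enumerate(["upstream", "centered", "downstream"][: len(label_lists)]))
    return ClusterResult(
        k=len(label_lists),
        medoid_ids=tuple(medoids),
        assignment=assignment,
        objective=0.0,
        labels=labels,
    )


class TestCrossTabulate:
    def test_self_cross_is_diagonal(self):
        r = synthetic_result([["a", "b"], ["c"], ["d", "e", "f"]])
        table = cross_tabulate_clusterings(r, r)
        assert np.all(np.asarray(table) == np.diag([2, 1, 3]))

    def test_universe_mismatch_errors(self):
        a = synthetic_result([["a"], ["b"], ["c"]])
        b = synthetic_result([["a"], ["b"], ["x"]])
        with pytest.raises(ValueError, match="universe"):
            cross_tabulate_clusterings(a, b)

    def test_printed_concordance_table_marginals(self):
        """Row sums of the printed 3×3 concordance table equal the reported
        cluster sizes 1,482 / 1,733 / 1,266 with grand total 4,481."""
        ids = iter(f"p{i:04d}" for i in range(5000))
        rows = [[], [], []]
        cols = [[], [], []]
        for i in range(3):
            for j in range(3):
                for _ in range(TABLE1_CELLS[i][j]):
                    pid = next(ids)
                    rows[i].append(pid)
                    cols[j].append(pid)
        table = cross_tabulate_clusterings(
            synthetic_result(rows), synthetic_result(cols)
        )
        assert np.all(np.asarray(table) == np.array(TABLE1_CELLS))
        assert list(table.sum(axis=1)) == [1482, 1733, 1266]
        assert int(table.values.sum()) == 4481

    def test_relabeling_permutes_columns_only(self):
        a = synthetic_result([["a", "b"], ["c", "d"], ["e"]])
        b = synthetic_result([["a", "e"], ["b"], ["c", "d"]])
        table = cross_tabulate_clusterings(a, b)
        # permute b's cluster order: swap clusters 0 and 2
        b_perm = synthetic_result([["c", "d"], ["b"], ["a", "e"]])
        table_perm = cross_tabulate_clusterings(a, b_perm)
        np.testing.assert_array_equal(
            np.asarray(table)[:, [2, 1, 0]], np.asarray(table_perm)
        )


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=50, deadline=None)
def test_pam_objective_never_below_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    dm = euclidean_dm(rng.uniform(0, 1, size=(n, 2)))
    result = k_medoids(dm, k=2)
    _, best = brute_force_medoids(dm.d, 2)
    assert result.objective >= best - 1e-9
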