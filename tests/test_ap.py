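import numpy as np
import pytest

from rlda.ap import (AffinityPropagation, exemplar_topics, net_similarity,
                     optimal_exemplars, set_preference)
from rlda.lda import TopicWordTable


def two_blob_matrix():
    n = 6
    S = np.full((n, n), -100.0)
    for blk in [(0, 1, 2), (3, 4, 5)]:
        for i in blk:
            for j in blk:
                if i != j:
                    S[i, j] = -1.01
    np.fill_diagonal(S, -5.0)
    return S


class TestSetPreference:
    def test_median_of_off_diagonals(self):
        S = np.zeros((3, 3))
        S[0, 1] = S[1, 0] = -1.0
        S[0, 2] = S[2, 0] = -2.0
        S[1, 2] = S[2, 1] = -3.0
        out = set_preference(S, "median")
        assert np.diag(out) == pytest.approx(-2.0)

    def test_fixed_value(self):
        out = set_preference(np.full((4, 4), -1.5), -7.0)
        assert np.diag(out) == pytest.approx(-7.0)

    def test_constant_off_diagonals(self):
        S = np.full((3, 3), -4.0)
        assert np.diag(set_preference(S, "median")) == pytest.approx(-4.0)

    def test_input_not_mutated(self):
        S = np.full((3, 3), -1.0)
        set_preference(S, -9.0)
        assert np.diag(S) == pytest.approx(-1.0)


class TestConfigDomain:
    @pytest.mark.parametrize("damping", [1.2, 1.0, 0.0, -0.1])
    def test_damping_outside_open_unit_interval_rejected(self, damping):
        with pytest.raises(ValueError):
            AffinityPropagation(damping=damping)

    def test_damping_inside_domain_accepted(self):
        AffinityPropagation(damping=0.5)
        AffinityPropagation(damping=0.999)


class TestUpdateEquations:
    def test_vanishing_damping_matches_raw_update(self):
        """One nearly undamped sweep equals the raw message equations."""
        rng = np.random.default_rng(4)
        S = rng.uniform(-5, -1, (6, 6))
        S = (S + S.T) / 2
        np.fill_diagonal(S, -3.0)
        n = 6
        res = AffinityPropagation(damping=1e-12, max_iter=1, jitter=0.0).fit(S)
        # raw Eq. values computed independently by direct loops
        R_raw = np.zeros((n, n))
        for i in range(n):
            for k in range(n):
                R_raw[i, k] = S[i, k] - max(
                    S[i, kp] for kp in range(n) if kp != k)  # A == 0 initially
        A_raw = np.zeros((n, n))
        for i in range(n):
            for k in range(n):
                if i == k:
                    A_raw[k, k] = sum(max(0, R_raw[ip, k])
                                      for ip in range(n) if ip != k)
                else:
                    A_raw[i, k] = min(0, R_raw[k, k] + sum(
                        max(0, R_raw[ip, k])
                        for ip in range(n) if ip not in (i, k)))
        assert np.allclose(res.R, R_raw, atol=1e-6)
        assert np.allclose(res.A, A_raw, atol=1e-6)


class TestClustering:
    def test_two_points_with_high_mutual_similarity_merge(self):
        S = np.array([[-1.0, -0.1], [-0.1, -1.0]])
        res = AffinityPropagation().fit(S)
        assert res.n_clusters == 1

    def test_two_separated_blobs_recovered(self):
        res = AffinityPropagation().fit(two_blob_matrix())
        assert res.n_clusters == 2
        clusters = {frozenset(res.members(k)) for k in res.exemplars}
        assert clusters == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_exemplars_self_assigned_and_partition(self):
        res = AffinityPropagation().fit(two_blob_matrix())
        for k in res.exemplars:
            assert res.assignment[k] == k
        assert sorted(res.assignment) == list(range(6))
        assert set(res.assignment.values()) == set(res.exemplars)

    def test_deterministic(self):
        rng = np.random.default_rng(11)
        A = rng.uniform(-10, -1, (7, 7))
        S = set_preference((A + A.T) / 2, "median")
        r1 = AffinityPropagation().fit(S)
        r2 = AffinityPropagation().fit(S)
        assert r1.exemplars == r2.exemplars
        assert r1.assignment == r2.assignment

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            AffinityPropagation().fit(np.array([[-1.0]]))


class TestQualityAgainstExhaustiveOptimum:
    def test_net_similarity_within_five_percent_of_optimum(self):
        """On random similarity matrices the message-passing solution is
        within ~5% (in magnitude) of the exhaustive exemplar-set optimum in
        at least 90% of draws."""
        rng = np.random.default_rng(42)
        ok = 0
        n_draws = 100
        for _ in range(n_draws):
            n = int(rng.integers(4, 9))
            A = rng.uniform(-10, -1, (n, n))
            S = set_preference((A + A.T) / 2, "median")
            res = AffinityPropagation().fit(S)
            _, opt = optimal_exemplars(S)
            if abs(res.net_similarity()) <= abs(opt) / 0.95:
                ok += 1
        assert ok / n_draws >= 0.90

    def test_net_similarity_helper_consistent(self):
        S = two_blob_matrix()
        res = AffinityPropagation().fit(S)
        assert res.net_similarity() == pytest.approx(
            net_similarity(S, res.exemplars))

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_matches_reference_implementation_quality(self):
        """Solutions are as good as scikit-learn's affinity propagation
        (same net-similarity objective) on random similarity matrices."""
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(4, 10))
            A = rng.uniform(-10, -1, (n, n))
            S = set_preference((A + A.T) / 2, "median")
            ours = AffinityPropagation().fit(S)
            ref = sklearn_cluster.AffinityPropagation(
                affinity="precomputed", damping=0.5,
                preference=np.diag(S).copy(), max_iter=1000,
                random_state=0).fit(S)
            ref_ex = sorted(set(int(k) for k in ref.cluster_centers_indices_))
            if not ref_ex:  # reference failed to converge; nothing to compare
                continue
            assert abs(ours.net_similarity()) <= abs(
                net_similarity(S, ref_ex)) * 1.05


class TestExemplarTopics:
    def make_table(self, n):
        return TopicWordTable([[(f"t{k}w", 0.5)] for k in range(n)])

    def test_rows_and_members_returned(self):
        res = AffinityPropagation().fit(two_blob_matrix())
        out = exemplar_topics(res, self.make_table(6))
        assert [e["topic_id"] for e in out] == res.exemplars
        members = [set(e["members"]) for e in out]
        assert set().union(*members) == set(range(6))

    def test_index_mismatch_rejected(self):
        res = AffinityPropagation().fit(two_blob_matrix())
        with pytest.raises(ValueError):
            exemplar_topics(res, self.make_table(2))
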