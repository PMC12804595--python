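import numpy as np
import pytest

from toxcascade import (
    DistanceMatrix,
    SynthSpec,
    build_distance_matrix,
    covariance_distance,
    covariance_matrix,
    generate_collection,
    rank_neighbors,
    worked_example,
)


def naive_covariance(X):
    """Double-loop oracle: entry (i,j) = Σₙ (Xᵢₙ−X̄ᵢ)(Xⱼₙ−X̄ⱼ) / (n−1)."""
    X = np.asarray(X, float)
    n, d = X.shape
    means = X.mean(axis=0)
    M = np.empty((d, d))
    for i in range(d):
        for j in range(d):
            M[i, j] = sum(
                (X[k, i] - means[i]) * (X[k, j] - means[j]) for k in range(n)
            ) / (n - 1)
    return M


def naive_distance(Xa, Xb):
    A, B = naive_covariance(Xa), naive_covariance(Xb)
    return float(np.mean(np.abs(A - B)))


class TestCovarianceMatrix:
    def test_hand_derived_example(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        np.testing.assert_allclose(covariance_matrix(X), [[4.0, 4.0], [4.0, 4.0]])

    def test_constant_column_gives_zero_row_and_column(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 4))
        X[:, 2] = 7.0
        M = covariance_matrix(X)
        np.testing.assert_allclose(M[2, :], 0.0, atol=1e-12)
        np.testing.assert_allclose(M[:, 2], 0.0, atol=1e-12)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            X = rng.normal(size=(30, 6))
            np.testing.assert_allclose(
                covariance_matrix(X), naive_covariance(X), atol=1e-10
            )

    def test_symmetric(self):
        rng = np.random.default_rng(2)
        M = covariance_matrix(rng.normal(size=(25, 5)))
        assert np.max(np.abs(M - M.T)) <= 1e-10

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="covariance undefined"):
            covariance_matrix(np.ones((1, 3)))


class TestCovarianceDistance:
    def test_identical_blocks_distance_zero(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 4))
        assert covariance_distance(X, X.copy()) == 0.0

    def test_distance_to_zero_covariance_block(self):
        Xa = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        Xb = np.zeros((3, 2))
        assert covariance_distance(Xa, Xb) == pytest.approx(4.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(4)
        A, B = rng.normal(size=(20, 5)), rng.normal(size=(30, 5))
        assert covariance_distance(A, B) == pytest.approx(covariance_distance(B, A))

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(5)
        A, B = rng.normal(size=(50, 10)), rng.normal(size=(50, 10))
        assert covariance_distance(A, B) == pytest.approx(
            naive_distance(A, B), abs=1e-10
        )

    def test_width_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            covariance_distance(np.ones((3, 2)), np.ones((3, 4)))


class TestDistanceMatrix:
    def test_laws_on_synthetic_collection(self):
        coll = generate_collection(
            SynthSpec(T=5, sizes=(40,) * 5, d=15, n_clusters=2, seed=6)
        )
        D = build_distance_matrix(coll).D
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0.0)
        assert np.all(D >= 0)

    def test_worked_example_distance(self):
        D = build_distance_matrix(worked_example(), use_rows="all")
        assert D.D[0, 1] == pytest.approx(4.0)

    def test_odd_endpoint_has_largest_distance_row_sum(self):
        # two tasks from one covariance cluster plus one shifted cluster
        coll = generate_collection(
            SynthSpec(
                T=3, sizes=(150, 150, 150), d=20, n_clusters=2,
                relatedness=0.5, seed=9,
            )
        )
        # generator assigns clusters round-robin: tasks 1,3 share a cluster
        D = build_distance_matrix(coll)
        row_sums = D.D.sum(axis=1)
        assert int(np.argmax(row_sums)) == 1  # endpoint 2, the singleton cluster

    def test_small_endpoint_named_in_error(self):
        from toxcascade import EndpointDataset, EndpointMeta, MultiTaskCollection

        split = np.array(["train", "test", "test"], dtype=object)  # 1 usable row
        tiny = EndpointDataset(
            EndpointMeta(7, 1, 1, 1), np.ones((3, 2)), np.ones(3), split
        )
        ok = EndpointDataset(
            EndpointMeta(8, 2, 1, 1),
            np.random.default_rng(0).normal(size=(10, 2)),
            np.ones(10),
            np.array(["train"] * 8 + ["valid", "test"], dtype=object),
        )
        with pytest.raises(ValueError, match="7"):
            build_distance_matrix(MultiTaskCollection([tiny, ok], "x"))


class TestRankNeighbors:
    def _dm(self, D, ids):
        return DistanceMatrix(np.asarray(D, float), ids)

    def test_argsort_of_row_self_excluded(self):
        D = self._dm([[0, 0.5, 0.2], [0.5, 0, 0.1], [0.2, 0.1, 0]], [1, 2, 3])
        assert rank_neighbors(D, 1) == [3, 2]

    def test_ties_broken_by_ascending_id(self):
        D = self._dm(np.ones((3, 3)) - np.eye(3), [5, 2, 9])
        assert rank_neighbors(D, 9) == [2, 5]

    def test_never_contains_self(self):
        rng = np.random.default_rng(10)
        M = rng.random((6, 6))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        D = self._dm(M, list(range(1, 7)))
        for i in range(1, 7):
            order = rank_neighbors(D, i)
            assert i not in order and len(order) == 5

    def test_unknown_endpoint(self):
        D = self._dm(np.zeros((2, 2)), [1, 2])
        with pytest.raises(KeyError):
            rank_neighbors(D, 3)
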