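"""Pair assembly, negative sampling and the cubic-distance kNN."""

import numpy as np
import pytest
from scipy.spatial.distance import minkowski

from rwrdti.containers import BipartiteDTI, FeatureMatrix
from rwrdti.dti_model import (
    CubicKNN,
    build_pair_dataset,
    cubic_distance,
    make_pair_vectors,
    sample_negatives,
)


@pytest.fixture
def toy_features(rng):
    drugF = FeatureMatrix(["d1", "d2"], rng.integers(0, 2, (2, 8)).astype(float))
    protF = FeatureMatrix(["p1", "p2"], rng.random((2, 5)))
    return drugF, protF


class TestPairVectors:
    def test_width_is_drug_plus_protein(self, toy_features):
        drugF, protF = toy_features
        pairs, X = make_pair_vectors([("d1", "p1")], drugF, protF)
        assert X.shape == (1, 13)

    def test_drug_block_comes_first(self, toy_features):
        drugF, protF = toy_features
        _, X = make_pair_vectors([("d1", "p1"), ("d1", "p2")], drugF, protF)
        np.testing.assert_array_equal(X[0, :8], X[1, :8])
        assert not np.array_equal(X[0, 8:], X[1, 8:])

    def test_zero_features_give_zero_vector(self):
        drugF = FeatureMatrix(["d"], np.zeros((1, 4)))
        protF = FeatureMatrix(["p"], np.zeros((1, 3)))
        _, X = make_pair_vectors([("d", "p")], drugF, protF)
        assert np.all(X == 0)

    def test_strict_mode_lists_dropped_pairs(self, toy_features):
        drugF, protF = toy_features
        with pytest.raises(KeyError, match="d9"):
            make_pair_vectors([("d9", "p1")], drugF, protF, strict=True)

    def test_lenient_mode_skips(self, toy_features):
        drugF, protF = toy_features
        kept, X = make_pair_vectors(
            [("d9", "p1"), ("d1", "p1")], drugF, protF, strict=False
        )
        assert kept == [("d1", "p1")]
        assert X.shape == (1, 13)


class TestNegativeSampling:
    def test_forced_complement(self):
        dti = BipartiteDTI({("d1", "p1"), ("d2", "p2")})
        sets = sample_negatives(dti, n_sets=3, rng_seed=0)
        for s in sets:
            assert sorted(s) == [("d1", "p2"), ("d2", "p1")]

    def test_disjoint_from_positives(self, rng):
        dti = BipartiteDTI(
            {(f"d{i}", f"p{rng.integers(0, 20)}") for i in range(30)}
        )
        for seed in range(10):
            for s in sample_negatives(dti, n_sets=5, rng_seed=seed):
                assert not set(s) & dti.pairs
                assert len(s) == len(set(s)) == dti.n_pairs

    def test_reproducible_and_seed_sensitive(self):
        dti = BipartiteDTI({(f"d{i}", f"p{i % 5}") for i in range(10)})
        a = sample_negatives(dti, 4, rng_seed=42)
        b = sample_negatives(dti, 4, rng_seed=42)
        c = sample_negatives(dti, 4, rng_seed=43)
        assert a == b
        assert a != c

    def test_insufficient_candidates(self):
        dti = BipartiteDTI({("d1", "p1"), ("d1", "p2"), ("d2", "p1"), ("d2", "p2")})
        with pytest.raises(ValueError, match="non-positive"):
            sample_negatives(dti, 1, rng_seed=0)

    def test_dataset_assembly_balances_each_replicate(self, rng):
        dti = BipartiteDTI({(f"d{i}", f"p{i % 4}") for i in range(8)})
        drugF = FeatureMatrix([f"d{i}" for i in range(8)], rng.random((8, 3)))
        protF = FeatureMatrix([f"p{i}" for i in range(4)], rng.random((4, 2)))
        ds = build_pair_dataset(dti, drugF, protF, n_negative_sets=5, rng_seed=1)
        assert ds.n_negative_sets == 5
        for j in range(5):
            X, y = ds.replicate(j)
            assert (y == 1).sum() == (y == 0).sum() == dti.n_pairs


class TestCubicDistance:
    def test_identity(self, rng):
        x = rng.random(10)
        assert cubic_distance(x, x) == 0

    def test_single_coordinate(self):
        assert cubic_distance([0.0], [2.0]) == pytest.approx(2.0)

    def test_unit_square_diagonal(self):
        assert cubic_distance([0, 0], [1, 1]) == pytest.approx(2 ** (1 / 3))

    def test_symmetry_and_scipy_agreement(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=(2, 16))
            d = cubic_distance(x, y)
            assert d == pytest.approx(cubic_distance(y, x))
            assert d == pytest.approx(minkowski(x, y, 3), rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            cubic_distance([1, 2], [1, 2, 3])


class TestCubicKNN:
    def test_exact_positive_match_scores_one(self, rng):
        X = rng.random((20, 4))
        y = np.zeros(20, dtype=int)
        y[3] = 1
        model = CubicKNN(k=1).fit(X, y)
        assert model.score_samples(X[3:4])[0] == 1.0

    def test_separated_clusters_near_perfect(self, rng):
        X0 = rng.normal(0, 0.5, size=(60, 5))
        X1 = rng.normal(6, 0.5, size=(60, 5))
        X = np.vstack([X0, X1])
        y = np.r_[np.zeros(60, int), np.ones(60, int)]
        test0 = rng.normal(0, 0.5, size=(20, 5))
        test1 = rng.normal(6, 0.5, size=(20, 5))
        model = CubicKNN(k=5).fit(X, y)
        pred = (model.score_samples(np.vstack([test0, test1])) >= 0.5).astype(int)
        assert (pred == np.r_[np.zeros(20, int), np.ones(20, int)]).mean() >= 0.975

    def test_matches_bruteforce_scan(self, rng):
        """Scores equal a naive all-pairs cubic-distance scan."""
        X = rng.normal(size=(150, 7))
        y = rng.integers(0, 2, 150)
        Q = rng.normal(size=(25, 7))
        k = 9
        model = CubicKNN(k=k).fit(X, y)
        got = model.score_samples(Q)
        for i, q in enumerate(Q):
            dists = [cubic_distance(q, x) for x in X]
            nn = np.argsort(dists, kind="stable")[:k]
            assert got[i] == pytest.approx(y[nn].mean())

    def test_matches_sklearn_neighbors(self, rng):
        """Independent cross-check against sklearn's Minkowski p=3 kNN."""
        from sklearn.neighbors import KNeighborsClassifier

        X = rng.normal(size=(120, 6))
        y = rng.integers(0, 2, 120)
        Q = rng.normal(size=(30, 6))
        model = CubicKNN(k=7).fit(X, y)
        sk = KNeighborsClassifier(
            n_neighbors=7, metric="minkowski", p=3, algorithm="brute"
        ).fit(X, y)
        np.testing.assert_allclose(
            model.score_samples(Q), sk.predict_proba(Q)[:, 1], atol=1e-12
        )

    def test_row_permutation_invariance_without_ties(self, rng):
        X = rng.normal(size=(80, 5))
        y = rng.integers(0, 2, 80)
        Q = rng.normal(size=(10, 5))
        perm = rng.permutation(80)
        a = CubicKNN(k=11).fit(X, y).score_samples(Q)
        b = CubicKNN(k=11).fit(X[perm], y[perm]).score_samples(Q)
        np.testing.assert_allclose(a, b)

    def test_k_larger_than_training_set(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            CubicKNN(k=10).fit(rng.random((5, 2)), np.zeros(5, int))

    def test_query_width_mismatch(self, rng):
        model = CubicKNN(k=2).fit(rng.random((5, 3)), np.zeros(5, int))
        with pytest.raises(ValueError, match="width"):
            model.score_samples(rng.random((2, 4)))
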