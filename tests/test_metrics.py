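import numpy as np
import pytest

from scin.metrics import (asw_normalized, build_joint_embedding,
                          cell_type_accuracy, cell_type_at_k,
                          evaluate_embeddings, median_rank, recall_at_k)
from scin.nn import EmbeddingSet
from scin.synthetic import generate_eval_embeddings

from oracles import (cell_type_at_k_brute, median_rank_brute,
                     recall_at_k_brute, silhouette_brute)


def random_embeddings(rng, n=30, d=6, n_types=3, paired=True):
    def unit(V):
        return V / np.linalg.norm(V, axis=1, keepdims=True)

    ids = np.array([f"c{i}" for i in range(n)])
    labels = np.array([f"T{rng.integers(n_types)}" for _ in range(n)])
    q = EmbeddingSet(unit(rng.normal(size=(n, d))), ids, labels, "m1")
    if paired:
        r = EmbeddingSet(unit(rng.normal(size=(n, d))), ids, labels, "m2")
    else:
        ids2 = np.array([f"d{i}" for i in range(n)])
        labels2 = np.array([f"T{rng.integers(n_types)}" for _ in range(n)])
        r = EmbeddingSet(unit(rng.normal(size=(n, d))), ids2, labels2, "m2")
    return q, r


class TestRecallAtK:
    def test_identical_embeddings_perfect_at_k1(self, rng):
        q, _ = random_embeddings(rng)
        r = EmbeddingSet(q.vectors.copy(), q.cell_ids, q.cell_types, "m2")
        assert recall_at_k(q, r, 1) == 1.0

    def test_k_equals_n_is_always_one(self, rng):
        q, r = random_embeddings(rng)
        assert recall_at_k(q, r, q.n_cells) == 1.0

    def test_non_decreasing_in_k(self, rng):
        q, r = random_embeddings(rng, n=40)
        vals = [recall_at_k(q, r, k) for k in range(1, 41)]
        assert np.all(np.diff(vals) >= 0)

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            q, r = random_embeddings(rng, n=20, d=4)
            for k in (1, 3, 7):
                assert recall_at_k(q, r, k) == recall_at_k_brute(
                    q.vectors, r.vectors, k)

    def test_unpaired_inputs_rejected(self, rng):
        q, r = random_embeddings(rng, paired=False)
        with pytest.raises(ValueError, match="same cells"):
            recall_at_k(q, r, 5)

    def test_oversized_k_clipped_with_warning(self, rng):
        q, r = random_embeddings(rng, n=10)
        with pytest.warns(UserWarning, match="clipping"):
            assert recall_at_k(q, r, 99) == 1.0


class TestCellTypeAtK:
    def test_single_type_everything_matches(self, rng):
        q, r = random_embeddings(rng, n_types=1)
        assert cell_type_at_k(q, r, 5) == 1.0

    def test_separated_clusters_perfect(self):
        emb1, emb2 = generate_eval_embeddings(60, 8, 3, noise=0.05, seed=0)
        counts = np.unique(emb2.cell_types, return_counts=True)[1]
        k = int(counts.min())
        assert cell_type_at_k(emb1, emb2, k) == 1.0

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            q, r = random_embeddings(rng, n=20, paired=False)
            for k in (1, 4):
                expected = cell_type_at_k_brute(
                    q.vectors, r.vectors, list(q.cell_types),
                    list(r.cell_types), k)
                assert cell_type_at_k(q, r, k) == pytest.approx(
                    expected, abs=1e-12)

    def test_k1_identity_with_accuracy(self, rng):
        for _ in range(10):
            q, r = random_embeddings(rng, paired=bool(rng.integers(2)))
            assert cell_type_accuracy(q, r) == cell_type_at_k(q, r, 1)


class TestMedianRank:
    def test_identical_embeddings_rank_one(self, rng):
        q, _ = random_embeddings(rng, n=25)
        r = EmbeddingSet(q.vectors.copy(), q.cell_ids, q.cell_types, "m2")
        raw, norm = median_rank(q, r)
        assert raw == 1.0
        assert norm == pytest.approx(1 / 25)

    def test_worst_case_rank_n(self):
        # query i = e_i, reference i = -e_i: the matched reference is at
        # distance 2 while every other is at sqrt(2), so rank is always N
        n = 6
        ids = np.array([f"c{i}" for i in range(n)])
        labels = np.array(["A"] * n)
        Q = np.eye(n)
        q = EmbeddingSet(Q, ids, labels, "m1")
        r = EmbeddingSet(-Q, ids, labels, "m2")
        raw, norm = median_rank(q, r)
        assert raw == float(n)
        assert norm == 1.0

    def test_matched_pair_wins_distance_ties(self):
        # all reference rows identical: every distance tied, matched gets
        # the best rank among equals
        n = 5
        ids = np.array([f"c{i}" for i in range(n)])
        labels = np.array(["A"] * n)
        Q = np.tile(np.eye(4)[0], (n, 1))
        q = EmbeddingSet(Q, ids, labels, "m1")
        r = EmbeddingSet(Q.copy(), ids, labels, "m2")
        raw, _ = median_rank(q, r)
        assert raw == 1.0

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            q, r = random_embeddings(rng, n=21)
            assert median_rank(q, r) == median_rank_brute(q.vectors, r.vectors)

    def test_unpaired_rejected(self, rng):
        q, r = random_embeddings(rng, paired=False)
        with pytest.raises(ValueError):
            median_rank(q, r)


class TestJointEmbedding:
    def test_matched_concatenates_features(self, rng):
        q, _ = random_embeddings(rng, n=5, d=128)
        r = EmbeddingSet(q.vectors.copy(), q.cell_ids, q.cell_types, "m2")
        joint, labels = build_joint_embedding(q, r, matched=True)
        assert joint.shape == (5, 256)
        assert np.array_equal(labels, q.cell_types)

    def test_unmatched_stacks_cells(self, rng):
        q, _ = random_embeddings(rng, n=3, d=6)
        r, _ = random_embeddings(rng, n=5, d=6)
        r = EmbeddingSet(r.vectors, np.array([f"z{i}" for i in range(5)]),
                         r.cell_types, "m2")
        joint, labels = build_joint_embedding(q, r, matched=False)
        assert joint.shape == (8, 6)
        assert len(labels) == 8

    def test_matched_on_unpaired_rejected(self, rng):
        q, r = random_embeddings(rng, paired=False)
        with pytest.raises(ValueError):
            build_joint_embedding(q, r, matched=True)


class TestASW:
    def test_boundary_affine_map(self):
        # the normalization is (ASW + 1) / 2: -1 -> 0, 0 -> 0.5, 1 -> 1
        for asw, expected in [(-1.0, 0.0), (0.0, 0.5), (1.0, 1.0)]:
            assert (asw + 1.0) / 2.0 == expected

    def test_tight_far_clusters_near_one(self, rng):
        a = rng.normal(0, 0.01, size=(30, 4))
        b = rng.normal(0, 0.01, size=(30, 4)) + 50.0
        X = np.vstack([a, b])
        labels = np.array(["A"] * 30 + ["B"] * 30)
        assert asw_normalized(X, labels) > 0.9

    def test_matches_from_scratch_silhouette(self, rng):
        for _ in range(5):
            X = rng.normal(size=(60, 5))
            labels = rng.choice(["A", "B", "C"], size=60)
            while len(set(labels)) < 2:
                labels = rng.choice(["A", "B", "C"], size=60)
            expected = (silhouette_brute(X, labels) + 1.0) / 2.0
            assert asw_normalized(X, labels) == pytest.approx(expected,
                                                              abs=1e-8)

    def test_single_label_rejected(self, rng):
        with pytest.raises(ValueError):
            asw_normalized(rng.normal(size=(10, 3)), ["A"] * 10)


class TestInvariances:
    def test_metrics_invariant_under_common_rotation(self, rng):
        q, r = random_embeddings(rng, n=30, d=6)
        A = rng.normal(size=(6, 6))
        Q_rot, _ = np.linalg.qr(A)

        def rotate(e):
            return EmbeddingSet(e.vectors @ Q_rot, e.cell_ids, e.cell_types,
                                e.modality_name)

        for k in (1, 5, 10):
            assert recall_at_k(q, r, k) == recall_at_k(rotate(q), rotate(r), k)
            assert cell_type_at_k(q, r, k) == cell_type_at_k(
                rotate(q), rotate(r), k)
        assert median_rank(q, r) == median_rank(rotate(q), rotate(r))

    def test_both_directions_reported(self, rng):
        q, r = random_embeddings(rng, n=25)
        fwd = evaluate_embeddings(q, r, k_grid=(5,), direction="mod1_to_mod2")
        rev = evaluate_embeddings(r, q, k_grid=(5,), direction="mod2_to_mod1")
        assert fwd.direction != rev.direction
        assert set(fwd.recall_at_k) == {5}
        rows = fwd.to_rows()
        assert {row["metric"] for row in rows} >= {
            "recall_at_k", "cell_type_at_k", "cell_type_accuracy",
            "median_rank_raw", "asw_normalized"}
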