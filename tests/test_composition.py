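import numpy as np
import pytest

from caoss.composition import (CompositionWeights, compose_additive,
                               compose_caoss, load_weights, proximity,
                               save_weights, score_proximities,
                               threshold_sweep, train_caoss, transparency)
from caoss.embeddings import EmbeddingTable
from caoss.lexicon import CompoundEntry, CompoundLexicon


def build_training_world(d, n, w1, w2, rng, noise_sd=0.0):
    """Tiny lexicon whose compound vectors are exactly (or nearly) W1 v1 + W2 v2."""
    table = EmbeddingTable(d, {})
    entries = []
    for i in range(n):
        a, b = f"a{i:02d}", f"b{i:02d}"
        v1, v2 = rng.standard_normal(d), rng.standard_normal(d)
        w = w1 @ v1 + w2 @ v2 + rng.normal(0, noise_sd, d)
        table.add(a, v1)
        table.add(b, v2)
        table.add(a + b, w)
        entries.append(CompoundEntry(a + b, a, b, 100, 100, 100))
    return CompoundLexicon(entries), table


def normal_equations_oracle(lexicon, table, d):
    """Independent dense solve of the stacked least-squares problem."""
    X = np.array([np.concatenate([table.lookup(e.c1), table.lookup(e.c2)]) for e in lexicon])
    Y = np.array([table.lookup(e.compound) for e in lexicon])
    B = np.linalg.solve(X.T @ X, X.T @ Y)
    return B[:d].T, B[d:].T


class TestTraining:
    def test_exact_recovery_of_planted_matrices(self):
        d, rng = 3, np.random.default_rng(0)
        w1_true, w2_true = np.eye(d), 2 * np.eye(d)
        lex, table = build_training_world(d, 10, w1_true, w2_true, rng)
        w = train_caoss(lex, table, 0.0)
        assert np.linalg.norm(w.w1 - w1_true) + np.linalg.norm(w.w2 - w2_true) < 1e-6

    def test_matches_normal_equations_oracle(self):
        d, rng = 4, np.random.default_rng(1)
        w1t = rng.standard_normal((d, d))
        w2t = rng.standard_normal((d, d))
        lex, table = build_training_world(d, 30, w1t, w2t, rng, noise_sd=0.05)
        w = train_caoss(lex, table, 0.0)
        o1, o2 = normal_equations_oracle(lex, table, d)
        assert np.linalg.norm(w.w1 - o1) < 1e-8
        assert np.linalg.norm(w.w2 - o2) < 1e-8

    def test_single_pair_returns_minimum_norm_solution(self):
        table = EmbeddingTable(1, {"a": np.array([1.0]), "b": np.array([1.0]),
                                   "ab": np.array([3.0])})
        lex = CompoundLexicon([CompoundEntry("ab", "a", "b", 1, 1, 1)])
        w = train_caoss(lex, table, 0.0)
        assert w.w1[0, 0] == pytest.approx(1.5)
        assert w.w2[0, 0] == pytest.approx(1.5)

    def test_huge_ridge_shrinks_weights_to_zero(self):
        d, rng = 3, np.random.default_rng(2)
        lex, table = build_training_world(d, 10, np.eye(d), np.eye(d), rng)
        w = train_caoss(lex, table, 1e9)
        assert np.max(np.abs(w.w1)) < 1e-3 and np.max(np.abs(w.w2)) < 1e-3

    def test_reconstruction_error_nondecreasing_along_ridge_path(self):
        d, rng = 4, np.random.default_rng(3)
        lex, table = build_training_world(d, 25, np.eye(d), 2 * np.eye(d), rng, noise_sd=0.1)
        errs = [train_caoss(lex, table, lam).mean_sq_reconstruction_error
                for lam in (0.0, 0.1, 1.0, 10.0, 100.0)]
        assert all(a <= b + 1e-12 for a, b in zip(errs, errs[1:]))

    def test_negative_ridge_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            train_caoss(small_dataset.lexicon, small_dataset.table, -1.0)


class TestCompose:
    def test_identity_weights_reduce_to_additive(self):
        w = CompositionWeights(np.eye(2), np.eye(2), 0.0, 1, 0.0)
        v1, v2 = np.array([1.0, 2.0]), np.array([3.0, -1.0])
        np.testing.assert_allclose(compose_caoss(w, v1, v2), compose_additive(v1, v2))

    def test_zero_second_matrix_ignores_second_constituent(self):
        w = CompositionWeights(np.eye(2), np.zeros((2, 2)), 0.0, 1, 0.0)
        np.testing.assert_allclose(compose_caoss(w, [1.0, 2.0], [9.0, 9.0]), [1.0, 2.0])

    def test_hand_matrix_arithmetic(self):
        w = CompositionWeights(np.array([[1.0, 0], [0, 2]]), np.array([[0.0, 1], [1, 0]]),
                               0.0, 1, 0.0)
        np.testing.assert_allclose(compose_caoss(w, [1.0, 1.0], [2.0, 3.0]), [4.0, 4.0])

    def test_additive_commutes_and_has_zero_identity(self):
        a, b = np.array([1.0, -2.0]), np.array([0.5, 4.0])
        np.testing.assert_array_equal(compose_additive(a, b), compose_additive(b, a))
        np.testing.assert_array_equal(compose_additive(a, np.zeros(2)), a)

    def test_dimension_mismatch(self):
        w = CompositionWeights(np.eye(2), np.eye(2), 0.0, 1, 0.0)
        with pytest.raises(ValueError):
            compose_caoss(w, [1.0, 2.0, 3.0], [1.0, 2.0])


class TestProximity:
    def test_additive_orthonormal_closed_form(self):
        rec = proximity("additive", [1.0, 0.0], [0.0, 1.0])
        assert rec.prox_c1 == pytest.approx(0.70710678, abs=1e-6)
        assert rec.prox_c2 == pytest.approx(0.70710678, abs=1e-6)

    def test_caoss_limit_when_second_term_vanishes(self):
        w = CompositionWeights(np.eye(2), 1e-12 * np.eye(2), 0.0, 1, 0.0)
        rec = proximity("caoss", [1.0, 0.5], [0.3, -0.2], weights=w)
        assert rec.prox_c1 == pytest.approx(1.0, abs=1e-9)

    def test_additive_reversal_swaps_proximities(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            v1, v2 = rng.standard_normal(5), rng.standard_normal(5)
            ab = proximity("additive", v1, v2)
            ba = proximity("additive", v2, v1)
            assert ab.prox_c1 == ba.prox_c2 and ab.prox_c2 == ba.prox_c1

    def test_caoss_is_position_sensitive(self, small_dataset):
        truth = small_dataset.truth_weights
        rng = np.random.default_rng(5)
        differing = 0
        for _ in range(200):
            v1 = rng.standard_normal(truth.d)
            v2 = rng.standard_normal(truth.d)
            ab = proximity("caoss", v1, v2, weights=truth)
            ba = proximity("caoss", v2, v1, weights=truth)
            if max(abs(ab.prox_c1 - ba.prox_c2), abs(ab.prox_c2 - ba.prox_c1)) > 0:
                differing += 1
        assert differing >= 198

    def test_all_outputs_within_unit_interval(self, small_dataset):
        prox = score_proximities(small_dataset.lexicon, small_dataset.table,
                                 weights=small_dataset.truth_weights)
        assert prox[["prox_c1", "prox_c2"]].abs().le(1.0).all().all()


class TestTransparency:
    def test_whole_word_equal_to_first_constituent(self):
        t = EmbeddingTable(2, {"a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0]),
                               "ab": np.array([2.0, 0.0])})
        e = CompoundEntry("ab", "a", "b", 1, 1, 1)
        t1, t2 = transparency(t, e)
        assert t1 == pytest.approx(1.0)
        assert t2 == pytest.approx(0.0)

    def test_orthonormal_sum_gives_root_half(self, toy_table):
        e = CompoundEntry("ab", "a", "b", 1, 1, 1)
        t1, t2 = transparency(toy_table, e)
        assert t1 == pytest.approx(0.70710678, abs=1e-6)
        assert t2 == pytest.approx(0.70710678, abs=1e-6)

    def test_missing_vector_yields_marker(self, toy_table):
        e = CompoundEntry("ac", "a", "c", 1, 1, 1)  # "ac" not stored
        assert transparency(toy_table, e) is None


class TestThresholdSweep:
    def test_perfect_ratings_give_rho_one(self, small_dataset):
        ds = small_dataset
        ratings = {}
        for e in ds.lexicon:
            t = transparency(ds.table, e)
            ratings[e.compound] = t
        sweep = threshold_sweep(ds.lexicon, ds.table, ratings, [1, 5, 10])
        assert np.allclose(sweep["rho_c1"], 1.0)
        assert np.allclose(sweep["rho_c2"], 1.0)

    def test_too_few_survivors_reported_missing(self, small_dataset):
        ds = small_dataset
        some = {e.compound: (3.0, 3.0) for e in list(ds.lexicon)[:2]}
        sweep = threshold_sweep(ds.lexicon, ds.table, some, [1])
        assert np.isnan(sweep["rho_c1"].iloc[0])


def test_weights_round_trip_through_text_format(tmp_path):
    rng = np.random.default_rng(6)
    w = CompositionWeights(rng.standard_normal((4, 4)), rng.standard_normal((4, 4)),
                           0.5, 10, 0.01)
    path = tmp_path / "weights.txt"
    save_weights(w, path)
    back = load_weights(path)
    np.testing.assert_allclose(back.w1, w.w1, atol=1e-9)
    np.testing.assert_allclose(back.w2, w.w2, atol=1e-9)
    assert back.ridge_lambda == 0.5
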