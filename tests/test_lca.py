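"""Tests for EM fitting, information criteria, selection, and alignment."""

import math

import numpy as np
import pandas as pd
import pytest

from ehrpheno import lca


def binary_model(pi, probs):
    """Build an all-binary LCAModel from per-class P(item = 1) rows."""
    probs = np.asarray(probs, dtype=float)
    C, J = probs.shape
    theta = [np.column_stack([1 - probs[:, j], probs[:, j]]) for j in range(J)]
    return lca.LCAModel(
        pi=np.asarray(pi, dtype=float),
        theta=theta,
        item_names=[f"i{j}" for j in range(J)],
        item_levels=[2] * J,
    )


def simulate_binary(probs, weights, n, seed):
    rng = np.random.default_rng(seed)
    probs = np.asarray(probs, dtype=float)
    z = rng.choice(len(weights), size=n, p=weights)
    X = (rng.random((n, probs.shape[1])) < probs[z]).astype(np.int64)
    return X, z


BENCH_PROBS = np.array([[0.9] * 10, [0.5] * 10, [0.1] * 10])


@pytest.fixture(scope="module")
def benchmark_data():
    return simulate_binary(BENCH_PROBS, [1 / 3] * 3, n=2000, seed=123)


class TestEStep:
    def test_single_class_all_ones(self):
        model = binary_model([1.0], [[0.3, 0.7]])
        X = np.array([[0, 1], [1, 0]])
        resp, _ = lca.e_step(model, X)
        assert np.allclose(resp, 1.0)

    def test_identical_classes_symmetric(self):
        model = binary_model([0.5, 0.5], [[0.3, 0.7], [0.3, 0.7]])
        resp, _ = lca.e_step(model, np.array([[1, 1], [0, 0], [1, 0]]))
        assert np.allclose(resp, 0.5)

    def test_hand_computed_posterior(self):
        # pi=(.5,.5); both items P(1)=0.9 in class 1, 0.1 in class 2; x=(1,1)
        model = binary_model([0.5, 0.5], [[0.9, 0.9], [0.1, 0.1]])
        resp, ll = lca.e_step(model, np.array([[1, 1]]))
        assert resp[0, 0] == pytest.approx(0.81 / 0.82, abs=1e-12)
        assert resp[0, 1] == pytest.approx(0.01 / 0.82, abs=1e-12)
        assert ll == pytest.approx(math.log(0.5 * 0.81 + 0.5 * 0.01), abs=1e-12)

    def test_rows_sum_to_one(self, benchmark_data):
        X, _ = benchmark_data
        model = binary_model([0.2, 0.3, 0.5], BENCH_PROBS)
        resp, _ = lca.e_step(model, X)
        assert np.abs(resp.sum(axis=1) - 1.0).max() < 1e-9

    def test_out_of_range_level_rejected(self):
        model = binary_model([1.0], [[0.5]])
        with pytest.raises(ValueError, match="level"):
            lca.e_step(model, np.array([[2]]))


class TestMStep:
    def test_hard_responsibilities_give_subgroup_frequencies(self):
        X = np.array([[1, 1], [1, 0], [0, 0], [0, 0]])
        resp = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        model = lca.m_step(resp, X, [2, 2])
        assert np.allclose(model.pi, [0.5, 0.5])
        assert model.theta[0][0, 1] == pytest.approx(1.0, abs=1e-5)  # item 0, class 0
        assert model.theta[0][1, 1] == pytest.approx(0.0, abs=1e-5)
        assert model.theta[1][0, 1] == pytest.approx(0.5, abs=1e-9)

    def test_uniform_responsibilities_pool(self):
        X = np.array([[1], [0], [1], [1]])
        resp = np.full((4, 2), 0.5)
        model = lca.m_step(resp, X, [2])
        assert np.allclose(model.theta[0][:, 1], 0.75)

    def test_single_observation_clipped(self):
        model = lca.m_step(np.array([[1.0]]), np.array([[1]]), [2])
        assert model.theta[0][0, 1] == pytest.approx(1.0, abs=1e-5)
        assert model.theta[0][0, 1] < 1.0  # clipped off the boundary

    def test_degenerate_class_error_names_class(self):
        resp = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(lca.DegenerateClassError, match=r"\[1\]"):
            lca.m_step(resp, np.array([[0], [1]]), [2])


class TestFit:
    def test_one_class_closed_form(self, benchmark_data):
        """C=1 log-likelihood equals the independent-marginals formula."""
        X, _ = benchmark_data
        model, stats, _ = lca.fit(X, [2] * 10, C=1, n_restarts=1, seed=0)
        n = X.shape[0]
        expected = 0.0
        for j in range(10):
            for level in (0, 1):
                cnt = int((X[:, j] == level).sum())
                if cnt:
                    expected += cnt * math.log(cnt / n)
        assert stats.logLik == pytest.approx(expected, abs=1e-6)

    def test_loglik_trace_monotone(self, benchmark_data):
        X, _ = benchmark_data
        _, _, trace = lca.fit(X, [2] * 10, C=3, n_restarts=2, seed=1)
        diffs = np.diff(trace)
        assert (diffs >= -1e-8).all()

    def test_seed_determinism(self, benchmark_data):
        X, _ = benchmark_data
        m1, s1, _ = lca.fit(X, [2] * 10, C=2, n_restarts=3, seed=5)
        m2, s2, _ = lca.fit(X, [2] * 10, C=2, n_restarts=3, seed=5)
        assert s1.logLik == s2.logLik
        assert np.array_equal(m1.pi, m2.pi)

    def test_classes_ordered_by_descending_pi(self, benchmark_data):
        X, _ = benchmark_data
        model, _, _ = lca.fit(X, [2] * 10, C=3, n_restarts=3, seed=2)
        assert (np.diff(model.pi) <= 1e-12).all()

    def test_two_class_parameter_recovery(self):
        probs = np.array([[0.9] * 10, [0.1] * 10])
        X, _ = simulate_binary(probs, [0.5, 0.5], n=2000, seed=3)
        model, _, _ = lca.fit(X, [2] * 10, C=2, n_restarts=5, seed=4)
        truth = binary_model([0.5, 0.5], probs)
        perm = lca.align_classes(truth, model)
        for j in range(10):
            for c in range(2):
                assert abs(model.theta[j][perm[c], 1] - probs[c, j]) <= 0.05

    def test_n_less_than_C_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            lca.fit(np.zeros((2, 3), dtype=int), [2] * 3, C=5)

    def test_permutation_invariance(self, benchmark_data):
        X, _ = benchmark_data
        model, _, _ = lca.fit(X, [2] * 10, C=2, n_restarts=2, seed=8)
        order = np.random.default_rng(0).permutation(len(X))
        classes, _ = lca.assign_classes(model, X)
        classes_perm, _ = lca.assign_classes(model, X[order])
        assert np.array_equal(classes[order], classes_perm)


class TestFitStatistics:
    def test_documented_example(self):
        # pick item levels so that k = 10: C=1 with ten binary items
        stats = lca.fit_statistics(-1000.0, C=1, item_levels=[2] * 10, n=100)
        assert stats.k == 10
        assert stats.aic == pytest.approx(2020.0, abs=1e-3)
        assert stats.bic == pytest.approx(2046.0517, abs=1e-3)
        assert stats.sabic == pytest.approx(2014.4692, abs=1e-3)
        assert stats.caic == pytest.approx(2056.0517, abs=1e-3)

    def test_parameter_count_one_class(self):
        assert lca.n_free_parameters(1, [2] * 40) == 40

    def test_parameter_count_six_classes_mixed(self):
        assert lca.n_free_parameters(6, [2] * 40 + [5]) == 269

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            lca.fit_statistics(-10.0, C=1, item_levels=[2], n=0)


class TestSelectModel:
    def test_three_class_recovery(self, benchmark_data):
        X, _ = benchmark_data
        table = lca.select_model(X, [2] * 10, c_range=range(1, 6), n_restarts=4, seed=7)
        assert table.selected["bic"] == 3

    def test_independent_items_select_one(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.2, 0.8, 10)
        X = (rng.random((2000, 10)) < p).astype(np.int64)
        table = lca.select_model(X, [2] * 10, c_range=range(1, 4), n_restarts=4, seed=11)
        assert table.selected["bic"] == 1

    def test_neg2_loglik_nonincreasing_in_C(self, benchmark_data):
        X, _ = benchmark_data
        table = lca.select_model(X, [2] * 10, c_range=range(1, 5), n_restarts=6, seed=13)
        ll = table.records["logLik"].to_numpy()
        assert (np.diff(ll) >= -1e-6 * np.abs(ll[:-1])).all()

    def test_noncontiguous_range_rejected(self, benchmark_data):
        X, _ = benchmark_data
        with pytest.raises(ValueError, match="contiguous"):
            lca.select_model(X, [2] * 10, c_range=[1, 3])

    def test_records_cover_all_criteria(self, benchmark_data):
        X, _ = benchmark_data
        table = lca.select_model(X, [2] * 10, c_range=range(1, 3), n_restarts=2, seed=1)
        assert set(lca.CRITERIA) <= set(table.records.columns)
        assert set(table.selected) == set(lca.CRITERIA)


class TestAssignClasses:
    def test_argmax(self):
        model = binary_model([0.5, 0.5], [[0.9, 0.9], [0.1, 0.1]])
        classes, resp = lca.assign_classes(model, np.array([[1, 1], [0, 0]]))
        assert list(classes) == [1, 2]
        assert resp.shape == (2, 2)

    def test_tie_goes_to_lower_class(self):
        model = binary_model([0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]])
        classes, _ = lca.assign_classes(model, np.array([[1, 0]]))
        assert classes[0] == 1

    def test_benchmark_assignment_accuracy(self, benchmark_data):
        """Fitted-model accuracy approaches the true-parameter (Bayes)
        classifier's ~91.6% on this benchmark; 95%+ is unattainable even
        with the generating parameters, so the bound tests proximity to
        the oracle ceiling instead."""
        X, z = benchmark_data
        model, _, _ = lca.fit(X, [2] * 10, C=3, n_restarts=5, seed=21)
        truth = binary_model([1 / 3] * 3, BENCH_PROBS)
        oracle_classes, _ = lca.assign_classes(truth, X)
        oracle_acc = (oracle_classes - 1 == z).mean()
        perm = lca.align_classes(truth, model)
        inv = np.empty(3, dtype=int)
        inv[perm] = np.arange(3)
        classes, _ = lca.assign_classes(model, X)
        acc = (inv[classes - 1] == z).mean()
        assert oracle_acc > 0.88
        assert acc >= oracle_acc - 0.03


class TestAlignClasses:
    def test_identity(self):
        model = binary_model([0.3, 0.7], [[0.9, 0.2], [0.1, 0.8]])
        assert list(lca.align_classes(model, model)) == [0, 1]

    def test_swap(self):
        a = binary_model([0.3, 0.7], [[0.9, 0.2], [0.1, 0.8]])
        b = binary_model([0.7, 0.3], [[0.1, 0.8], [0.9, 0.2]])
        assert list(lca.align_classes(a, b)) == [1, 0]

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            a = binary_model(np.full(4, 0.25), rng.uniform(0.05, 0.95, (4, 6)))
            b = binary_model(np.full(4, 0.25), rng.uniform(0.05, 0.95, (4, 6)))
            assert np.array_equal(
                lca.align_classes(a, b), lca.brute_force_align(a, b)
            )

    def test_shape_mismatch_rejected(self):
        a = binary_model([1.0], [[0.5]])
        b = binary_model([0.5, 0.5], [[0.5], [0.5]])
        with pytest.raises(ValueError):
            lca.align_classes(a, b)


class TestEncodeFeatures:
    def test_round_trip(self):
        df = pd.DataFrame({"a": ["x", "y", "x"], "b": [0, 1, 1]})
        levels = {"a": ["x", "y"], "b": [0, 1]}
        X, names, L = lca.encode_features(df, levels)
        assert names == ["a", "b"]
        assert L == [2, 2]
        assert X.tolist() == [[0, 0], [1, 1], [0, 1]]

    def test_undeclared_value_rejected(self):
        df = pd.DataFrame({"a": ["x", "z"]})
        with pytest.raises(ValueError, match="outside declared levels"):
            lca.encode_features(df, {"a": ["x", "y"]})


class TestModelSerialization:
    def test_json_round_trip(self, tmp_path):
        model = binary_model([0.4, 0.6], [[0.9, 0.2], [0.1, 0.8]])
        path = tmp_path / "model.json"
        model.to_json(path, seed=3)
        again = lca.LCAModel.from_json(path)
        assert np.allclose(again.pi, model.pi)
        for j in range(2):
            assert np.allclose(again.theta[j], model.theta[j])
        assert again.item_names == model.item_names
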