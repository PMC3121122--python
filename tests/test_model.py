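"""Competitor rule, modified kernel, reduced and full trainers, baselines."""

import json

import numpy as np
import pytest

from hiersvm.hierarchy import build_tree_from_labels
from hiersvm.model import (
    KernelSpec,
    count_dual_variables,
    grid_search,
    joint_kernel,
    joint_kernel_matrix,
    load_model,
    save_model,
    select_competitor,
    svmhl_primal_objective,
    train_flat_multiclass,
    train_pmsvmhl_oracle,
    train_svmhl,
)
from conftest import random_instance

GLASS_COUNTS = {"1.1": 20, "2.1": 60, "2.2": 66}


class TestCompetitorRule:
    def test_sibling_with_largest_count(self, glass):
        # "2.1"'s only sibling leaf is "2.2"
        assert select_competitor(glass, GLASS_COUNTS, "2.1") == "2.2"
        assert select_competitor(glass, GLASS_COUNTS, "2.2") == "2.1"

    def test_lone_leaf_falls_back_to_largest_class(self, glass):
        assert select_competitor(glass, GLASS_COUNTS, "1.1") == "2.2"

    def test_two_leaf_tree_only_candidate(self):
        tree = build_tree_from_labels(["1", "2"])
        assert select_competitor(tree, {"1": 5, "2": 5}, "1") == "2"

    def test_sibling_tie_breaks_to_smallest_node_id(self):
        tree = build_tree_from_labels(["1.1", "1.2", "1.3"])
        assert select_competitor(tree, {"1.1": 5, "1.2": 7, "1.3": 7}, "1.1") == "1.2"


class TestJointKernel:
    def test_diagonal_entry_is_path_difference_norm(self, glass):
        x = np.array([0.3, -1.0])
        val = joint_kernel(glass, x, "2.1", "2.2", x, "2.1", "2.2",
                          KernelSpec("rbf", 1.0))
        assert val == pytest.approx(2.0)  # paths {2,5} vs {3,5} differ in 2 nodes

    def test_gram_matrix_symmetric_and_psd(self, rng):
        for _ in range(25):
            tree, X, y, _ = random_instance(rng, max_l=15)
            from hiersvm.model import assign_competitors
            comp = assign_competitors(tree, y)
            K = joint_kernel_matrix(tree, X, y, comp,
                                    KernelSpec("rbf", float(rng.uniform(0.1, 2))))
            assert np.allclose(K, K.T)
            assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestTrainSVMHL:
    def test_single_sample_closed_form(self, glass):
        # max a - a^2 over [0, C]: optimum 1/2 once C >= 1/2
        m = train_svmhl(np.array([[1.0, 2.0]]), ["2.1"], glass, C=5.0,
                        kernel=KernelSpec("rbf", 1.0), tol=1e-12)
        assert m.alpha[0] == pytest.approx(0.5, abs=1e-8)
        assert m.comp == ["2.2"]
        x = np.array([1.0, 2.0])
        assert m.score(x, "2.1") == pytest.approx(0.5, abs=1e-8)
        assert m.score(x, "2.2") == pytest.approx(-0.5, abs=1e-8)
        assert m.score(x, "1.1") == pytest.approx(0.0, abs=1e-12)
        assert m.predict(np.array([[1.0, 2.0]])) == ["2.1"]

    def test_one_dual_variable_per_sample(self, glass, rng):
        X = rng.normal(size=(17, 3))
        y = list(rng.choice(glass.leaf_names, size=17))
        y[:3] = ["1.1", "2.1", "2.2"]
        m = train_svmhl(X, y, glass, C=1.0)
        assert len(m.alpha) == 17
        assert np.all(m.alpha >= 0) and np.all(m.alpha <= 1.0 + 1e-12)

    def test_separable_data_margins_satisfied_at_large_C(self, glass, rng):
        # well-separated clusters per leaf
        centers = {"1.1": [8, 0], "2.1": [0, 8], "2.2": [0, -8]}
        X, y = [], []
        for lab, c in centers.items():
            X.append(np.asarray(c) + 0.1 * rng.normal(size=(10, 2)))
            y += [lab] * 10
        X = np.vstack(X)
        m = train_svmhl(X, y, glass, C=1e4, kernel=KernelSpec("linear", None),
                        tol=1e-10)
        Ktil = joint_kernel_matrix(m.tree, m.X, m.y, m.comp, m.kernel)
        margins = Ktil @ m.alpha
        assert margins.min() >= 1 - 1e-6
        assert m.predict(X) == y

    def test_score_linear_in_alpha(self, glass, rng):
        X = rng.normal(size=(8, 2))
        y = list(rng.choice(glass.leaf_names, size=8))
        y[:3] = ["1.1", "2.1", "2.2"]
        m = train_svmhl(X, y, glass, C=1.0)
        t1 = m.decision_table(X).to_numpy()
        m.alpha = 2 * m.alpha
        t2 = m.decision_table(X).to_numpy()
        assert np.allclose(t2, 2 * t1)

    def test_zero_alpha_predicts_smallest_leaf_id(self, glass, rng):
        X = rng.normal(size=(4, 2))
        y = ["1.1", "2.1", "2.2", "2.1"]
        m = train_svmhl(X, y, glass, C=1.0)
        m.alpha = np.zeros_like(m.alpha)
        assert m.predict(X) == ["1.1"] * 4  # documented tie rule

    def test_predict_matches_exhaustive_argmax(self, rng):
        for _ in range(10):
            tree, X, y, C = random_instance(rng, max_l=15)
            m = train_svmhl(X, y, tree, C=C, kernel=KernelSpec("rbf", 0.5))
            pred = m.predict(X)
            for i, x in enumerate(X):
                scores = [m.score(x, name) for name in tree.leaf_names]
                best = int(np.argmax(scores))
                assert pred[i] == tree.leaf_names[best]

    def test_rejects_bad_inputs(self, glass):
        with pytest.raises(ValueError):
            train_svmhl(np.zeros((2, 2)), ["1.1", "2.1"], glass, C=0.0)
        with pytest.raises(ValueError):
            train_svmhl(np.zeros((2, 2)), ["1.1"], glass, C=1.0)


class TestDuality:
    def test_dual_and_reconstructed_primal_agree(self, rng):
        for _ in range(15):
            tree, X, y, C = random_instance(rng)
            m = train_svmhl(X, y, tree, C=C, kernel=KernelSpec("linear", None),
                            tol=1e-10)
            primal = svmhl_primal_objective(m)
            assert primal >= m.objective - 1e-9
            assert abs(primal - m.objective) <= 1e-4 * (1 + abs(m.objective))

    def test_explicit_weight_reconstruction_matches_kernel_primal(self, rng):
        # linear kernel: w = sum_i a_i dPhi_i evaluated explicitly
        from hiersvm.hierarchy import attribute_vector
        tree, X, y, C = random_instance(rng)
        m = train_svmhl(X, y, tree, C=C, kernel=KernelSpec("linear", None),
                        tol=1e-10)
        s, d = tree.s, X.shape[1]
        w = np.zeros((s, d))
        for i in range(len(y)):
            dlam = attribute_vector(tree, m.y[i]) - attribute_vector(tree, m.comp[i])
            w += m.alpha[i] * np.outer(dlam, X[i])
        margins = np.array([
            (attribute_vector(tree, m.y[i]) - attribute_vector(tree, m.comp[i]))
            @ (w @ X[i])
            for i in range(len(y))
        ])
        explicit = 0.5 * np.sum(w * w) + C * np.maximum(0, 1 - margins).sum()
        assert explicit == pytest.approx(svmhl_primal_objective(m), rel=1e-8)


class TestOracle:
    def test_constraint_count(self, glass, rng):
        X = rng.normal(size=(6, 2))
        y = ["1.1", "2.1", "2.2"] * 2
        pm = train_pmsvmhl_oracle(X, y, glass, C=1.0)
        assert pm.n_constraints == 6 * (glass.q - 1)

    def test_separable_two_sample_zero_slack(self):
        tree = build_tree_from_labels(["1", "2"])
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        pm = train_pmsvmhl_oracle(X, ["1", "2"], tree, C=1e3)
        assert pm.xi.max() < 1e-6
        assert pm.predict(X) == ["1", "2"]

    def test_reduced_model_is_a_relaxation(self, rng):
        # SVMHL drops constraints, so its optimal primal never exceeds the
        # full model's optimum
        for _ in range(8):
            tree, X, y, C = random_instance(rng, max_l=20)
            m = train_svmhl(X, y, tree, C=C, kernel=KernelSpec("linear", None),
                            tol=1e-10)
            pm = train_pmsvmhl_oracle(X, y, tree, C=C)
            assert svmhl_primal_objective(m) <= pm.objective + 1e-6

    def test_oracle_refuses_large_instances(self, glass):
        with pytest.raises(ValueError):
            train_pmsvmhl_oracle(np.zeros((2000, 2)), ["1.1"] * 1000 + ["2.1"] * 1000,
                                 glass, C=1.0)


class TestDualVariableCounting:
    @pytest.mark.parametrize(
        "l,q,reduced,expected",
        [(5007, 65, False, 320448), (5007, 65, True, 5007), (1, 2, False, 1)],
    )
    def test_counts(self, l, q, reduced, expected):
        assert count_dual_variables(l, q, reduced) == expected

    def test_rejects_degenerate_sizes(self):
        with pytest.raises(ValueError):
            count_dual_variables(0, 2, True)


class TestFlatTreeReduction:
    def test_two_leaf_predictions_match_no_offset_binary_svm(self, rng):
        from hiersvm.model import kernel_matrix
        from oracles import no_offset_svm_predict

        tree = build_tree_from_labels(["1", "2"])
        kern = KernelSpec("rbf", 0.7)
        for trial in range(20):
            l = int(rng.integers(6, 25))
            X = rng.normal(size=(l, 3))
            y = list(rng.choice(["1", "2"], size=l))
            while len(set(y)) < 2:
                y = list(rng.choice(["1", "2"], size=l))
            C = float(rng.choice([0.5, 2.0]))
            m = train_svmhl(X, y, tree, C=C, kernel=kern, tol=1e-12)
            Xte = rng.normal(size=(15, 3))
            signs = np.where(np.asarray(y) == "1", 1, -1)
            # the reduced dual equals the no-offset binary dual with C' = 2C
            oracle = no_offset_svm_predict(
                X, signs, Xte, 2 * C, kernel_matrix(X, X, kern),
                kernel_matrix(X, Xte, kern),
            )
            pred = np.where(np.asarray(m.predict(Xte)) == "1", 1, -1)
            assert np.array_equal(pred, oracle)


class TestGridSearch:
    def test_single_point_grid_returns_that_point(self, glass, rng):
        X = rng.normal(size=(18, 2))
        y = ["1.1", "2.1", "2.2"] * 6
        C, g, table = grid_search(X, y, glass, (2.0,), (0.5,), folds=3, seed=0)
        assert (C, g) == (2.0, 0.5)
        assert len(table) == 1

    def test_table_covers_the_grid(self, glass, rng):
        X = rng.normal(size=(18, 2))
        y = ["1.1", "2.1", "2.2"] * 6
        _, _, table = grid_search(X, y, glass, (0.5, 2.0), (0.1, 1.0, 10.0),
                                  folds=2, seed=0)
        assert len(table) == 6

    def test_small_class_reduces_folds_with_warning(self, glass, rng):
        X = rng.normal(size=(14, 2))
        y = ["1.1", "2.1"] * 6 + ["2.2"] * 2
        with pytest.warns(UserWarning, match="fold"):
            grid_search(X, y, glass, (1.0,), (0.5,), folds=3, seed=0)


class TestFlatBaseline:
    def test_separable_two_class_perfect_training_fit(self, rng):
        tree = build_tree_from_labels(["1", "2"])
        X = np.vstack([rng.normal(size=(10, 2)) + [6, 0],
                       rng.normal(size=(10, 2)) - [6, 0]])
        y = ["1"] * 10 + ["2"] * 10
        m = train_flat_multiclass(X, y, tree, C=100.0, kernel=KernelSpec("linear", None))
        assert m.predict(X) == y

    def test_shares_predict_surface(self, glass, rng):
        X = rng.normal(size=(9, 2))
        y = ["1.1", "2.1", "2.2"] * 3
        m = train_flat_multiclass(X, y, glass, C=1.0)
        pred = m.predict(X)
        assert len(pred) == 9
        assert set(pred) <= set(glass.leaf_names)


class TestSerialization:
    def test_round_trip_is_exact(self, tmp_path, rng):
        tree, X, y, C = random_instance(rng)
        m = train_svmhl(X, y, tree, C=C, kernel=KernelSpec("rbf", 0.3))
        p = tmp_path / "model.json"
        save_model(m, p)
        back = load_model(p)
        assert np.array_equal(back.alpha, m.alpha)
        assert np.array_equal(back.X, m.X)
        assert back.y == m.y and back.comp == m.comp
        assert back.kernel == m.kernel
        assert back.predict(X) == m.predict(X)

    def test_identical_inputs_identical_serialization(self, tmp_path, glass):
        rng1 = np.random.default_rng(7)
        X = rng1.normal(size=(12, 2))
        y = ["1.1", "2.1", "2.2"] * 4
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        save_model(train_svmhl(X, y, glass, C=1.0), p1)
        save_model(train_svmhl(X.copy(), list(y), glass, C=1.0), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_rejects_foreign_files(self, tmp_path):
        p = tmp_path / "x.json"
        p.write_text(json.dumps({"format": "something-else"}))
        with pytest.raises(ValueError):
            load_model(p)
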