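"""Dual SVM solver: hand cases, KKT conditions, QP oracle, CV and grid."""

import numpy as np
import pytest
from scipy import optimize

from ginsengms import (
    SyntheticSpec,
    cross_validate,
    fit_binary_svm,
    fit_multiclass_svm,
    generate_feature_table,
    grid_search,
    kernel_eval,
    normalize_zscore,
)
from ginsengms.svm import (
    _smo_core_nb,
    _smo_core_py,
    dual_objective,
    kernel_matrix,
)


def slsqp_dual_oracle(K, y, C):
    """Brute-force reference solution of the C-SVM dual via SLSQP."""
    n = len(y)
    Q = (y[:, None] * y[None, :]) * K

    def neg_obj(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    def neg_grad(a):
        return -(np.ones(n) - Q @ a)

    res = optimize.minimize(
        neg_obj,
        np.full(n, C / 2),
        jac=neg_grad,
        bounds=[(0, C)] * n,
        constraints={"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y},
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    assert res.success
    return res.x


class TestKernels:
    def test_rbf_self_similarity(self):
        x = np.array([1.0, 2.0, 3.0])
        assert kernel_eval(x, x, "rbf", gamma=0.5) == 1.0

    def test_rbf_hand_value(self):
        assert kernel_eval(np.array([0.0]), np.array([1.0]), "rbf", gamma=np.log(2)) == (
            pytest.approx(0.5)
        )

    def test_linear_hand_value(self):
        assert kernel_eval(np.array([1.0, 2.0]), np.array([3.0, 4.0]), "linear") == 11.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            kernel_eval(np.ones(2), np.ones(3), "linear")

    def test_matrix_agrees_with_pointwise(self, rng):
        X = rng.normal(size=(5, 3))
        Z = rng.normal(size=(4, 3))
        K = kernel_matrix(X, Z, "rbf", gamma=0.2)
        for i in range(5):
            for j in range(4):
                assert K[i, j] == pytest.approx(kernel_eval(X[i], Z[j], "rbf", 0.2))


class TestBinarySvm:
    def test_two_point_hand_solution(self):
        m = fit_binary_svm(
            np.array([[-1.0], [1.0]]), np.array([-1.0, 1.0]), C=10, kernel="linear"
        )
        np.testing.assert_allclose(m.alphas, [0.5, 0.5], atol=1e-6)
        assert m.b == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(
            m.decision_function(np.array([[-1.0], [1.0]])), [-1.0, 1.0], atol=1e-6
        )

    def test_xor_with_rbf(self):
        X = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], float)
        y = np.array([1, 1, -1, -1], float)
        m = fit_binary_svm(X, y, C=10, kernel="rbf", gamma=1.0)
        np.testing.assert_array_equal(m.predict(X), y)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_binary_svm(np.ones((3, 1)), np.ones(3), C=1)

    def test_w_only_for_linear_kernel(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([-1.0, 1.0])
        lin = fit_binary_svm(X, y, C=10, kernel="linear")
        np.testing.assert_allclose(lin.w, [1.0], atol=1e-6)
        rbf = fit_binary_svm(X, y, C=10, kernel="rbf", gamma=1.0)
        with pytest.raises(ValueError):
            _ = rbf.w

    @pytest.mark.parametrize("trial", range(10))
    def test_kkt_conditions(self, trial):
        rng = np.random.default_rng(trial)
        n = rng.integers(6, 16)
        X = rng.normal(size=(n, 3))
        y = np.where(rng.random(n) < 0.5, -1.0, 1.0)
        if len(np.unique(y)) < 2:
            y[0] = -y[1]
        C = float(rng.choice([0.1, 1.0, 10.0]))
        tol = 1e-4
        m = fit_binary_svm(X, y, C=C, kernel="rbf", gamma=0.5, tol=tol)
        # stored coefficients respect the box and equality constraints
        assert np.all(m.alphas > 0)
        assert np.all(m.alphas <= C + 1e-10)
        assert abs(np.sum(m.alphas * m.sv_labels)) < 1e-8
        # margins: free SVs on the margin, bound SVs inside/outside
        f_all = m.decision_function(X)
        alpha_full = np.zeros(n)
        # reconstruct full alpha vector by matching support vectors
        for a, sv, lab in zip(m.alphas, m.support_vectors, m.sv_labels):
            idx = np.nonzero((X == sv).all(axis=1))[0][0]
            alpha_full[idx] = a
        margins = y * f_all
        for i in range(n):
            if alpha_full[i] < 1e-10:
                assert margins[i] >= 1 - 10 * tol
            elif alpha_full[i] > C - 1e-8:
                assert margins[i] <= 1 + 10 * tol
            else:
                assert abs(margins[i] - 1) <= 10 * tol

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_qp_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(4, 7))
        X = rng.normal(size=(n, 2))
        y = np.r_[np.ones(n // 2), -np.ones(n - n // 2)]
        rng.shuffle(y)
        if len(np.unique(y)) < 2:
            y[0] = -y[1]
        C = float(rng.choice([0.5, 1.0, 5.0]))
        gamma = float(rng.choice([0.2, 1.0]))
        K = kernel_matrix(X, X, "rbf", gamma)
        m = fit_binary_svm(X, y, C=C, kernel="rbf", gamma=gamma, tol=1e-7)
        a_ref = slsqp_dual_oracle(K, y, C)
        obj_ref = dual_objective(a_ref, K, y)
        assert m.dual_objective_value == pytest.approx(obj_ref, abs=1e-6)
        # predictions on a probe grid agree
        probes = rng.normal(size=(20, 2))
        f_ref = (a_ref * y) @ kernel_matrix(X, probes, "rbf", gamma)
        free = (a_ref > 1e-6 * C) & (a_ref < C * (1 - 1e-6))
        if free.any():
            b_ref = np.mean(
                y[free] - ((a_ref * y) @ kernel_matrix(X, X[free], "rbf", gamma))
            )
            preds_ref = np.sign(f_ref + b_ref)
            agree = np.mean(preds_ref == np.sign(m.decision_function(probes)))
            assert agree == 1.0

    def test_duplicated_point_stability(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 2))
        y = np.where(X[:, 0] > 0, 1.0, -1.0)
        m1 = fit_binary_svm(X, y, C=1, gamma=0.5)
        X2 = np.vstack([X, X[:1]])
        y2 = np.r_[y, y[:1]]
        m2 = fit_binary_svm(X2, y2, C=1, gamma=0.5)
        probes = rng.normal(size=(30, 2))
        np.testing.assert_array_equal(m1.predict(probes), m2.predict(probes))


@pytest.mark.skipif(_smo_core_nb is None, reason="numba not installed")
class TestSmoBackends:
    @pytest.mark.parametrize("trial", range(10))
    def test_numba_matches_numpy(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(4, 20))
        X = rng.normal(size=(n, 3))
        y = np.where(rng.random(n) < 0.5, -1.0, 1.0)
        if len(np.unique(y)) < 2:
            y[0] = -y[1]
        K = kernel_matrix(X, X, "rbf", 0.5)
        a1, g1, s1 = _smo_core_py(K, y, 1.0, 1e-5, 100000)
        a2, g2, s2 = _smo_core_nb(K, y, 1.0, 1e-5, 100000)
        assert s1 == s2 == 0
        np.testing.assert_allclose(a1, a2, atol=1e-12)
        np.testing.assert_allclose(g1, g2, atol=1e-10)


class TestMulticlass:
    def test_two_classes_single_machine(self, rng):
        X = rng.normal(size=(10, 2))
        labels = ["A"] * 5 + ["B"] * 5
        m = fit_multiclass_svm(X, labels, C=1, gamma=0.5)
        assert len(m.machines) == 1

    def test_separated_blobs_perfect_training_accuracy(self, rng):
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        X = np.vstack([c + rng.normal(scale=0.3, size=(15, 2)) for c in centers])
        labels = ["a"] * 15 + ["b"] * 15 + ["c"] * 15
        m = fit_multiclass_svm(X, labels, C=10, gamma=0.5)
        assert m.predict(X) == labels

    def test_label_renaming_equivariance(self, rng):
        X = rng.normal(size=(18, 3))
        labels = ["x", "y", "z"] * 6
        mapping = {"x": "JL", "y": "LN", "z": "HLJ"}
        m1 = fit_multiclass_svm(X, labels, C=1, gamma=0.5)
        m2 = fit_multiclass_svm(X, [mapping[l] for l in labels], C=1, gamma=0.5)
        probes = rng.normal(size=(20, 3))
        assert [mapping[p] for p in m1.predict(probes)] == m2.predict(probes)

    def test_json_round_trip(self, tmp_path, rng):
        import json

        X = rng.normal(size=(12, 2))
        labels = ["a", "b", "c"] * 4
        m = fit_multiclass_svm(X, labels, C=1, gamma=0.5)
        path = tmp_path / "model.json"
        m.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["classes"] == ["a", "b", "c"]
        assert len(payload["machines"]) == 3


class TestCrossValidate:
    def test_seeded_determinism(self, strong_signal_zscores):
        Z, labels, _ = strong_signal_zscores
        a = cross_validate(Z, labels, k=10, seed=5)
        b = cross_validate(Z, labels, k=10, seed=5)
        assert a == b

    def test_gram_path_equals_explicit_models(self, strong_signal_zscores):
        # the fast Gram-slicing CV must reproduce fold-by-fold refits
        from ginsengms.validation import stratified_kfold

        Z, labels, _ = strong_signal_zscores
        _, oof = cross_validate(Z, labels, C=1, gamma=0.03, k=5, seed=2)
        y = np.asarray(labels)
        expected = [None] * len(labels)
        for te in stratified_kfold(y, 5, seed=2):
            tr = np.setdiff1d(np.arange(len(labels)), te)
            m = fit_multiclass_svm(Z[tr], y[tr], C=1, gamma=0.03)
            for i, p in zip(te, m.predict(Z[te])):
                expected[i] = p
        assert oof == expected

    def test_strong_signal_perfect(self, strong_signal_zscores):
        # a perfectly separable input: the discriminative columns alone
        # (noise dimensions would otherwise dominate the RBF distances)
        Z, labels, truth = strong_signal_zscores
        acc, _ = cross_validate(Z[:, truth.informative], labels, C=1, gamma=0.03, k=10, seed=0)
        assert acc == 1.0

    def test_random_labels_at_chance(self):
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 10))
            labels = list(np.repeat(["A", "B", "C"], 10))
            acc, _ = cross_validate(X, labels, C=1, gamma=0.03, k=10, seed=seed)
            accs.append(acc)
        assert abs(np.mean(accs) - 1 / 3) <= 0.15

    def test_k_bounds(self, strong_signal_zscores):
        Z, labels, _ = strong_signal_zscores
        with pytest.raises(ValueError):
            cross_validate(Z, labels, k=len(labels) + 1)


class TestGridSearch:
    def test_single_cell(self, strong_signal_zscores):
        Z, labels, _ = strong_signal_zscores
        gs = grid_search(Z, labels, C_grid=[2.0], gamma_grid=[0.05], k=5, seed=0)
        assert (gs.best_C, gs.best_gamma) == (2.0, 0.05)

    def test_tie_prefers_small_C_then_small_gamma(self, strong_signal_zscores):
        Z, labels, _ = strong_signal_zscores
        gs = grid_search(Z, labels, C_grid=[1.0, 10.0], gamma_grid=[0.01, 0.03], k=5, seed=0)
        ties = np.argwhere(gs.accuracy >= gs.accuracy.max() - 1e-12)
        i, j = ties[0]
        assert gs.best_C == gs.C_grid[i]
        assert gs.best_gamma == gs.gamma_grid[j]

    def test_plateau_on_separable_data(self, strong_signal_zscores):
        # strongly separable data shows a broad accuracy plateau
        Z, labels, truth = strong_signal_zscores
        gs = grid_search(
            Z[:, truth.informative],
            labels,
            C_grid=[0.5, 1, 2, 4, 8],
            gamma_grid=[0.005, 0.01, 0.02, 0.04],
            k=5,
            seed=0,
        )
        frac_near_max = np.mean(gs.accuracy >= gs.accuracy.max() - 0.02)
        assert frac_near_max > 0.5

    def test_surface_values_in_unit_interval(self, strong_signal_zscores):
        Z, labels, _ = strong_signal_zscores
        gs = grid_search(Z, labels, C_grid=[1.0], gamma_grid=[0.01, 0.1], k=5, seed=0)
        assert np.all((gs.accuracy >= 0) & (gs.accuracy <= 1))


class TestNormalizationEffect:
    def test_zscore_beats_raw_under_scale_heterogeneity(self):
        # mirrors the raw-vs-normalized contrast: with feature scales
        # spanning 1e3, Z-scoring rescues the RBF geometry
        wins, gaps = 0, []
        for seed in range(10):
            table, _ = generate_feature_table(SyntheticSpec(seed=seed))
            raw, _ = cross_validate(table.areas, table.origins, C=1, gamma=0.03, k=10, seed=seed)
            z, _ = cross_validate(
                normalize_zscore(table).values, table.origins, C=1, gamma=0.03, k=10, seed=seed
            )
            wins += z >= raw
            gaps.append(z - raw)
        assert wins >= 9
        assert np.mean(gaps) > 0.05
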