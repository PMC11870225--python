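import numpy as np
import pytest

from akw_mrpk import KernelParams, KeyedInstance, SVMModel, gram_matrix, poly_kernel, predict, train_svm

from _oracles import kkt_violation, qp_dual_optimum


def _instances(X, y):
    return [KeyedInstance(i, X[i], int(y[i]), "train") for i in range(len(y))]


class TestPolyKernel:
    @pytest.mark.parametrize(
        "x, y, r, d, expected",
        [
            ([1.0, 1.0], [1.0, 1.0], 1.0, 2, 9.0),
            ([2.0, 3.0], [4.0, 5.0], 0.0, 1, 23.0),  # reduces to dot product
            ([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], 1.0, 2, 1089.0),
        ],
    )
    def test_values(self, x, y, r, d, expected):
        assert poly_kernel(x, y, KernelParams(r=r, d=d)) == expected

    def test_symmetry_and_length_check(self):
        params = KernelParams(r=0.5, d=3)
        assert poly_kernel([1, 2], [3, 4], params) == poly_kernel([3, 4], [1, 2], params)
        with pytest.raises(ValueError):
            poly_kernel([1.0], [1.0, 2.0], params)

    def test_gram_psd_for_nonnegative_r(self):
        rng = np.random.default_rng(0)
        for d in (1, 2, 3, 4):
            for r in (0.0, 0.5, 1.0):
                X = rng.normal(size=(12, 3))
                K = gram_matrix(X, X, KernelParams(r=r, d=d))
                np.testing.assert_allclose(K, K.T, atol=1e-12)
                assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_negative_r_needs_explicit_flag(self):
        with pytest.raises(ValueError):
            KernelParams(r=-1.0, d=2)
        with pytest.warns(UserWarning):
            KernelParams(r=-1.0, d=2, allow_negative_r=True)

    def test_degree_must_be_positive_integer(self):
        with pytest.raises(ValueError):
            KernelParams(r=1.0, d=0)


class TestTrainSvm:
    def test_two_point_separable_matches_qp_oracle(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        y = np.array([1, -1])
        params = KernelParams(r=0.0, d=1)
        model = train_svm(_instances(X, y), RP=10.0, params=params, tol=1e-8)
        assert list(model.predict(X)) == [1, -1]
        K = gram_matrix(X, X, params)
        assert model.dual_objective() == pytest.approx(
            qp_dual_optimum(K, y, model.per_sample_C), abs=1e-6
        )

    def test_xor_separable_with_degree_two(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
        y = np.array([-1, -1, 1, 1])
        model = train_svm(
            _instances(X, y), RP=10.0, params=KernelParams(r=1.0, d=2), tol=1e-6
        )
        assert list(model.predict(X)) == [-1, -1, 1, 1]

    def test_dual_feasibility_and_kkt(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 4))
        y = np.where(X[:, 0] + 0.3 * rng.normal(size=30) > 0, 1, -1)
        if abs(y.sum()) == 30:
            y[0] *= -1
        params = KernelParams(r=1.0, d=3)
        model = train_svm(_instances(X, y), RP=1.0, params=params, tol=1e-4)
        assert (model.alphas >= -1e-12).all()
        assert (model.alphas <= model.per_sample_C + 1e-12).all()
        assert abs(model.alphas @ model.targets) < 1e-8
        K = gram_matrix(X, X, params)
        assert kkt_violation(K, y, model.per_sample_C, model.alphas) <= 1e-3

    def test_free_support_vectors_classified_consistently(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 3))
        y = np.where(X[:, 0] > 0, 1, -1)
        model = train_svm(
            _instances(X, y), RP=5.0, params=KernelParams(r=0.5, d=2), tol=1e-6
        )
        free = (model.alphas > 1e-8) & (model.alphas < model.per_sample_C - 1e-8)
        preds = model.predict(X)
        assert (preds[free] == y[free]).all()

    def test_dropping_non_support_vectors_changes_nothing(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(25, 3))
        y = np.where(X[:, 1] > 0, 1, -1)
        model = train_svm(_instances(X, y), RP=1.0, params=KernelParams(r=1.0, d=2))
        pruned = model.without_non_support()
        assert pruned.support_vectors.shape[0] < model.support_vectors.shape[0]
        probes = rng.normal(size=(50, 3))
        np.testing.assert_allclose(
            pruned.decision_function(probes), model.decision_function(probes), atol=1e-10
        )

    def test_duplicated_training_set_same_sign_pattern(self):
        # duplicating every point splits its dual capacity over two copies,
        # so the duplicated problem at RP matches the original at 2*RP
        rng = np.random.default_rng(8)
        X = rng.normal(size=(15, 2))
        y = np.where(X[:, 0] + X[:, 1] > 0, 1, -1)
        params = KernelParams(r=1.0, d=2)
        base = train_svm(_instances(X, y), RP=2.0, params=params, tol=1e-8)
        doubled = train_svm(
            _instances(np.vstack([X, X]), np.concatenate([y, y])),
            RP=1.0, params=params, tol=1e-8,
        )
        grid = rng.normal(size=(100, 2))
        assert (base.predict(grid) == doubled.predict(grid)).all()

    def test_class_weights_scale_box_bounds(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 2))
        y = np.array([1] * 5 + [-1] * 15)
        model = train_svm(
            _instances(X, y), RP=2.0, params=KernelParams(r=1.0, d=2),
            class_weight={1: 2.0, 0: 2 / 3},
        )
        np.testing.assert_allclose(model.per_sample_C[y == 1], 4.0)
        np.testing.assert_allclose(model.per_sample_C[y == -1], 4.0 / 3.0)

    def test_single_class_rejected(self):
        X = np.ones((3, 2))
        with pytest.raises(ValueError):
            train_svm(_instances(X, np.array([1, 1, 1])), RP=1.0, params=KernelParams())

    def test_nonpositive_rp_rejected(self):
        X = np.eye(2)
        with pytest.raises(ValueError):
            train_svm(_instances(X, np.array([1, -1])), RP=0.0, params=KernelParams())


class TestPredict:
    def test_zero_decision_value_maps_to_plus_one(self):
        model = SVMModel(
            support_vectors=np.array([[1.0, 0.0]]),
            alphas=np.array([0.0]),
            targets=np.array([1]),
            bias=0.0,
            kernel=KernelParams(r=0.0, d=1),
            RP=1.0,
            per_sample_C=np.array([1.0]),
        )
        assert predict(model, [0.0, 0.0]) == +1

    def test_dimension_mismatch(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        model = train_svm(_instances(X, np.array([-1, 1])), RP=1.0, params=KernelParams())
        with pytest.raises(ValueError):
            predict(model, [1.0, 2.0, 3.0])

    def test_agrees_with_reference_svm(self):
        sklearn_svm = pytest.importorskip("sklearn.svm")
        rng = np.random.default_rng(12)
        X = np.vstack([rng.normal(-2, 1, size=(25, 3)), rng.normal(2, 1, size=(25, 3))])
        y = np.array([-1] * 25 + [1] * 25)
        params = KernelParams(r=1.0, d=3)
        model = train_svm(_instances(X, y), RP=1.0, params=params, tol=1e-6)
        ref = sklearn_svm.SVC(kernel="poly", degree=3, gamma=1.0, coef0=1.0, C=1.0)
        ref.fit(X, y)
        probes = rng.normal(0, 2, size=(80, 3))
        assert (model.predict(probes) == ref.predict(probes)).mean() > 0.95
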