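"""Kernels and the bordered-system LS-SVM solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glocalsvm import (
    ConfigError,
    InputError,
    KernelSpec,
    LabeledDataset,
    UnfittableError,
    decision_value,
    fit_lssvm,
    kernel_matrix,
    predict,
)
from conftest import random_small_problem

RBF1 = KernelSpec("rbf", bandwidth_sq=1.0)


def brute_force_solve(X, y, spec, gamma):
    """Independent oracle: assemble the bordered KKT system entry by
    entry with python loops and solve it with a plain dense solver."""
    n = len(y)
    A = np.zeros((n + 1, n + 1))
    rhs = np.zeros(n + 1)
    for i in range(n):
        A[0, 1 + i] = y[i]
        A[1 + i, 0] = y[i]
        rhs[1 + i] = 1.0
        for j in range(n):
            if spec.family == "rbf":
                k = np.exp(-np.sum((X[i] - X[j]) ** 2) / spec.bandwidth_sq)
            else:
                k = float(X[i] @ X[j])
            A[1 + i, 1 + j] = y[i] * y[j] * k
        A[1 + i, 1 + i] += 1.0 / gamma
    sol = np.linalg.solve(A, rhs)
    return sol[0], sol[1:]


def brute_force_decision(X, y, alphas, b, spec, query):
    """Literal term-by-term evaluation of the dual sum."""
    out = []
    for q in query:
        s = b
        for i in range(len(y)):
            if spec.family == "rbf":
                k = np.exp(-np.sum((X[i] - q) ** 2) / spec.bandwidth_sq)
            else:
                k = float(X[i] @ q)
            s += alphas[i] * y[i] * k
        out.append(s)
    return np.array(out)


class TestKernelMatrix:
    def test_rbf_closed_form(self):
        K = kernel_matrix([[0.0, 0.0]], [[1.0, 0.0]], RBF1)
        assert K.shape == (1, 1)
        assert K[0, 0] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_rbf_self_similarity_and_symmetry(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(7, 3))
        K = kernel_matrix(X, X, KernelSpec("rbf", bandwidth_sq=2.5))
        assert np.allclose(np.diag(K), 1.0)
        assert np.allclose(K, K.T)

    def test_linear_on_basis_vectors(self):
        E = np.eye(2)
        assert np.allclose(kernel_matrix(E, E, KernelSpec("linear")), np.eye(2))

    def test_polynomial(self):
        a, b = np.array([[1.0, 2.0]]), np.array([[3.0, 1.0]])
        spec = KernelSpec("polynomial", degree=2, offset=1.0)
        assert kernel_matrix(a, b, spec)[0, 0] == pytest.approx((5 + 1) ** 2)

    def test_dimension_mismatch(self):
        with pytest.raises(InputError):
            kernel_matrix(np.zeros((2, 2)), np.zeros((2, 3)), RBF1)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ConfigError):
            KernelSpec("rbf", bandwidth_sq=0.0)


class TestFit:
    def test_worked_two_point_example(self, two_point_model):
        assert two_point_model.alphas == pytest.approx([2 / 3, 2 / 3], abs=1e-10)
        assert two_point_model.bias == pytest.approx(1 / 3, abs=1e-10)
        # alpha_k = gamma * e_k with e_k = 1 - y_k f(x_k)
        dv = decision_value(two_point_model, [[0.0, 0.0], [1.0, 0.0]])
        e = 1.0 - np.array([1.0, -1.0]) * dv
        assert e == pytest.approx([2 / 3, 2 / 3], abs=1e-10)

    @pytest.mark.parametrize("gamma", [0.1, 1.0, 100.0])
    @pytest.mark.parametrize("spec", [RBF1, KernelSpec("linear")], ids=["rbf", "linear"])
    def test_kkt_conditions(self, gamma, spec):
        rng = np.random.default_rng(3)
        data = random_small_problem(rng)
        model = fit_lssvm(data, spec, gamma)
        # sum alpha_i y_i = 0
        assert abs(model.alphas @ model.support_labels) <= 1e-6 * data.n
        # alpha_k = gamma e_k within 1e-6 relative
        e = 1.0 - data.labels * decision_value(model, data.features)
        assert np.allclose(model.alphas, gamma * e, rtol=1e-6, atol=1e-9)

    def test_duplication_halved_gamma_invariance(self, two_point_data):
        """Duplicating every point while halving gamma leaves the
        decision function unchanged (residual weight is conserved)."""
        spec = KernelSpec("linear")
        base = fit_lssvm(two_point_data, spec, 1.0, standardize=False)
        doubled = LabeledDataset(
            np.vstack([two_point_data.features] * 2),
            np.concatenate([two_point_data.labels] * 2),
            np.arange(4),
        )
        dup = fit_lssvm(doubled, spec, 0.5, standardize=False)
        q = two_point_data.features
        assert decision_value(dup, q) == pytest.approx(
            decision_value(base, q), abs=1e-6
        )

    def test_oracle_equivalence_small_problems(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            data = random_small_problem(rng)
            spec = RBF1 if rng.random() < 0.5 else KernelSpec("linear")
            gamma = float(10 ** rng.uniform(-1, 2))
            model = fit_lssvm(data, spec, gamma, standardize=False)
            b, alphas = brute_force_solve(data.features, data.labels, spec, gamma)
            query = rng.normal(size=(5, data.n_features))
            expected = brute_force_decision(
                data.features, data.labels, alphas, b, spec, query
            )
            assert decision_value(model, query) == pytest.approx(expected, abs=1e-8)

    def test_separable_blobs_high_gamma_perfect(self, blobs):
        model = fit_lssvm(blobs, RBF1, 1e6)
        assert np.array_equal(predict(model, blobs.features), blobs.labels)

    def test_determinism_bitwise(self, blobs):
        m1 = fit_lssvm(blobs, RBF1, 10.0)
        m2 = fit_lssvm(blobs, RBF1, 10.0)
        assert np.array_equal(m1.alphas, m2.alphas)
        assert m1.bias == m2.bias

    def test_single_class_unfittable(self):
        data = LabeledDataset([[0.0], [1.0]], [1.0, 1.0], [0, 1])
        with pytest.raises(UnfittableError):
            fit_lssvm(data, RBF1, 1.0)

    def test_bad_gamma(self, two_point_data):
        with pytest.raises(ConfigError):
            fit_lssvm(two_point_data, RBF1, 0.0)


class TestPredict:
    def test_decision_values_at_training_points(self, two_point_model):
        dv = decision_value(two_point_model, [[0.0, 0.0], [1.0, 0.0]])
        assert dv == pytest.approx([1 / 3, -1 / 3], abs=1e-10)

    def test_training_points_recovered(self, two_point_model):
        assert np.array_equal(
            predict(two_point_model, [[0.0, 0.0], [1.0, 0.0]]), [1.0, -1.0]
        )

    def test_exact_zero_maps_to_positive(self, two_point_model):
        # midpoint of the two training points lies exactly on the boundary
        assert decision_value(two_point_model, [[0.5, 0.0]])[0] == pytest.approx(0, abs=1e-15)
        assert predict(two_point_model, [[0.5, 0.0]])[0] == 1.0

    def test_empty_query(self, two_point_model):
        assert decision_value(two_point_model, np.zeros((0, 2))).shape == (0,)
        assert predict(two_point_model, np.zeros((0, 2))).shape == (0,)

    def test_dimension_mismatch(self, two_point_model):
        with pytest.raises(InputError):
            decision_value(two_point_model, np.zeros((3, 5)))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000), st.floats(0.1, 100.0))
def test_predictions_always_signed(seed, gamma):
    rng = np.random.default_rng(seed)
    data = random_small_problem(rng, n_max=20)
    model = fit_lssvm(data, RBF1, gamma)
    labels = predict(model, rng.normal(size=(8, data.n_features)))
    assert set(np.unique(labels)) <= {-1.0, 1.0}
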