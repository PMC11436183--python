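"""Routing algebra against independent nested-loop oracles, plus the
structural invariants (coupling normalization, Gram symmetry, permutation
equivariance, batch independence)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stcapsnet as sc
from stcapsnet.errors import ConfigurationError, ShapeError

# ------------------------------------------------------------------ oracles
# Naive loop implementations, written directly from the routing definitions
# and kept free of any code shared with the package internals.


def oracle_predict(U, W):
    b, n_l, d_l = U.shape
    _, n_out, _, d_out = W.shape
    out = np.zeros((b, n_l, n_out, d_out))
    for bi in range(b):
        for i in range(n_l):
            for j in range(n_out):
                for e in range(d_out):
                    acc = 0.0
                    for d in range(d_l):
                        acc += U[bi, i, d] * W[i, j, d, e]
                    out[bi, i, j, e] = acc
    return out


def oracle_self_correlation(U_hat, d_l):
    b, n_l, n_out, d_out = U_hat.shape
    A = np.zeros((b, n_l, n_l, n_out))
    for bi in range(b):
        for i in range(n_l):
            for k in range(n_l):
                for j in range(n_out):
                    A[bi, i, k, j] = np.dot(U_hat[bi, i, j], U_hat[bi, k, j]) / d_l
    return A


def oracle_coupling(A):
    b, n_l, _, n_out = A.shape
    C = np.zeros((b, n_l, n_out))
    for bi in range(b):
        for i in range(n_l):
            logits = np.array([A[bi, i, :, j].sum() for j in range(n_out)])
            ex = np.exp(logits - logits.max())
            C[bi, i] = ex / ex.sum()
    return C


def oracle_route_presquash(U_hat, C, B):
    b, n_l, n_out, d_out = U_hat.shape
    S = np.zeros((b, n_out, d_out))
    for bi in range(b):
        for j in range(n_out):
            for i in range(n_l):
                S[bi, j] += U_hat[bi, i, j] * (C[bi, i, j] + B[i, j])
    return S


def oracle_squash(v):
    n = np.linalg.norm(v)
    if n == 0:
        return v
    return (1 - np.exp(-n)) * v / n


def oracle_dynamic_routing(U, W, iterations):
    U_hat = oracle_predict(U, W)
    b, n_l, n_out, d_out = U_hat.shape
    out = np.zeros((b, n_out, d_out))
    for bi in range(b):
        logits = np.zeros((n_l, n_out))
        for it in range(iterations):
            c = np.zeros_like(logits)
            for i in range(n_l):
                ex = np.exp(logits[i] - logits[i].max())
                c[i] = ex / ex.sum()
            v = np.zeros((n_out, d_out))
            for j in range(n_out):
                s = sum(c[i, j] * U_hat[bi, i, j] for i in range(n_l))
                v[j] = oracle_squash(s)
            if it < iterations - 1:
                for i in range(n_l):
                    for j in range(n_out):
                        logits[i, j] += np.dot(U_hat[bi, i, j], v[j])
        out[bi] = v
    return out


def random_instance(seed, n_l=None, n_out=None, d_l=None, d_out=None, batch=2):
    rng = np.random.default_rng(seed)
    n_l = n_l or int(rng.integers(1, 5))
    n_out = n_out or int(rng.integers(1, 4))
    d_l = d_l or int(rng.integers(1, 5))
    d_out = d_out or int(rng.integers(1, 5))
    U = np.asarray(sc.squash(rng.normal(size=(batch, n_l, d_l))))
    W = rng.normal(size=(n_l, n_out, d_l, d_out))
    B = rng.normal(size=(n_l, n_out)) * 0.1
    return U, W, B


# -------------------------------------------------------------- oracle tests
@pytest.mark.parametrize("seed", range(8))
def test_stages_match_loop_oracles(seed):
    U, W, B = random_instance(seed)
    U_hat = np.asarray(sc.predict_capsules(U, W))
    np.testing.assert_allclose(U_hat, oracle_predict(U, W), rtol=1e-5, atol=1e-12)

    d_l = U.shape[2]
    A = np.asarray(sc.self_correlation(U_hat, d_l))
    np.testing.assert_allclose(A, oracle_self_correlation(U_hat, d_l), rtol=1e-5, atol=1e-12)

    C = np.asarray(sc.coupling_coefficients(A))
    np.testing.assert_allclose(C, oracle_coupling(A), rtol=1e-5, atol=1e-12)

    S = np.asarray(sc.route(U_hat, C, B, squash_output=False))
    np.testing.assert_allclose(S, oracle_route_presquash(U_hat, C, B), rtol=1e-5, atol=1e-12)


@pytest.mark.parametrize("seed", range(6))
@pytest.mark.parametrize("iterations", [1, 3])
def test_dynamic_routing_matches_loop_oracle(seed, iterations):
    U, W, _ = random_instance(seed, n_l=3, n_out=2, d_l=2, d_out=2)
    weights = sc.RoutingWeights(
        W=sc.routing.Tensor(W), B=sc.routing.Tensor(np.zeros(W.shape[:2])))
    out = np.asarray(sc.dynamic_routing(U, weights, iterations=iterations).values)
    np.testing.assert_allclose(out, oracle_dynamic_routing(U, W, iterations),
                               rtol=1e-5, atol=1e-12)


def test_composition_equals_manual_stages():
    U, W, B = random_instance(99)
    weights = sc.RoutingWeights(W=sc.routing.Tensor(W), B=sc.routing.Tensor(B))
    composed = np.asarray(sc.self_correlation_routing(U, weights).values)
    U_hat = sc.predict_capsules(U, weights.W)
    A = sc.self_correlation(U_hat, U.shape[2])
    C = sc.coupling_coefficients(A)
    manual = np.asarray(sc.route(U_hat, C, weights.B))
    np.testing.assert_allclose(composed, manual, rtol=1e-12)


# --------------------------------------------------------------- edge cases
def test_identity_transform_passes_capsules_through():
    U = np.asarray(sc.squash(np.random.default_rng(0).normal(size=(3, 1, 4))))
    W = np.eye(4).reshape(1, 1, 4, 4)
    np.testing.assert_allclose(np.asarray(sc.predict_capsules(U, W))[:, 0, 0], U[:, 0])


def test_zero_transform_and_zero_predictions():
    U, W, B = random_instance(3)
    np.testing.assert_array_equal(np.asarray(sc.predict_capsules(U, np.zeros_like(W))), 0.0)
    U_hat = np.zeros((2, 3, 2, 4))
    np.testing.assert_array_equal(np.asarray(sc.self_correlation(U_hat, 4)), 0.0)
    S = np.asarray(sc.route(U_hat, np.full((2, 3, 2), 0.5), np.zeros((3, 2)),
                            squash_output=False))
    np.testing.assert_array_equal(S, 0.0)


def test_single_capsule_self_correlation_closed_form():
    rng = np.random.default_rng(5)
    v = rng.normal(size=(1, 1, 1, 4))
    A = np.asarray(sc.self_correlation(v, 4))
    np.testing.assert_allclose(A[0, 0, 0, 0], np.dot(v[0, 0, 0], v[0, 0, 0]) / 4)


def test_uniform_coupling_for_zero_logits():
    C = np.asarray(sc.coupling_coefficients(np.zeros((2, 4, 4, 3))))
    np.testing.assert_allclose(C, 1.0 / 3.0)


def test_softmax_saturation():
    A = np.zeros((1, 2, 2, 3))
    A[:, :, :, 1] = 10.0  # +20 to output-capsule-1 logits after the k-sum
    C = np.asarray(sc.coupling_coefficients(A))
    assert np.all(C[:, :, 1] > 0.999)


def test_shape_errors_are_informative():
    U, W, _ = random_instance(1, n_l=3, d_l=4)
    with pytest.raises(ShapeError, match="n_l"):
        sc.predict_capsules(U[:, :2, :], W)
    with pytest.raises(ConfigurationError, match="iterations"):
        sc.dynamic_routing(U, sc.init_routing_weights(3, 2, 4, 4), iterations=0)


# --------------------------------------------------------------- invariants
@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_coupling_rows_sum_to_one(seed):
    U, W, _ = random_instance(seed)
    A = sc.self_correlation(sc.predict_capsules(U, W), U.shape[2])
    C = np.asarray(sc.coupling_coefficients(A))
    np.testing.assert_allclose(C.sum(axis=-1), 1.0, atol=1e-12)
    assert np.all(C > 0) and np.all(C < 1 + 1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_self_correlation_is_symmetric(seed):
    U, W, _ = random_instance(seed)
    A = np.asarray(sc.self_correlation(sc.predict_capsules(U, W), U.shape[2]))
    np.testing.assert_allclose(A, A.transpose(0, 2, 1, 3), rtol=1e-12)


def test_permutation_equivariance():
    U, W, B = random_instance(11, n_l=4, n_out=2, d_l=3, d_out=3)
    perm = np.array([2, 0, 3, 1])
    weights = sc.RoutingWeights(W=sc.routing.Tensor(W), B=sc.routing.Tensor(B))
    permuted = sc.RoutingWeights(W=sc.routing.Tensor(W[perm]), B=sc.routing.Tensor(B[perm]))
    out = np.asarray(sc.self_correlation_routing(U, weights).values)
    out_p = np.asarray(sc.self_correlation_routing(U[:, perm], permuted).values)
    np.testing.assert_allclose(out, out_p, rtol=1e-10)


def test_batch_independence():
    U, W, B = random_instance(13, batch=5)
    weights = sc.RoutingWeights(W=sc.routing.Tensor(W), B=sc.routing.Tensor(B))
    full = np.asarray(sc.self_correlation_routing(U, weights).values)
    single = np.concatenate([
        np.asarray(sc.self_correlation_routing(U[i : i + 1], weights).values)
        for i in range(U.shape[0])
    ])
    np.testing.assert_allclose(full, single, rtol=1e-12)


def test_routing_gradient_matches_finite_difference():
    """d(margin loss)/dW via backprop agrees with central differences and is
    nonzero for a random non-degenerate instance."""
    U, W, B = random_instance(21, n_l=2, n_out=2, d_l=2, d_out=3, batch=2)
    targets = sc.one_hot([0, 1])

    def loss_at(Wa):
        weights = sc.RoutingWeights(W=sc.routing.Tensor(Wa), B=sc.routing.Tensor(B))
        out = sc.self_correlation_routing(U, weights)
        return sc.margin_loss(sc.class_scores(out.values), targets)

    weights = sc.RoutingWeights(
        W=sc.routing.Tensor(W.copy()), B=sc.routing.Tensor(B))
    weights.W.requires_grad = True
    out = sc.self_correlation_routing(U, weights)
    loss = sc.margin_loss(sc.class_scores(out.values), targets)
    loss.backward()
    grad = weights.W.grad
    assert grad is not None and np.all(np.isfinite(grad)) and np.any(grad != 0)

    h = 1e-6
    num = np.zeros_like(W)
    it = np.nditer(W, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        Wp, Wm = W.copy(), W.copy()
        Wp[idx] += h
        Wm[idx] -= h
        num[idx] = (float(loss_at(Wp).data) - float(loss_at(Wm).data)) / (2 * h)
    np.testing.assert_allclose(grad, num, rtol=1e-4, atol=1e-7)


def test_class_scores_and_tie_break():
    S = np.zeros((2, 2, 4))
    S[0, 0, 0] = 0.9
    S[0, 1, 0] = 0.1
    S[1, 0, 0] = 0.5
    S[1, 1, 1] = 0.5
    scores = np.asarray(sc.class_scores(S))
    preds = sc.predict_classes(scores)
    assert preds[0] == 0
    assert preds[1] == 0  # exact tie resolves to the lower class index


def test_routed_scores_bounded_below_one():
    U, W, B = random_instance(17, batch=4)
    weights = sc.RoutingWeights(W=sc.routing.Tensor(W * 10), B=sc.routing.Tensor(B))
    scores = np.asarray(sc.class_scores(sc.self_correlation_routing(U, weights).values))
    assert np.all(scores >= 0) and np.all(scores < 1.0)
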