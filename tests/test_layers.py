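"""Layer nodes: masquerading, commuted bias, approximations, gradients."""

import numpy as np
import pytest
from scipy.signal import correlate

from fhenet.autofhe import parameterise_ckks
from fhenet.ckks import decrypt, encrypt, rotate
from fhenet.errors import (FHEIncompatibilityError, ShapeError, StateError)
from fhenet.layers import (ArgmaxNode, CCENode, CrossCorrelationNode,
                           DenseNode, MSENode, ReluApproxNode,
                           SigmoidApproxNode, SoftmaxNode, argmax_onehot,
                           cce_loss, masquerade, mse_loss, onehot_decode,
                           onehot_encode, relu, relu_approx,
                           relu_approx_derivative, relu_range_update, sigmoid,
                           sigmoid_approx, sigmoid_approx_derivative, softmax)

from conftest import central_difference

THREE_PI = 3.0 * np.pi


# ---------------------------------------------------------------------------
# masquerade
# ---------------------------------------------------------------------------

def test_masquerade_places_kernel_and_zeros_elsewhere():
    kernel = np.arange(1.0, 5.0).reshape(2, 2)
    mask = masquerade(kernel, (3, 3), (0, 0))
    expected = np.array([[1, 2, 0], [3, 4, 0], [0, 0, 0]], dtype=float)
    np.testing.assert_array_equal(mask, expected)
    shifted = masquerade(kernel, (3, 3), (1, 1))
    np.testing.assert_array_equal(shifted[1:, 1:], kernel)
    assert shifted[0].sum() == 0


def test_masquerade_out_of_bounds_window_rejected():
    with pytest.raises(ShapeError):
        masquerade(np.ones((2, 2)), (3, 3), (2, 2))


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def test_relu_approximation_pins():
    assert relu_approx(0.0, 1.0) == 1.0 / THREE_PI
    assert np.isclose(relu_approx(1.0, 1.0), 5.0 / THREE_PI + 0.5)
    assert relu_approx_derivative(0.0, 1.0) == 0.5
    with pytest.raises(ValueError):
        relu_approx(1.0, 0.0)
    with pytest.raises(ValueError):
        relu_approx_derivative(1.0, -1.0)


def test_relu_approx_error_curve_against_exact_oracle():
    """Inside [-q, q] the worst error sits at x=0 (value q/3π) and the
    approximation stays non-negative at the range edges; beyond q the error
    grows monotonically."""
    q = 1.0
    grid = np.linspace(-q, q, 10001)
    err = np.abs(relu_approx(grid, q) - relu(grid))
    assert np.isclose(err.max(), 0.1061032953945969, atol=1e-12)
    assert grid[np.argmax(err)] == 0.0
    assert relu_approx(q, q) >= 0 and relu_approx(-q, q) >= 0
    outside = np.linspace(q, 3 * q, 100)
    out_err = np.abs(relu_approx(outside, q) - relu(outside))
    assert np.all(np.diff(out_err) >= 0)


def test_relu_derivative_matches_central_difference():
    q = 0.7
    grid = np.linspace(-1.5, 1.5, 31)
    num = central_difference(lambda v: relu_approx(v, q).sum(), grid)
    np.testing.assert_allclose(relu_approx_derivative(grid, q), num,
                               atol=1e-6)


def test_relu_derivative_slope_doubles_when_q_halves():
    x = 0.3
    slope_q = relu_approx_derivative(x, 1.0) - 0.5
    slope_half = relu_approx_derivative(x, 0.5) - 0.5
    assert np.isclose(slope_half, 2 * slope_q)


def test_relu_range_update_ema_fixed_point():
    node = ReluApproxNode(q=1.0, alpha=0.1)
    for _ in range(300):
        relu_range_update(node, np.array([3.0, -3.0]))
    assert np.isclose(node.q, 3.0, atol=1e-6)
    node = ReluApproxNode(q=1.0, alpha=1.0)
    relu_range_update(node, np.array([0.2, -2.5]))
    assert node.q == 2.5
    node = ReluApproxNode(q=1.0, alpha=0.0)
    relu_range_update(node, np.array([9.9]))
    assert node.q == 1.0


def test_sigmoid_approximation_pins_and_error_curve():
    assert sigmoid_approx(0.0) == 0.5
    assert np.isclose(sigmoid_approx(1.0), 0.693)
    grid = np.linspace(-5, 5, 10001)
    err = np.abs(sigmoid(grid) - sigmoid_approx(grid))
    assert np.isclose(err.max(), 0.0510309833778404, atol=1e-12)
    num = central_difference(lambda v: sigmoid_approx(v).sum(),
                             np.linspace(-3, 3, 21))
    np.testing.assert_allclose(
        sigmoid_approx_derivative(np.linspace(-3, 3, 21)), num, atol=1e-6)


def test_polynomial_activations_run_identically_on_cyphertexts():
    params = parameterise_ckks(2)
    x = np.array([-1.0, -0.25, 0.5, 2.0])
    for fn in (lambda v: relu_approx(v, 1.3), sigmoid_approx):
        ct = encrypt(x, params, "k")
        np.testing.assert_array_equal(decrypt(fn(ct)), fn(x))


def test_exact_activations_refuse_cyphertexts():
    ct = encrypt([1.0], parameterise_ckks(2), "k")
    for fn in (relu, sigmoid, softmax, argmax_onehot):
        with pytest.raises(FHEIncompatibilityError):
            fn(ct)


# ---------------------------------------------------------------------------
# plaintext circuit functions
# ---------------------------------------------------------------------------

def test_softmax_basics():
    np.testing.assert_allclose(softmax([0.0, 0.0]), [0.5, 0.5])
    a = np.array([0.3, -1.2, 2.0])
    np.testing.assert_allclose(softmax(a + 7.5), softmax(a), atol=1e-12)
    np.testing.assert_allclose(softmax(np.zeros(10)), np.full(10, 0.1))
    assert np.isclose(softmax(a).sum(), 1.0)


def test_cce_loss_values_and_gradient():
    y = onehot_encode(1, 3)
    loss, grad = cce_loss(np.array([0.0, 1.0, 0.0]), y)
    assert loss == 0.0
    uniform = np.full(10, 0.1)
    loss10, _ = cce_loss(uniform, onehot_encode(4, 10))
    assert np.isclose(loss10, np.log(10))
    p = softmax(np.array([0.2, -0.1, 0.5]))
    _, grad = cce_loss(p, onehot_encode(2, 3))
    np.testing.assert_allclose(grad, p - onehot_encode(2, 3))
    with pytest.warns(UserWarning, match="sum to 1"):
        cce_loss(np.array([0.5, 0.9]), onehot_encode(0, 2))


def test_argmax_and_onehot_roundtrip():
    np.testing.assert_array_equal(argmax_onehot([0.1, 0.7, 0.2]), [0, 1, 0])
    np.testing.assert_array_equal(argmax_onehot([0.5, 0.5]), [1, 0])  # tie->low
    for k in range(4):
        assert onehot_decode(onehot_encode(k, 4)) == k
    with pytest.raises(ValueError):
        onehot_encode(4, 4)


def test_mse_loss_values_and_gradient():
    loss, grad = mse_loss([2.0], [2.0])
    assert loss == 0.0 and grad[0] == 0.0
    loss, grad = mse_loss([3.0], [1.0])
    assert loss == 4.0 and grad[0] == 4.0
    yhat = np.array([1.0, -0.5, 2.0])
    y = np.array([0.5, 0.5, 0.5])
    _, grad = mse_loss(yhat, y)
    num = central_difference(lambda v: mse_loss(v, y)[0], yhat)
    np.testing.assert_allclose(grad, num, rtol=1e-6, atol=1e-8)
    with pytest.raises(ShapeError):
        mse_loss([1.0, 2.0], [1.0])


# ---------------------------------------------------------------------------
# cross-correlation node
# ---------------------------------------------------------------------------

def _fold_windows(node, x):
    """Plaintext fold-sum of each masqueraded window output."""
    return np.array([float(np.sum(w)) for w in node.forward(x.ravel())])


def _direct_cc(x, kernel, stride, bias):
    """Independent oracle: scipy valid cross-correlation + stride + bias."""
    full = correlate(x, kernel, mode="valid", method="direct")
    slices = tuple(slice(None, None, s) for s in stride)
    return full[slices].ravel() + bias


def test_commuted_bias_worked_example():
    """x=(1,2,3,4), w=1, b=4: slots become (2,3,4,5); fold-sum = 14 = Σxw+b."""
    node = CrossCorrelationNode((4,), (4,), stride=1, bias=4.0,
                                kernel=np.ones(4))
    outs = list(node.forward(np.array([1.0, 2.0, 3.0, 4.0])))
    assert len(outs) == 1
    np.testing.assert_array_equal(outs[0], [2, 3, 4, 5])
    assert outs[0].sum() == 14.0


@pytest.mark.parametrize("shape,kshape,stride,n_windows", [
    ((3, 3), (2, 2), (1, 1), 4),
    ((4, 4), (2, 2), (2, 2), 4),
    ((8, 8), (3, 3), (2, 2), 9),
    ((5,), (2,), (1,), 4),
])
def test_window_census(shape, kshape, stride, n_windows):
    node = CrossCorrelationNode(shape, kshape, stride, seed=0)
    assert node.window_count == n_windows
    assert len(list(node.forward(np.zeros(int(np.prod(shape)))))) == n_windows


def test_masqueraded_fold_equals_direct_cross_correlation():
    """100 random (input, kernel, stride) cases against the scipy oracle."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        ndim = int(rng.integers(1, 3))
        shape = tuple(int(rng.integers(3, 7)) for _ in range(ndim))
        kshape = tuple(int(rng.integers(1, d + 1)) for d in shape)
        stride = tuple(int(rng.integers(1, 3)) for _ in range(ndim))
        x = rng.normal(size=shape)
        kernel = rng.normal(size=kshape)
        bias = float(rng.normal())
        node = CrossCorrelationNode(shape, kshape, stride, bias=bias,
                                    kernel=kernel)
        got = _fold_windows(node, x)
        want = _direct_cc(x, kernel, stride, bias)
        np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)


def test_masqueraded_fold_matches_oracle_under_encryption():
    """The simulated backend reproduces the plaintext conv exactly."""
    rng = np.random.default_rng(7)
    params = parameterise_ckks(2)
    for _ in range(10):
        x = rng.normal(size=(4, 4))
        node = CrossCorrelationNode((4, 4), (2, 2), (2, 2),
                                    bias=float(rng.normal()),
                                    kernel=rng.normal(size=(2, 2)))
        plain = _fold_windows(node, x)
        ct = encrypt(x.ravel(), params, "k")
        enc = np.concatenate([
            decrypt(rotate(w, mode="fold")) for w in node.forward(ct)])
        np.testing.assert_array_equal(enc, plain)


def test_cc_consumes_exactly_one_level():
    params = parameterise_ckks(3)
    node = CrossCorrelationNode((3, 3), (2, 2), seed=1)
    ct = encrypt(np.zeros(9), params, "k")
    outs = list(node.forward(ct))
    assert all(o.level == ct.level - node.cost() for o in outs)


def test_cc_backward_matches_finite_differences():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(4, 4))
    kernel = rng.normal(size=(2, 2))
    coeffs = rng.normal(size=9)  # random downstream weighting per window

    def loss_for(kern, bias, inp):
        node = CrossCorrelationNode((4, 4), (2, 2), (1, 1), bias=bias,
                                    kernel=kern)
        return float(np.dot(coeffs, _fold_windows(node, inp)))

    node = CrossCorrelationNode((4, 4), (2, 2), (1, 1), bias=0.3,
                                kernel=kernel)
    list(node.forward(x.ravel()))
    gx = node.backward([np.asarray([c]) for c in coeffs])

    num_k = central_difference(lambda k: loss_for(k, 0.3, x), kernel)
    np.testing.assert_allclose(node._gk, num_k, rtol=1e-4, atol=1e-8)
    num_b = central_difference(
        lambda b: np.array(loss_for(kernel, float(b), x)),
        np.array(0.3))
    np.testing.assert_allclose(node._gb, num_b, rtol=1e-4)
    num_x = central_difference(lambda v: loss_for(kernel, 0.3, v), x)
    np.testing.assert_allclose(gx, num_x.ravel(), rtol=1e-4, atol=1e-8)


def test_cc_backward_requires_forward_cache():
    node = CrossCorrelationNode((3, 3), (2, 2), seed=0)
    with pytest.raises(StateError):
        node.backward([np.ones(1)] * 4)


def test_cc_zero_gradients_give_zero_updates():
    node = CrossCorrelationNode((3, 3), (2, 2), seed=0, bias=0.1)
    before_k, before_b = node.kernel.copy(), node.bias
    list(node.forward(np.ones(9)))
    node.backward([np.zeros(1)] * 4)
    node.apply_gradients(0.5)
    np.testing.assert_array_equal(node.kernel, before_k)
    assert node.bias == before_b


# ---------------------------------------------------------------------------
# dense node
# ---------------------------------------------------------------------------

def test_dense_forward_matches_affine_map():
    node = DenseNode(3, bias=0.6, weights=np.array([1.0, 2.0, -1.0]))
    xs = [np.array([2.0]), np.array([0.5]), np.array([1.0])]
    z = node.forward(xs)
    # Σ x_i w_i + b = 2 + 1 - 1 + 0.6
    np.testing.assert_allclose(z, [2.6])
    single = DenseNode(1, bias=0.5, weights=np.array([1.0]))
    np.testing.assert_allclose(single.forward([np.array([1.0])]), [1.5])


def test_dense_shape_mismatch_rejected():
    node = DenseNode(2, weights=np.array([1.0, 1.0]))
    with pytest.raises(ShapeError):
        node.forward([np.array([1.0])])


def test_dense_backward_matches_finite_differences():
    rng = np.random.default_rng(5)
    w = rng.normal(size=4)
    xs = [np.array([v]) for v in rng.normal(size=4)]

    def loss_for(weights, bias, values):
        node = DenseNode(4, bias=float(bias), weights=weights)
        return float(node.forward([np.array([v]) for v in values])[0])

    node = DenseNode(4, bias=0.2, weights=w)
    node.forward(xs)
    gxs = node.backward(np.array([1.0]))
    vals = np.array([float(x[0]) for x in xs])
    np.testing.assert_allclose(
        node._gw, central_difference(lambda ww: loss_for(ww, 0.2, vals), w),
        rtol=1e-4, atol=1e-8)
    np.testing.assert_allclose(
        node._gb,
        central_difference(lambda b: np.array(loss_for(w, b, vals)),
                           np.array(0.2)), rtol=1e-4)
    num_x = central_difference(lambda vv: loss_for(w, 0.2, vv), vals)
    np.testing.assert_allclose(np.concatenate(gxs), num_x, rtol=1e-4)


def test_dense_runs_identically_on_cyphertexts():
    params = parameterise_ckks(3)
    node = DenseNode(2, bias=0.4, weights=np.array([0.7, -0.2]))
    xs = [np.array([1.5]), np.array([-2.0])]
    plain = node.forward(xs)
    cts = [encrypt(x, params, "k") for x in xs]
    enc = decrypt(node.forward(cts))
    np.testing.assert_array_equal(enc, plain)


# ---------------------------------------------------------------------------
# activation / circuit nodes wired as receptors
# ---------------------------------------------------------------------------

def test_activation_node_sequence_gradients():
    node = ReluApproxNode(q=1.2)
    xs = [np.array([0.3]), np.array([-0.4])]
    node.forward(xs)
    grads = list(node.backward([np.array([2.0]), np.array([1.0])]))
    np.testing.assert_allclose(
        grads[0], 2.0 * relu_approx_derivative(xs[0], 1.2))
    np.testing.assert_allclose(
        grads[1], 1.0 * relu_approx_derivative(xs[1], 1.2))


def test_activation_node_depth_accounting():
    params = parameterise_ckks(4)
    for node in (ReluApproxNode(q=1.0), SigmoidApproxNode()):
        ct = encrypt([0.5], params, "k")
        out = node.forward(ct)
        assert ct.level - out.level == node.cost()


def test_softmax_node_splits_gradient_per_class():
    node = SoftmaxNode()
    p = node.forward([np.array([0.1]), np.array([0.9]), np.array([0.2])])
    assert np.isclose(p.sum(), 1.0)
    grads = list(node.backward(np.array([0.5, -0.2, 0.1])))
    assert [g.shape for g in grads] == [(1,)] * 3
    np.testing.assert_allclose(np.concatenate(grads), [0.5, -0.2, 0.1])


def test_cce_node_caches_loss_and_combined_gradient():
    node = CCENode()
    p = softmax(np.array([0.4, -0.4]))
    y = onehot_encode(0, 2)
    loss = node.forward([p, y])
    assert node.last_loss == loss > 0
    np.testing.assert_allclose(node.backward(1.0), p - y)


def test_softmax_cce_gradient_matches_finite_differences():
    """The combined p - y gradient equals d(CCE(softmax(a)))/da."""
    a = np.array([0.3, -0.7, 1.1])
    y = onehot_encode(2, 3)
    grad = softmax(a) - y
    num = central_difference(lambda v: cce_loss(softmax(v), y)[0], a)
    np.testing.assert_allclose(grad, num, rtol=1e-4, atol=1e-8)


def test_mse_node_roundtrip():
    node = MSENode()
    loss = node.forward([np.array([1.5]), np.array([1.0])])
    assert np.isclose(loss, 0.25)
    np.testing.assert_allclose(node.backward(1.0), [1.0])


def test_argmax_node_is_output_only():
    node = ArgmaxNode()
    out = node.forward([np.array([0.2]), np.array([0.9])])
    np.testing.assert_array_equal(out, [0, 1])
    assert node.backward(np.ones(2)) is None
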