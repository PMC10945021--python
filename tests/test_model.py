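"""Network forward pass, loss components and analytic gradients."""

import numpy as np
import pytest

from cropsae.model import (SSAEWeights, accuracy_f1, forward, huber_loss,
                           init_weights, loss_and_grads, softmax_scores,
                           ssae_loss)

_LAYERS = ("W1", "b1", "W2", "b2", "W3", "b3", "W4", "b4")


@pytest.mark.parametrize("row,expected", [
    ((0.0, 0.0), (0.5, 0.5)),
    ((np.log(3.0), 0.0), (0.75, 0.25)),
])
def test_softmax_closed_forms(row, expected):
    np.testing.assert_allclose(softmax_scores(np.array([row]))[0], expected,
                               atol=1e-12)


def test_softmax_overflow_safe():
    s = softmax_scores(np.array([[1000.0, 0.0]]))
    assert np.all(np.isfinite(s))
    np.testing.assert_allclose(s[0], [1.0, 0.0], atol=1e-300)


def test_softmax_rows_sum_to_one(rng):
    Z = rng.normal(scale=50, size=(40, 2))
    np.testing.assert_allclose(softmax_scores(Z).sum(axis=1), 1.0, atol=1e-6)


@pytest.mark.parametrize("r,delta,expected", [
    (0.5, 1.0, 0.125),   # quadratic branch: 0.5 * 0.25 / 1
    (2.0, 1.0, 1.5),     # linear branch: 2 - 0.5
])
def test_huber_branches(r, delta, expected):
    assert huber_loss(np.array([r]), delta) == pytest.approx(expected)


def test_huber_branch_continuity():
    delta = 0.7
    quad = 0.5 * delta ** 2 / delta
    lin = delta - 0.5 * delta
    assert quad == pytest.approx(lin)
    assert huber_loss(np.array([delta]), delta) == pytest.approx(quad)


def _toy_weights(rng, d=8, h=4):
    return init_weights(d, h, rng)


def test_forward_zero_weights_gives_even_scores():
    w = SSAEWeights(W1=np.zeros((3, 2)), b1=np.zeros(2),
                    W2=np.zeros((2, 2)), b2=np.zeros(2),
                    W3=np.zeros((2, 2)), b3=np.zeros(2),
                    W4=np.zeros((2, 3)), b4=np.zeros(3))
    out = forward(w, np.array([[1.0, 2.0, 3.0]]))
    np.testing.assert_allclose(out.Z, 0.0)
    np.testing.assert_allclose(out.scores, 0.5)


def test_forward_hand_computed_single_cell():
    # d=2, h=2, identity-like weights; all pre-activations positive so the
    # ReLUs are pass-through and the map is plain matrix arithmetic
    w = SSAEWeights(W1=np.eye(2), b1=np.zeros(2),
                    W2=np.array([[1.0, 0.0], [0.0, 1.0]]), b2=np.zeros(2),
                    W3=np.array([[1.0, 0.0], [0.0, 1.0]]), b3=np.zeros(2),
                    W4=2.0 * np.eye(2), b4=np.array([1.0, -1.0]))
    x = np.array([[3.0, 5.0]])
    out = forward(w, x)
    np.testing.assert_allclose(out.Z, [[3.0, 5.0]])
    np.testing.assert_allclose(out.X_hat, [[7.0, 9.0]])


def test_forward_dimension_mismatch(rng):
    w = _toy_weights(rng)
    with pytest.raises(ValueError):
        forward(w, np.zeros((3, 5)))


def test_forward_deterministic(rng):
    w = _toy_weights(rng)
    X = rng.poisson(3.0, size=(6, 8)).astype(float)
    a, b = forward(w, X), forward(w, X)
    np.testing.assert_array_equal(a.Z, b.Z)
    np.testing.assert_array_equal(a.X_hat, b.X_hat)


def test_loss_lambda_zero_is_pure_cross_entropy(rng):
    w = _toy_weights(rng)
    X = rng.poisson(3.0, size=(5, 8)).astype(float)
    Y = np.array([0, 1, 0, 1, 1])
    out = forward(w, X)
    total, ce, rec = ssae_loss(out, X, Y, lam=0.0)
    assert total == pytest.approx(ce)
    assert rec >= 0.0


def test_loss_perfect_reconstruction_component(rng):
    w = _toy_weights(rng)
    X = rng.poisson(3.0, size=(5, 8)).astype(float)
    out = forward(w, X)
    out.X_hat = X.copy()
    _, _, rec = ssae_loss(out, X, np.array([0, 1, 0, 1, 1]))
    assert rec == 0.0


def test_loss_perfect_scores_near_zero_ce(rng):
    w = _toy_weights(rng)
    X = rng.poisson(3.0, size=(4, 8)).astype(float)
    Y = np.array([0, 1, 0, 1])
    out = forward(w, X)
    out.scores = np.eye(2)[Y] * (1 - 1e-12) + 1e-13
    _, ce, _ = ssae_loss(out, X, Y)
    assert ce < 1e-10


def test_loss_rejects_negative_lambda(rng):
    w = _toy_weights(rng)
    X = np.ones((2, 8))
    out = forward(w, X)
    with pytest.raises(ValueError):
        ssae_loss(out, X, np.array([0, 1]), lam=-0.1)


@pytest.mark.parametrize("class_weights", [None, np.array([0.3, 0.7])])
def test_analytic_gradients_match_finite_differences(rng, class_weights):
    """Central finite differences on a 5-cell, 8-gene toy problem."""
    w = _toy_weights(rng)
    X = rng.poisson(3.0, size=(5, 8)).astype(float) + rng.uniform(0, 0.3, (5, 8))
    Y = np.array([0, 1, 0, 1, 1])
    lam, delta = 0.7, 1.3
    _, _, _, grads = loss_and_grads(w, X, Y, lam=lam, delta=delta,
                                    class_weights=class_weights)
    eps = 1e-6
    for layer in _LAYERS:
        arr = getattr(w, layer)
        flat_idx = [tuple(i) for i in np.argwhere(np.ones_like(arr))][:12]
        for idx in flat_idx:
            orig = arr[idx]
            arr[idx] = orig + eps
            lp = ssae_loss(forward(w, X), X, Y, lam=lam, delta=delta,
                           class_weights=class_weights)[0]
            arr[idx] = orig - eps
            lm = ssae_loss(forward(w, X), X, Y, lam=lam, delta=delta,
                           class_weights=class_weights)[0]
            arr[idx] = orig
            num = (lp - lm) / (2 * eps)
            ana = grads[layer][idx]
            assert ana == pytest.approx(num, rel=1e-4, abs=1e-8), \
                f"gradient mismatch at {layer}{idx}"


def test_accuracy_f1_perfect():
    scores = np.array([[0.9, 0.1], [0.2, 0.8], [0.7, 0.3]])
    assert accuracy_f1(scores, np.array([0, 1, 0])) == (1.0, 1.0)


def test_accuracy_f1_degenerate_predictor():
    scores = np.tile([0.9, 0.1], (4, 1))
    acc, f1 = accuracy_f1(scores, np.array([0, 0, 1, 1]))
    assert acc == 0.5
    assert f1 == 0.0


def test_accuracy_f1_contingency():
    # TP=9, FP=1, FN=1, TN=9 -> accuracy 0.9, F1 0.9
    Y = np.array([1] * 10 + [0] * 10)
    pred = np.array([1] * 9 + [0] + [1] + [0] * 9)
    scores = np.eye(2)[pred]
    acc, f1 = accuracy_f1(scores, Y)
    assert acc == pytest.approx(0.9)
    assert f1 == pytest.approx(0.9)
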