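"""Analytic gradients of every layer are checked against finite differences
-- the base oracle for everything the classifier and the attribution do."""

import numpy as np
import pytest

from metabarcode.nn.layers import (Conv1d, Dropout, Flatten, Linear, ReLU,
                                   conv_out_len)
from metabarcode.nn.model import ModelSpec, build_model
from metabarcode.nn.train import softmax_cross_entropy


def numeric_grad(f, arr, eps=1e-3):
    g = np.zeros_like(arr, dtype=np.float64)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = arr[i]
        arr[i] = orig + eps
        fp = f()
        arr[i] = orig - eps
        fm = f()
        arr[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


@pytest.mark.parametrize("c_in,c_out,kernel,stride,l_in", [
    (1, 3, 5, 1, 12), (2, 4, 3, 2, 11), (3, 2, 1, 1, 7), (2, 3, 7, 3, 20),
])
def test_conv1d_gradients_match_finite_differences(c_in, c_out, kernel,
                                                   stride, l_in):
    rng = np.random.default_rng(0)
    conv = Conv1d(c_in, c_out, kernel, stride, rng)
    x = rng.normal(size=(2, l_in, c_in)).astype(np.float32)
    target = rng.normal(size=(2, conv_out_len(l_in, kernel, stride), c_out)) \
        .astype(np.float32)

    def loss():
        return float(((conv.forward(x) - target) ** 2).sum())

    y = conv.forward(x)
    dy = (2 * (y - target)).astype(np.float32)
    dx = conv.backward(dy)
    assert np.allclose(dx, numeric_grad(loss, x), atol=2e-2)
    assert np.allclose(conv.dW, numeric_grad(loss, conv.W), atol=2e-2)
    assert np.allclose(conv.db, numeric_grad(loss, conv.b), atol=2e-2)


def test_linear_gradients_match_finite_differences():
    rng = np.random.default_rng(1)
    lin = Linear(6, 3, rng)
    x = rng.normal(size=(4, 6)).astype(np.float32)
    target = rng.normal(size=(4, 3)).astype(np.float32)

    def loss():
        return float(((lin.forward(x) - target) ** 2).sum())

    dy = (2 * (lin.forward(x) - target)).astype(np.float32)
    dx = lin.backward(dy)
    assert np.allclose(dx, numeric_grad(loss, x), atol=2e-2)
    assert np.allclose(lin.dW, numeric_grad(loss, lin.W), atol=2e-2)


def test_model_end_to_end_gradient_check():
    """Loss gradient w.r.t. a conv weight of a full small network."""
    spec = ModelSpec("pruned", n_wavenumbers=40, dropout=0.0)
    m = build_model(spec, seed=0)
    rng = np.random.default_rng(2)
    x = rng.random((3, 1, 40)).astype(np.float32)
    y = np.array([0, 1, 1])

    def loss():
        return softmax_cross_entropy(m.forward(x), y)[0]

    _, dl = softmax_cross_entropy(m.forward(x), y)
    m.backward(dl)
    for p, g in [(m.params()[0], m.grads()[0]), (m.params()[-2], m.grads()[-2])]:
        flat_idx = [(0, 0), (1, 1) if p.ndim > 1 else (1,)]
        for i in flat_idx:
            num = numeric_grad_at(loss, p, i)
            assert num == pytest.approx(float(g[i]), abs=5e-3)


def numeric_grad_at(f, arr, i, eps=1e-3):
    orig = arr[i]
    arr[i] = orig + eps
    fp = f()
    arr[i] = orig - eps
    fm = f()
    arr[i] = orig
    return (fp - fm) / (2 * eps)


def test_conv_output_length_formula():
    assert conv_out_len(251, 5, 2) == 124
    assert conv_out_len(251, 7, 1) == 245
    assert conv_out_len(124, 3, 1) == 122


def test_input_shorter_than_kernel_rejected():
    rng = np.random.default_rng(0)
    conv = Conv1d(1, 2, 7, 1, rng)
    with pytest.raises(ValueError):
        conv.forward(np.zeros((1, 5, 1), dtype=np.float32))


class TestDropout:
    def test_identity_in_inference_mode(self):
        d = Dropout(0.5)
        x = np.ones((2, 4, 3), dtype=np.float32)
        assert np.array_equal(d.forward(x, train=False), x)

    def test_training_mode_zeroes_and_rescales(self):
        d = Dropout(0.5)
        rng = np.random.default_rng(0)
        x = np.ones((100, 10, 4), dtype=np.float32)
        y = d.forward(x, rng=rng, train=True)
        kept = y[y > 0]
        assert np.allclose(kept, 2.0)  # inverted scaling by 1/(1-p)
        assert 0.3 < (y == 0).mean() < 0.7

    def test_training_without_rng_rejected(self):
        with pytest.raises(ValueError):
            Dropout(0.2).forward(np.ones((1, 2, 2), dtype=np.float32),
                                 train=True)

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            Dropout(1.0)


def test_flatten_round_trip():
    f = Flatten()
    x = np.arange(24, dtype=np.float32).reshape(2, 4, 3)
    y = f.forward(x)
    assert y.shape == (2, 12)
    assert np.array_equal(f.backward(y), x)


def test_relu_masks_negative_inputs():
    r = ReLU()
    x = np.array([[-1.0, 2.0], [3.0, -4.0]], dtype=np.float32)
    assert np.array_equal(r.forward(x), [[0, 2], [3, 0]])
    assert np.array_equal(r.backward(np.ones_like(x)), [[0, 1], [1, 0]])
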