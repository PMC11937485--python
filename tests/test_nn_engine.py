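"""Training engine: backpropagated gradients against numerical
finite-difference gradients, plus optimizer/training contracts."""

import numpy as np
import pytest

from mvmdm import nn


def numeric_gradient(loss_fn, param, eps=1e-3):
    g = np.zeros_like(param, dtype=np.float64)
    it = np.nditer(param, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        old = param[idx]
        param[idx] = old + eps
        lp = loss_fn()
        param[idx] = old - eps
        lm = loss_fn()
        param[idx] = old
        g[idx] = (lp - lm) / (2 * eps)
    return g


def _net_loss(net, x, y, training):
    z = net.forward_logits(x, training=training)
    return nn.bce_with_logits(z, y)


def _backprop(net, x, y, training):
    out = np.asarray(x, dtype=np.float32)
    for layer in net.layers:
        out = layer.forward(out, training=training)
    z = out.ravel().astype(np.float64)
    p = 1.0 / (1.0 + np.exp(-z))
    g = ((p - y) / len(y)).astype(np.float32).reshape(out.shape)
    for layer in reversed(net.layers):
        g = layer.backward(g)


@pytest.mark.parametrize(
    "layers,shape",
    [
        (lambda: [nn.Dense(6, 4), nn.Dense(4, 1, activation="none")], (5, 6)),
        (
            lambda: [nn.Conv((3,), 1, 2), nn.MaxPool((2,)), nn.Flatten(), nn.Dense(4, 1, "none")],
            (3, 7, 1),
        ),
        (
            lambda: [
                nn.Conv((3, 3), 1, 2),
                nn.BatchNorm(2),
                nn.MaxPool((2, 2)),
                nn.Flatten(),
                nn.Dense(8, 1, "none"),
            ],
            (4, 6, 6, 1),
        ),
        (
            lambda: [
                nn.Conv((2, 3, 3), 1, 2),
                nn.MaxPool((1, 2, 2)),
                nn.Flatten(),
                nn.Dense(4, 1, "none"),
            ],
            (3, 3, 5, 5, 1),
        ),
    ],
    ids=["dense", "conv1d", "conv2d_batchnorm", "conv3d"],
)
@pytest.mark.parametrize("training", [True, False], ids=["train_mode", "eval_mode"])
def test_backprop_matches_numerical_gradient(layers, shape, training):
    """Analytic parameter gradients agree with central finite differences
    for each architecture family, in both training mode (batch statistics
    enter the loss) and eval mode (running statistics are constants)."""
    rng = np.random.default_rng(0)
    net = nn.Network(layers(), seed=1)
    # non-trivial batchnorm running statistics for the eval-mode path
    for layer in net.layers:
        if isinstance(layer, nn.BatchNorm):
            layer.running_mean[...] = rng.normal(size=layer.channels).astype(np.float32)
            layer.running_var[...] = rng.uniform(0.5, 2.0, size=layer.channels).astype(np.float32)
            layer.momentum = 1.0  # freeze running stats so repeated forwards agree
    x = rng.normal(size=shape).astype(np.float32)
    y = rng.integers(0, 2, size=shape[0]).astype(np.float64)
    _backprop(net, x, y, training)
    for layer in net.layers:
        for param, grad in zip(layer.params, layer.grads):
            num = numeric_gradient(lambda: _net_loss(net, x, y, training), param)
            np.testing.assert_allclose(grad, num, atol=2e-3, rtol=2e-2)


def test_maxpool_routes_gradient_to_argmax():
    pool = nn.MaxPool((2,))
    x = np.array([[[1.0], [3.0], [2.0], [0.0]]], dtype=np.float32)  # (1, 4, 1)
    out = pool.forward(x, training=True)
    np.testing.assert_allclose(out[..., 0], [[3.0, 2.0]])
    dx = pool.backward(np.ones_like(out))
    np.testing.assert_allclose(dx[..., 0], [[0.0, 1.0, 1.0, 0.0]])


def test_dropout_inverted_scaling_and_eval_identity():
    rng = np.random.default_rng(0)
    drop = nn.Dropout(0.5)
    drop.rng = rng
    x = np.ones((200, 10), dtype=np.float32)
    out = drop.forward(x, training=True)
    kept = out > 0
    assert 0.3 < kept.mean() < 0.7
    np.testing.assert_allclose(out[kept], 2.0)  # 1 / (1 - rate)
    np.testing.assert_array_equal(drop.forward(x, training=False), x)


def test_fit_is_deterministic_under_seed():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(24, 6)).astype(np.float32)
    y = (x[:, 0] > 0).astype(float)
    hists = []
    for _ in range(2):
        net = nn.Network([nn.Dense(6, 8), nn.Dense(8, 1, "none")], seed=5)
        hists.append(net.fit(x, y, epochs=5, batch_size=8))
    assert hists[0] == hists[1]


def test_zero_epochs_returns_initialization_and_empty_history():
    net = nn.Network([nn.Dense(4, 1, "none")], seed=0)
    w0 = [p.copy() for p in net.get_weights()]
    hist = net.fit(np.zeros((4, 4), dtype=np.float32), np.array([0, 1, 0, 1.0]), epochs=0)
    assert hist == {"loss": [], "accuracy": []}
    for a, b in zip(w0, net.get_weights()):
        np.testing.assert_array_equal(a, b)


def test_single_class_training_rejected():
    net = nn.Network([nn.Dense(3, 1, "none")], seed=0)
    with pytest.raises(ValueError, match="both classes"):
        net.fit(np.zeros((4, 3), dtype=np.float32), np.ones(4), epochs=1)


def test_convex_probe_loss_decreases():
    """On a frozen-feature logistic probe (single dense layer, convex
    objective) full-batch Adam at lr 0.001 decreases the loss monotonically
    over the first epochs."""
    rng = np.random.default_rng(7)
    x = rng.normal(size=(64, 5)).astype(np.float32)
    y = (x @ np.array([1.0, -1.0, 0.5, 0.0, 0.0]) > 0).astype(float)
    net = nn.Network([nn.Dense(5, 1, activation="none")], seed=1)
    hist = net.fit(x, y, epochs=5, batch_size=64)
    assert all(a >= b for a, b in zip(hist["loss"], hist["loss"][1:]))


def test_memorization_overfit_small_sample():
    """A tiny sample with many epochs is memorized: training accuracy 1.0."""
    rng = np.random.default_rng(4)
    x = rng.normal(size=(8, 16, 1)).astype(np.float32)
    y = np.array([0, 1] * 4, dtype=float)
    net = nn.Network(
        [nn.Conv((3,), 1, 4), nn.MaxPool((2,)), nn.Flatten(), nn.Dense(28, 1, "none")], seed=2
    )
    hist = net.fit(x, y, epochs=200, batch_size=8)
    assert hist["accuracy"][-1] == 1.0


def test_validation_checkpoint_restores_best_epoch():
    rng = np.random.default_rng(9)
    x = rng.normal(size=(32, 4)).astype(np.float32)
    y = (x[:, 0] > 0).astype(float)
    xv = rng.normal(size=(16, 4)).astype(np.float32)
    yv = (xv[:, 0] > 0).astype(float)
    net = nn.Network([nn.Dense(4, 8), nn.Dense(8, 1, "none")], seed=3)
    hist = net.fit(x, y, epochs=30, batch_size=8, x_val=xv, y_val=yv)
    final_val = nn.bce_with_logits(net.forward_logits(xv), yv)
    assert final_val == pytest.approx(min(hist["val_loss"]), abs=1e-6)
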