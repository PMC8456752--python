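"""A compact NumPy neural-network core for the scrambled-edge classifier.

Implements exactly the pieces the classifier needs — a row-spanning
convolution, batch normalization, ReLU, dropout, dense layers, a two-class
softmax with categorical cross-entropy, and the Adam optimizer — together
with the reverse-mode machinery required by the interpretability methods:
gradients with respect to inputs, guided backpropagation (negative gradients
zeroed at each ReLU), and access to the convolutional feature maps and their
gradients for Grad-CAM.

All array math is float32. Every source of randomness (weight init, batch
shuffling, dropout masks) comes from a caller-supplied Generator, so runs
are reproducible on one device.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, training):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad, guided=False):  # pragma: no cover - interface
        raise NotImplementedError


class RowConv(Layer):
    """Convolution whose every filter spans one full grid row across bands.

    Input (B, R, C) with C = columns x bands; each of ``n_filters`` filters
    is a length-C template applied at every row, sharing weights across rows.
    Output (B, R, F). Equivalent to a dense map over the last axis.
    """

    def __init__(self, row_len: int, n_filters: int, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (row_len + n_filters))  # Glorot uniform
        self.W = rng.uniform(-limit, limit, size=(row_len, n_filters)).astype(DTYPE)
        self.b = np.zeros(n_filters, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training):
        self._x2d = x.reshape(-1, x.shape[-1])
        self._shape = x.shape
        out = self._x2d @ self.W + self.b
        return out.reshape(x.shape[:-1] + (self.W.shape[1],))

    def backward(self, grad, guided=False):
        B = grad.shape[0]
        g2d = grad.reshape(-1, grad.shape[-1])
        self.grads[0][...] = self._x2d.T @ g2d / B
        self.grads[1][...] = g2d.sum(axis=0) / B
        return (g2d @ self.W.T).reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad, guided=False):
        B = grad.shape[0]
        self.grads[0][...] = self._x.T @ grad / B
        self.grads[1][...] = grad.sum(axis=0) / B
        return grad @ self.W.T


class BatchNorm(Layer):
    """Normalization over all axes but the last (per feature channel)."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-3):
        super().__init__()
        self.gamma = np.ones(n_features, dtype=DTYPE)
        self.beta = np.zeros(n_features, dtype=DTYPE)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(n_features, dtype=DTYPE)
        self.running_var = np.ones(n_features, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var[...] = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        self._axes = axes
        self._m = int(np.prod([x.shape[a] for a in axes]))
        self._std = np.sqrt(var + self.eps).astype(DTYPE)
        self._xhat = ((x - mean) / self._std).astype(DTYPE)
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, grad, guided=False):
        axes, m = self._axes, self._m
        self.grads[0][...] = (grad * self._xhat).sum(axis=axes) / grad.shape[0]
        self.grads[1][...] = grad.sum(axis=axes) / grad.shape[0]
        if not self._training:
            return grad * (self.gamma / self._std)
        dxhat = grad * self.gamma
        return (
            dxhat - dxhat.mean(axis=axes)
            - self._xhat * (dxhat * self._xhat).mean(axis=axes)
        ) / self._std


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, grad, guided=False):
        grad = np.where(self._mask, grad, 0)
        if guided:
            grad = np.where(grad > 0, grad, 0)
        return grad


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, grad, guided=False):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad, guided=False):
        return grad.reshape(self._shape)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    return float(-(onehot * np.log(probs + 1e-12)).sum(axis=-1).mean())


class Network:
    """A feed-forward stack with training, prediction and saliency hooks."""

    def __init__(self, layers: list[Layer], conv_relu_index: int | None = None):
        self.layers = layers
        #: index of the post-convolution ReLU whose output feeds Grad-CAM
        self.conv_relu_index = conv_relu_index

    # -- forward / backward ------------------------------------------------
    def forward(self, x, training=False, record=False):
        h = x.astype(DTYPE)
        self._feature_maps = None
        for i, layer in enumerate(self.layers):
            h = layer.forward(h, training)
            if record and i == self.conv_relu_index:
                self._feature_maps = h
        return h

    def backward_from_logits(self, grad_logits, guided=False, record=False):
        """Backpropagate an upstream gradient on the logits to the input.

        Returns the input gradient; when ``record`` the gradient arriving at
        the Grad-CAM feature maps is stored as ``feature_map_grads``.
        """
        g = grad_logits.astype(DTYPE)
        self._feature_map_grads = None
        for i in range(len(self.layers) - 1, -1, -1):
            if record and i == self.conv_relu_index:
                self._feature_map_grads = g
            g = self.layers[i].backward(g, guided=guided)
        return g

    @property
    def feature_maps(self):
        return self._feature_maps

    @property
    def feature_map_grads(self):
        return self._feature_map_grads

    # -- inference ---------------------------------------------------------
    def predict_proba(self, x, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[i:i + batch_size], training=False)))
        return np.concatenate(out) if out else np.empty((0, 2))

    # -- parameters --------------------------------------------------------
    def parameters(self):
        return [p for layer in self.layers for p in layer.params]

    def gradients(self):
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def get_weights(self):
        state = [p.copy() for p in self.parameters()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def set_weights(self, state):
        params = self.parameters()
        for p, s in zip(params, state):
            p[...] = s
        rest = state[len(params):]
        k = 0
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = rest[k]
                layer.running_var[...] = rest[k + 1]
                k += 2


class Adam:
    """Adam with the framework-conventional defaults (lr 1e-3, b1 .9, b2 .999)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def fit(
    net: Network,
    x_train, y_train, x_val, y_val,
    epochs: int,
    batch_size: int,
    rng: np.random.Generator,
    lr: float = 1e-3,
) -> dict:
    """Minibatch Adam training with best-validation-accuracy weight restore.

    ``y_*`` are integer class labels. Returns a log dict with per-epoch loss
    and validation accuracy plus the selected best epoch (ties -> earliest).
    """
    n_classes = int(max(y_train.max(), y_val.max())) + 1
    onehot = np.eye(n_classes, dtype=DTYPE)[y_train]
    opt = Adam(net.parameters(), lr=lr)
    best_acc, best_epoch, best_state = -np.inf, -1, net.get_weights()
    log = {"loss": [], "val_accuracy": []}
    n = len(x_train)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            logits = net.forward(x_train[idx], training=True)
            probs = softmax(logits)
            losses.append(cross_entropy(probs, onehot[idx]))
            net.backward_from_logits(probs - onehot[idx])
            opt.step(net.gradients())
        val_acc = float(
            (net.predict_proba(x_val).argmax(axis=1) == y_val).mean()
        )
        log["loss"].append(float(np.mean(losses)))
        log["val_accuracy"].append(val_acc)
        if val_acc > best_acc:
            best_acc, best_epoch = val_acc, epoch
            best_state = net.get_weights()
    net.set_weights(best_state)
    log["best_epoch"] = best_epoch
    log["best_val_accuracy"] = best_acc
    return log
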