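"""Minimal numpy neural-network engine for the CoD classifier.

Implements exactly the layer set the window classifier needs — 1-D valid
convolution, batch normalization, dense layers, ReLU, inverted dropout —
with softmax/cross-entropy loss, Adam, and early stopping.  Everything is
plain numpy and deterministic under a seed, which keeps ensemble training
reproducible bit-for-bit on one CPU.

Array layout: convolutional stages use (batch, length, channels); batch
normalization always normalizes the trailing (feature/channel) axis over
all other axes, matching the per-feature convention of standard deep
learning frameworks (4 parameters per feature: gamma, beta and the
non-trainable running mean and variance).
"""

from __future__ import annotations

import numpy as np

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9  # running = m*running + (1-m)*batch


class Layer:
    """Base layer: trainable params, their grads, non-trainable state."""

    name = "layer"

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []
        self.state: list[np.ndarray] = []  # non-trainable (BN running stats)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, in_shape: tuple) -> tuple:
        return in_shape

    @property
    def n_trainable(self) -> int:
        return sum(p.size for p in self.params)

    @property
    def n_non_trainable(self) -> int:
        return sum(s.size for s in self.state)


class Conv1D(Layer):
    """Valid convolution along the length axis, stride 1, (B, L, C) layout."""

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.kernel = kernel
        fan_in = in_channels * kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (kernel, in_channels, filters))
        self.b = np.zeros(filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.name = f"conv1d({filters})"

    def out_shape(self, in_shape: tuple) -> tuple:
        L, C = in_shape
        L_out = L - self.kernel + 1
        if L_out < 1:
            raise ValueError(
                f"kernel {self.kernel} does not fit input length {L}")
        if C != self.W.shape[1]:
            raise ValueError(f"expected {self.W.shape[1]} channels, got {C}")
        return (L_out, self.W.shape[2])

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        L_out = x.shape[1] - self.kernel + 1
        out = np.broadcast_to(self.b, (x.shape[0], L_out, self.b.size)).copy()
        for dk in range(self.kernel):
            out += x[:, dk:dk + L_out, :] @ self.W[dk]
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        L_out = g.shape[1]
        gx = np.zeros_like(x)
        for dk in range(self.kernel):
            self.grads[0][dk] = np.einsum("blc,blo->co", x[:, dk:dk + L_out, :], g)
            gx[:, dk:dk + L_out, :] += g @ self.W[dk].T
        self.grads[1][...] = g.sum(axis=(0, 1))
        return gx


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.name = f"dense({n_out})"

    def out_shape(self, in_shape: tuple) -> tuple:
        if in_shape != (self.W.shape[0],):
            raise ValueError(
                f"dense layer expects {self.W.shape[0]} inputs, got {in_shape}")
        return (self.W.shape[1],)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.W.T


class BatchNorm(Layer):
    """Normalizes the trailing feature axis; 2 trainable + 2 running arrays."""

    def __init__(self, n_features: int) -> None:
        super().__init__()
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.state = [self.running_mean, self.running_var]
        self.name = f"batchnorm({n_features})"

    def out_shape(self, in_shape: tuple) -> tuple:
        if in_shape[-1] != self.gamma.size:
            raise ValueError(
                f"batchnorm expects {self.gamma.size} features, got {in_shape}")
        return in_shape

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean *= _BN_MOMENTUM
            self.running_mean += (1 - _BN_MOMENTUM) * mean
            self.running_var *= _BN_MOMENTUM
            self.running_var += (1 - _BN_MOMENTUM) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + _BN_EPS)
        self._xhat = (x - mean) / self._std
        self._m = int(np.prod([x.shape[a] for a in axes]))
        return self.gamma * self._xhat + self.beta

    def backward(self, g: np.ndarray) -> np.ndarray:
        axes = tuple(range(g.ndim - 1))
        self.grads[0][...] = (g * self._xhat).sum(axis=axes)
        self.grads[1][...] = g.sum(axis=axes)
        m = self._m
        gxhat = g * self.gamma
        return (gxhat - gxhat.mean(axis=axes)
                - self._xhat * (gxhat * self._xhat).mean(axis=axes)) / self._std


class ReLU(Layer):
    name = "relu"

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self.name = f"dropout({rate})"

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask


class Flatten(Layer):
    name = "flatten"

    def out_shape(self, in_shape: tuple) -> tuple:
        return (int(np.prod(in_shape)),)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._shape)


class Network:
    """A plain layer stack with softmax output."""

    def __init__(self, layers: list[Layer], input_shape: tuple) -> None:
        self.layers = layers
        self.input_shape = input_shape
        # validate the shape chain at construction time
        shape = input_shape
        self.shape_chain = [shape]
        for layer in layers:
            shape = layer.out_shape(shape)
            self.shape_chain.append(shape)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, g: np.ndarray) -> None:
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Softmax class probabilities in evaluation mode."""
        outs = []
        for k in range(0, len(x), batch_size):
            logits = self.forward(x[k:k + batch_size], training=False)
            outs.append(softmax(logits))
        return np.concatenate(outs) if outs else np.empty((0, 2))

    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(p.copy() for p in layer.params)
            out.extend(s.copy() for s in layer.state)
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        k = 0
        for layer in self.layers:
            for p in layer.params:
                p[...] = weights[k]
                k += 1
            for s in layer.state:
                s[...] = weights[k]
                k += 1
        if k != len(weights):
            raise ValueError("weight list does not match network structure")


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(y)
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    grad = p
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def fit(
    network: Network,
    x_train: np.ndarray, y_train: np.ndarray,
    x_val: np.ndarray, y_val: np.ndarray,
    lr: float = 1e-3, batch_size: int = 64, epochs: int = 100,
    patience: int = 10, seed: int = 0,
) -> dict:
    """Minibatch Adam with early stopping on validation loss.

    Restores the best-validation weights before returning.  History holds
    per-epoch train loss, validation loss and validation accuracy.
    """
    if len(x_train) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    opt = Adam(network.parameters, lr=lr)
    history = {"train_loss": [], "val_loss": [], "val_acc": []}
    best_loss, best_weights, bad_epochs = np.inf, network.get_weights(), 0
    for _ in range(epochs):
        order = rng.permutation(len(x_train))
        losses = []
        for k in range(0, len(order), batch_size):
            idx = order[k:k + batch_size]
            logits = network.forward(x_train[idx], training=True)
            loss, grad = cross_entropy_grad(logits, y_train[idx])
            network.backward(grad)
            opt.step(network.gradients)
            losses.append(loss)
        val_logits = network.forward(x_val, training=False)
        val_loss, _ = cross_entropy_grad(val_logits, y_val)
        val_acc = float((val_logits.argmax(axis=1) == y_val).mean())
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        if val_loss < best_loss - 1e-6:
            best_loss, best_weights, bad_epochs = val_loss, network.get_weights(), 0
        else:
            bad_epochs += 1
            if bad_epochs >= patience:
                break
    network.set_weights(best_weights)
    return history
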