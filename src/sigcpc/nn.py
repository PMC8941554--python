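"""Minimal numpy neural-network layers with hand-written backpropagation.

Everything the pretext and downstream models need lives here: dense layers,
1-D batch normalization, ReLU, a GRU cell unrolled over short sequences,
valid-padding 1-D convolution over a latent sequence, softmax/sigmoid heads
and an Adam optimizer.  Layers are stateless across calls: ``forward``
returns ``(output, cache)`` and ``backward(grad, cache)`` returns the input
gradient while accumulating parameter gradients into ``layer.grads`` — this
lets one weight-shared layer (the encoder used on both halves of a sample
pair) be applied several times per step.

All arithmetic is float64.  Shapes follow the convention ``(batch, features)``
or ``(batch, time, features)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "BatchNorm",
    "GRU",
    "Conv1dSeq",
    "Adam",
    "relu",
    "relu_grad",
    "sigmoid",
    "softmax",
]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_grad(dy: np.ndarray, x: np.ndarray) -> np.ndarray:
    return dy * (x > 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable two-branch form
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Layer:
    """Base: parameter/gradient dicts plus train/infer bookkeeping."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


class Dense(Layer):
    """Affine map ``y = x @ W + b`` with He-scaled initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.params["b"] = np.zeros(n_out)
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = True):
        return x @ self.params["W"] + self.params["b"], x

    def backward(self, dy: np.ndarray, cache: np.ndarray) -> np.ndarray:
        x = cache
        self.grads["W"] += x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


class BatchNorm(Layer):
    """Per-feature batch normalization with running statistics.

    Train mode normalizes by batch statistics and updates the running
    mean/variance (momentum 0.9); infer mode uses the running statistics,
    making the layer a deterministic function of its input.
    """

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(n_features)
        self.params["beta"] = np.zeros(n_features)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = True):
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        y = self.params["gamma"] * xhat + self.params["beta"]
        return y, (xhat, inv_std, train, x.shape[0])

    def backward(self, dy: np.ndarray, cache) -> np.ndarray:
        xhat, inv_std, train, n = cache
        self.grads["gamma"] += (dy * xhat).sum(axis=0)
        self.grads["beta"] += dy.sum(axis=0)
        dxhat = dy * self.params["gamma"]
        if not train:
            return dxhat * inv_std
        # batch statistics participate in the forward pass
        return (
            inv_std
            / n
            * (n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        )


class GRU(Layer):
    """Gated recurrent unit consuming a short latent sequence.

    ``forward`` runs over ``x`` of shape ``(B, T, n_in)`` from a zero initial
    hidden state and returns the final hidden state ``(B, n_hidden)`` — the
    context vector that summarizes the left half of a sample pair.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        s_x = np.sqrt(1.0 / n_in)
        s_h = np.sqrt(1.0 / n_hidden)
        for gate in ("r", "z", "n"):
            self.params[f"Wx{gate}"] = rng.uniform(-s_x, s_x, size=(n_in, n_hidden))
            self.params[f"Wh{gate}"] = rng.uniform(-s_h, s_h, size=(n_hidden, n_hidden))
            self.params[f"bx{gate}"] = np.zeros(n_hidden)
            self.params[f"bh{gate}"] = np.zeros(n_hidden)
        self.n_hidden = n_hidden
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = True):
        P = self.params
        B, T, _ = x.shape
        h = np.zeros((B, self.n_hidden))
        steps = []
        for t in range(T):
            xt = x[:, t, :]
            r = sigmoid(xt @ P["Wxr"] + P["bxr"] + h @ P["Whr"] + P["bhr"])
            z = sigmoid(xt @ P["Wxz"] + P["bxz"] + h @ P["Whz"] + P["bhz"])
            hn = h @ P["Whn"] + P["bhn"]  # candidate's recurrent pre-activation
            n = np.tanh(xt @ P["Wxn"] + P["bxn"] + r * hn)
            h_new = (1.0 - z) * n + z * h
            steps.append((xt, h, r, z, n, hn))
            h = h_new
        return h, steps

    def backward(self, dh: np.ndarray, cache) -> np.ndarray:
        P, G = self.params, self.grads
        steps = cache
        T = len(steps)
        B = dh.shape[0]
        dx = np.zeros((B, T, P["Wxr"].shape[0]))
        dh = dh.copy()
        for t in reversed(range(T)):
            xt, h_prev, r, z, n, hn = steps[t]
            dn = dh * (1.0 - z)
            dz = dh * (h_prev - n)
            dh_prev = dh * z
            da_n = dn * (1.0 - n**2)  # through tanh
            dr = da_n * hn
            dhn = da_n * r
            da_r = dr * r * (1.0 - r)
            da_z = dz * z * (1.0 - z)
            G["Wxn"] += xt.T @ da_n
            G["bxn"] += da_n.sum(axis=0)
            G["Whn"] += h_prev.T @ dhn
            G["bhn"] += dhn.sum(axis=0)
            G["Wxr"] += xt.T @ da_r
            G["bxr"] += da_r.sum(axis=0)
            G["Whr"] += h_prev.T @ da_r
            G["bhr"] += da_r.sum(axis=0)
            G["Wxz"] += xt.T @ da_z
            G["bxz"] += da_z.sum(axis=0)
            G["Whz"] += h_prev.T @ da_z
            G["bhz"] += da_z.sum(axis=0)
            dx[:, t, :] = da_n @ P["Wxn"].T + da_r @ P["Wxr"].T + da_z @ P["Wxz"].T
            dh_prev = dh_prev + dhn @ P["Whn"].T + da_r @ P["Whr"].T + da_z @ P["Whz"].T
            dh = dh_prev
        return dx


class Conv1dSeq(Layer):
    """Valid-padding 1-D convolution along a short time axis.

    Input ``(B, T, C_in)`` → output ``(B, T - k + 1, C_out)``; the kernel
    ``W`` has shape ``(k, C_in, C_out)``.  T is the latent-sequence length
    (4 for the replicate-by-4 classifier input), so the loops over kernel
    taps are cheap.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.kernel = kernel
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / (kernel * c_in)), size=(kernel, c_in, c_out))
        self.params["b"] = np.zeros(c_out)
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = True):
        B, T, _ = x.shape
        k = self.kernel
        if T < k:
            raise ValueError(f"sequence length {T} shorter than kernel {k}")
        T_out = T - k + 1
        W, b = self.params["W"], self.params["b"]
        y = np.zeros((B, T_out, W.shape[2]))
        for u in range(k):
            y += x[:, u : u + T_out, :] @ W[u]
        y += b
        return y, x

    def backward(self, dy: np.ndarray, cache: np.ndarray) -> np.ndarray:
        x = cache
        k = self.kernel
        T_out = dy.shape[1]
        W = self.params["W"]
        dx = np.zeros_like(x)
        for u in range(k):
            xs = x[:, u : u + T_out, :]
            # (k, C_in, C_out) gradient: contract batch and time
            self.grads["W"][u] += np.einsum("btc,bto->co", xs, dy)
            dx[:, u : u + T_out, :] += dy @ W[u].T
        self.grads["b"] += dy.sum(axis=(0, 1))
        return dx


class Adam:
    """Adam optimizer over a list of layers (keyed param/grad dicts)."""

    def __init__(
        self,
        layers: list[Layer],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.layers = layers
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in layers]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = self.beta1 * m[k] + (1.0 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1.0 - self.beta2) * g**2
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)
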