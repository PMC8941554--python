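"""Contrastive-predictive-coding pretext task.

The pretext model learns, without class labels ever entering the loss, to
tell whether the two halves of a sample pair come from the same class:

* an encoder ``g_enc`` — four identical (dense → batch-norm → ReLU) blocks
  plus a final dense layer — maps each raw epoch to a latent ``z``;
* a GRU ``g_ar`` consumes the four left-block latents in order and emits a
  context vector ``c``;
* per-step linear predictors ``W_k`` project ``c`` toward each right-block
  latent; the inner-product scores ``s_k = <W_k c, z_k^W>`` are mean-pooled
  and squashed through a sigmoid into the pair probability ``p``;
* the loss is mean binary cross-entropy between ``p`` and the pair label
  (1 positive / 0 negative).

Positive pairs push the context to predict same-class latents, negative
pairs push it away from other-class latents, so the encoder is forced to
organize its latent space by class — exactly the representation the
downstream classifier reuses.  An alternative softmax (InfoNCE-style) loss
over in-batch negatives is available behind ``loss="infonce"`` for
comparison; the default objective is the binary one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data import EpochDataset
from .nn import GRU, Adam, BatchNorm, Dense, Layer, relu, relu_grad, sigmoid, softmax
from .pairs import SamplePair, batch_arrays, pair_batch

__all__ = [
    "Encoder",
    "PretextModel",
    "PretextConfig",
    "PretextHistory",
    "encode",
    "contextualize",
    "pair_probability",
    "pretext_loss",
    "train_pretext",
    "save_encoder",
    "load_encoder",
]

CHECKPOINT_FORMAT_VERSION = 1


class TrainingDivergenceError(RuntimeError):
    """Raised when a training loss becomes non-finite."""


class Encoder:
    """Shared epoch encoder: 4 × (dense → batch-norm → ReLU) + dense output.

    The same weights encode every epoch of both halves of every pair (and,
    later, the replicated classifier input).  In infer mode batch-norm uses
    running statistics, so encoding is deterministic.
    """

    def __init__(
        self,
        input_length: int,
        hidden: tuple[int, ...] = (256, 128, 128, 128),
        d_z: int = 64,
        rng: np.random.Generator | None = None,
    ) -> None:
        if rng is None:
            rng = np.random.default_rng()
        self.input_length = int(input_length)
        self.hidden = tuple(int(h) for h in hidden)
        self.d_z = int(d_z)
        self.blocks: list[tuple[Dense, BatchNorm]] = []
        n_in = self.input_length
        for h in self.hidden:
            self.blocks.append((Dense(n_in, h, rng), BatchNorm(h)))
            n_in = h
        self.out = Dense(n_in, self.d_z, rng)

    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        for dense, bn in self.blocks:
            out.extend([dense, bn])
        out.append(self.out)
        return out

    def forward(self, x: np.ndarray, train: bool = True):
        if x.shape[-1] != self.input_length:
            raise ValueError(
                f"epoch length {x.shape[-1]} does not match encoder input "
                f"width {self.input_length}"
            )
        caches = []
        h = x
        for dense, bn in self.blocks:
            a, c_dense = dense.forward(h, train)
            b, c_bn = bn.forward(a, train)
            h = relu(b)
            caches.append((c_dense, c_bn, b))
        z, c_out = self.out.forward(h, train)
        caches.append(c_out)
        return z, caches

    def backward(self, dz: np.ndarray, caches) -> np.ndarray:
        dh = self.out.backward(dz, caches[-1])
        for (dense, bn), (c_dense, c_bn, pre_relu) in zip(
            reversed(self.blocks), reversed(caches[:-1])
        ):
            db = relu_grad(dh, pre_relu)
            da = bn.backward(db, c_bn)
            dh = dense.backward(da, c_dense)
        return dh

    # -- checkpoint plumbing -------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, (dense, bn) in enumerate(self.blocks):
            state[f"block{i}.W"] = dense.params["W"]
            state[f"block{i}.b"] = dense.params["b"]
            state[f"block{i}.gamma"] = bn.params["gamma"]
            state[f"block{i}.beta"] = bn.params["beta"]
            state[f"block{i}.running_mean"] = bn.running_mean
            state[f"block{i}.running_var"] = bn.running_var
        state["out.W"] = self.out.params["W"]
        state["out.b"] = self.out.params["b"]
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, (dense, bn) in enumerate(self.blocks):
            dense.params["W"] = np.array(state[f"block{i}.W"])
            dense.params["b"] = np.array(state[f"block{i}.b"])
            bn.params["gamma"] = np.array(state[f"block{i}.gamma"])
            bn.params["beta"] = np.array(state[f"block{i}.beta"])
            bn.running_mean = np.array(state[f"block{i}.running_mean"])
            bn.running_var = np.array(state[f"block{i}.running_var"])
        self.out.params["W"] = np.array(state["out.W"])
        self.out.params["b"] = np.array(state["out.b"])
        for layer in self.layers():
            layer.zero_grad()


class StepPredictors(Layer):
    """The per-step linear maps W_k (context → predicted latent), k = 1..t."""

    def __init__(self, t: int, d_c: int, d_z: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / (d_c + d_z))
        self.t = t
        self.params["W"] = rng.normal(0.0, scale, size=(t, d_c, d_z))
        self.zero_grad()


@dataclass
class PretextConfig:
    """Training regime and architecture of the pretext task."""

    epochs: int = 20
    iterations_per_epoch: int = 1000
    batch_size: int = 32
    positive_fraction: float = 0.5
    hidden: tuple[int, ...] = (256, 128, 128, 128)
    d_z: int = 64
    d_c: int = 64
    steps: int = 4
    lr: float = 1e-3
    seed: int = 0
    eval_pairs: int = 128
    loss: str = "bce"  # "bce" (default objective) or "infonce"


@dataclass
class PretextHistory:
    """Per-epoch training loss and train/test pair accuracies."""

    loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    test_accuracy: list[float] = field(default_factory=list)


class PretextModel:
    def __init__(self, input_length: int, config: PretextConfig | None = None,
                 rng: np.random.Generator | None = None) -> None:
        self.config = config or PretextConfig()
        if rng is None:
            rng = np.random.default_rng(self.config.seed)
        self.encoder = Encoder(input_length, self.config.hidden, self.config.d_z, rng)
        self.gru = GRU(self.config.d_z, self.config.d_c, rng)
        self.predictors = StepPredictors(
            self.config.steps, self.config.d_c, self.config.d_z, rng
        )

    def layers(self) -> list[Layer]:
        return self.encoder.layers() + [self.gru, self.predictors]

    def forward(self, left: np.ndarray, right: np.ndarray, train: bool = True):
        """Pair probabilities for stacked pair blocks.

        ``left``/``right``: ``(B, t, epoch_length)``.  Returns ``(p, cache)``
        with ``p`` of shape ``(B,)``.
        """
        B, T, L = left.shape
        if T != self.config.steps:
            raise ValueError(f"expected {self.config.steps} epochs per block, got {T}")
        x = np.concatenate([left.reshape(B * T, L), right.reshape(B * T, L)], axis=0)
        z, enc_cache = self.encoder.forward(x, train)
        zT = z[: B * T].reshape(B, T, -1)
        zW = z[B * T :].reshape(B, T, -1)
        c, gru_cache = self.gru.forward(zT, train)
        W = self.predictors.params["W"]
        pred = np.einsum("bc,tcz->btz", c, W)  # predicted right-block latents
        scores = (pred * zW).sum(axis=-1)  # (B, T) inner products
        s = scores.mean(axis=1)
        p = sigmoid(s)
        cache = (enc_cache, gru_cache, c, zW, pred, (B, T, L))
        return p, cache

    def backward(self, ds: np.ndarray, cache) -> None:
        """Backpropagate from ``dL/ds`` (gradient w.r.t. the pooled score)."""
        enc_cache, gru_cache, c, zW, pred, (B, T, L) = cache
        W = self.predictors.params["W"]
        dscores = np.repeat(ds[:, None] / T, T, axis=1)  # mean pooling
        dpred = dscores[:, :, None] * zW
        dzW = dscores[:, :, None] * pred
        self.predictors.grads["W"] += np.einsum("bc,btz->tcz", c, dpred)
        dc = np.einsum("btz,tcz->bc", dpred, W)
        dzT = self.gru.backward(dc, gru_cache)
        dz = np.concatenate(
            [dzT.reshape(B * T, -1), dzW.reshape(B * T, -1)], axis=0
        )
        self.encoder.backward(dz, enc_cache)

    def score_matrix(self, left: np.ndarray, right: np.ndarray, train: bool = True):
        """All-pairs score matrix for the InfoNCE objective.

        ``S[i, j]`` scores context ``c_i`` against right-block latents of
        pair ``j``; the diagonal holds the matching pairs.
        """
        B, T, L = left.shape
        x = np.concatenate([left.reshape(B * T, L), right.reshape(B * T, L)], axis=0)
        z, enc_cache = self.encoder.forward(x, train)
        zT = z[: B * T].reshape(B, T, -1)
        zW = z[B * T :].reshape(B, T, -1)
        c, gru_cache = self.gru.forward(zT, train)
        W = self.predictors.params["W"]
        pred = np.einsum("bc,tcz->btz", c, W)
        S = np.einsum("btz,jtz->bj", pred, zW) / T
        cache = (enc_cache, gru_cache, c, zW, pred, (B, T, L))
        return S, cache

    def backward_infonce(self, dS: np.ndarray, cache) -> None:
        enc_cache, gru_cache, c, zW, pred, (B, T, L) = cache
        W = self.predictors.params["W"]
        dpred = np.einsum("bj,jtz->btz", dS, zW) / T
        dzW = np.einsum("bj,btz->jtz", dS, pred) / T
        self.predictors.grads["W"] += np.einsum("bc,btz->tcz", c, dpred)
        dc = np.einsum("btz,tcz->bc", dpred, W)
        dzT = self.gru.backward(dc, gru_cache)
        dz = np.concatenate(
            [dzT.reshape(B * T, -1), dzW.reshape(B * T, -1)], axis=0
        )
        self.encoder.backward(dz, enc_cache)


# -- functional surface ------------------------------------------------------


def encode(epoch: np.ndarray, encoder: Encoder, mode: str = "infer") -> np.ndarray:
    """Latent coding feature(s) ``z`` for one epoch or a stack of epochs."""
    x = np.asarray(epoch, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[None, :]
    z, _ = encoder.forward(x, train=(mode == "train"))
    return z[0] if squeeze else z


def contextualize(z_sequence: np.ndarray, model: PretextModel) -> np.ndarray:
    """GRU context vector after consuming the left-block latents in order."""
    z = np.asarray(z_sequence, dtype=float)
    squeeze = z.ndim == 2
    if squeeze:
        z = z[None, ...]
    if z.shape[1] != model.config.steps:
        raise ValueError(
            f"expected a sequence of {model.config.steps} latents, got {z.shape[1]}"
        )
    c, _ = model.gru.forward(z, train=False)
    return c[0] if squeeze else c


def pair_probability(pair: SamplePair, model: PretextModel, mode: str = "infer") -> float:
    """Probability that ``pair`` is positive, per the trained pretext head."""
    p, _ = model.forward(
        pair.left_block[None, ...], pair.right_block[None, ...], train=(mode == "train")
    )
    return float(p[0])


_EPS = np.finfo(float).eps


def pretext_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy between pair probabilities and pair labels.

    ``L = -(1/N) * sum_i [y_i log p_i + (1 - y_i) log(1 - p_i)]`` with the
    probabilities clipped to machine-epsilon bounds.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} probabilities vs {y.shape} labels")
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("probabilities must lie in [0, 1]")
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())


def _pair_accuracy(model: PretextModel, pairs) -> float:
    left, right, y = batch_arrays(pairs)
    p, _ = model.forward(left, right, train=False)
    return float(((p > 0.5).astype(float) == y).mean())


def train_pretext(
    train: EpochDataset,
    test: EpochDataset,
    config: PretextConfig | None = None,
) -> tuple[PretextModel, PretextHistory]:
    """Train the pretext model on randomly drawn pair batches.

    Runs ``config.epochs`` training epochs of ``config.iterations_per_epoch``
    batches each (defaults 20 x 1000, so every raw epoch recurs across many
    pairs and the task is fully trained), records per-epoch mean loss and
    pair accuracy on fixed train/test evaluation pair sets, and returns the
    model with its history.
    """
    config = config or PretextConfig()
    if len(train) == 0 or len(test) == 0:
        raise ValueError("train and test datasets must be nonempty")
    rng = np.random.default_rng(config.seed)
    model = PretextModel(train.epoch_length, config, rng)
    sample_rng = np.random.default_rng(rng.integers(2**31))
    eval_rng = np.random.default_rng(rng.integers(2**31))
    eval_train = pair_batch(train, config.eval_pairs, config.positive_fraction, eval_rng)
    eval_test = pair_batch(test, config.eval_pairs, config.positive_fraction, eval_rng)
    opt = Adam(model.layers(), lr=config.lr)
    history = PretextHistory()
    infonce = config.loss == "infonce"
    for epoch in range(config.epochs):
        total = 0.0
        for _ in range(config.iterations_per_epoch):
            opt.zero_grad()
            if infonce:
                # all same-class pairs; in-batch rights act as negatives
                pairs = pair_batch(train, config.batch_size, 1.0, sample_rng)
                left, right, _ = batch_arrays(pairs)
                S, cache = model.score_matrix(left, right, train=True)
                P = softmax(S)
                B = S.shape[0]
                loss = float(-np.log(np.clip(np.diag(P), _EPS, None)).mean())
                dS = (P - np.eye(B)) / B
                model.backward_infonce(dS, cache)
            else:
                pairs = pair_batch(
                    train, config.batch_size, config.positive_fraction, sample_rng
                )
                left, right, y = batch_arrays(pairs)
                p, cache = model.forward(left, right, train=True)
                loss = pretext_loss(p, y)
                ds = (p - y) / y.shape[0]  # d(BCE)/d(score) through the sigmoid
                model.backward(ds, cache)
            if not np.isfinite(loss):
                raise TrainingDivergenceError(
                    f"non-finite pretext loss at training epoch {epoch}"
                )
            opt.step()
            total += loss
        history.loss.append(total / config.iterations_per_epoch)
        history.train_accuracy.append(_pair_accuracy(model, eval_train))
        history.test_accuracy.append(_pair_accuracy(model, eval_test))
    return model, history


# -- encoder checkpointing ---------------------------------------------------


def save_encoder(model: PretextModel | Encoder, path, extra_meta: dict | None = None) -> None:
    """Write the encoder weights (and batch-norm statistics) to ``path``.

    The container is a compressed ``.npz`` with a JSON metadata record
    (format version, layer shapes, optional run configuration); the GRU and
    step predictors of the pretext model are deliberately not saved — the
    downstream task reuses only the encoder.
    """
    enc = model.encoder if isinstance(model, PretextModel) else model
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "kind": "encoder",
        "input_length": enc.input_length,
        "hidden": list(enc.hidden),
        "d_z": enc.d_z,
    }
    if extra_meta:
        meta.update(extra_meta)
    state = enc.state_dict()
    np.savez_compressed(path, __meta__=np.array(json.dumps(meta)), **state)


def load_encoder(path) -> Encoder:
    """Reconstruct an :class:`Encoder` saved by :func:`save_encoder`.

    The round trip is lossless: the loaded encoder reproduces bit-identical
    latents on any probe epoch.
    """
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        if meta.get("kind") != "encoder" and "encoder." not in " ".join(npz.files):
            raise IOError(f"{path}: not an encoder checkpoint")
        if meta["format_version"] > CHECKPOINT_FORMAT_VERSION:
            raise IOError(
                f"{path}: unsupported checkpoint format {meta['format_version']}"
            )
        enc = Encoder(
            meta["input_length"], tuple(meta["hidden"]), meta["d_z"],
            rng=np.random.default_rng(0),
        )
        enc.load_state_dict({k: npz[k] for k in npz.files if k != "__meta__"})
    return enc
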