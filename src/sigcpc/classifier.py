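"""Downstream supervised classifier reusing the pretext encoder.

Architecture: each input epoch is replicated four times (so the encoder sees
the same ``[x, x, x, x]`` latent-sequence layout the pretext task trained
on), encoded by the shared-weight encoder into a ``4 x d_z`` latent
sequence, passed through two *different* 1-D convolution layers, globally
average-pooled and classified by a dense softmax head.  Training minimizes
categorical cross-entropy over one-hot targets with Adam; the learning rate
starts at 1e-3 and is cut to 1/3 whenever validation loss fails to improve
for two consecutive epochs (reduce-on-plateau).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data import EpochDataset
from .nn import Adam, Conv1dSeq, Dense, Layer, relu, relu_grad, softmax
from .pretext import CHECKPOINT_FORMAT_VERSION, Encoder, TrainingDivergenceError

__all__ = [
    "ClassifierModel",
    "TrainConfig",
    "PlateauScheduler",
    "replicate_input",
    "build_classifier",
    "train_classifier",
    "predict",
    "save_classifier",
    "load_classifier",
]

#: number of identical copies fed to the encoder per sample
N_REPLICAS = 4


def replicate_input(epoch: np.ndarray) -> np.ndarray:
    """Stack four identical copies of an epoch: ``x -> [x, x, x, x]``.

    Keeps the classifier input dimensionally compatible with the
    pretext-trained encoder, which consumes length-4 epoch blocks.
    """
    x = np.asarray(epoch, dtype=float)
    return np.tile(x[None, :], (N_REPLICAS, 1))


@dataclass
class TrainConfig:
    """Fine-tuning regime of the downstream classifier."""

    initial_lr: float = 1e-3
    plateau_patience: int = 2
    lr_factor: float = 1.0 / 3.0
    min_delta: float = 1e-4  # improvement threshold on validation loss
    min_lr: float = 1e-6
    max_epochs: int = 30
    batch_size: int = 16
    seed: int = 0
    encoder_trainable: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.lr_factor < 1.0:
            raise ValueError(f"lr_factor must lie in (0, 1), got {self.lr_factor}")
        if self.plateau_patience < 1:
            raise ValueError(f"plateau_patience must be >= 1, got {self.plateau_patience}")


class PlateauScheduler:
    """Reduce-on-plateau learning-rate schedule.

    An epoch *improves* when its monitored loss is lower than the best seen
    so far by at least ``min_delta``.  After ``patience`` consecutive
    non-improving epochs the rate is multiplied by ``factor`` (never below
    ``min_lr``) and the wait counter resets.
    """

    def __init__(
        self,
        initial_lr: float = 1e-3,
        factor: float = 1.0 / 3.0,
        patience: int = 2,
        min_delta: float = 1e-4,
        min_lr: float = 1e-6,
    ) -> None:
        self.lr = initial_lr
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.min_lr = min_lr
        self.best = np.inf
        self.wait = 0

    def step(self, monitored_loss: float) -> float:
        """Record one epoch's monitored loss; return the lr for the NEXT epoch."""
        if monitored_loss < self.best - self.min_delta:
            self.best = monitored_loss
            self.wait = 0
        else:
            self.wait += 1
            if self.wait >= self.patience:
                self.lr = max(self.lr * self.factor, self.min_lr)
                self.wait = 0
        return self.lr


class ClassifierModel:
    """Encoder → conv1 → conv2 → global average pool → dense softmax."""

    def __init__(
        self,
        encoder: Encoder,
        n_classes: int,
        conv1: tuple[int, int] = (64, 3),
        conv2: tuple[int, int] = (32, 2),
        rng: np.random.Generator | None = None,
        encoder_trainable: bool = True,
    ) -> None:
        if n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {n_classes}")
        if conv1 == conv2:
            raise ValueError(
                f"the two convolution layers must differ in filters or kernel "
                f"size, both are {conv1}"
            )
        if rng is None:
            rng = np.random.default_rng()
        self.encoder = encoder
        self.n_classes = n_classes
        self.conv_specs = (tuple(conv1), tuple(conv2))
        self.conv1 = Conv1dSeq(encoder.d_z, conv1[0], conv1[1], rng)
        self.conv2 = Conv1dSeq(conv1[0], conv2[0], conv2[1], rng)
        self.head = Dense(conv2[0], n_classes, rng)
        self.encoder_trainable = encoder_trainable
        t_out = N_REPLICAS - conv1[1] + 1 - conv2[1] + 1
        if t_out < 1:
            raise ValueError("convolution kernels too large for the length-4 latent sequence")

    def layers(self) -> list[Layer]:
        own: list[Layer] = [self.conv1, self.conv2, self.head]
        if self.encoder_trainable:
            return self.encoder.layers() + own
        return own

    def parameter_count(self) -> int:
        return sum(p.size for l in self.encoder.layers() + [self.conv1, self.conv2, self.head]
                   for p in l.params.values())

    def forward(self, x: np.ndarray, train: bool = True):
        """Class logits for a batch of raw epochs ``(B, epoch_length)``.

        The four replicas of each epoch are identical, so the encoder runs
        once per epoch and its latent is tiled along the time axis; batch
        statistics are unchanged by duplicating rows, so this is exactly
        equivalent to encoding ``replicate_input(x)`` explicitly.
        """
        z, enc_cache = self.encoder.forward(x, train and self.encoder_trainable)
        seq = np.repeat(z[:, None, :], N_REPLICAS, axis=1)
        a1, c1 = self.conv1.forward(seq, train)
        h1 = relu(a1)
        a2, c2 = self.conv2.forward(h1, train)
        h2 = relu(a2)
        pooled = h2.mean(axis=1)
        logits, c_head = self.head.forward(pooled, train)
        cache = (enc_cache, c1, a1, c2, a2, h2.shape[1], c_head)
        return logits, cache

    def backward(self, dlogits: np.ndarray, cache) -> None:
        enc_cache, c1, a1, c2, a2, t_pool, c_head = cache
        dpool = self.head.backward(dlogits, c_head)
        dh2 = np.repeat(dpool[:, None, :] / t_pool, t_pool, axis=1)
        da2 = relu_grad(dh2, a2)
        dh1 = self.conv2.backward(da2, c2)
        da1 = relu_grad(dh1, a1)
        dseq = self.conv1.backward(da1, c1)
        if self.encoder_trainable:
            dz = dseq.sum(axis=1)
            self.encoder.backward(dz, enc_cache)


def build_classifier(
    encoder: Encoder,
    n_classes: int,
    conv1: tuple[int, int] = (64, 3),
    conv2: tuple[int, int] = (32, 2),
    seed: int = 0,
    encoder_trainable: bool = True,
) -> ClassifierModel:
    """Assemble the downstream model around a (pretrained or fresh) encoder."""
    rng = np.random.default_rng(seed)
    return ClassifierModel(encoder, n_classes, conv1, conv2, rng, encoder_trainable)


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    eye = np.eye(n_classes)
    return eye[labels]


def _ce_loss(logits: np.ndarray, y_onehot: np.ndarray) -> float:
    p = softmax(logits)
    p = np.clip(p, np.finfo(float).eps, None)
    return float(-(y_onehot * np.log(p)).sum(axis=1).mean())


def train_classifier(
    model: ClassifierModel,
    train: EpochDataset,
    validation: EpochDataset,
    config: TrainConfig | None = None,
) -> tuple[ClassifierModel, dict[str, list[float]]]:
    """Fine-tune the classifier with the reduce-on-plateau schedule.

    Returns the trained model and a history dict with per-epoch train loss,
    validation loss, validation accuracy and the learning rate that was in
    effect during each epoch.
    """
    config = config or TrainConfig()
    if len(train) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    model.encoder_trainable = config.encoder_trainable
    opt = Adam(model.layers(), lr=config.initial_lr)
    sched = PlateauScheduler(
        config.initial_lr, config.lr_factor, config.plateau_patience,
        config.min_delta, config.min_lr,
    )
    n_classes = model.n_classes
    y_train = _one_hot(train.labels, n_classes)
    history: dict[str, list[float]] = {
        "train_loss": [], "val_loss": [], "val_accuracy": [], "lr": [],
    }
    n = len(train)
    for epoch in range(config.max_epochs):
        opt.lr = sched.lr
        order = rng.permutation(n)
        total, batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = train.epochs[idx], y_train[idx]
            opt.zero_grad()
            logits, cache = model.forward(xb, train=True)
            loss = _ce_loss(logits, yb)
            if not np.isfinite(loss):
                raise TrainingDivergenceError(
                    f"non-finite classifier loss at training epoch {epoch}"
                )
            dlogits = (softmax(logits) - yb) / yb.shape[0]
            model.backward(dlogits, cache)
            opt.step()
            total += loss
            batches += 1
        val_logits, _ = model.forward(validation.epochs, train=False)
        val_loss = _ce_loss(val_logits, _one_hot(validation.labels, n_classes))
        val_acc = float((val_logits.argmax(axis=1) == validation.labels).mean())
        history["train_loss"].append(total / max(batches, 1))
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)
        history["lr"].append(sched.lr)
        sched.step(val_loss)
    return model, history


def predict(model: ClassifierModel, epochs: EpochDataset) -> tuple[np.ndarray, np.ndarray]:
    """Argmax class ids plus the full softmax probability matrix."""
    logits, _ = model.forward(epochs.epochs, train=False)
    probs = softmax(logits)
    return probs.argmax(axis=1), probs


# -- checkpointing -----------------------------------------------------------


def save_classifier(model: ClassifierModel, path, extra_meta: dict | None = None) -> None:
    """Full classifier checkpoint (same container family as encoder files)."""
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "kind": "classifier",
        "input_length": model.encoder.input_length,
        "hidden": list(model.encoder.hidden),
        "d_z": model.encoder.d_z,
        "n_classes": model.n_classes,
        "conv1": list(model.conv_specs[0]),
        "conv2": list(model.conv_specs[1]),
    }
    if extra_meta:
        meta.update(extra_meta)
    state = {f"encoder.{k}": v for k, v in model.encoder.state_dict().items()}
    state["conv1.W"] = model.conv1.params["W"]
    state["conv1.b"] = model.conv1.params["b"]
    state["conv2.W"] = model.conv2.params["W"]
    state["conv2.b"] = model.conv2.params["b"]
    state["head.W"] = model.head.params["W"]
    state["head.b"] = model.head.params["b"]
    np.savez_compressed(path, __meta__=np.array(json.dumps(meta)), **state)


def load_classifier(path) -> ClassifierModel:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        if meta.get("kind") != "classifier":
            raise IOError(f"{path}: not a classifier checkpoint")
        enc = Encoder(
            meta["input_length"], tuple(meta["hidden"]), meta["d_z"],
            rng=np.random.default_rng(0),
        )
        enc.load_state_dict(
            {k[len("encoder."):]: npz[k] for k in npz.files if k.startswith("encoder.")}
        )
        model = build_classifier(
            enc, meta["n_classes"], tuple(meta["conv1"]), tuple(meta["conv2"])
        )
        model.conv1.params["W"] = np.array(npz["conv1.W"])
        model.conv1.params["b"] = np.array(npz["conv1.b"])
        model.conv2.params["W"] = np.array(npz["conv2.W"])
        model.conv2.params["b"] = np.array(npz["conv2.b"])
        model.head.params["W"] = np.array(npz["head.W"])
        model.head.params["b"] = np.array(npz["head.b"])
    return model
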