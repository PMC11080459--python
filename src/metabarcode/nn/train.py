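"""Training protocol and evaluation.

The study protocol: stratified 70/30 train/validation split, 160 epochs,
dropout 0.2, two-class softmax cross-entropy.  Optimizer details are not part
of the protocol and default to Adam (lr 1e-3, batch 32).  All randomness
(split, initialization, batch order, dropout masks) is driven by explicit
seeds, so runs are bit-reproducible single-threaded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..datasets import LabeledDataset
from .model import CNN1D

__all__ = ["TrainConfig", "TrainingDiverged", "EvalReport", "split_dataset",
           "train", "evaluate", "softmax_cross_entropy"]


@dataclass(frozen=True)
class TrainConfig:
    split: float = 0.7
    epochs: int = 160
    dropout: float = 0.2
    seed: int = 0
    lr: float = 1e-3
    batch_size: int = 32
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.split < 1.0:
            raise ValueError("split must lie in (0, 1)")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


class TrainingDiverged(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclass
class EvalReport:
    """confusion[p, a]: rows = predicted class, columns = actual class."""

    confusion: np.ndarray
    accuracy: float

    @property
    def n_items(self) -> int:
        return int(self.confusion.sum())

    def to_dict(self) -> dict:
        return {"confusion": self.confusion.tolist(),
                "accuracy": self.accuracy, "n_items": self.n_items}


def split_dataset(ds: LabeledDataset, fraction: float = 0.7,
                  seed: int = 0) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified split: floor(fraction * n_class) training items per class."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for cls in np.unique(ds.y):
        idx = np.flatnonzero(ds.y == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 items")
        idx = rng.permutation(idx)
        n_train = int(np.floor(fraction * len(idx)))
        train_idx.append(idx[:n_train])
        val_idx.append(idx[n_train:])
    train_idx = np.sort(np.concatenate(train_idx))
    val_idx = np.sort(np.concatenate(val_idx))
    return ds.subset(train_idx), ds.subset(val_idx)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and gradient w.r.t. logits."""
    z = logits.astype(np.float64)
    z -= z.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = len(y)
    loss = float(-np.mean(np.log(p[np.arange(n), y] + 1e-300)))
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


class Adam:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 cfg: TrainConfig):
        self.params, self.grads, self.cfg = params, grads, cfg
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.beta1 ** self.t
        bc2 = 1.0 - c.beta2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= c.beta1
            m += (1.0 - c.beta1) * g
            v *= c.beta2
            v += (1.0 - c.beta2) * g * g
            p -= c.lr * (m / bc1) / (np.sqrt(v / bc2) + c.eps)


def _to_input(X: np.ndarray, model: CNN1D) -> np.ndarray:
    """Arrange dataset items for the model's input layout."""
    if model.spec.arrangement == "concat":
        return X.reshape(len(X), 1, -1)
    return X


def train(model: CNN1D, train_set: LabeledDataset | tuple[np.ndarray, np.ndarray],
          config: TrainConfig) -> dict:
    """Train in place for exactly ``config.epochs`` epochs; returns a log.

    Dropout is active only here (training mode).  Raises
    :class:`TrainingDiverged` with the epoch index on non-finite loss.
    """
    if isinstance(train_set, LabeledDataset):
        X, y = train_set.X, train_set.y
    else:
        X, y = train_set
    if len(y) == 0:
        raise ValueError("training set is empty")
    X = _to_input(np.asarray(X, dtype=np.float32), model)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), model.grads(), config)
    log = {"epoch_loss": [], "epoch_acc": []}
    n = len(y)
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        losses, correct = [], 0
        for lo in range(0, n, config.batch_size):
            sel = perm[lo:lo + config.batch_size]
            xb, yb = X[sel], y[sel]
            logits = model.forward(xb, train=True, rng=rng)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise TrainingDiverged(epoch)
            model.backward(dlogits, need_input_grad=False)
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == yb).sum())
        log["epoch_loss"].append(float(np.mean(losses)))
        log["epoch_acc"].append(correct / n)
    return log


def evaluate(model: CNN1D,
             val_set: LabeledDataset | tuple[np.ndarray, np.ndarray]
             ) -> EvalReport:
    """Confusion matrix (rows predicted, columns actual) and accuracy."""
    if isinstance(val_set, LabeledDataset):
        X, y = val_set.X, val_set.y
    else:
        X, y = val_set
    if len(y) == 0:
        raise ValueError("validation set is empty")
    pred = model.predict(_to_input(np.asarray(X, dtype=np.float32), model))
    confusion = np.zeros((2, 2), dtype=np.int64)
    for p, a in zip(pred, y):
        confusion[p, a] += 1
    return EvalReport(confusion=confusion,
                      accuracy=float(np.trace(confusion) / confusion.sum()))
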