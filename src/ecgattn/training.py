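"""Training protocol: Adam, categorical cross-entropy, checkpoint selection.

Mini-batch gradient descent with the Adam optimizer (β1 = 0.9, β2 = 0.999,
fixed learning rate 0.001), batch size 32, 30 epochs by default.  No early
stopping, no learning-rate schedule, and no class re-weighting: the network
trains on the natural (imbalanced) class distribution.  The retained
checkpoint is the epoch with the best validation accuracy, ties broken by
lowest validation loss, then earliest epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .model import Model
from .nn import Adam, cross_entropy
from .preprocessing import SegmentDataset, one_hot

logger = logging.getLogger(__name__)


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 0.001
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class History:
    """Per-epoch training/validation loss and accuracy."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


def evaluate_dataset(model: Model, ds: SegmentDataset, batch_size: int = 256
                     ) -> tuple[float, float]:
    """(mean cross-entropy loss, accuracy) of ``model`` on ``ds``."""
    n = len(ds)
    losses, correct = 0.0, 0
    onehot = one_hot(ds.y, model.cfg.n_classes)
    for i in range(0, n, batch_size):
        probs = model.forward(ds.X[i : i + batch_size])
        losses += cross_entropy(probs, onehot[i : i + batch_size]) * len(probs)
        correct += int((probs.argmax(axis=1) == ds.y[i : i + batch_size]).sum())
    return losses / n, correct / n


def train(model: Model, train_ds: SegmentDataset, val_ds: SegmentDataset,
          cfg: TrainConfig) -> tuple[Model, History]:
    """Train ``model`` in place and return it with its History.

    Batch order is reshuffled every epoch from the run seed.  The weights of
    the best epoch (by :func:`select_checkpoint`'s rule) are restored into the
    model before returning.  With ``epochs=0`` the weights are untouched and
    the History is empty.
    """
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise TrainingError("training and validation datasets must be non-empty")
    if train_ds.y.max(initial=0) >= model.cfg.n_classes:
        raise TrainingError("label arity exceeds the model's class head")
    history = History()
    if cfg.epochs == 0:
        return model, history

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.layers, lr=cfg.learning_rate,
               beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
    n = len(train_ds)
    onehot = one_hot(train_ds.y, model.cfg.n_classes)
    best_weights = model.get_weights()
    best_epoch = -1
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb, yb = train_ds.X[idx], onehot[idx]
            probs = model.forward(xb)
            loss = cross_entropy(probs, yb)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"NaN/inf loss at epoch {epoch + 1}, batch {i // cfg.batch_size}: "
                    f"learning_rate={cfg.learning_rate}, batch max |x|="
                    f"{float(np.abs(xb).max()):.3g}"
                )
            ep_loss += loss * len(idx)
            ep_correct += int((probs.argmax(axis=1) == train_ds.y[idx]).sum())
            model.backward((probs - yb) / len(idx))
            opt.step()
        val_loss, val_acc = evaluate_dataset(model, val_ds)
        history.train_loss.append(ep_loss / n)
        history.train_accuracy.append(ep_correct / n)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        logger.info(
            "epoch %d/%d: loss %.4f acc %.4f | val loss %.4f val acc %.4f",
            epoch + 1, cfg.epochs, history.train_loss[-1],
            history.train_accuracy[-1], val_loss, val_acc,
        )
        if select_checkpoint(history) == epoch:
            best_weights = model.get_weights()
            best_epoch = epoch
    if best_epoch != cfg.epochs - 1:
        model.set_weights(best_weights)
    return model, history


def select_checkpoint(history: History) -> int:
    """Index of the best epoch: maximum validation accuracy, ties broken by
    minimum validation loss, then earliest epoch.  Pure function of History."""
    if len(history) == 0:
        raise TrainingError("cannot select a checkpoint from an empty history")
    order = sorted(
        range(len(history)),
        key=lambda e: (-history.val_accuracy[e], history.val_loss[e], e),
    )
    return order[0]
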