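"""Training loop: Adam, mini-batches, early stopping on validation loss.

Defaults honor the study protocol — Adam with batch size 3 and learning
rate 1e-6, at most 50 epochs (30 for the count task), stopping after 10
epochs without validation improvement and restoring the best-validation
weights. Scaled desk runs raise the learning rate and batch size; both are
plain configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Conv3DClassifier


@dataclass
class TrainConfig:
    batch_size: int = 3
    learning_rate: float = 1e-6
    max_epochs: int = 50
    patience: int = 10
    seed: int = 0
    monitor: str = "val_loss"

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


class Adam:
    """Adam optimizer over a model's layer parameter dictionaries."""

    def __init__(
        self,
        model: Conv3DClassifier,
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in layer.params.items()}
            for _, layer in model.layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in layer.params.items()}
            for _, layer in model.layers
        ]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, (_, layer) in enumerate(self.model.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                self.m[i][k] = self.beta1 * self.m[i][k] + (1 - self.beta1) * g
                self.v[i][k] = self.beta2 * self.v[i][k] + (1 - self.beta2) * g**2
                mhat = self.m[i][k] / b1t
                vhat = self.v[i][k] / b2t
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _epoch_loss(
    model: Conv3DClassifier, x: np.ndarray, y: np.ndarray, batch_size: int
) -> tuple[float, float]:
    """Mean loss and accuracy without touching gradients."""
    from .layers import cross_entropy

    losses, correct = [], 0
    for i in range(0, len(x), batch_size):
        logits = model.forward(x[i : i + batch_size])
        loss, _ = cross_entropy(logits, y[i : i + batch_size])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[i : i + batch_size]).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train(
    model: Conv3DClassifier,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
) -> dict:
    """Train in place; returns the per-epoch history.

    The model is left holding the weights of the best-validation epoch.
    Raises on empty splits and aborts on non-finite loss.
    """
    x_tr, y_tr = train_set
    x_va, y_va = val_set
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("empty train or validation split")
    y_tr = np.asarray(y_tr, dtype=int)
    y_va = np.asarray(y_va, dtype=int)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model, lr=cfg.learning_rate)
    history: dict[str, list] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []
    }
    best_loss = np.inf
    best_weights = model.get_weights()
    epochs_since_best = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_tr))
        batch_losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            loss = model.loss_and_grad(x_tr[idx], y_tr[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch "
                    f"{i // cfg.batch_size}: {loss}"
                )
            opt.step()
            batch_losses.append(loss * len(idx))
        tr_loss = float(np.sum(batch_losses) / len(x_tr))
        _, tr_acc = _epoch_loss(model, x_tr, y_tr, max(cfg.batch_size, 16))
        va_loss, va_acc = _epoch_loss(model, x_va, y_va, max(cfg.batch_size, 16))
        history["train_loss"].append(tr_loss)
        history["train_acc"].append(tr_acc)
        history["val_loss"].append(va_loss)
        history["val_acc"].append(va_acc)
        if va_loss < best_loss:
            best_loss = va_loss
            best_weights = model.get_weights()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            # stop once `patience` consecutive epochs lack improvement
            # (patience 0: halt at the first non-improving epoch)
            if epochs_since_best >= max(1, cfg.patience):
                break
    model.set_weights(best_weights)
    history["best_val_loss"] = best_loss
    return history


def predict(
    model: Conv3DClassifier, voxels: np.ndarray, batch_size: int = 32
) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels for a voxel batch."""
    probs = model.predict_proba(np.asarray(voxels), batch_size=batch_size)
    return probs, probs.argmax(axis=1)
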