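"""Training loop: Adam with Nesterov momentum on the combined BCE+Dice loss.

The loss is applied to the softmax class-probability vector of each sample
against its one-hot label, averaged over the batch.  Initialization, batch
order and dropout are all driven by the training seed, so runs are exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .losses import combined_loss, combined_loss_grad
from .model import DualEncoderAttentionUNet, ModelBundle

__all__ = ["TrainConfig", "Nadam", "train_model"]


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    epochs: int = 10
    batch_size: int = 32
    seed: int = 0
    val_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("learning_rate, epochs and batch_size must be positive")


class Nadam:
    """Adam with Nesterov momentum (Dozat's incorporation)."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for k, p in params.items():
            g = grads[k]
            m = self.m.setdefault(k, np.zeros_like(p))
            v = self.v.setdefault(k, np.zeros_like(p))
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            # Nesterov look-ahead on the first moment
            update = b1 * m_hat + (1 - b1) * g / (1 - b1**self.t)
            p -= self.lr * update / (np.sqrt(v_hat) + self.eps)


def _one_hot(labels: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((labels.size, k))
    out[np.arange(labels.size), labels] = 1.0
    return out


def train_model(
    bundle: ModelBundle,
    images: np.ndarray,
    labels: np.ndarray,
    tcfg: TrainConfig,
    val_images: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
) -> ModelBundle:
    """Train a model bundle in place and return it with an updated log.

    ``images`` is ``(N, H, W)`` or ``(N, H, W, C)`` and ``labels`` integer
    class indices.  When no validation split is passed, ``val_fraction`` of
    the data (seed-shuffled) is held out.  Each log row records epoch,
    train/val loss and accuracy.  A non-finite loss aborts with a
    diagnostic.
    """
    images = np.asarray(images, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if images.shape[0] == 0:
        raise ValueError("empty training data")
    if labels.min() < 0 or labels.max() >= bundle.config.n_classes:
        raise ValueError("labels out of range")
    rng = np.random.default_rng(tcfg.seed)
    if val_images is None:
        order = rng.permutation(images.shape[0])
        n_val = int(round(tcfg.val_fraction * images.shape[0]))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        val_images, val_labels = images[val_idx], labels[val_idx]
        images, labels = images[tr_idx], labels[tr_idx]

    net = DualEncoderAttentionUNet(bundle.config, seed=bundle.seed)
    net.load_parameters(bundle.parameters)
    opt = Nadam(lr=tcfg.learning_rate)
    k = bundle.config.n_classes
    v = bundle.config.loss_weight_v

    def batch_loss_and_grad(probs: np.ndarray, onehot: np.ndarray):
        B = probs.shape[0]
        loss = 0.0
        dprobs = np.zeros_like(probs)
        for b in range(B):
            loss += combined_loss(probs[b], onehot[b], v)
            dprobs[b] = combined_loss_grad(probs[b], onehot[b], v)
        loss /= B
        dprobs /= B
        # backprop through the softmax
        dlogits = probs * (dprobs - np.sum(dprobs * probs, axis=1, keepdims=True))
        return loss, dlogits

    def evaluate(x: np.ndarray, y: np.ndarray):
        if x.shape[0] == 0:
            return float("nan"), float("nan")
        probs = net.forward(x, train=False)
        onehot = _one_hot(y, k)
        loss = float(np.mean([combined_loss(probs[b], onehot[b], v) for b in range(x.shape[0])]))
        acc = float(np.mean(probs.argmax(axis=1) == y))
        return loss, acc

    n = images.shape[0]
    for epoch in range(1, tcfg.epochs + 1):
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            xb, yb = images[idx], labels[idx]
            net.zero_grad()
            probs = net.forward(xb, train=True)
            loss, dlogits = batch_loss_and_grad(probs, _one_hot(yb, k))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss {loss} at epoch {epoch}, batch starting {start}"
                )
            net.backward(dlogits)
            opt.step(net.parameters(), net.gradients())
            ep_loss += loss * len(idx)
            ep_correct += int(np.sum(probs.argmax(axis=1) == yb))
        val_loss, val_acc = evaluate(val_images, val_labels)
        bundle.training_log.append(
            {
                "epoch": epoch,
                "train_loss": ep_loss / n,
                "train_acc": ep_correct / n,
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
        )
    bundle.parameters = net.parameters()
    return bundle
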