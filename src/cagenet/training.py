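"""Training protocol: class-weighted cross-entropy, SGD, LR-on-plateau,
early stopping, and multi-seed runs."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .architectures import DualStreamModel
from .nn.engine import Tensor
from .video_io import DatasetSplit

__all__ = [
    "TrainingConfig", "compute_class_weights", "weighted_cross_entropy",
    "train", "SGD",
]


@dataclass
class TrainingConfig:
    epochs: int = 85
    batch_size: int = 8
    learning_rate: float = 0.001
    momentum: float = 0.9
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    early_stop_patience: int = 12
    min_delta: float = 1e-4
    seeds: tuple = (0, 1, 2, 3)
    class_weights: np.ndarray | None = None

    def __post_init__(self):
        if not 0 < self.plateau_factor < 1:
            raise ValueError("plateau_factor must be in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def compute_class_weights(class_counts) -> np.ndarray:
    """Inverse-frequency weights w_k = N / (K * n_k) (mean-one normalized)."""
    counts = np.asarray(class_counts, dtype=np.float64)
    for k, c in enumerate(counts):
        if c <= 0:
            raise ValueError(f"class {k} has zero samples")
    return counts.sum() / (len(counts) * counts)


def weighted_cross_entropy(probs, label, weights) -> float:
    """-w_label * log(probs[label]) for one predicted distribution."""
    probs = np.asarray(probs, dtype=np.float64)
    if abs(probs.sum() - 1.0) > 1e-5:
        raise ValueError("probabilities must sum to 1")
    weights = np.asarray(weights, dtype=np.float64)
    return float(-weights[label] * np.log(max(probs[label], 1e-300)))


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, lr, momentum=0.9):
        self.params = [p for p in params]
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros(p.shape, dtype=np.float32) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            g = p.tensor.grad
            if g is None:
                continue
            v *= self.momentum
            v -= self.lr * g
            p.tensor.data += v

    def zero_grad(self):
        for p in self.params:
            p.tensor.grad = None


def _loss_and_probs(model, xr, xf, y, weights):
    """Mean class-weighted cross-entropy from logits (log-sum-exp form)."""
    logits = model.forward(Tensor(xr), Tensor(xf), train=True)
    zmax = Tensor(logits.data.max(axis=-1, keepdims=True))
    z = logits - zmax
    lse = z.exp().sum(axis=-1, keepdims=True).log()
    logp = z - lse
    n, k = logits.shape
    onehot = np.zeros((n, k), dtype=np.float32)
    onehot[np.arange(n), y] = weights[y]
    loss = (logp * Tensor(-onehot)).sum() * (1.0 / n)
    with np.errstate(over="ignore"):
        probs = np.exp(logp.data)
    return loss, probs


def _arrays(cuboids):
    xr = np.stack([c.data for c in cuboids])
    xf = np.stack([np.zeros_like(c.data) if c.flow is None else c.flow
                   for c in cuboids])
    y = np.array([c.label for c in cuboids], dtype=int)
    return xr, xf, y


def _eval_pass(model, xr, xf, y, weights, batch_size):
    tot, correct, n = 0.0, 0, len(y)
    for i in range(0, n, batch_size):
        sl = slice(i, i + batch_size)
        probs = model.predict_proba(xr[sl], xf[sl])
        p = np.clip(probs[np.arange(len(y[sl])), y[sl]], 1e-12, None)
        tot += float(-(weights[y[sl]] * np.log(p)).sum())
        correct += int((probs.argmax(axis=1) == y[sl]).sum())
    return tot / n, correct / n


def train(model: DualStreamModel, split: DatasetSplit, cfg: TrainingConfig,
          seed: int = 0, target_train_acc: float | None = None):
    """Run the training protocol; returns (history, best_state).

    The learning rate is halved whenever validation loss fails to improve for
    ``plateau_patience`` epochs; training stops early after
    ``early_stop_patience`` epochs without improvement, restoring the best
    checkpoint. Fully deterministic given (cfg, seed).
    """
    if not split.train:
        raise ValueError("training split is empty")
    model.initialize(seed)
    xr, xf, y = _arrays(split.train)
    has_val = bool(split.validation)
    if has_val:
        vxr, vxf, vy = _arrays(split.validation)
    weights = (np.ones(split.num_classes) if cfg.class_weights is None
               else np.asarray(cfg.class_weights)).astype(np.float32)
    opt = SGD(model.parameters(), cfg.learning_rate, cfg.momentum)
    rng = np.random.default_rng(seed * 9973 + 17)
    history = {k: [] for k in ("train_loss", "train_acc", "val_loss",
                               "val_acc", "lr")}
    best = np.inf
    best_state = model.state()
    wait = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(y))
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            opt.zero_grad()
            loss, probs = _loss_and_probs(model, xr[idx], xf[idx], y[idx], weights)
            loss.backward()
            opt.step()
            ep_loss += float(loss.data) * len(idx)
            ep_correct += int((probs.argmax(axis=1) == y[idx]).sum())
        history["train_loss"].append(ep_loss / len(y))
        history["train_acc"].append(ep_correct / len(y))
        history["lr"].append(opt.lr)
        if has_val:
            vloss, vacc = _eval_pass(model, vxr, vxf, vy, weights, cfg.batch_size)
        else:
            vloss, vacc = history["train_loss"][-1], history["train_acc"][-1]
        history["val_loss"].append(vloss)
        history["val_acc"].append(vacc)
        if vloss < best - cfg.min_delta:
            best = vloss
            best_state = model.state()
            wait = 0
        else:
            wait += 1
            if wait > 0 and wait % cfg.plateau_patience == 0:
                opt.lr *= cfg.plateau_factor
            if wait >= cfg.early_stop_patience:
                break
        if (target_train_acc is not None
                and history["train_acc"][-1] >= target_train_acc):
            best_state = model.state()
            break
    model.load_state(best_state)
    return history, best_state
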