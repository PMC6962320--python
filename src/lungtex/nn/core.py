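"""Loss, optimizer and the shared training procedure.

All seven networks are trained the same way: Adam on the L2-regularized
categorical cross-entropy, mini-batches with per-epoch shuffling, and
early stopping that restores the parameters of the best-validation epoch
once the validation loss has not improved for ``patience`` epochs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .layers import BatchNorm, Layer


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, stabilized by max subtraction."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_loss(probs: np.ndarray, labels: np.ndarray,
                       eps: float = 1e-12) -> float:
    """Mean negative log-probability of the true class.

    ``labels`` are integer class indices in 0..n_classes-1.
    """
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= probs.shape[1]:
        raise ValueError(
            f"labels must lie in 0..{probs.shape[1] - 1}, got range "
            f"[{labels.min()}, {labels.max()}]")
    p = probs[np.arange(len(labels)), labels]
    return float(-np.log(np.clip(p, eps, None)).mean())


def l2_penalty(layers: Sequence[Layer], l2_strength: float) -> float:
    """(lambda/2) * sum of squared weights; biases and batch-norm
    gamma/beta are excluded."""
    if l2_strength == 0.0:
        return 0.0
    total = 0.0
    for lyr in layers:
        for key in lyr.weight_keys:
            total += float(np.sum(lyr.params[key] ** 2))
    return 0.5 * l2_strength * total


@dataclass
class TrainConfig:
    """Shared training hyper-parameters (defaults are the tuned values
    used for every network of the ensemble)."""

    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    l2_strength: float = 0.0025
    dropout_p: float = 0.5
    batch_size: int = 128
    patience: int = 30
    max_epochs: int = 300
    rng_seed: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


class Adam:
    """Adam over the parameters of a list of layers."""

    def __init__(self, layers: Sequence[Layer], cfg: TrainConfig):
        self.layers = list(layers)
        self.cfg = cfg
        self.t = 0
        self.m: Dict[Tuple[int, str], np.ndarray] = {}
        self.v: Dict[Tuple[int, str], np.ndarray] = {}
        for i, lyr in enumerate(self.layers):
            for key, p in lyr.params.items():
                self.m[(i, key)] = np.zeros_like(p)
                self.v[(i, key)] = np.zeros_like(p)

    def step(self):
        c = self.cfg
        self.t += 1
        bc1 = 1 - c.beta1 ** self.t
        bc2 = 1 - c.beta2 ** self.t
        for i, lyr in enumerate(self.layers):
            for key, p in lyr.params.items():
                g = lyr.grads[key]
                if key in lyr.weight_keys and c.l2_strength:
                    g = g + c.l2_strength * p
                m = self.m[(i, key)] = (c.beta1 * self.m[(i, key)]
                                        + (1 - c.beta1) * g)
                v = self.v[(i, key)] = (c.beta2 * self.v[(i, key)]
                                        + (1 - c.beta2) * g * g)
                p -= c.learning_rate * (m / bc1) / (np.sqrt(v / bc2) + c.eps)


@dataclass
class TrainedState:
    """Outcome of one training run: restored best parameters live on the
    network itself; this records the log and stopping bookkeeping."""

    training_log: List[dict] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0
    best_val_loss: float = float("inf")


def _snapshot(layers: Sequence[Layer]) -> list:
    snap = []
    for lyr in layers:
        entry = {k: v.copy() for k, v in lyr.params.items()}
        if isinstance(lyr, BatchNorm):
            entry["__running_mean"] = lyr.running_mean.copy()
            entry["__running_var"] = lyr.running_var.copy()
        snap.append(entry)
    return snap


def _restore(layers: Sequence[Layer], snap: list) -> None:
    for lyr, entry in zip(layers, snap):
        for k in lyr.params:
            lyr.params[k][...] = entry[k]
        if isinstance(lyr, BatchNorm):
            lyr.running_mean[...] = entry["__running_mean"]
            lyr.running_var[...] = entry["__running_var"]


def train_network(net, train_inputs, train_labels, val_inputs, val_labels,
                  cfg: TrainConfig) -> TrainedState:
    """Train a network (any object with ``forward_logits``,
    ``backward_from_logits`` and ``param_layers``) with early stopping.

    ``train_inputs``/``val_inputs`` are tuples of arrays whose first axis
    indexes samples (multi-input architectures take more than one array).
    The network is left holding the parameters of the best-validation
    epoch. Raises ``ValueError`` on an empty validation set.
    """
    train_labels = np.asarray(train_labels)
    val_labels = np.asarray(val_labels)
    if len(val_labels) == 0:
        raise ValueError("validation set must not be empty")
    n = len(train_labels)
    if n == 0:
        raise ValueError("training set must not be empty")
    layers = net.param_layers()
    opt = Adam(layers, cfg)
    rng = np.random.default_rng(cfg.rng_seed)
    state = TrainedState()
    best_snap = _snapshot(layers)
    bad_epochs = 0

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = tuple(a[idx] for a in train_inputs)
            yb = train_labels[idx]
            logits = net.forward_logits(xb, training=True, rng=rng)
            probs = softmax(logits)
            loss = (cross_entropy_loss(probs, yb)
                    + l2_penalty(layers, cfg.l2_strength))
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(yb)), yb] = 1.0
            net.backward_from_logits((probs - onehot) / len(yb))
            opt.step()
            epoch_loss += loss
            n_batches += 1
        val_probs = evaluate_in_batches(net, val_inputs, cfg.batch_size)
        val_loss = (cross_entropy_loss(val_probs, val_labels)
                    + l2_penalty(layers, cfg.l2_strength))
        val_acc = float((val_probs.argmax(axis=1) == val_labels).mean())
        state.training_log.append({
            "epoch": epoch,
            "train_loss": epoch_loss / max(n_batches, 1),
            "val_loss": val_loss,
            "val_acc": val_acc,
        })
        if val_loss < state.best_val_loss:
            state.best_val_loss = val_loss
            state.best_epoch = epoch
            best_snap = _snapshot(layers)
            bad_epochs = 0
        else:
            bad_epochs += 1
        state.stopped_epoch = epoch
        # patience = number of non-improving epochs tolerated; patience 0
        # stops at the first epoch without improvement
        if bad_epochs >= max(cfg.patience, 1):
            break
    _restore(layers, best_snap)
    return state


def evaluate_in_batches(net, inputs, batch_size: int = 128) -> np.ndarray:
    """Inference-mode class probabilities for a (possibly large) input set."""
    n = len(inputs[0])
    out = []
    for start in range(0, n, batch_size):
        xb = tuple(a[start:start + batch_size] for a in inputs)
        out.append(softmax(net.forward_logits(xb, training=False, rng=None)))
    return np.concatenate(out, axis=0) if out else np.zeros((0, 0))
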