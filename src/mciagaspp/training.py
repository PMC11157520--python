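"""Deterministic training loop for the volumetric classifier.

Regime: mini-batches of 8, Adam at base learning rate 1e-3, decayed by
a factor 0.1 every 10 epochs, 50 epochs, two-class cross-entropy on the
logits.  A subject-level validation portion is carved out of the
training cohort, the checkpoint with the best validation accuracy is
kept, and every stochastic component (shuffling, validation split)
draws from streams derived from the config seed, so identical runs
produce identical histories.
"""

from __future__ import annotations

import copy
import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import autodiff as ad
from .architecture import MCIDetector
from .data_io import Cohort

__all__ = [
    "TrainConfig",
    "History",
    "lr_schedule",
    "train",
    "make_optimizer",
    "SGD",
    "Momentum",
    "RMSProp",
    "Adam",
]


@dataclasses.dataclass
class TrainConfig:
    batch_size: int = 8
    optimizer: str = "adam"
    base_lr: float = 0.001
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 10
    epochs: int = 50
    seed: int = 0
    val_fraction: float = 0.2

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 < self.lr_decay_factor <= 1.0:
            raise ValueError("lr_decay_factor must be in (0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")
        if self.optimizer not in ("adam", "sgd", "momentum", "rmsprop"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Step decay: base_lr * decay_factor ** floor(epoch / decay_every)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return cfg.base_lr * cfg.lr_decay_factor ** (epoch // cfg.lr_decay_every)


# --------------------------------------------------------------------------
# optimizers
# --------------------------------------------------------------------------

class _Optimizer:
    def __init__(self, params, lr: float):
        self.params = list(params)
        self.lr = lr

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):  # pragma: no cover - abstract
        raise NotImplementedError


class SGD(_Optimizer):
    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad


class Momentum(_Optimizer):
    def __init__(self, params, lr, momentum: float = 0.9):
        super().__init__(params, lr)
        self.momentum = momentum
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.v):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v


class RMSProp(_Optimizer):
    def __init__(self, params, lr, rho: float = 0.9, eps: float = 1e-8):
        super().__init__(params, lr)
        self.rho, self.eps = rho, eps
        self.s = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, s in zip(self.params, self.s):
            if p.grad is None:
                continue
            s *= self.rho
            s += (1 - self.rho) * p.grad ** 2
            p.data -= self.lr * p.grad / (np.sqrt(s) + self.eps)


class Adam(_Optimizer):
    def __init__(self, params, lr, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1c = 1 - self.beta1 ** self.t
        b2c = 1 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad ** 2
            p.data -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


_OPTIMIZERS = {"adam": Adam, "sgd": SGD, "momentum": Momentum, "rmsprop": RMSProp}


def make_optimizer(name: str, params, lr: float) -> _Optimizer:
    return _OPTIMIZERS[name](params, lr)


# --------------------------------------------------------------------------
# history
# --------------------------------------------------------------------------

@dataclasses.dataclass
class History:
    """Per-epoch training log."""

    rows: list[dict] = dataclasses.field(default_factory=list)

    def append(self, **row):
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["epoch", "lr", "train_loss", "train_acc", "val_loss", "val_acc"],
        )

    def write_tsv(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def _load_arrays(cohort: Cohort) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    vols = cohort.load_volumes()
    X = np.stack([v.voxels for v in vols])[:, None].astype(np.float32)
    y = np.array([v.label for v in vols], dtype=np.intp)
    subjects = np.array([v.subject_id for v in vols])
    return X, y, subjects


def _val_subjects(cohort: Cohort, fraction: float, rng: np.random.Generator) -> set[str]:
    if fraction <= 0:
        return set()
    labels = cohort.subject_labels()
    chosen: list[str] = []
    for cls in (0, 1):
        subjects = sorted(labels.index[labels == cls])
        n_val = int(round(fraction * len(subjects)))
        n_val = min(max(n_val, 1), max(len(subjects) - 1, 0))
        order = rng.permutation(len(subjects))
        chosen.extend(subjects[i] for i in order[:n_val])
    return set(chosen)


def _eval_arrays(model: MCIDetector, X, y, batch_size: int) -> tuple[float, float]:
    model.eval()
    losses, correct = [], 0
    for lo in range(0, len(X), batch_size):
        xb, yb = X[lo : lo + batch_size], y[lo : lo + batch_size]
        logits = model(ad.Tensor(xb))
        losses.append(float(ad.cross_entropy(logits, yb).data) * len(xb))
        correct += int((logits.data.argmax(axis=1) == yb).sum())
    return sum(losses) / len(X), correct / len(X)


def train(
    model: MCIDetector,
    train_cohort: Cohort,
    cfg: TrainConfig,
    run_dir: str | None = None,
) -> tuple[dict, History]:
    """Fit the model; returns (best state dict, per-epoch History).

    The best checkpoint is the epoch with the highest validation
    accuracy (training accuracy when no validation split is requested);
    ties resolve to the earlier epoch.
    """
    rng = np.random.default_rng(int(cfg.seed) & 0x7FFFFFFF)
    X, y, subjects = _load_arrays(train_cohort)
    if len(np.unique(y)) < 2:
        raise ValueError("training cohort must contain both classes")

    val_ids = _val_subjects(train_cohort, cfg.val_fraction, rng)
    val_mask = np.isin(subjects, sorted(val_ids))
    assert not (set(subjects[val_mask]) & set(subjects[~val_mask])), "validation leakage"
    Xtr, ytr = X[~val_mask], y[~val_mask]
    Xva, yva = X[val_mask], y[val_mask]
    if len(np.unique(ytr)) < 2:
        raise ValueError("training portion lost a class after the validation split")

    optimizer = make_optimizer(cfg.optimizer, model.parameters(), cfg.base_lr)
    history = History()
    best = {"acc": -1.0, "state": copy.deepcopy(model.state_dict()), "epoch": -1}

    for epoch in range(cfg.epochs):
        lr = lr_schedule(epoch, cfg)
        optimizer.lr = lr
        model.train()
        order = rng.permutation(len(Xtr))
        epoch_loss, epoch_correct = 0.0, 0
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            optimizer.zero_grad()
            logits = model(ad.Tensor(xb))
            loss = ad.cross_entropy(logits, yb)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {lo // cfg.batch_size}"
                )
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(xb)
            epoch_correct += int((logits.data.argmax(axis=1) == yb).sum())

        train_loss = epoch_loss / len(Xtr)
        train_acc = epoch_correct / len(Xtr)
        if len(Xva):
            val_loss, val_acc = _eval_arrays(model, Xva, yva, cfg.batch_size)
        else:
            val_loss, val_acc = float("nan"), float("nan")
        history.append(
            epoch=epoch, lr=lr, train_loss=train_loss, train_acc=train_acc,
            val_loss=val_loss, val_acc=val_acc,
        )
        select_acc = val_acc if len(Xva) else train_acc
        if select_acc > best["acc"]:
            best = {"acc": select_acc, "state": copy.deepcopy(model.state_dict()), "epoch": epoch}

    if run_dir is not None:
        history.write_tsv(Path(run_dir) / "history.tsv")
    model.load_state_dict(best["state"])
    model.eval()
    return best["state"], history
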