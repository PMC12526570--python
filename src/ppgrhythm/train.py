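"""Training loop: Adam, class-weighted KL-divergence loss, plateau learning
rate decay, early stopping, and best-validation-accuracy checkpointing.

With one-hot targets the KL divergence reduces to weighted categorical
cross-entropy (the target entropy term is zero); the loss is nevertheless
implemented literally as KL with epsilon clipping, and the equivalence is
asserted in the test suite.  Class weights enter as per-sample loss
multipliers — one mechanism only, so imbalance is not double-counted on
top of the window augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import InvalidParameterError, LeakageError
from .model import DualBranchAttentionNet, save_checkpoint
from .nn.autograd import Tensor
from .nn.optim import Adam
from .spectral import WelchConfig, ssm_batch
from .windowing import ClassWeights, WindowSet

__all__ = [
    "TrainConfig", "TrainHistory", "FeatureSet", "kl_loss",
    "ReduceLROnPlateau", "EarlyStopping", "fit",
]

EPS = 1e-7


@dataclass
class FeatureSet:
    """Model-ready bundle: raw 10 s windows, their SSM tensors, labels and
    per-window record provenance."""

    x_time: np.ndarray      # [n, window_samples]
    x_ssm: np.ndarray       # [n, B, B]
    y: np.ndarray           # [n] int labels
    source_ids: np.ndarray  # [n] str
    split: str = ""

    @classmethod
    def from_window_set(cls, ws: WindowSet,
                        welch_cfg: WelchConfig = WelchConfig(),
                        ) -> "FeatureSet":
        ssm = (ssm_batch(ws.windows, ws.fs, welch_cfg) if len(ws)
               else np.empty((0, welch_cfg.n_bands, welch_cfg.n_bands)))
        return cls(x_time=ws.windows, x_ssm=ssm, y=ws.labels,
                   source_ids=ws.source_ids, split=ws.split)

    def __len__(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol. Defaults: Adam at 5e-4, batch 60, 160 epochs,
    learning rate divided by 10 after 30 epochs without validation-loss
    improvement (floor 1e-6), early stop after 50, best validation
    accuracy checkpointed and restored."""

    lr: float = 5e-4
    batch_size: int = 60
    epochs: int = 160
    reduce_lr_factor: float = 0.1
    reduce_lr_patience: int = 30
    early_stop_patience: int = 50
    min_lr: float = 1e-6
    dropout: float = 0.2
    seed: int = 0
    checkpoint_path: str | None = None

    def validate(self) -> None:
        if self.lr <= 0:
            raise InvalidParameterError("lr must be positive")
        if self.batch_size < 1:
            raise InvalidParameterError("batch_size must be >= 1")
        if not 0 < self.reduce_lr_factor < 1:
            raise InvalidParameterError("reduce_lr_factor must be in (0,1)")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1
    checkpoint_path: str | None = None


def _check_simplex(rows: np.ndarray, name: str, tol: float = 1e-5) -> None:
    if np.any(rows < -tol) or np.any(np.abs(rows.sum(axis=-1) - 1) > tol):
        raise InvalidParameterError(
            f"{name} rows must lie on the probability simplex (tol {tol})")


def kl_loss(true_dist: np.ndarray, pred_dist: np.ndarray,
            sample_weights: np.ndarray | None = None) -> float:
    """Mean weighted KL divergence D(true || pred) over rows.

    Predictions are clipped to [eps, 1] (eps = 1e-7) before the log;
    0*log 0 terms in the target are dropped.  For one-hot targets this is
    exactly weighted categorical cross-entropy.
    """
    t = np.asarray(true_dist, dtype=np.float64)
    p = np.asarray(pred_dist, dtype=np.float64)
    _check_simplex(t, "true_dist")
    _check_simplex(p, "pred_dist")
    p = np.clip(p, EPS, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logt = np.where(t > 0, np.log(np.maximum(t, EPS)), 0.0)
    rows = np.sum(np.where(t > 0, t * (logt - np.log(p)), 0.0), axis=-1)
    if sample_weights is not None:
        rows = rows * np.asarray(sample_weights, dtype=np.float64)
    return float(rows.mean())


def _kl_loss_graph(pred: Tensor, y_onehot: np.ndarray,
                   sample_weights: np.ndarray) -> Tensor:
    """Differentiable loss for one-hot targets (target entropy is zero, so
    KL equals the weighted cross-entropy built here)."""
    logp = (pred + EPS).log()
    per_row = -(Tensor(y_onehot) * logp).sum(axis=-1)
    return (per_row * Tensor(sample_weights)).mean()


class ReduceLROnPlateau:
    """Divide the learning rate by 1/factor after `patience` consecutive
    epochs without improvement of the monitored value (lower is better)."""

    def __init__(self, factor: float = 0.1, patience: int = 30,
                 min_lr: float = 1e-6, min_delta: float = 0.0):
        self.factor, self.patience = factor, patience
        self.min_lr, self.min_delta = min_lr, min_delta
        self.best = np.inf
        self.wait = 0

    def update(self, value: float, lr: float) -> float:
        """Feed one epoch's monitored value; returns the (possibly reduced)
        learning rate."""
        if value < self.best - self.min_delta:
            self.best = value
            self.wait = 0
            return lr
        self.wait += 1
        if self.wait >= self.patience:
            self.wait = 0
            return max(self.min_lr, lr * self.factor)
        return lr


class EarlyStopping:
    def __init__(self, patience: int = 50, min_delta: float = 0.0):
        self.patience, self.min_delta = patience, min_delta
        self.best = np.inf
        self.wait = 0

    def update(self, value: float) -> bool:
        """Returns True when training should stop."""
        if value < self.best - self.min_delta:
            self.best = value
            self.wait = 0
            return False
        self.wait += 1
        return self.wait >= self.patience


def _onehot(y: np.ndarray, n: int = 4) -> np.ndarray:
    out = np.zeros((len(y), n))
    out[np.arange(len(y)), y] = 1.0
    return out


def evaluate_loss_acc(model: DualBranchAttentionNet, data: FeatureSet,
                      sample_weights: np.ndarray | None = None,
                      batch_size: int = 64) -> tuple[float, float]:
    probs = model.predict_proba(data.x_time, data.x_ssm, batch_size)
    loss = kl_loss(_onehot(data.y), probs, sample_weights)
    acc = float((probs.argmax(axis=1) == data.y).mean())
    return loss, acc


def fit(model: DualBranchAttentionNet, train_data: FeatureSet,
        val_data: FeatureSet, cfg: TrainConfig = TrainConfig(),
        class_weights: ClassWeights | None = None,
        verbose: bool = False) -> TrainHistory:
    """Train the classifier; returns the per-epoch history with the best
    validation-accuracy weights restored into ``model``.

    Raises :class:`LeakageError` if any source record contributes windows
    to both the training and validation sets.
    """
    cfg.validate()
    overlap = set(map(str, train_data.source_ids)) & set(
        map(str, val_data.source_ids))
    if overlap:
        raise LeakageError(
            f"records in both train and val splits: {sorted(overlap)[:5]}")

    n = len(train_data)
    w_sample = np.ones(n)
    if class_weights is not None:
        w_sample = np.array(
            [class_weights[int(label)] for label in train_data.y])
    y_onehot = _onehot(train_data.y)

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    plateau = ReduceLROnPlateau(cfg.reduce_lr_factor, cfg.reduce_lr_patience,
                                cfg.min_lr)
    stopper = EarlyStopping(cfg.early_stop_patience)
    history = TrainHistory()
    best_acc = -np.inf
    best_state: dict | None = None

    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_correct = 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo: lo + cfg.batch_size]
            probs = model.forward(train_data.x_time[idx],
                                  train_data.x_ssm[idx])
            loss = _kl_loss_graph(probs, y_onehot[idx], w_sample[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch + 1} "
                    f"(lr={opt.lr:g}, batch start {lo})")
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
            epoch_correct += int(
                (probs.data.argmax(axis=1) == train_data.y[idx]).sum())

        val_loss, val_acc = evaluate_loss_acc(model, val_data)
        history.train_loss.append(epoch_loss / n)
        history.train_acc.append(epoch_correct / n)
        history.val_loss.append(val_loss)
        history.val_acc.append(val_acc)
        if verbose:
            print(f"epoch {epoch + 1:3d}  loss {epoch_loss / n:.4f}  "
                  f"acc {epoch_correct / n:.3f}  val_loss {val_loss:.4f}  "
                  f"val_acc {val_acc:.3f}  lr {opt.lr:g}")

        if val_acc > best_acc:
            best_acc = val_acc
            history.best_epoch = epoch
            best_state = model.state_dict()
        opt.lr = plateau.update(val_loss, opt.lr)
        history.lr.append(opt.lr)
        if stopper.update(val_loss):
            break

    if best_state is not None:
        model.load_state_dict(best_state)
        if cfg.checkpoint_path is not None:
            path = Path(cfg.checkpoint_path)
            path.parent.mkdir(parents=True, exist_ok=True)
            save_checkpoint(model, path)
            history.checkpoint_path = str(path)
    return history
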