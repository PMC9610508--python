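"""Mini-batch training loop with the schedule used for the reconstructor.

Per epoch: shuffle, NADAM steps on the Huber loss, then validation loss and
mean per-sample Pearson correlation.  Callbacks: reduce-LR-on-plateau
monitoring validation CC (factor 0.1, floored), early stopping on
validation loss, and checkpointing of the best-validation-loss weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .losses import huber_loss, huber_loss_grad
from .model import Network
from .optim import Nadam

__all__ = ["EpochRecord", "TrainingLoop"]


@dataclass
class EpochRecord:
    phase: int
    epoch: int
    train_loss: float
    val_loss: float
    val_cc: float
    lr: float
    events: str = ""


def _mean_sample_cc(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean over samples of the per-sample Pearson correlation.

    Samples where either vector is constant are excluded (CC undefined).
    """
    yc = y - y.mean(axis=1, keepdims=True)
    pc = yhat - yhat.mean(axis=1, keepdims=True)
    sy = np.sqrt((yc**2).sum(axis=1))
    sp = np.sqrt((pc**2).sum(axis=1))
    ok = (sy > 0) & (sp > 0)
    if not np.any(ok):
        return float("nan")
    cc = (yc[ok] * pc[ok]).sum(axis=1) / (sy[ok] * sp[ok])
    return float(cc.mean())


@dataclass
class TrainingLoop:
    delta: float
    batch_size: int
    epochs: int
    lr: float = 1e-3
    plateau_patience: int = 7
    plateau_factor: float = 0.1
    lr_floor: float = 1e-5
    early_stop_patience: int = 15
    phase: int = 1
    history: list[EpochRecord] = field(default_factory=list)

    def fit(
        self,
        model: Network,
        x_train: np.ndarray,
        y_train: np.ndarray,
        x_val: np.ndarray,
        y_val: np.ndarray,
        rng: np.random.Generator,
    ) -> list[EpochRecord]:
        opt = Nadam(model.parameters(), lr=self.lr)
        best_val = np.inf
        best_state = model.get_state()
        best_cc = -np.inf
        epochs_since_cc = 0
        epochs_since_val = 0
        n = len(x_train)

        for epoch in range(self.epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = x_train[idx], y_train[idx]
                pred = model.forward(xb, training=True)
                loss = huber_loss(yb, pred, self.delta)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged (non-finite loss) at phase "
                        f"{self.phase}, epoch {epoch + 1}"
                    )
                total += loss * len(idx)
                model.backward(huber_loss_grad(yb, pred, self.delta))
                opt.step(model.gradients())
            train_loss = total / n

            val_pred = model.predict(x_val)
            val_loss = huber_loss(y_val, val_pred, self.delta)
            val_cc = _mean_sample_cc(y_val, val_pred)
            events = []

            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_state = model.get_state()
                epochs_since_val = 0
            else:
                epochs_since_val += 1

            if val_cc > best_cc + 1e-12:
                best_cc = val_cc
                epochs_since_cc = 0
            else:
                epochs_since_cc += 1
                if (
                    epochs_since_cc >= self.plateau_patience
                    and opt.lr > self.lr_floor
                ):
                    opt.lr = max(opt.lr * self.plateau_factor, self.lr_floor)
                    epochs_since_cc = 0
                    events.append(f"lr->{opt.lr:.1e}")

            self.history.append(
                EpochRecord(
                    self.phase, epoch + 1, train_loss, val_loss, val_cc,
                    opt.lr, ";".join(events),
                )
            )
            if epochs_since_val >= self.early_stop_patience:
                self.history[-1].events += ";early_stop" if events else "early_stop"
                break

        model.set_state(best_state)  # keep the best-validation-loss weights
        return self.history
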