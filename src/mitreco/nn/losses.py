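"""The Huber loss: quadratic core, linear tails.

    L_i = 1/2 (y_i - yhat_i)^2            if |y_i - yhat_i| <= delta
          delta |y_i - yhat_i| - delta^2/2  otherwise

averaged over all elements.  With delta >= the largest error it reduces to
half the MSE; as delta -> 0, L/delta approaches the MAE.  The quadratic
core keeps gradients smooth near the optimum while the linear tails bound
the influence of outliers.
"""

from __future__ import annotations

import numpy as np

__all__ = ["huber_loss", "huber_loss_grad"]


def huber_loss(y: np.ndarray, yhat: np.ndarray, delta: float) -> float:
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {yhat.shape}")
    err = np.abs(y - yhat)
    quad = err <= delta
    vals = np.where(quad, 0.5 * err**2, delta * err - 0.5 * delta**2)
    return float(vals.mean())


def huber_loss_grad(y: np.ndarray, yhat: np.ndarray, delta: float) -> np.ndarray:
    """d(mean Huber)/d(yhat): the clipped residual, divided by n."""
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    resid = np.asarray(yhat, dtype=np.float64) - np.asarray(y, dtype=np.float64)
    return (np.clip(resid, -delta, delta) / resid.size).astype(np.float32)
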