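"""Reconstruction quality metrics and the synthetic robustness cases.

All metrics compare coarse-grid conductivity vectors in their native
units (values already in [0, 1], so no rescaling).  SSIM is computed
globally — one window covering the whole volume — with population
(divide-by-N) moments:

    SSIM = (2 m_y m_yhat + C1)(2 s_{y yhat} + C2)
           / ((m_y^2 + m_yhat^2 + C1)(s_y^2 + s_yhat^2 + C2)),

C1 = (K1 L)^2, C2 = (K2 L)^2 with K1 = 0.01, K2 = 0.03 and dynamic range
L = 1.  The report correlation coefficient is the mean of per-sample
Pearson CCs (not the CC of pooled vectors); samples with a constant
prediction, where CC is undefined, are excluded and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import (
    ConductivityGrid,
    CuboidPerturbation,
    VoxelGrid,
    stamp_perturbations,
)
from .nn.losses import huber_loss

__all__ = [
    "SSIMParams",
    "MetricsReport",
    "mse",
    "mae",
    "pearson_cc",
    "ssim",
    "evaluate_predictions",
    "evaluate_model",
    "make_special_cases",
]


def _check_pair(y, yhat):
    y = np.asarray(y, dtype=float).reshape(-1)
    yhat = np.asarray(yhat, dtype=float).reshape(-1)
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch {y.shape} vs {yhat.shape}")
    return y, yhat


def mse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean squared error."""
    y, yhat = _check_pair(y, yhat)
    return float(np.mean((y - yhat) ** 2))


def mae(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean absolute error."""
    y, yhat = _check_pair(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def pearson_cc(y: np.ndarray, yhat: np.ndarray) -> float:
    """Pearson correlation; NaN (with no exception) if either input is
    constant, so callers can flag rather than silently zero it."""
    y, yhat = _check_pair(y, yhat)
    sy = y.std()
    sp = yhat.std()
    if sy == 0 or sp == 0:
        return float("nan")
    return float(((y - y.mean()) * (yhat - yhat.mean())).mean() / (sy * sp))


@dataclass(frozen=True)
class SSIMParams:
    K1: float = 0.01
    K2: float = 0.03
    L: float = 1.0

    @property
    def C1(self) -> float:
        return (self.K1 * self.L) ** 2

    @property
    def C2(self) -> float:
        return (self.K2 * self.L) ** 2


def ssim(y: np.ndarray, yhat: np.ndarray, params: SSIMParams = SSIMParams()) -> float:
    """Global (windowless) structural similarity over the whole volume."""
    y, yhat = _check_pair(y, yhat)
    if y.min() < 0 or y.max() > params.L or yhat.min() < 0 or yhat.max() > params.L:
        raise ValueError(f"values must lie in [0, {params.L}]")
    my, mp = y.mean(), yhat.mean()
    vy, vp = y.var(), yhat.var()
    cov = ((y - my) * (yhat - mp)).mean()
    c1, c2 = params.C1, params.C2
    return float(
        (2 * my * mp + c1) * (2 * cov + c2) / ((my**2 + mp**2 + c1) * (vy + vp + c2))
    )


@dataclass
class MetricsReport:
    """Per-sample metric table plus its column means."""

    per_sample: pd.DataFrame
    huber_delta: float = 0.05
    cc_undefined: int = 0

    @property
    def means(self) -> dict[str, float]:
        return {
            "Loss": float(self.per_sample["loss"].mean()),
            "MAE": float(self.per_sample["mae"].mean()),
            "MSE": float(self.per_sample["mse"].mean()),
            "CC": float(self.per_sample["cc"].mean(skipna=True)),
            "SSIM": float(self.per_sample["ssim"].mean()),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.means])


def evaluate_predictions(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    huber_delta: float = 0.05,
    ssim_params: SSIMParams = SSIMParams(),
) -> MetricsReport:
    """Metric suite for a set of (target, prediction) vector pairs."""
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float))
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float))
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction set shape mismatch")
    rows = []
    undefined = 0
    for yt, yp in zip(y_true, y_pred):
        cc = pearson_cc(yt, yp)
        if np.isnan(cc):
            undefined += 1
        rows.append(
            {
                "loss": huber_loss(yt, yp, huber_delta),
                "mae": mae(yt, yp),
                "mse": mse(yt, yp),
                "cc": cc,
                "ssim": ssim(yt, yp, ssim_params),
            }
        )
    return MetricsReport(pd.DataFrame(rows), huber_delta, undefined)


def evaluate_model(model, x, y_true, **kw) -> MetricsReport:
    """Evaluate a reconstruction model on standardised signals ``x``."""
    from .reconstructor import _as_input

    preds = model.network.predict(_as_input(x)).astype(float)
    return evaluate_predictions(np.asarray(y_true, dtype=float), preds, **kw)


def make_special_cases(
    grid: VoxelGrid,
    length_range_cm: tuple[int, int] = (6, 10),
    overlap_extent_cm: float = 13.0,
    unseen_sigma: float = 0.8,
    background: float = 0.5,
) -> dict[str, ConductivityGrid]:
    """The two synthetic robustness cases, as fine-grid conductivity fields.

    Case "overlap": two cuboids of the maximum training length overlapping
    along x so their union is one non-cuboid object of total length
    ``overlap_extent_cm`` (longer than anything in the training corpus),
    at 0.0 S/m, centred in the body.  Case "unseen_sigma": a single
    centred cuboid with a conductivity never used in training (0.8 S/m).
    Both are meant to be pushed through the standard forward + noise +
    coarsening pipeline and reconstructed with the trained model.
    """
    ex, ey, ez = grid.extent_cm
    lmax = float(length_range_cm[1])
    if overlap_extent_cm <= lmax or overlap_extent_cm > 2 * lmax:
        raise ValueError(
            "overlap extent must exceed one object length and fit two"
        )
    if overlap_extent_cm > ex:
        raise ValueError("overlap case does not fit in the body")

    h = grid.voxel_cm
    side = min(lmax, ey - 2 * h, ez - 2 * h)

    def centred_origin(lengths):
        return tuple(
            round((e - l) / 2 / h) * h for e, l in zip((ex, ey, ez), lengths)
        )

    # two cuboids shifted along x; second one offset in y to break cuboid shape
    l1 = (lmax, side, side)
    x0 = round((ex - overlap_extent_cm) / 2 / h) * h
    y0 = centred_origin(l1)[1]
    z0 = centred_origin(l1)[2]
    shift_y = min(2 * h, ey - side - y0)
    c1 = CuboidPerturbation((x0, y0, z0), l1, 0.0)
    c2 = CuboidPerturbation(
        (x0 + overlap_extent_cm - lmax, y0 + shift_y, z0), l1, 0.0
    )
    overlap = stamp_perturbations(grid, [c1, c2], background=background)

    l3 = (lmax, side, side)
    c3 = CuboidPerturbation(centred_origin(l3), l3, unseen_sigma)
    unseen = stamp_perturbations(grid, [c3], background=background)
    return {"overlap": overlap, "unseen_sigma": unseen}
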