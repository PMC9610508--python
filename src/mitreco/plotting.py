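"""Slice-montage plots of conductivity volumes.

A reconstruction is conventionally inspected as its stack of z-slices
(depth sections), ground truth above prediction, one common colour scale
over the conductivity range [0, 1].
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .grids import ConductivityGrid

__all__ = ["save_slice_montage"]


def save_slice_montage(
    truth: ConductivityGrid,
    prediction: ConductivityGrid | None,
    path,
    title: str = "",
) -> None:
    """Write a PNG of per-z slices; two rows when a prediction is given."""
    if prediction is not None and prediction.grid.shape != truth.grid.shape:
        raise ValueError("prediction grid does not match truth grid")
    nz = truth.grid.shape[2]
    rows = 1 if prediction is None else 2
    fig, axes = plt.subplots(
        rows, nz, figsize=(1.4 * nz, 1.8 * rows), squeeze=False
    )
    volumes = [("truth", truth)] + (
        [("reconstruction", prediction)] if prediction is not None else []
    )
    for r, (label, vol) in enumerate(volumes):
        for z in range(nz):
            ax = axes[r][z]
            ax.imshow(
                vol.sigma[:, :, z].T, origin="lower", vmin=0.0, vmax=1.0,
                cmap="viridis",
            )
            ax.set_xticks([])
            ax.set_yticks([])
            if r == 0:
                ax.set_title(f"z={z}", fontsize=8)
        axes[r][0].set_ylabel(label, fontsize=8)
    if title:
        fig.suptitle(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
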