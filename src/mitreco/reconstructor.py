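"""The deep residual reconstruction network and its two-phase training.

The inverse problem is posed as regression: a standardised differential
signal, reshaped to a 6 x P matrix (one row per receiver, one column per
scan position), is mapped to the coarse-grid conductivity vector.  The
network is a 2D-convolutional residual net: a 5x5 stem with max pooling
compresses the strongly correlated neighbouring measurement points, a
stack of residual and bottleneck blocks (3x5 kernels, three conv stages
per block, bottlenecks striding 1x3 along the position axis) extracts
features, and after average pooling two sigmoid dense layers feed a
hard-sigmoid output layer whose [0, 1] range matches the conductivity
domain exactly.

Training minimises the Huber loss in two phases: pretraining with
delta = 1.0 (pure quadratic regime, batch 64), then fine-tuning with
delta = 0.05 (batch 32), each with NADAM, a reduce-on-plateau learning
rate monitoring the validation correlation coefficient, and early
stopping on the validation loss.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .dataset import Standardizer
from .grids import ConductivityGrid, VoxelGrid, unflatten_fortran

__all__ = [
    "ArchitectureSpec",
    "TrainingSchedule",
    "ReconstructionModel",
    "reshape_signal",
    "build_model",
    "train_two_phase",
    "reconstruct",
]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Structural description of the reconstruction network.

    ``block_plan`` is an ordered list of ("residual" | "bottleneck",
    filters) pairs.  The default full-scale plan alternates residual and
    bottleneck blocks, doubling the width at each bottleneck; the
    full-scale head uses two dense layers of 5172 units.  ``init`` selects
    weight initialisation: "normal" draws N(0, init_std^2) for every
    weight; "scaled" uses fan-averaged variance scaling, the standard
    choice for deep nets.
    """

    input_shape: tuple[int, int] = (6, 206)
    stem_filters: int = 64
    stem_kernel: tuple[int, int] = (5, 5)
    block_plan: tuple[tuple[str, int], ...] = (
        ("residual", 64),
        ("bottleneck", 128),
        ("residual", 128),
        ("bottleneck", 256),
        ("residual", 256),
    )
    block_kernel: tuple[int, int] = (3, 5)
    dense_units: int = 5172
    n_dense: int = 2
    output_units: int = 4200
    init: str = "normal"
    init_std: float = 1.0


@dataclass(frozen=True)
class TrainingSchedule:
    """Two-phase Huber schedule with NADAM and validation-driven callbacks."""

    phase1_delta: float = 1.0
    phase1_batch: int = 64
    phase1_epochs: int = 50
    phase2_delta: float = 0.05
    phase2_batch: int = 32
    phase2_epochs: int = 50
    learning_rate: float = 1e-3
    plateau_patience: int = 7
    plateau_factor: float = 0.1
    lr_floor: float = 1e-5
    early_stop_patience: int = 15


@dataclass
class ReconstructionModel:
    """Architecture + learned weights + the standardizer fitted at training."""

    spec: ArchitectureSpec
    network: nn.Network
    coarse_grid: VoxelGrid
    standardizer: Standardizer | None = None
    history: list[nn.EpochRecord] = field(default_factory=list)

    def save(self, path) -> None:
        meta = {
            "spec": asdict(self.spec),
            "coarse_extent_cm": list(self.coarse_grid.extent_cm),
            "coarse_voxel_cm": self.coarse_grid.voxel_cm,
        }
        arrays = {f"state_{i}": a for i, a in enumerate(self.network.get_state())}
        if self.standardizer is not None:
            arrays["std_mean"] = self.standardizer.mean
            arrays["std_scale"] = self.standardizer.scale
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "ReconstructionModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            spec_d = meta["spec"]
            for key in ("input_shape", "stem_kernel", "block_kernel"):
                spec_d[key] = tuple(spec_d[key])
            spec_d["block_plan"] = tuple(tuple(b) for b in spec_d["block_plan"])
            spec = ArchitectureSpec(**spec_d)
            grid = VoxelGrid(
                tuple(meta["coarse_extent_cm"]), meta["coarse_voxel_cm"]
            )
            model = build_model(spec, grid, rng=np.random.default_rng(0))
            n_state = len(model.network.get_state())
            model.network.set_state(
                [data[f"state_{i}"] for i in range(n_state)]
            )
            if "std_mean" in data:
                model.standardizer = Standardizer(
                    data["std_mean"], data["std_scale"]
                )
        return model


def reshape_signal(flat: np.ndarray, n_receivers: int = 6) -> np.ndarray:
    """Reshape a flattened signal [r1 trace | r2 trace | ...] to a matrix
    with one row per receiver and one column per scan position."""
    flat = np.asarray(flat)
    if flat.shape[-1] % n_receivers:
        raise ValueError(
            f"signal length {flat.shape[-1]} is not divisible by "
            f"{n_receivers} receivers"
        )
    return flat.reshape(*flat.shape[:-1], n_receivers, -1)


def build_model(
    spec: ArchitectureSpec,
    coarse_grid: VoxelGrid,
    rng: np.random.Generator,
) -> ReconstructionModel:
    """Instantiate the network for a given architecture and target grid."""
    if coarse_grid.n_voxels != spec.output_units:
        raise ValueError(
            f"output_units {spec.output_units} does not match coarse grid "
            f"with {coarse_grid.n_voxels} voxels"
        )
    kw = dict(rng=rng, init=spec.init, init_std=spec.init_std)
    layers: list[nn.Layer] = [
        nn.Conv2D(1, spec.stem_filters, spec.stem_kernel, **kw),
        nn.ELU(),
        nn.BatchNorm(spec.stem_filters),
        nn.MaxPool2D(),
    ]
    h = (spec.input_shape[0] // 2, spec.input_shape[1] // 2)
    channels = spec.stem_filters
    for b, (kind, filters) in enumerate(spec.block_plan):
        if kind == "residual":
            if channels != filters:
                raise ValueError(
                    f"block {b}: residual block filters {filters} must match "
                    f"incoming channels {channels}"
                )
            layers.append(
                nn.ResidualBlock(channels, filters, spec.block_kernel, **kw)
            )
        elif kind == "bottleneck":
            layers.append(
                nn.BottleneckBlock(channels, filters, spec.block_kernel, **kw)
            )
            h = (h[0], -(-h[1] // 3))
        else:
            raise ValueError(f"block {b}: unknown block kind {kind!r}")
        channels = filters
    layers.append(nn.AvgPool2D())
    h = (h[0] // 2, h[1] // 2)
    if h[0] < 1 or h[1] < 1:
        raise ValueError("block plan collapses the feature map to zero size")
    layers.append(nn.Flatten())
    units_in = h[0] * h[1] * channels
    for _ in range(spec.n_dense):
        layers += [nn.Dense(units_in, spec.dense_units, **kw), nn.Sigmoid()]
        units_in = spec.dense_units
    layers += [nn.Dense(units_in, spec.output_units, **kw), nn.HardSigmoid()]
    return ReconstructionModel(spec, nn.Network(layers), coarse_grid)


def train_two_phase(
    model: ReconstructionModel,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    schedule: TrainingSchedule,
    rng: np.random.Generator,
) -> list[nn.EpochRecord]:
    """Run the two Huber phases; returns the combined epoch history.

    Inputs are standardised signals shaped (N, 6, P); targets are coarse
    conductivity vectors in [0, 1].  After each phase the network carries
    its best-validation-loss weights.
    """
    x_train = _as_input(x_train)
    x_val = _as_input(x_val)
    y_train = y_train.astype(np.float32)
    y_val = y_val.astype(np.float32)
    history: list[nn.EpochRecord] = []
    phases = [
        (1, schedule.phase1_delta, schedule.phase1_batch, schedule.phase1_epochs),
        (2, schedule.phase2_delta, schedule.phase2_batch, schedule.phase2_epochs),
    ]
    for phase, delta, batch, epochs in phases:
        if epochs == 0:
            continue
        loop = nn.TrainingLoop(
            delta=delta,
            batch_size=batch,
            epochs=epochs,
            lr=schedule.learning_rate,
            plateau_patience=schedule.plateau_patience,
            plateau_factor=schedule.plateau_factor,
            lr_floor=schedule.lr_floor,
            early_stop_patience=schedule.early_stop_patience,
            phase=phase,
        )
        history += loop.fit(model.network, x_train, y_train, x_val, y_val, rng)
    model.history = history
    return history


def _as_input(x: np.ndarray) -> np.ndarray:
    """(N, 6, P) or (N, 6*P) signals -> NHWC (N, 6, P, 1) float32."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 2:
        x = reshape_signal(x)
    if x.ndim == 3:
        x = x[..., None]
    return x


def reconstruct(
    model: ReconstructionModel,
    signal: np.ndarray,
    standardized: bool | None = None,
) -> tuple[np.ndarray, ConductivityGrid]:
    """Invert one signal: returns the conductivity vector and 3D grid.

    ``signal`` is a flattened or 6 x P differential signal.  Unless
    ``standardized`` is True, the model's own standardizer is applied
    first (the network must see inputs scaled exactly as in training).
    """
    flat = np.asarray(signal, dtype=float).reshape(-1)
    if standardized is None:
        standardized = False
    if not standardized:
        if model.standardizer is None:
            raise ValueError("model has no standardizer; pass standardized=True")
        flat = model.standardizer.transform(flat[None, :])[0]
    elif np.max(np.abs(flat)) > 50:
        import warnings

        warnings.warn(
            "input magnitudes look unstandardised; reconstruction may be "
            "meaningless", stacklevel=2
        )
    x = _as_input(flat[None, :])
    vec = model.network.predict(x)[0].astype(float)
    return vec, unflatten_fortran(vec, model.coarse_grid)
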