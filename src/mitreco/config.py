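"""Experiment configuration: geometry, physics, dataset, network, training.

Two profiles ship with the package: ``paper`` — the full-scale torso
configuration (50 x 28 x 24 cm body, 256-position scan, 66,000-sample
corpus, 5172-unit dense head) — and ``desk`` — a proportionally reduced
configuration (24 x 12 x 12 cm body, 96-position scan, 2,600-sample
corpus, small block plan) that trains on a single CPU in minutes and is
used throughout the test suite.  A stored config re-runs to bitwise
identical datasets given the same seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources

import yaml

from .coils import CoilSpec, make_receiver_array, make_undulator
from .forward import ForwardContext, PhysicsParams, ScanConfig
from .grids import VoxelGrid, make_body_grid
from .reconstructor import ArchitectureSpec, TrainingSchedule

__all__ = ["ExperimentConfig", "load_profile", "RunRecord"]


@dataclass(frozen=True)
class BodyConfig:
    extent_cm: tuple[float, float, float] = (50.0, 28.0, 24.0)
    fine_cm: float = 1.0
    coarse_cm: float = 2.0


@dataclass(frozen=True)
class ExciterConfig:
    n_wires: int = 11
    pitch_cm: float = 5.5
    wire_length_cm: float = 60.0
    z_cm: float = -5.0


@dataclass(frozen=True)
class ReceiverArrayConfig:
    wide_lobe_cm: float = 11.0
    narrow_lobe_cm: float = 11.0 / 3.0
    wide_z_offset_cm: float = 5.0
    narrow_z_offset_cm: float = 7.0


@dataclass(frozen=True)
class DatasetConfig:
    cases_1obj: int = 3000
    cases_2obj: int = 15000
    snr_db: float = 60.0
    length_range_cm: tuple[int, int] = (6, 10)
    margin_cm: float = 0.0
    fractions: tuple[float, float, float] = (0.65, 0.25, 0.10)
    seed: int = 2022


@dataclass(frozen=True)
class ArchitectureConfig:
    stem_filters: int = 64
    block_plan: tuple[tuple[str, int], ...] = (
        ("residual", 64),
        ("bottleneck", 128),
        ("residual", 128),
        ("bottleneck", 256),
        ("residual", 256),
    )
    dense_units: int = 5172
    n_dense: int = 2
    init: str = "normal"
    init_std: float = 1.0


@dataclass(frozen=True)
class EvaluationConfig:
    overlap_extent_cm: float = 13.0
    unseen_sigma: float = 0.8


@dataclass
class ExperimentConfig:
    profile: str = "paper"
    body: BodyConfig = field(default_factory=BodyConfig)
    exciter: ExciterConfig = field(default_factory=ExciterConfig)
    receivers: ReceiverArrayConfig = field(default_factory=ReceiverArrayConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    physics: PhysicsParams = field(default_factory=PhysicsParams)
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    architecture: ArchitectureConfig = field(default_factory=ArchitectureConfig)
    training: TrainingSchedule = field(default_factory=TrainingSchedule)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    # -- derived objects ---------------------------------------------------

    def fine_grid(self) -> VoxelGrid:
        return make_body_grid(self.body.extent_cm, self.body.fine_cm)

    def coarse_grid(self) -> VoxelGrid:
        return make_body_grid(self.body.extent_cm, self.body.coarse_cm)

    @property
    def coarse_factor(self) -> int:
        return int(round(self.body.coarse_cm / self.body.fine_cm))

    def make_exciter(self) -> CoilSpec:
        return make_undulator(
            self.exciter.n_wires,
            self.exciter.pitch_cm,
            self.exciter.wire_length_cm,
            self.exciter.z_cm,
            y_center_cm=self.body.extent_cm[1] / 2,
        )

    def make_receivers(self) -> list[CoilSpec]:
        return make_receiver_array(self.body.extent_cm, **asdict(self.receivers))

    def build_context(self, voxel_cm: float | None = None) -> ForwardContext:
        """Forward context on the fine grid (or an explicit voxel size)."""
        grid = (
            self.fine_grid()
            if voxel_cm is None
            else make_body_grid(self.body.extent_cm, voxel_cm)
        )
        return ForwardContext(
            grid, self.make_exciter(), self.make_receivers(),
            self.physics, self.scan,
        )

    def architecture_spec(self) -> ArchitectureSpec:
        return ArchitectureSpec(
            input_shape=(6, self.scan.kept_positions),
            stem_filters=self.architecture.stem_filters,
            block_plan=self.architecture.block_plan,
            dense_units=self.architecture.dense_units,
            n_dense=self.architecture.n_dense,
            output_units=self.coarse_grid().n_voxels,
            init=self.architecture.init,
            init_std=self.architecture.init_std,
        )

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "profile": self.profile,
            "body": asdict(self.body),
            "exciter": asdict(self.exciter),
            "receivers": asdict(self.receivers),
            "scan": asdict(self.scan),
            "physics": asdict(self.physics),
            "dataset": asdict(self.dataset),
            "architecture": asdict(self.architecture),
            "training": asdict(self.training),
            "evaluation": asdict(self.evaluation),
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        def _tup(x):
            return tuple(x) if isinstance(x, list) else x

        sections = {
            "body": BodyConfig,
            "exciter": ExciterConfig,
            "receivers": ReceiverArrayConfig,
            "scan": ScanConfig,
            "physics": PhysicsParams,
            "dataset": DatasetConfig,
            "architecture": ArchitectureConfig,
            "training": TrainingSchedule,
            "evaluation": EvaluationConfig,
        }
        kwargs: dict = {"profile": d.get("profile", "custom")}
        for name, klass in sections.items():
            sub = dict(d.get(name, {}))
            for k, v in sub.items():
                if k == "block_plan":
                    sub[k] = tuple((kind, f) for kind, f in v)
                else:
                    sub[k] = _tup(v)
            try:
                kwargs[name] = klass(**sub)
            except TypeError as exc:
                raise ValueError(f"bad config section {name!r}: {exc}") from exc
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def load_profile(name: str) -> ExperimentConfig:
    """Load one of the packaged profiles ("paper" or "desk")."""
    ref = resources.files("mitreco") / "profiles" / f"{name}.yaml"
    if not ref.is_file():
        raise ValueError(f"unknown profile {name!r}")
    return ExperimentConfig.from_dict(yaml.safe_load(ref.read_text()))


@dataclass
class RunRecord:
    """Reproducibility record written next to every produced artifact."""

    config_hash: str
    seed: int
    stage: str
    wall_time_s: float
    artifacts: list[str]
    package_version: str = ""

    def save(self, path) -> None:
        if not self.package_version:
            from . import __version__

            self.package_version = __version__
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=2)
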