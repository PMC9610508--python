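"""Synthetic training corpus generation, splitting and standardisation.

The corpus is built exactly the way the study conditions prescribe: cuboid
perturbations are placed on the fine 1 cm grid; for every geometric case
the scan signal is computed for *every* conductivity combination of its
objects (2 combos for one object, 4 for two) because highly conductive
(1.0 S/m) objects give much weaker signals than insulating (0.0 S/m) ones
and would otherwise be under-represented; 60 dB white noise is injected
independently into the perturbed and background scans before subtraction;
and the regression target is the conductivity averaged onto the coarse
2 cm grid, Fortran-flattened.  Simulating on the fine grid while
reconstructing on the coarse one (plus the noise) avoids the inverse
crime.

Splitting is by geometric case, not by sample: the 2-4 samples sharing a
geometry land in the same split, so the test set never contains a
geometry seen in training.  Standardisation is per measurement feature
(each of the 6 x P signal entries) with population statistics fitted on
the training split only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .forward import ForwardContext, ScanSignal, add_noise, differential_signal
from .grids import (
    ConductivityGrid,
    CuboidPerturbation,
    coarsen,
    flatten_fortran,
    place_perturbations,
    stamp_perturbations,
)

__all__ = [
    "SampleSpec",
    "DatasetManifest",
    "Dataset",
    "Standardizer",
    "enumerate_combos",
    "generate_dataset",
    "split_dataset",
    "fit_standardizer",
    "save_dataset",
    "load_dataset",
]


def enumerate_combos(n_objects: int) -> list[tuple[float, ...]]:
    """All conductivity assignments over the objects of one case.

    One object: (0.0,), (1.0,).  Two objects: the four pairs over
    {0.0, 1.0}^2, ordered lexicographically.
    """
    if n_objects not in (1, 2):
        raise ValueError(f"n_objects must be 1 or 2, got {n_objects}")
    if n_objects == 1:
        return [(0.0,), (1.0,)]
    return [(a, b) for a in (0.0, 1.0) for b in (0.0, 1.0)]


@dataclass(frozen=True)
class SampleSpec:
    """Provenance of one dataset sample."""

    sample_id: int
    case_id: int
    n_objects: int
    combo: tuple[float, ...]
    perturbations: tuple[CuboidPerturbation, ...]


@dataclass
class DatasetManifest:
    cases_1obj: int
    cases_2obj: int
    samples: list[SampleSpec]
    skipped: list[int] = field(default_factory=list)
    split: dict[str, list[int]] | None = None

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @staticmethod
    def expected_samples(cases_1obj: int, cases_2obj: int) -> int:
        return cases_1obj * 2 + cases_2obj * 4

    def to_json(self) -> str:
        return json.dumps(
            {
                "cases_1obj": self.cases_1obj,
                "cases_2obj": self.cases_2obj,
                "skipped": self.skipped,
                "split": self.split,
                "samples": [asdict(s) for s in self.samples],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DatasetManifest":
        d = json.loads(text)
        samples = [
            SampleSpec(
                s["sample_id"],
                s["case_id"],
                s["n_objects"],
                tuple(s["combo"]),
                tuple(
                    CuboidPerturbation(
                        tuple(p["origin_cm"]), tuple(p["lengths_cm"]), p["sigma"]
                    )
                    for p in s["perturbations"]
                ),
            )
            for s in d["samples"]
        ]
        split = d.get("split")
        if split is not None:
            split = {k: list(v) for k, v in split.items()}
        return cls(d["cases_1obj"], d["cases_2obj"], samples, d["skipped"], split)


@dataclass
class Dataset:
    """In-memory corpus: raw differential signals plus coarse targets."""

    signals: np.ndarray  # (N, n_receivers, P) noise-realised S_Diff
    targets: np.ndarray  # (N, n_coarse) Fortran-flattened conductivities
    manifest: DatasetManifest

    def split_arrays(
        self, name: str, standardizer: "Standardizer | None" = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """(signals, targets) for one split, optionally standardised."""
        if self.manifest.split is None:
            raise ValueError("dataset has not been split")
        idx = np.asarray(self.manifest.split[name], dtype=int)
        x = self.signals[idx].reshape(len(idx), -1)
        if standardizer is not None:
            x = standardizer.transform(x)
        return x.reshape(len(idx), *self.signals.shape[1:]), self.targets[idx]


def generate_dataset(
    ctx: ForwardContext,
    cases_1obj: int,
    cases_2obj: int,
    seed: int,
    snr_db: float | None = 60.0,
    length_range_cm: tuple[int, int] = (6, 10),
    margin_cm: float = 0.0,
    coarse_factor: int = 2,
    background: float = 0.5,
    progress: bool = False,
) -> Dataset:
    """Simulate the full corpus for one forward context.

    Deterministic under ``seed``: the master seed fans out into separate
    placement and noise streams, so the same seed reproduces the corpus
    bitwise.  A forward-solve failure skips the sample and records the gap
    in the manifest instead of aborting the run.
    """
    ss = np.random.SeedSequence(seed)
    place_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    s_norm = ctx.background(background)
    specs: list[tuple[int, int, tuple[CuboidPerturbation, ...]]] = []
    for case_id in range(cases_1obj + cases_2obj):
        n_obj = 1 if case_id < cases_1obj else 2
        _, perts = place_perturbations(
            ctx.grid,
            n_obj,
            place_rng,
            length_range_cm=length_range_cm,
            margin_cm=margin_cm,
            background=background,
        )
        specs.append((case_id, n_obj, tuple(perts)))

    iterator = specs
    if progress:
        from tqdm import tqdm

        iterator = tqdm(specs, desc="simulating cases")

    signals, targets, samples, skipped = [], [], [], []
    sample_id = 0
    for case_id, n_obj, perts in iterator:
        for combo in enumerate_combos(n_obj):
            stamped = [
                CuboidPerturbation(p.origin_cm, p.lengths_cm, s)
                for p, s in zip(perts, combo)
            ]
            fine = stamp_perturbations(ctx.grid, stamped, background=background)
            try:
                s_e = ctx.simulate(fine)
            except Exception:
                skipped.append(sample_id)
                sample_id += 1
                continue
            s_diff = differential_signal(s_e, s_norm, snr_db=snr_db, rng=noise_rng)
            target = flatten_fortran(coarsen(fine, coarse_factor))
            signals.append(s_diff.values)
            targets.append(target)
            samples.append(
                SampleSpec(sample_id, case_id, n_obj, combo, tuple(stamped))
            )
            sample_id += 1

    manifest = DatasetManifest(cases_1obj, cases_2obj, samples, skipped)
    return Dataset(np.array(signals), np.array(targets), manifest)


def split_dataset(
    manifest: DatasetManifest,
    fractions: tuple[float, float, float] = (0.65, 0.25, 0.10),
    rng: np.random.Generator | None = None,
    paper_counts: bool = False,
) -> dict[str, list[int]]:
    """Assign samples to train/test/validation splits, case by case.

    ``fractions`` is (train, test, validation) and must sum to 1.  With
    ``paper_counts`` the absolute historical sample counts 49,500 train /
    16,500 test are targeted instead (leaving no validation samples); the
    two conventions are mutually inconsistent in their source, so both are
    offered and the fractional split is the default.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = rng or np.random.default_rng()
    case_ids = sorted({s.case_id for s in manifest.samples})
    order = [case_ids[i] for i in rng.permutation(len(case_ids))]
    by_case: dict[int, list[int]] = {}
    for s in manifest.samples:
        by_case.setdefault(s.case_id, []).append(s.sample_id)

    n_total = manifest.n_samples
    if paper_counts:
        quota = {"train": 49500, "test": 16500, "val": 0}
    else:
        quota = {
            "train": fractions[0] * n_total,
            "test": fractions[1] * n_total,
            "val": fractions[2] * n_total,
        }
    split: dict[str, list[int]] = {"train": [], "test": [], "val": []}
    for cid in order:
        # put the whole case in the currently most under-filled split
        deficits = {
            k: (quota[k] - len(split[k])) / max(quota[k], 1) for k in split
        }
        best = max(deficits, key=lambda k: deficits[k])
        split[best].extend(by_case[cid])
    for k in split:
        split[k].sort()
    manifest.split = split
    return split


@dataclass
class Standardizer:
    """Per-feature affine map z = (x - mean) / scale fitted on training data."""

    mean: np.ndarray
    scale: np.ndarray
    constant_features: np.ndarray | None = None

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.mean.shape[0]:
            raise ValueError(
                f"feature dimension {x.shape[-1]} does not match fitted "
                f"standardizer ({self.mean.shape[0]})"
            )
        return (x - self.mean) / self.scale

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.scale + self.mean


def fit_standardizer(train_signals: np.ndarray, eps: float = 1e-12) -> Standardizer:
    """Fit per-feature mean and population standard deviation.

    ``train_signals`` is (N, n_features) (or (N, 6, P), flattened
    internally).  Constant features get their scale floored at ``eps`` and
    are flagged in ``constant_features``.
    """
    x = np.asarray(train_signals, dtype=float)
    if x.ndim > 2:
        x = x.reshape(x.shape[0], -1)
    if x.shape[0] == 0:
        raise ValueError("cannot fit a standardizer on an empty training set")
    mean = x.mean(axis=0)
    scale = x.std(axis=0)  # population (divide-by-N) convention
    constant = scale < eps
    scale = np.where(constant, eps, scale)
    return Standardizer(mean, scale, constant)


# ---------------------------------------------------------------------------
# HDF5 container


def save_dataset(
    path,
    dataset: Dataset,
    standardizer: Standardizer | None = None,
    snr_db: float | None = 60.0,
    seed: int | None = None,
) -> None:
    """Write the corpus to an HDF5 container.

    Layout: /signals/raw (N x 6 x P), /targets (N x n_coarse), /manifest
    (JSON string), optional /standardizer group and /signals/std.
    """
    import h5py

    with h5py.File(path, "w") as f:
        sig = f.create_group("signals")
        raw = sig.create_dataset("raw", data=dataset.signals)
        raw.attrs["kind"] = "S_Diff"
        if snr_db is not None:
            raw.attrs["snr_db"] = snr_db
        if seed is not None:
            raw.attrs["seed"] = seed
        f.create_dataset("targets", data=dataset.targets)
        f.create_dataset("manifest", data=dataset.manifest.to_json())
        if standardizer is not None:
            g = f.create_group("standardizer")
            g.create_dataset("mean", data=standardizer.mean)
            g.create_dataset("scale", data=standardizer.scale)
            flat = dataset.signals.reshape(len(dataset.signals), -1)
            sig.create_dataset("std", data=standardizer.transform(flat))


def load_dataset(path) -> tuple[Dataset, Standardizer | None]:
    import h5py

    with h5py.File(path, "r") as f:
        signals = f["signals/raw"][...]
        targets = f["targets"][...]
        manifest = DatasetManifest.from_json(f["manifest"][()].decode())
        std = None
        if "standardizer" in f:
            std = Standardizer(
                f["standardizer/mean"][...], f["standardizer/scale"][...]
            )
    return Dataset(signals, targets, manifest), std
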