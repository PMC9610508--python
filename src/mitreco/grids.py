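"""Voxel lattices for the torso phantom and cuboid perturbation handling.

The body is a cuboid volume (default 50 x 28 x 24 cm, roughly a human torso)
discretised into cubic voxels.  Signals are simulated on a fine 1 cm lattice
while reconstruction targets live on a coarse 2 cm lattice; the deliberate
mismatch between the two discretisations (together with measurement noise)
is what keeps synthetic experiments honest — inverting on the same grid that
generated the data would commit the inverse crime.

Axes: x is the travel direction of the body through the scanner, y is
vertical, z is depth towards the receiver array.  Voxel indices are 0-based
and voxel centres sit at ``origin + (index + 0.5) * voxel_cm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoxelGrid",
    "CuboidPerturbation",
    "ConductivityGrid",
    "make_body_grid",
    "place_perturbations",
    "coarsen",
    "flatten_fortran",
    "unflatten_fortran",
]

_AXES = "xyz"

#: background conductivity of the phantom in S/m (mean soft-tissue value
#: at ~1.5 MHz, where tissue conductivities span 0..1 S/m)
BACKGROUND_SIGMA = 0.5


@dataclass(frozen=True)
class VoxelGrid:
    """A regular cubic-voxel lattice covering the body volume."""

    extent_cm: tuple[float, float, float]
    voxel_cm: float

    def __post_init__(self) -> None:
        for ax, e in zip(_AXES, self.extent_cm):
            if e <= 0:
                raise ValueError(f"extent along {ax} must be positive, got {e}")
            n = e / self.voxel_cm
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"extent {e} cm along axis {ax} is not divisible by "
                    f"voxel size {self.voxel_cm} cm"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(int(round(e / self.voxel_cm)) for e in self.extent_cm)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def centers_cm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-centre coordinates, body-local frame (origin at 0)."""
        return tuple(
            (np.arange(n) + 0.5) * self.voxel_cm for n in self.shape
        )


@dataclass(frozen=True)
class CuboidPerturbation:
    """An axis-aligned cuboid conductivity anomaly inside the body.

    ``sigma`` is 0.0 S/m for an insulating inclusion (e.g. a pneumothorax)
    or 1.0 S/m for a highly conductive one (e.g. internal bleeding); other
    values in [0, 1] are allowed for robustness experiments.
    """

    origin_cm: tuple[float, float, float]
    lengths_cm: tuple[float, float, float]
    sigma: float

    def slices(self, grid: VoxelGrid) -> tuple[slice, slice, slice]:
        """Index slices of the voxels fully covered by this cuboid."""
        lo = [int(round(o / grid.voxel_cm)) for o in self.origin_cm]
        hi = [
            int(round((o + l) / grid.voxel_cm))
            for o, l in zip(self.origin_cm, self.lengths_cm)
        ]
        return tuple(slice(a, b) for a, b in zip(lo, hi))


@dataclass
class ConductivityGrid:
    """A per-voxel conductivity field sigma(x) in S/m on a voxel lattice."""

    grid: VoxelGrid
    sigma: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.shape != self.grid.shape:
            raise ValueError(
                f"sigma shape {self.sigma.shape} does not match grid "
                f"shape {self.grid.shape}"
            )

    def copy(self) -> "ConductivityGrid":
        return ConductivityGrid(self.grid, self.sigma.copy())


def make_body_grid(
    extent_cm: tuple[float, float, float] = (50.0, 28.0, 24.0),
    voxel_cm: float = 1.0,
) -> VoxelGrid:
    """Create the body lattice; default torso phantom at 1 cm resolution."""
    return VoxelGrid(tuple(float(e) for e in extent_cm), float(voxel_cm))


def uniform_conductivity(
    grid: VoxelGrid, sigma: float = BACKGROUND_SIGMA
) -> ConductivityGrid:
    """Homogeneous body at the background conductivity."""
    return ConductivityGrid(grid, np.full(grid.shape, sigma))


def _cuboids_overlap(a: CuboidPerturbation, b: CuboidPerturbation) -> bool:
    for o1, l1, o2, l2 in zip(a.origin_cm, a.lengths_cm, b.origin_cm, b.lengths_cm):
        if o1 + l1 <= o2 or o2 + l2 <= o1:
            return False
    return True


def place_perturbations(
    grid: VoxelGrid,
    n_objects: int,
    rng: np.random.Generator,
    length_range_cm: tuple[int, int] = (6, 10),
    sigmas: tuple[float, ...] | None = None,
    margin_cm: float = 0.0,
    background: float = BACKGROUND_SIGMA,
    max_attempts: int = 1000,
) -> tuple[ConductivityGrid, list[CuboidPerturbation]]:
    """Randomly place non-overlapping cuboid anomalies into the body.

    Edge lengths are drawn as integer centimetres uniformly on
    ``[length_range_cm[0], length_range_cm[1]]`` so cuboids align with the
    fine lattice; origins are lattice-aligned and the cuboid is kept fully
    inside the body (optionally with ``margin_cm`` clearance to the body
    surface).  Placement uses rejection sampling to enforce non-overlap;
    objects may touch.

    Parameters
    ----------
    sigmas:
        Conductivity per object.  ``None`` leaves the assignment to the
        caller (objects are stamped later via :func:`stamp_perturbations`);
        training data uses 0.0 or 1.0 S/m.
    """
    if n_objects not in (1, 2):
        raise ValueError(f"n_objects must be 1 or 2, got {n_objects}")
    if sigmas is not None and len(sigmas) != n_objects:
        raise ValueError("one sigma per object required")

    lo, hi = length_range_cm
    placed: list[CuboidPerturbation] = []
    seed_info = rng.bit_generator.state["state"]
    for k in range(n_objects):
        for attempt in range(max_attempts):
            lengths = tuple(float(rng.integers(lo, hi + 1)) for _ in range(3))
            origin = []
            ok = True
            for ext, length in zip(grid.extent_cm, lengths):
                space = ext - length - 2 * margin_cm
                if space < 0:
                    ok = False
                    break
                # lattice-aligned origin
                n_slots = int(round(space / grid.voxel_cm)) + 1
                origin.append(margin_cm + float(rng.integers(0, n_slots)) * grid.voxel_cm)
            if not ok:
                continue
            cand = CuboidPerturbation(tuple(origin), lengths, 0.0)
            if any(_cuboids_overlap(cand, p) for p in placed):
                continue
            placed.append(cand)
            break
        else:
            raise RuntimeError(
                f"could not place object {k + 1} without overlap after "
                f"{max_attempts} attempts (rng state {seed_info})"
            )

    if sigmas is not None:
        placed = [
            CuboidPerturbation(p.origin_cm, p.lengths_cm, float(s))
            for p, s in zip(placed, sigmas)
        ]
    cgrid = stamp_perturbations(grid, placed, background=background)
    return cgrid, placed


def stamp_perturbations(
    grid: VoxelGrid,
    perturbations: list[CuboidPerturbation],
    background: float = BACKGROUND_SIGMA,
) -> ConductivityGrid:
    """Rasterise cuboids onto a uniform background conductivity field."""
    sigma = np.full(grid.shape, background)
    for p in perturbations:
        sigma[p.slices(grid)] = p.sigma
    return ConductivityGrid(grid, sigma)


def coarsen(fine: ConductivityGrid, factor: int = 2) -> ConductivityGrid:
    """Average fine voxels into coarse ones (default 2x2x2 -> 1).

    Each coarse voxel takes the arithmetic mean conductivity of its
    ``factor**3`` fine children, so a coarse cell half covered by a 0.0 S/m
    inclusion in a 0.5 S/m background averages to 0.25 S/m.  The
    volume-weighted mean conductivity of the body is conserved exactly.
    """
    shape = fine.grid.shape
    for ax, n in zip(_AXES, shape):
        if n % factor:
            raise ValueError(
                f"fine grid extent along {ax} ({n} voxels) is not divisible "
                f"by the coarsening factor {factor}"
            )
    nx, ny, nz = (n // factor for n in shape)
    blocks = fine.sigma.reshape(nx, factor, ny, factor, nz, factor)
    coarse_sigma = blocks.mean(axis=(1, 3, 5))
    coarse_grid = VoxelGrid(fine.grid.extent_cm, fine.grid.voxel_cm * factor)
    return ConductivityGrid(coarse_grid, coarse_sigma)


def flatten_fortran(cgrid: ConductivityGrid) -> np.ndarray:
    """Flatten a conductivity grid to a vector in Fortran (column-major)
    index order, the storage convention for reconstruction targets."""
    return cgrid.sigma.flatten(order="F")


def unflatten_fortran(vector: np.ndarray, grid: VoxelGrid) -> ConductivityGrid:
    """Inverse of :func:`flatten_fortran`."""
    vector = np.asarray(vector, dtype=float)
    if vector.size != grid.n_voxels:
        raise ValueError(
            f"vector length {vector.size} does not match grid with "
            f"{grid.n_voxels} voxels"
        )
    return ConductivityGrid(grid, vector.reshape(grid.shape, order="F"))
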