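"""Analytic magnetic vector potentials of the exciter and receiver coils.

The exciter is an "undulator": 11 vertical parallel wires carrying
antiparallel currents, which produces a primary field that alternates in
sign along the travel direction x with a spatial period of twice the wire
pitch.  The receivers are butterfly (figure-eight) coils: two counter-wound
rectangular lobes stacked vertically, sharing a horizontal edge.  Because
the wires are long, the primary field is nearly uniform along y over a
lobe pair, so it couples to the two counter-wound lobes almost equally and
cancels as common mode — the gradiometric arrangement that isolates the
secondary (eddy-current) field, which is localised and varies quickly in
y.  For a butterfly centred on the undulator midplane the cancellation is
exact by symmetry.

All potentials are computed per unit current from the closed-form straight
wire-segment solution of the Biot-Savart law,

    A(p) = (mu0 I / 4 pi) * u_hat * ln[(l2 + sqrt(l2^2 + d^2)) /
                                       (l1 + sqrt(l1^2 + d^2))],

with d the perpendicular distance of p from the wire axis and l1, l2 the
signed axial distances to the segment ends.  The prefactor mu0 I / 4 pi is
left out and folded into a single overall signal gain, since only relative,
standardised signals are ever used downstream.

Coordinates are lab-frame centimetres; the coils are fixed and the body
moves along x.  ``ScanFieldTable`` evaluates a coil potential once on an
extended lattice covering every scan position and serves per-position
samples by index shifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .grids import VoxelGrid

__all__ = [
    "WireSegment",
    "CoilSpec",
    "segment_vector_potential",
    "coil_potential",
    "make_undulator",
    "make_butterfly",
    "make_receiver_array",
    "ScanFieldTable",
    "primary_coupling",
]

#: wire-singularity exclusion radius in cm (1 mm); voxel centres never come
#: this close to a wire in the default geometries
EXCLUSION_RADIUS_CM = 0.1

#: number of points clamped to the exclusion radius since import (diagnostic)
clamp_counter: dict[str, int] = {"clamped": 0}


@dataclass(frozen=True)
class WireSegment:
    """A straight wire segment carrying unit current of a given sign."""

    start_cm: tuple[float, float, float]
    end_cm: tuple[float, float, float]
    current_sign: float = 1.0

    def __post_init__(self) -> None:
        if math.dist(self.start_cm, self.end_cm) == 0.0:
            raise ValueError("wire segment has zero length")


@dataclass(frozen=True)
class CoilSpec:
    """A coil as a list of wire segments plus bookkeeping metadata."""

    role: str  # "exciter" | "receiver"
    segments: tuple[WireSegment, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError(f"coil {self.label!r} has no segments")


def segment_vector_potential(seg: WireSegment, points_cm: np.ndarray) -> np.ndarray:
    """Vector potential of one straight segment at ``points_cm``.

    ``points_cm`` has shape (..., 3); the result has the same shape and is
    parallel to the segment direction.  Points closer to the wire axis than
    ``EXCLUSION_RADIUS_CM`` are clamped to that radius (counted in
    ``clamp_counter``).
    """
    p = np.asarray(points_cm, dtype=float)
    a = np.asarray(seg.start_cm)
    b = np.asarray(seg.end_cm)
    length = math.dist(seg.start_cm, seg.end_cm)
    u = (b - a) / length

    w = p - a
    s = w @ u  # axial coordinate of the point along the wire
    d2 = np.einsum("...i,...i->...", w, w) - s * s
    d2 = np.maximum(d2, 0.0)
    n_clamped = int(np.count_nonzero(d2 < EXCLUSION_RADIUS_CM**2))
    if n_clamped:
        clamp_counter["clamped"] += n_clamped
        d2 = np.maximum(d2, EXCLUSION_RADIUS_CM**2)

    l1 = -s
    l2 = length - s
    log_term = np.log(
        (l2 + np.sqrt(l2 * l2 + d2)) / (l1 + np.sqrt(l1 * l1 + d2))
    )
    return seg.current_sign * log_term[..., None] * u


def coil_potential(coil: CoilSpec, points_cm: np.ndarray) -> np.ndarray:
    """Total vector potential of a coil: sum over its segments."""
    p = np.asarray(points_cm, dtype=float)
    total = np.zeros(p.shape)
    for seg in coil.segments:
        total += segment_vector_potential(seg, p)
    return total


# ---------------------------------------------------------------------------
# coil builders


def make_undulator(
    n_wires: int = 11,
    pitch_cm: float = 5.5,
    wire_length_cm: float = 100.0,
    z_cm: float = -5.0,
    y_center_cm: float = 14.0,
) -> CoilSpec:
    """Build the undulator exciter: vertical wires with alternating currents.

    Wires are centred on the scanner midline x = 0 with uniform pitch; the
    centre wire carries positive current and neighbours alternate sign, so
    for an odd wire count the array is mirror-symmetric about x = 0.
    """
    if n_wires < 2:
        raise ValueError("undulator needs at least 2 wires")
    y0 = y_center_cm - wire_length_cm / 2
    y1 = y_center_cm + wire_length_cm / 2
    segments = []
    for k in range(n_wires):
        x = (k - (n_wires - 1) / 2) * pitch_cm
        sign = 1.0 if (k - (n_wires - 1) // 2) % 2 == 0 else -1.0
        segments.append(WireSegment((x, y0, z_cm), (x, y1, z_cm), sign))
    return CoilSpec("exciter", tuple(segments), label="undulator")


def _rectangle_loop(
    x0: float, x1: float, y0: float, y1: float, z: float, sign: float
) -> list[WireSegment]:
    """A rectangular loop in a z-plane; sign=+1 winds counter-clockwise."""
    corners = [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]
    if sign < 0:
        corners = corners[::-1]
    segs = []
    for (xa, ya), (xb, yb) in zip(corners, corners[1:] + corners[:1]):
        segs.append(WireSegment((xa, ya, z), (xb, yb, z), 1.0))
    return segs


def make_butterfly(
    lobe_width_cm: float,
    y_edge_cm: float,
    lobe_height_cm: float,
    z_cm: float,
    label: str = "",
    center_x_cm: float = 0.0,
) -> CoilSpec:
    """A butterfly receiver: two counter-wound lobes sharing the horizontal
    edge at ``y_edge_cm``, each ``lobe_height_cm`` tall and centred on
    ``center_x_cm``."""
    if lobe_width_cm <= 0 or lobe_height_cm <= 0:
        raise ValueError("butterfly lobes must have positive extent")
    x0 = center_x_cm - lobe_width_cm / 2
    x1 = center_x_cm + lobe_width_cm / 2
    segs = _rectangle_loop(x0, x1, y_edge_cm - lobe_height_cm, y_edge_cm, z_cm, +1.0)
    segs += _rectangle_loop(x0, x1, y_edge_cm, y_edge_cm + lobe_height_cm, z_cm, -1.0)
    return CoilSpec("receiver", tuple(segs), label=label)


def make_receiver_array(
    body_extent_cm: tuple[float, float, float] = (50.0, 28.0, 24.0),
    wide_lobe_cm: float = 11.0,
    narrow_lobe_cm: float = 11.0 / 3.0,
    wide_z_offset_cm: float = 5.0,
    narrow_z_offset_cm: float = 7.0,
) -> list[CoilSpec]:
    """Six butterfly receivers: three wide and three narrow, stacked in y.

    The shared lobe edges sit at 1/4, 1/2 and 3/4 of the body height with
    lobes a quarter-height tall, so the six antisymmetry planes tile the
    body vertically (an object on one receiver's null plane is seen by the
    others).  Wide and narrow coils (the narrow ones slightly further from
    the body) weight depth differently, improving z-resolution; the
    vertical stacking resolves y.
    """
    _, ey, ez = body_extent_cm
    h = ey / 4.0
    coils = []
    for j, y_edge in enumerate((ey / 4, ey / 2, 3 * ey / 4)):
        coils.append(
            make_butterfly(
                wide_lobe_cm, y_edge, h, ez + wide_z_offset_cm,
                label=f"R{j + 1}-wide",
            )
        )
    for j, y_edge in enumerate((ey / 4, ey / 2, 3 * ey / 4)):
        coils.append(
            make_butterfly(
                narrow_lobe_cm, y_edge, h, ez + narrow_z_offset_cm,
                label=f"R{j + 4}-narrow",
            )
        )
    return coils


# ---------------------------------------------------------------------------
# scan-position field caching


def _float_gcd(a: float, b: float) -> float:
    fa = Fraction(a).limit_denominator(10**6)
    fb = Fraction(b).limit_denominator(10**6)
    g = Fraction(math.gcd(fa.numerator * fb.denominator, fb.numerator * fa.denominator),
                 fa.denominator * fb.denominator)
    return float(g)


@dataclass
class ScanFieldTable:
    """Per-position vector potential of one coil at body sample points.

    The body slides along x by ``offsets_cm[p]`` (its local origin in the
    lab frame at scan position p).  Because offsets and the voxel lattice
    are commensurate, every required sample lies on one extended x-lattice;
    the potential is evaluated there once and per-position arrays are read
    out by index shifts, so each (coil, position) pair costs one slice
    instead of a fresh Biot-Savart evaluation.

    ``lattice`` selects the sample points within a voxel: "centers" (voxel
    centres, used for eddy-current projection), or "edges_x"/"edges_y"/
    "edges_z" (midpoints of the voxel-to-voxel edges along one axis, used
    for the EMF source terms of the network model).
    """

    coil: CoilSpec
    grid: VoxelGrid
    offsets_cm: np.ndarray
    lattice: str = "centers"
    _table: np.ndarray = field(init=False, repr=False)
    _x_step_idx: int = field(init=False)
    _offset_idx: np.ndarray = field(init=False)
    _nx: int = field(init=False)

    def __post_init__(self) -> None:
        xs, ys, zs = [np.asarray(c) for c in self.grid.centers_cm()]
        h = self.grid.voxel_cm
        if self.lattice == "edges_x":
            xs = xs[:-1] + h / 2
        elif self.lattice == "edges_y":
            ys = ys[:-1] + h / 2
        elif self.lattice == "edges_z":
            zs = zs[:-1] + h / 2
        elif self.lattice != "centers":
            raise ValueError(f"unknown lattice {self.lattice!r}")
        self._nx = len(xs)

        offsets = np.asarray(self.offsets_cm, dtype=float)
        if len(offsets) > 1:
            steps = np.diff(offsets)
            step = float(steps[0])
            if not np.allclose(steps, step):
                raise ValueError("scan offsets must be uniformly spaced")
            g = _float_gcd(abs(step), h)
        else:
            g = h
        # extended lattice along x covering all positions
        span_idx = int(round(((xs[-1] - xs[0]) + (offsets[-1] - offsets[0])) / g))
        x0 = xs[0] + offsets[0]
        x_ext = x0 + np.arange(span_idx + 1) * g
        self._x_step_idx = int(round(h / g))
        self._offset_idx = np.round((offsets - offsets[0]) / g).astype(int)

        pts = np.empty((len(x_ext), len(ys), len(zs), 3))
        pts[..., 0] = x_ext[:, None, None]
        pts[..., 1] = ys[None, :, None]
        pts[..., 2] = zs[None, None, :]
        self._table = coil_potential(self.coil, pts)

    def at(self, position: int) -> np.ndarray:
        """Potential sampled at the body lattice for scan position index."""
        start = self._offset_idx[position]
        idx = start + np.arange(self._nx) * self._x_step_idx
        return self._table[idx]

    def direct(self, position: int) -> np.ndarray:
        """Uncached evaluation at the same points (for verification)."""
        xs, ys, zs = [np.asarray(c) for c in self.grid.centers_cm()]
        h = self.grid.voxel_cm
        if self.lattice == "edges_x":
            xs = xs[:-1] + h / 2
        elif self.lattice == "edges_y":
            ys = ys[:-1] + h / 2
        elif self.lattice == "edges_z":
            zs = zs[:-1] + h / 2
        pts = np.empty((len(xs), len(ys), len(zs), 3))
        pts[..., 0] = xs[:, None, None] + self.offsets_cm[position]
        pts[..., 1] = ys[None, :, None]
        pts[..., 2] = zs[None, None, :]
        return coil_potential(self.coil, pts)


def precompute_receiver_maps(
    receivers: list[CoilSpec],
    grid: VoxelGrid,
    offsets_cm: np.ndarray,
) -> list[ScanFieldTable]:
    """One voxel-centre field table per receiver, shared across positions."""
    return [ScanFieldTable(r, grid, offsets_cm, "centers") for r in receivers]


def primary_coupling(
    exciter: CoilSpec, receiver: CoilSpec, n_quad: int = 16
) -> float:
    """Direct flux coupling of the exciter into a receiver loop.

    Computed as the circulation of the exciter vector potential along the
    receiver winding (equal to the mutual flux by Stokes' theorem), with
    Gauss-Legendre quadrature along each receiver segment.  For butterflies
    on the scanner midline this cancels by symmetry — the gradiometric
    design goal.
    """
    nodes, weights = np.polynomial.legendre.leggauss(n_quad)
    total = 0.0
    for seg in receiver.segments:
        a = np.array(seg.start_cm)
        b = np.array(seg.end_cm)
        t = (nodes + 1) / 2
        pts = a[None, :] + t[:, None] * (b - a)[None, :]
        A = coil_potential(exciter, pts)
        # dl = (b - a) dt / 2 * w
        total += seg.current_sign * 0.5 * np.sum((A @ (b - a)) * weights)
    return float(total)
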