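"""The forward operator F: sigma -> S of magnetic induction tomography.

Physics summary.  The undulator drives a time-harmonic primary field at
~1.5 MHz.  Under the quasistatic, weak-coupling approximation the electric
field in the body is E = -i w (A - grad psi), where A is the (unit-current)
exciter vector potential and the scalar potential enforces charge
conservation div(sigma (A - grad psi)) = 0.  Discretising the body into
voxels turns this into a resistor network: one node per conducting voxel,
edge conductances from the harmonic mean of adjacent conductivities, and
the vector potential acting as a per-edge EMF source.  Classical nodal
analysis (Kirchhoff's current law) yields a sparse symmetric linear system
for psi.  The eddy-current density J = sigma (w A - grad psi) is then
projected onto each receiver through the Geselowitz reciprocity integral

    S = integral_V  J . A_R  dV,

with A_R the unit-current vector potential of the receiver.  Because A and
sigma are real, the physical phasors are phi = -i w psi and J, S purely in
quadrature; the package stores the real quadrature amplitudes throughout,
which halves memory with no loss of information under weak coupling.

A measurement scans the body through 256 one-centimetre steps; the 25
uninformative positions at either end are trimmed, leaving 206 positions
per receiver and a flattened signal of length 6 * 206 = 1236.  Differential
signals subtract the homogeneous-background scan after independent 60 dB
noise injection into both terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu as _splu

from .coils import CoilSpec, ScanFieldTable
from .grids import ConductivityGrid, VoxelGrid


def splu(matrix):
    """Sparse LU tuned for the symmetric Kirchhoff systems solved here."""
    return _splu(
        matrix, permc_spec="MMD_AT_PLUS_A", options=dict(SymmetricMode=True)
    )

__all__ = [
    "PhysicsParams",
    "ScanConfig",
    "NetworkSystem",
    "ScanSignal",
    "assemble_network",
    "solve_potential",
    "eddy_currents",
    "receiver_projection",
    "ForwardContext",
    "scan_body",
    "add_noise",
    "differential_signal",
]


@dataclass(frozen=True)
class PhysicsParams:
    """Excitation and scaling constants.

    ``signal_gain`` is an arbitrary overall scale (absolute receiver units
    are not reproducible without the full hardware chain); it is typically
    calibrated once so a reference perturbation gives an order-1 signal.
    ``emf_rule`` selects how the exciter potential enters the edge EMFs:
    evaluation at the edge midpoint (default) or the two-point trapezoid
    average of the adjacent voxel centres.
    """

    frequency_hz: float = 1.5e6
    signal_gain: float = 1.0
    emf_rule: str = "midpoint"

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")
        if self.emf_rule not in ("midpoint", "trapezoid"):
            raise ValueError(f"unknown emf_rule {self.emf_rule!r}")

    @property
    def omega(self) -> float:
        return 2 * math.pi * self.frequency_hz


@dataclass(frozen=True)
class ScanConfig:
    """Scan range: total positions, 1 cm steps, symmetric edge trimming."""

    positions: int = 256
    trim: int = 25
    step_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.trim < 0 or 2 * self.trim >= self.positions:
            raise ValueError(
                f"trim {self.trim} must satisfy 0 <= 2*trim < positions "
                f"({self.positions})"
            )

    @property
    def kept_positions(self) -> int:
        return self.positions - 2 * self.trim

    def offsets_cm(self, body_extent_x: float, trimmed: bool = True) -> np.ndarray:
        """Lab-frame x of the body's local origin at each scan position.

        The scan is centred on the coil midline x = 0.
        """
        p = np.arange(self.positions)
        centers = (p - (self.positions - 1) / 2) * self.step_cm
        offs = centers - body_extent_x / 2
        if trimmed:
            offs = offs[self.trim : self.positions - self.trim]
        return offs


@dataclass
class ScanSignal:
    """A 6 x P real receiver signal matrix (quadrature amplitudes)."""

    values: np.ndarray
    kind: str = "S_E"  # "S_norm" | "S_E" | "S_Diff"
    noise_db: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("signal must be a 2D (receivers x positions) array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal contains non-finite values")

    def flatten(self) -> np.ndarray:
        """Receiver traces concatenated: [r1 trace | r2 trace | ...]."""
        return self.values.reshape(-1)


# ---------------------------------------------------------------------------
# network assembly and solve


@dataclass
class NetworkSystem:
    """The discrete Kirchhoff system L psi = D^T (G * V) for one body state.

    Nodes are the conducting (sigma > 0) voxels; air and sigma = 0 regions
    carry no current and are excluded.  ``laplacian`` is symmetric with zero
    row sums before grounding; grounding adds 1 to the diagonal of one
    reference node per connected component, which pins psi = 0 there without
    perturbing the (compatible) solution.
    """

    grid: VoxelGrid
    node_index: np.ndarray  # (nx, ny, nz) int, -1 where non-conducting
    n_nodes: int
    laplacian: sp.csc_matrix
    incidence: sp.csr_matrix  # edges x nodes, +1 head / -1 tail
    conductance: np.ndarray  # per-edge G
    edge_axis: np.ndarray  # 0/1/2 per edge
    edge_cell: np.ndarray  # (n_edges, 3) index of the tail voxel
    ref_nodes: np.ndarray
    omega: float
    conducting_mask: np.ndarray = field(repr=False, default=None)

    def edge_emf(self, A_fields: dict[str, np.ndarray]) -> np.ndarray:
        """Per-edge EMF V_e = w * A(edge) . (r_head - r_tail).

        ``A_fields`` maps lattice names ("centers" and/or "edges_x/y/z") to
        potential arrays; the midpoint rule reads the edge lattices, the
        trapezoid rule averages the two centre values.
        """
        h = self.grid.voxel_cm
        emf = np.empty(len(self.conductance))
        for ax, name in enumerate(("edges_x", "edges_y", "edges_z")):
            m = self.edge_axis == ax
            if not np.any(m):
                continue
            cells = self.edge_cell[m]
            if name in A_fields:
                A_mid = A_fields[name][cells[:, 0], cells[:, 1], cells[:, 2], ax]
            else:
                Ac = A_fields["centers"]
                head = cells.copy()
                head[:, ax] += 1
                A_mid = 0.5 * (
                    Ac[cells[:, 0], cells[:, 1], cells[:, 2], ax]
                    + Ac[head[:, 0], head[:, 1], head[:, 2], ax]
                )
            emf[m] = self.omega * A_mid * h
        return emf

    def source_vector(self, A_fields: dict[str, np.ndarray]) -> np.ndarray:
        """Nodal current injection f = D^T (G * V) for one exciter state."""
        if self.n_nodes == 0:
            return np.zeros(0)
        emf = self.edge_emf(A_fields)
        return self.incidence.T @ (self.conductance * emf)


def assemble_network(
    cgrid: ConductivityGrid,
    params: PhysicsParams,
    A_ex: dict[str, np.ndarray] | np.ndarray | None = None,
    node_order: np.ndarray | None = None,
) -> tuple[NetworkSystem, np.ndarray | None]:
    """Build the nodal-analysis system for one conductivity state.

    Edge conductance between face-adjacent voxels is the harmonic mean of
    the two conductivities times face area over centre distance (series
    resistors); an edge touching a sigma = 0 voxel therefore carries zero
    conductance and is dropped.  Returns the system and, if ``A_ex`` is
    given, the corresponding source vector.

    ``node_order`` optionally permutes node numbering (the solved signal is
    invariant under relabeling; used for verification).
    """
    sigma = cgrid.sigma
    if np.any(sigma < 0):
        raise ValueError("conductivities must be non-negative")
    grid = cgrid.grid
    cond = sigma > 0
    n_nodes = int(np.count_nonzero(cond))
    node_index = np.full(grid.shape, -1, dtype=np.int64)
    if node_order is None:
        node_index[cond] = np.arange(n_nodes)
    else:
        node_index[cond] = np.asarray(node_order)

    h = grid.voxel_cm  # face area h^2 over distance h -> factor h
    edges_rows = []
    for ax in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(None, -1)
        sl_hi[ax] = slice(1, None)
        s_a = sigma[tuple(sl_lo)]
        s_b = sigma[tuple(sl_hi)]
        both = (s_a > 0) & (s_b > 0)
        idx = np.argwhere(both)
        if idx.size == 0:
            continue
        g = (2 * s_a[both] * s_b[both] / (s_a[both] + s_b[both])) * h
        head = idx.copy()
        head[:, ax] += 1
        tail_nodes = node_index[idx[:, 0], idx[:, 1], idx[:, 2]]
        head_nodes = node_index[head[:, 0], head[:, 1], head[:, 2]]
        edges_rows.append((tail_nodes, head_nodes, g, ax, idx))

    if edges_rows:
        tails = np.concatenate([e[0] for e in edges_rows])
        heads = np.concatenate([e[1] for e in edges_rows])
        G = np.concatenate([e[2] for e in edges_rows])
        edge_axis = np.concatenate(
            [np.full(len(e[2]), e[3], dtype=np.int8) for e in edges_rows]
        )
        edge_cell = np.concatenate([e[4] for e in edges_rows])
    else:
        tails = heads = np.zeros(0, dtype=np.int64)
        G = np.zeros(0)
        edge_axis = np.zeros(0, dtype=np.int8)
        edge_cell = np.zeros((0, 3), dtype=np.int64)

    n_edges = len(G)
    rows = np.repeat(np.arange(n_edges), 2)
    cols = np.stack([heads, tails], axis=1).reshape(-1)
    vals = np.tile([1.0, -1.0], n_edges)
    D = sp.csr_matrix((vals, (rows, cols)), shape=(n_edges, max(n_nodes, 1)))
    L = (D.T @ sp.diags(G) @ D).tocsc() if n_nodes else sp.csc_matrix((1, 1))

    # ground one node per connected conducting component
    if n_nodes:
        adj = sp.csr_matrix(
            (np.ones(n_edges), (tails, heads)), shape=(n_nodes, n_nodes)
        )
        n_comp, labels = connected_components(adj, directed=False)
        ref = np.array(
            [int(np.argmax(labels == c)) for c in range(n_comp)], dtype=np.int64
        )
        L = L + sp.csc_matrix(
            (np.ones(len(ref)), (ref, ref)), shape=L.shape
        )
    else:
        ref = np.zeros(0, dtype=np.int64)

    system = NetworkSystem(
        grid=grid,
        node_index=node_index,
        n_nodes=n_nodes,
        laplacian=L,
        incidence=D,
        conductance=G,
        edge_axis=edge_axis,
        edge_cell=edge_cell,
        ref_nodes=ref,
        omega=params.omega,
        conducting_mask=cond,
    )
    source = None
    if A_ex is not None:
        if isinstance(A_ex, np.ndarray):
            A_ex = {"centers": A_ex}
        source = system.source_vector(A_ex)
    return system, source


def solve_potential(
    system: NetworkSystem,
    sources: np.ndarray,
    check_residual: bool = False,
    residual_tol: float = 1e-10,
) -> np.ndarray:
    """Solve the grounded Kirchhoff system for the auxiliary potential psi.

    ``sources`` is (n_nodes,) or (n_nodes, P) for P excitation states; the
    solution satisfies Kirchhoff's current law at every non-reference node
    and psi = 0 at the reference nodes.
    """
    if system.n_nodes == 0:
        return np.zeros_like(sources)
    sources = np.asarray(sources, dtype=float)
    if sources.shape[0] != system.n_nodes:
        raise ValueError("source vector does not match node count")
    lu = splu(system.laplacian)
    psi = lu.solve(sources)
    if check_residual:
        res = system.laplacian @ psi - sources
        scale = max(float(np.max(np.abs(sources))), 1e-300)
        rel = float(np.max(np.abs(res))) / scale
        if rel > residual_tol:
            raise RuntimeError(f"Kirchhoff residual {rel:.2e} above tolerance")
    return psi


def _masked_gradient(psi: np.ndarray, cond: np.ndarray, h: float) -> np.ndarray:
    """Gradient of psi over the conducting region, batched over axis 0.

    Central differences where both along-axis neighbours conduct, one-sided
    where only one does, zero where neither (psi is meaningless outside the
    conducting mask and never read there).
    """
    grad = np.empty(psi.shape + (3,))
    for ax in range(3):
        axis = ax + 1  # psi is (P, nx, ny, nz)
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(None, -1)
        sl_hi[ax] = slice(1, None)
        valid = cond[tuple(sl_lo)] & cond[tuple(sl_hi)]

        d = np.diff(psi, axis=axis)
        d /= h
        d *= valid  # one-sided difference, defined only across conducting edges

        num = np.zeros(psi.shape)
        den = np.zeros(cond.shape, dtype=np.int8)
        num[(slice(None),) + tuple(sl_lo)] += d
        num[(slice(None),) + tuple(sl_hi)] += d
        den[tuple(sl_lo)] += valid
        den[tuple(sl_hi)] += valid
        num /= np.maximum(den, 1)  # mean of the valid one-sided differences
        grad[..., ax] = num
    return grad


def eddy_currents(
    psi_grid: np.ndarray,
    A_centers: np.ndarray,
    cgrid: ConductivityGrid,
    params: PhysicsParams,
) -> np.ndarray:
    """Quadrature eddy-current density J = sigma (w A - grad psi).

    ``psi_grid`` is (P, nx, ny, nz) with the solved EMFs already carrying
    the factor w (so grad psi enters without an extra w); ``A_centers`` is
    (P, nx, ny, nz, 3).  J vanishes identically where sigma = 0.
    """
    sigma = cgrid.sigma
    cond = sigma > 0
    grad = _masked_gradient(psi_grid, cond, cgrid.grid.voxel_cm)
    J = sigma[None, ..., None] * (params.omega * A_centers - grad)
    J[:, ~cond] = 0.0
    return J


def receiver_projection(
    J: np.ndarray, A_R: np.ndarray, grid: VoxelGrid, params: PhysicsParams
) -> np.ndarray:
    """Geselowitz reciprocity integral S = gain * sum(J . A_R) dV.

    Midpoint-rule quadrature over voxel centres; broadcasts over leading
    batch axes of J and A_R.
    """
    if J.shape[-4:] != A_R.shape[-4:]:
        raise ValueError(
            f"J sampling {J.shape[-4:]} does not match receiver map "
            f"{A_R.shape[-4:]}"
        )
    dv = grid.voxel_cm**3
    return params.signal_gain * dv * np.einsum("...xyzc,...xyzc->...", J, A_R)


# ---------------------------------------------------------------------------
# scanning


class ForwardContext:
    """Caches coil field tables and the background scan for one geometry.

    Building the Biot-Savart tables is the expensive geometric step; the
    context shares them across every conductivity state simulated on the
    same (grid, coils, scan) combination.
    """

    def __init__(
        self,
        grid: VoxelGrid,
        exciter: CoilSpec,
        receivers: list[CoilSpec],
        params: PhysicsParams = PhysicsParams(),
        scan: ScanConfig = ScanConfig(),
        position_block: int = 32,
        stack_budget: float = 2e7,
    ) -> None:
        self.grid = grid
        self.exciter = exciter
        self.receivers = receivers
        self.params = params
        self.scan = scan
        self.position_block = position_block
        offs = scan.offsets_cm(grid.extent_cm[0])
        self.offsets = offs
        lattices = ["centers"]
        if params.emf_rule == "midpoint":
            lattices += ["edges_x", "edges_y", "edges_z"]
        self.exciter_tables = {
            lat: ScanFieldTable(exciter, grid, offs, lat) for lat in lattices
        }
        self.receiver_tables = [
            ScanFieldTable(r, grid, offs, "centers") for r in receivers
        ]
        self._s_norm: ScanSignal | None = None
        # small problems: stack per-position fields once and vectorise the
        # whole scan (memory ~ stack_budget doubles); large grids fall back
        # to position blocks
        self._stacked = len(offs) * grid.n_voxels * 3 * (1 + len(receivers)) <= stack_budget
        if self._stacked:
            P = len(offs)
            self._A_centers_all = np.stack(
                [self.exciter_tables["centers"].at(p) for p in range(P)]
            )
            self._A_edges_all = {}
            for lat in ("edges_x", "edges_y", "edges_z"):
                if lat in self.exciter_tables:
                    self._A_edges_all[lat] = np.stack(
                        [self.exciter_tables[lat].at(p) for p in range(P)]
                    )
            self._A_R_all = np.stack(
                [
                    np.stack([t.at(p) for p in range(P)])
                    for t in self.receiver_tables
                ]
            )

    @property
    def n_positions(self) -> int:
        return len(self.offsets)

    def simulate(self, cgrid: ConductivityGrid) -> ScanSignal:
        """Noise-free scan of one conductivity state: a 6 x P signal."""
        if cgrid.grid.shape != self.grid.shape:
            raise ValueError("conductivity grid does not match context grid")
        if np.any(cgrid.sigma < 0) or np.any(cgrid.sigma > 1):
            raise ValueError("conductivities must lie in [0, 1]")
        system, _ = assemble_network(cgrid, self.params)
        P = self.n_positions
        n_rx = len(self.receivers)
        out = np.zeros((n_rx, P))
        if system.n_nodes == 0:
            return ScanSignal(out, kind="S_E")
        idx = system.node_index[system.conducting_mask]
        lu = splu(system.laplacian)
        if self._stacked:
            return self._simulate_stacked(cgrid, system, lu, idx)
        for start in range(0, P, self.position_block):
            block = range(start, min(start + self.position_block, P))
            A_blocks = {
                lat: np.stack([t.at(p) for p in block])
                for lat, t in self.exciter_tables.items()
            }
            B = len(A_blocks["centers"])
            sources = np.empty((system.n_nodes, B))
            for b in range(B):
                fields = {lat: arr[b] for lat, arr in A_blocks.items()}
                sources[:, b] = system.source_vector(fields)
            psi_nodes = lu.solve(sources)
            psi = np.zeros((B,) + self.grid.shape)
            psi[:, system.conducting_mask] = psi_nodes[idx].T
            J = eddy_currents(psi, A_blocks["centers"], cgrid, self.params)
            for r, table in enumerate(self.receiver_tables):
                A_R = np.stack([table.at(p) for p in block])
                out[r, list(block)] = receiver_projection(
                    J, A_R, self.grid, self.params
                )
        return ScanSignal(out, kind="S_E")

    def _simulate_stacked(self, cgrid, system, lu, idx) -> ScanSignal:
        """All-positions vectorised scan using the precomputed field stacks."""
        P = self.n_positions
        h = self.grid.voxel_cm
        names = ("edges_x", "edges_y", "edges_z")
        V = np.empty((len(system.conductance), P))
        for ax, name in enumerate(names):
            m = system.edge_axis == ax
            if not np.any(m):
                continue
            cells = system.edge_cell[m]
            if name in self._A_edges_all:
                A_mid = self._A_edges_all[name][
                    :, cells[:, 0], cells[:, 1], cells[:, 2], ax
                ]
            else:
                head = cells.copy()
                head[:, ax] += 1
                Ac = self._A_centers_all
                A_mid = 0.5 * (
                    Ac[:, cells[:, 0], cells[:, 1], cells[:, 2], ax]
                    + Ac[:, head[:, 0], head[:, 1], head[:, 2], ax]
                )
            V[m] = (system.omega * h) * A_mid.T
        sources = system.incidence.T @ (system.conductance[:, None] * V)
        psi_nodes = lu.solve(sources)
        psi = np.zeros((P,) + self.grid.shape)
        psi[:, system.conducting_mask] = psi_nodes[idx].T
        J = eddy_currents(psi, self._A_centers_all, cgrid, self.params)
        dv = h**3
        out = self.params.signal_gain * dv * np.einsum(
            "rpxyzc,pxyzc->rp", self._A_R_all, J, optimize=True
        )
        return ScanSignal(out, kind="S_E")

    def background(self, sigma: float = 0.5) -> ScanSignal:
        """The homogeneous-body reference scan S_norm (cached)."""
        if self._s_norm is None:
            from .grids import uniform_conductivity

            sig = self.simulate(uniform_conductivity(self.grid, sigma))
            self._s_norm = ScanSignal(sig.values, kind="S_norm")
        return self._s_norm

    def forward_operator(self, sigma_vector: np.ndarray) -> np.ndarray:
        """F: sigma in [0,1]^n (Fortran-flattened fine grid) -> flat signal."""
        from .grids import unflatten_fortran

        cgrid = unflatten_fortran(np.asarray(sigma_vector), self.grid)
        return self.simulate(cgrid).flatten()


def scan_body(
    cgrid: ConductivityGrid,
    exciter: CoilSpec,
    receivers: list[CoilSpec],
    params: PhysicsParams = PhysicsParams(),
    scan: ScanConfig = ScanConfig(),
) -> ScanSignal:
    """One-shot scan of a conductivity state (builds a fresh context)."""
    ctx = ForwardContext(cgrid.grid, exciter, receivers, params, scan)
    return ctx.simulate(cgrid)


# ---------------------------------------------------------------------------
# noise and differential signals


def add_noise(
    signal: ScanSignal,
    snr_db: float | None,
    rng: np.random.Generator,
    reference: ScanSignal | None = None,
) -> ScanSignal:
    """Additive white Gaussian noise at a prescribed signal-to-noise ratio.

    The noise RMS is RMS(signal) / 10^(snr_db/20) over the full matrix.
    ``snr_db=None`` means noise-free (identity).  For an all-zero signal the
    RMS is taken from ``reference`` (typically the paired background scan).
    """
    if snr_db is None:
        return signal
    if not math.isfinite(snr_db):
        return signal
    rms = float(np.sqrt(np.mean(signal.values**2)))
    if rms == 0.0:
        if reference is None:
            raise ValueError(
                "cannot scale noise for an all-zero signal without a reference"
            )
        rms = float(np.sqrt(np.mean(reference.values**2)))
    noise_rms = rms / 10 ** (snr_db / 20)
    noisy = signal.values + rng.normal(0.0, noise_rms, size=signal.values.shape)
    return ScanSignal(noisy, kind=signal.kind, noise_db=snr_db)


def differential_signal(
    s_e: ScanSignal,
    s_norm: ScanSignal,
    snr_db: float | None = None,
    rng: np.random.Generator | None = None,
) -> ScanSignal:
    """S_Diff = S_E - S_norm, after independent noise injection into both.

    This mimics subtracting a separately measured background scan: each
    term receives its own noise realisation, so the differential noise
    variance is twice the single-scan value.
    """
    if s_e.values.shape != s_norm.values.shape:
        raise ValueError("S_E and S_norm shapes differ")
    if snr_db is not None:
        if rng is None:
            raise ValueError("rng required when adding noise")
        s_e = add_noise(s_e, snr_db, rng, reference=s_norm)
        s_norm = add_noise(s_norm, snr_db, rng)
    return ScanSignal(s_e.values - s_norm.values, kind="S_Diff", noise_db=snr_db)
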