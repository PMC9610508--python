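"""Nodal-analysis solve, eddy currents, Geselowitz projection, scanning,
noise and differential signals."""

import numpy as np
import pytest

from mitreco import forward
from mitreco.forward import (
    PhysicsParams,
    ScanConfig,
    ScanSignal,
    add_noise,
    assemble_network,
    differential_signal,
    eddy_currents,
    receiver_projection,
    solve_potential,
)
from mitreco.grids import ConductivityGrid, make_body_grid, uniform_conductivity


from reference_oracles import dense_reference_solution


class TestAssembly:
    def test_uniform_sigma_zero_potential_without_sources(self):
        grid = make_body_grid((3, 3, 3), 1)
        system, src = assemble_network(
            uniform_conductivity(grid), PhysicsParams(),
            A_ex=np.zeros(grid.shape + (3,)),
        )
        assert np.allclose(src, 0)
        psi = solve_potential(system, src)
        assert np.allclose(psi, 0)

    def test_two_voxel_network_hand_solution(self):
        """Single edge with conductance G and EMF V: potential difference
        across the edge equals V (no other current path)."""
        grid = make_body_grid((2, 1, 1), 1)
        cgrid = ConductivityGrid(grid, np.full((2, 1, 1), 0.5))
        A = np.zeros((2, 1, 1, 3))
        A[..., 0] = 2.0  # uniform x-directed potential
        params = PhysicsParams()
        system, src = assemble_network(cgrid, params, A_ex=A)
        psi = solve_potential(system, src)
        emf = params.omega * 2.0 * 1.0  # omega * A_x * h
        assert psi[1] - psi[0] == pytest.approx(emf, rel=1e-12)

    def test_sigma_zero_blocks_edge(self):
        grid = make_body_grid((2, 1, 1), 1)
        cgrid = ConductivityGrid(grid, np.array([[[0.5]], [[0.0]]]))
        system, _ = assemble_network(cgrid, PhysicsParams())
        assert system.n_nodes == 1
        assert len(system.conductance) == 0

    def test_laplacian_symmetric_zero_row_sums(self, rng):
        grid = make_body_grid((3, 2, 2), 1)
        cgrid = ConductivityGrid(grid, rng.uniform(0.1, 1, grid.shape))
        system, _ = assemble_network(cgrid, PhysicsParams())
        L = system.laplacian.toarray()
        # undo the grounding diagonal before checking pure-KCL structure
        for r in system.ref_nodes:
            L[r, r] -= 1.0
        assert np.allclose(L, L.T)
        assert np.allclose(L.sum(axis=1), 0, atol=1e-12)

    def test_negative_conductivity_rejected(self):
        grid = make_body_grid((2, 1, 1), 1)
        cgrid = ConductivityGrid(grid, np.array([[[-0.1]], [[0.5]]]))
        with pytest.raises(ValueError, match="non-negative"):
            assemble_network(cgrid, PhysicsParams())


class TestSolve:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_oracle(self, seed):
        """Sparse nodal solve == dense loop-built oracle, including a
        sigma = 0 inclusion (trapezoid EMF rule to match the oracle)."""
        rng = np.random.default_rng(seed)
        grid = make_body_grid((4, 3, 3), 1)
        sigma = rng.uniform(0.1, 1.0, grid.shape)
        if seed == 2:
            sigma[1:3, 1, 1] = 0.0  # punch an insulating hole
        A = rng.normal(size=grid.shape + (3,))
        params = PhysicsParams(emf_rule="trapezoid")
        system, src = assemble_network(
            ConductivityGrid(grid, sigma), params, A_ex=A
        )
        psi = solve_potential(system, src, check_residual=True)
        full = np.zeros(grid.shape)
        full[system.conducting_mask] = psi[
            system.node_index[system.conducting_mask]
        ]
        oracle = dense_reference_solution(sigma, A, params)
        assert np.allclose(full, oracle, rtol=1e-9, atol=1e-9 * np.abs(oracle).max())

    def test_source_scaling_linearity(self, rng):
        grid = make_body_grid((3, 3, 3), 1)
        cgrid = ConductivityGrid(grid, rng.uniform(0.2, 1, grid.shape))
        A = rng.normal(size=grid.shape + (3,))
        system, src = assemble_network(cgrid, PhysicsParams(), A_ex=A)
        psi = solve_potential(system, src)
        psi3 = solve_potential(system, 3.0 * src)
        assert np.allclose(psi3, 3 * psi, rtol=1e-12)

    def test_disconnected_components_auto_grounded(self):
        """Two conducting islands separated by a sigma = 0 wall solve fine."""
        grid = make_body_grid((5, 1, 1), 1)
        sigma = np.array([0.5, 0.5, 0.0, 0.5, 0.5]).reshape(5, 1, 1)
        A = np.zeros(grid.shape + (3,))
        A[..., 0] = 1.0
        system, src = assemble_network(ConductivityGrid(grid, sigma),
                                       PhysicsParams(), A_ex=A)
        assert len(system.ref_nodes) == 2
        psi = solve_potential(system, src, check_residual=True)
        assert np.all(np.isfinite(psi))

    def test_kirchhoff_conservation(self, rng):
        grid = make_body_grid((4, 4, 4), 1)
        cgrid = ConductivityGrid(grid, rng.uniform(0.1, 1, grid.shape))
        A = rng.normal(size=grid.shape + (3,))
        system, src = assemble_network(cgrid, PhysicsParams(), A_ex=A)
        # raises if the relative KCL residual exceeds 1e-10 at any node
        solve_potential(system, src, check_residual=True, residual_tol=1e-10)


class TestEddyCurrents:
    def test_zero_sigma_zero_current(self):
        grid = make_body_grid((3, 3, 3), 1)
        cgrid = ConductivityGrid(grid, np.zeros(grid.shape))
        psi = np.zeros((1,) + grid.shape)
        A = np.ones((1,) + grid.shape + (3,))
        J = eddy_currents(psi, A, cgrid, PhysicsParams())
        assert np.all(J == 0)

    def test_uniform_a_zero_psi_gives_sigma_omega_a(self):
        grid = make_body_grid((3, 3, 3), 1)
        params = PhysicsParams()
        cgrid = uniform_conductivity(grid, 0.5)
        psi = np.zeros((1,) + grid.shape)
        A = np.full((1,) + grid.shape + (3,), 2.0)
        J = eddy_currents(psi, A, cgrid, params)
        assert np.allclose(J, 0.5 * params.omega * 2.0)

    def test_current_vanishes_in_insulating_inclusion(self, rng):
        grid = make_body_grid((4, 4, 4), 1)
        sigma = np.full(grid.shape, 0.5)
        sigma[1:3, 1:3, 1:3] = 0.0
        psi = rng.normal(size=(2,) + grid.shape)
        A = rng.normal(size=(2,) + grid.shape + (3,))
        J = eddy_currents(psi, A, ConductivityGrid(grid, sigma), PhysicsParams())
        assert np.all(J[:, 1:3, 1:3, 1:3] == 0)

    def test_interior_gradient_is_central_difference(self):
        grid = make_body_grid((5, 3, 3), 1)
        cgrid = uniform_conductivity(grid, 1.0)
        psi = np.zeros((1,) + grid.shape)
        psi[0, :, 1, 1] = [0.0, 1.0, 4.0, 9.0, 16.0]
        params = PhysicsParams()
        J = eddy_currents(psi, np.zeros((1,) + grid.shape + (3,)), cgrid, params)
        # J_x = -sigma * dpsi/dx; central at x=2: (9-1)/2 = 4
        assert J[0, 2, 1, 1, 0] == pytest.approx(-4.0)
        # one-sided at the x=0 boundary: (1-0)/1 = 1
        assert J[0, 0, 1, 1, 0] == pytest.approx(-1.0)


class TestProjection:
    def test_zero_inputs(self):
        grid = make_body_grid((2, 2, 2), 1)
        J = np.zeros(grid.shape + (3,))
        A = np.ones(grid.shape + (3,))
        assert receiver_projection(J, A, grid, PhysicsParams()) == 0
        assert receiver_projection(A, J, grid, PhysicsParams()) == 0

    def test_single_voxel_hand_value(self):
        grid = make_body_grid((1, 1, 1), 1)
        J = np.zeros((1, 1, 1, 3))
        J[..., 0] = 1.0
        A = np.zeros((1, 1, 1, 3))
        A[..., 0] = 2.0
        got = receiver_projection(J, A, grid, PhysicsParams(signal_gain=1.0))
        assert got == pytest.approx(2.0)  # J.A * volume(1) * gain(1)

    def test_shape_mismatch_rejected(self):
        grid = make_body_grid((2, 2, 2), 1)
        with pytest.raises(ValueError, match="does not match"):
            receiver_projection(
                np.zeros((2, 2, 2, 3)), np.zeros((2, 2, 1, 3)), grid,
                PhysicsParams(),
            )


class TestScan:
    def test_nonconducting_body_zero_signal(self, mini_context):
        grid = mini_context.grid
        sig = mini_context.simulate(ConductivityGrid(grid, np.zeros(grid.shape)))
        assert np.all(sig.values == 0)
        assert sig.values.shape == (6, mini_context.scan.kept_positions)

    def test_zero_perturbation_zero_differential(self, mini_context):
        s_norm = mini_context.background()
        s_e = mini_context.simulate(uniform_conductivity(mini_context.grid))
        d = differential_signal(s_e, s_norm)
        assert np.all(d.values == 0)

    def test_insulating_perturbation_stronger_than_conductive(self, mini_context):
        """sigma = 0 anomalies give larger |S_Diff| than sigma = 1 at the
        same geometry in a 0.5 S/m background."""
        from mitreco.grids import CuboidPerturbation, stamp_perturbations

        s_norm = mini_context.background()
        box = ((2.0, 1.0, 1.0), (4.0, 3.0, 3.0))
        d = {}
        for sig_val in (0.0, 1.0):
            cg = stamp_perturbations(
                mini_context.grid, [CuboidPerturbation(*box, sig_val)]
            )
            d[sig_val] = np.abs(
                differential_signal(mini_context.simulate(cg), s_norm).values
            ).max()
        assert d[0.0] > 2 * d[1.0]

    def test_mirrored_body_reverses_scan(self, mini_context):
        """Mirroring the conductivity about the scan midline time-reverses
        the signal traces (up to receiver sign conventions)."""
        from mitreco.grids import CuboidPerturbation, stamp_perturbations

        cg = stamp_perturbations(
            mini_context.grid, [CuboidPerturbation((1, 1, 1), (3, 3, 3), 0.0)]
        )
        mirrored = ConductivityGrid(mini_context.grid, cg.sigma[::-1].copy())
        s = mini_context.simulate(cg).values
        sm = mini_context.simulate(mirrored).values
        assert np.allclose(np.abs(sm), np.abs(s[:, ::-1]), atol=1e-9 * np.abs(s).max())

    def test_node_relabeling_leaves_signal_invariant(self, rng, mini_context):
        """Solving with a permuted node numbering gives the same potential
        field, hence the same signal."""
        grid = make_body_grid((3, 3, 3), 1)
        cgrid = ConductivityGrid(grid, rng.uniform(0.1, 1, grid.shape))
        A = rng.normal(size=grid.shape + (3,))
        params = PhysicsParams()
        sys_a, src_a = assemble_network(cgrid, params, A_ex=A)
        perm = rng.permutation(sys_a.n_nodes)
        sys_b, src_b = assemble_network(cgrid, params, A_ex=A, node_order=perm)
        psi_a = solve_potential(sys_a, src_a)
        psi_b = solve_potential(sys_b, src_b)
        full_a = np.zeros(grid.shape)
        full_b = np.zeros(grid.shape)
        full_a[sys_a.conducting_mask] = psi_a[sys_a.node_index[sys_a.conducting_mask]]
        full_b[sys_b.conducting_mask] = psi_b[sys_b.node_index[sys_b.conducting_mask]]
        # the potential is defined up to a per-component constant (the
        # grounded reference changes under relabeling); compare gauge-free
        full_a -= full_a.mean()
        full_b -= full_b.mean()
        assert np.allclose(full_a, full_b, rtol=1e-9, atol=1e-9 * np.abs(full_a).max())

    def test_doubling_frequency_doubles_signal(self, mini_geometry):
        from mitreco.grids import CuboidPerturbation, stamp_perturbations

        grid, exciter, receivers = mini_geometry
        scan = ScanConfig(positions=12, trim=2)
        cg = stamp_perturbations(grid, [CuboidPerturbation((1, 1, 1), (3, 3, 3), 0.0)])
        vals = {}
        for f in (1.5e6, 3.0e6):
            ctx = forward.ForwardContext(
                grid, exciter, receivers, PhysicsParams(frequency_hz=f), scan
            )
            vals[f] = ctx.simulate(cg).values
        assert np.allclose(vals[3.0e6], 2 * vals[1.5e6], rtol=1e-12)

    def test_forward_operator_contract(self, mini_context):
        n = mini_context.grid.n_voxels
        out = mini_context.forward_operator(np.full(n, 0.5))
        assert out.shape == (6 * mini_context.scan.kept_positions,)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            mini_context.forward_operator(np.full(n, 1.5))

    def test_trim_validation(self):
        with pytest.raises(ValueError, match="trim"):
            ScanConfig(positions=10, trim=5)
        assert ScanConfig(positions=256, trim=25).kept_positions == 206


class TestNoise:
    def test_empirical_snr(self, rng):
        signal = ScanSignal(np.sin(np.linspace(0, 20, 480)).reshape(6, 80))
        p_sig = np.mean(signal.values**2)
        p_noise = []
        for _ in range(2000):
            noisy = add_noise(signal, 60.0, rng)
            p_noise.append(np.mean((noisy.values - signal.values) ** 2))
        snr = 10 * np.log10(p_sig / np.mean(p_noise))
        assert snr == pytest.approx(60.0, abs=0.1)

    def test_noiseless_flag_identity(self, rng):
        signal = ScanSignal(np.ones((6, 10)))
        assert add_noise(signal, None, rng) is signal
        assert np.array_equal(
            add_noise(signal, np.inf, rng).values, signal.values
        )

    def test_seed_reproducibility(self):
        signal = ScanSignal(np.ones((6, 10)))
        a = add_noise(signal, 60.0, np.random.default_rng(5))
        b = add_noise(signal, 60.0, np.random.default_rng(5))
        assert np.array_equal(a.values, b.values)

    def test_zero_signal_uses_reference(self, rng):
        zero = ScanSignal(np.zeros((6, 10)))
        ref = ScanSignal(np.ones((6, 10)))
        noisy = add_noise(zero, 60.0, rng, reference=ref)
        assert np.std(noisy.values) > 0
        with pytest.raises(ValueError, match="reference"):
            add_noise(zero, 60.0, rng)


class TestDifferential:
    def test_toy_hand_value(self):
        s_e = ScanSignal(np.array([[3.0, 5.0]]))
        s_n = ScanSignal(np.array([[1.0, 2.0]]))
        assert np.array_equal(
            differential_signal(s_e, s_n).values, [[2.0, 3.0]]
        )

    def test_noise_variance_doubles(self, rng):
        base = ScanSignal(np.sin(np.linspace(0, 10, 120)).reshape(6, 20))
        rms = np.sqrt(np.mean(base.values**2))
        single_var = (rms / 1000) ** 2  # 60 dB
        diffs = [
            differential_signal(base, base, snr_db=60.0, rng=rng).values
            for _ in range(800)
        ]
        var = np.var(np.stack(diffs))
        assert var == pytest.approx(2 * single_var, rel=0.1)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes differ"):
            differential_signal(
                ScanSignal(np.zeros((6, 5))), ScanSignal(np.zeros((6, 4)))
            )
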