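"""Biot-Savart potentials, coil geometry and the scan field cache."""

import numpy as np
import pytest
from scipy.integrate import quad

from mitreco import coils
from mitreco.coils import (
    CoilSpec,
    ScanFieldTable,
    WireSegment,
    coil_potential,
    make_butterfly,
    make_receiver_array,
    make_undulator,
    primary_coupling,
    segment_vector_potential,
)
from mitreco.grids import make_body_grid


from reference_oracles import quadrature_potential


class TestSegmentPotential:
    def test_matches_quadrature_oracle(self):
        seg = WireSegment((0, -7, 0), (0, 7, 0), 1.0)
        for point in [(3.0, 1.0, 2.0), (0.5, 10.0, -0.2), (-4.0, -9.0, 1.0)]:
            got = segment_vector_potential(seg, np.array(point))
            want = quadrature_potential(seg, np.array(point))
            assert np.allclose(got, want, rtol=1e-8)

    def test_perpendicular_midpoint_closed_form(self):
        # half-length L at perpendicular distance d: ln((sqrt(L^2+d^2)+L)/(sqrt(L^2+d^2)-L))
        L, d = 5.0, 2.0
        seg = WireSegment((0, -L, 0), (0, L, 0), 1.0)
        got = segment_vector_potential(seg, np.array([d, 0.0, 0.0]))
        r = np.hypot(L, d)
        assert got[1] == pytest.approx(np.log((r + L) / (r - L)), rel=1e-12)
        assert got[0] == got[2] == 0.0

    def test_direction_and_sign(self):
        seg = WireSegment((0, 0, 0), (0, 4, 0), -1.0)
        A = segment_vector_potential(seg, np.array([1.0, 2.0, 0.0]))
        assert A[1] < 0 and A[0] == A[2] == 0.0

    def test_mirror_symmetry_about_axis(self):
        seg = WireSegment((0, 0, -3), (0, 0, 3), 1.0)
        a = segment_vector_potential(seg, np.array([2.0, 0.0, 0.0]))
        b = segment_vector_potential(seg, np.array([-2.0, 0.0, 0.0]))
        assert np.allclose(a, b)

    def test_exclusion_radius_clamps_and_counts(self):
        seg = WireSegment((0, -1, 0), (0, 1, 0), 1.0)
        before = coils.clamp_counter["clamped"]
        val = segment_vector_potential(seg, np.array([1e-6, 0.0, 0.0]))
        assert np.all(np.isfinite(val))
        assert coils.clamp_counter["clamped"] == before + 1

    def test_zero_length_segment_rejected(self):
        with pytest.raises(ValueError, match="zero length"):
            WireSegment((1, 1, 1), (1, 1, 1))


class TestCoilPotential:
    def test_single_wire_coil_identity(self, rng):
        seg = WireSegment((0, -5, 0), (0, 5, 0), 1.0)
        coil = CoilSpec("exciter", (seg,))
        pts = rng.normal(scale=4, size=(10, 3))
        assert np.array_equal(coil_potential(coil, pts),
                              segment_vector_potential(seg, pts))

    def test_undulator_equals_pairwise_sum(self, rng):
        und = make_undulator(n_wires=5, pitch_cm=2.0, wire_length_cm=10.0,
                             z_cm=-2.0, y_center_cm=0.0)
        pts = rng.normal(scale=3, size=(7, 3))
        oracle = sum(segment_vector_potential(s, pts) for s in und.segments)
        assert np.allclose(coil_potential(und, pts), oracle, rtol=1e-14)

    def test_linearity_in_current(self):
        seg1 = WireSegment((0, -5, 0), (0, 5, 0), 1.0)
        seg2 = WireSegment((0, -5, 0), (0, 5, 0), 2.0)
        p = np.array([1.0, 2.0, 3.0])
        assert np.allclose(
            2 * segment_vector_potential(seg1, p),
            segment_vector_potential(seg2, p),
        )

    def test_translation_frame_equivalence(self):
        """Shifting the evaluation points by +dx equals shifting the coil by -dx."""
        und = make_undulator(n_wires=3, pitch_cm=2.0, wire_length_cm=8.0,
                             z_cm=-2.0, y_center_cm=0.0)
        dx = 3.0
        shifted = CoilSpec(
            "exciter",
            tuple(
                WireSegment(
                    (s.start_cm[0] - dx, s.start_cm[1], s.start_cm[2]),
                    (s.end_cm[0] - dx, s.end_cm[1], s.end_cm[2]),
                    s.current_sign,
                )
                for s in und.segments
            ),
        )
        pts = np.array([[0.5, 1.0, 2.0], [2.0, -1.0, 4.0]])
        assert np.allclose(
            coil_potential(und, pts + [dx, 0, 0]),
            coil_potential(shifted, pts),
            rtol=1e-13,
        )

    def test_empty_coil_rejected(self):
        with pytest.raises(ValueError, match="no segments"):
            CoilSpec("receiver", ())

    def test_far_field_decay_along_z(self):
        und = make_undulator(n_wires=5, pitch_cm=2.0, wire_length_cm=10.0,
                             z_cm=0.0, y_center_cm=0.0)
        extent = 10.0  # coil span
        zs = np.linspace(5 * extent, 20 * extent, 40)
        pts = np.stack([np.zeros_like(zs), np.zeros_like(zs), zs], axis=1)
        mags = np.linalg.norm(coil_potential(und, pts), axis=1)
        assert np.all(np.diff(mags) < 0)


def _shift_coil(coil: CoilSpec, dx: float) -> CoilSpec:
    return CoilSpec(
        coil.role,
        tuple(
            WireSegment(
                (s.start_cm[0] + dx, s.start_cm[1], s.start_cm[2]),
                (s.end_cm[0] + dx, s.end_cm[1], s.end_cm[2]),
                s.current_sign,
            )
            for s in coil.segments
        ),
        coil.label,
    )


def _single_lobe(coil: CoilSpec, x_offset: float) -> CoilSpec:
    """One rectangle the size of a butterfly lobe, at the same location."""
    xs = [s.start_cm[0] for s in coil.segments]
    ys = [s.start_cm[1] for s in coil.segments]
    z = coil.segments[0].start_cm[2]
    y_mid = (min(ys) + max(ys)) / 2
    return CoilSpec(
        "receiver",
        tuple(
            coils._rectangle_loop(
                min(xs) + x_offset, max(xs) + x_offset, y_mid, max(ys), z, 1.0
            )
        ),
    )


class TestReceiverArray:
    def test_array_composition(self):
        rx = make_receiver_array()
        assert len(rx) == 6
        assert sum("wide" in c.label for c in rx) == 3
        assert sum("narrow" in c.label for c in rx) == 3
        # butterfly = two rectangular lobes = 8 segments
        assert all(len(c.segments) == 8 for c in rx)

    def test_gradiometric_null_aligned(self):
        """On the scanner midline the primary flux cancels exactly (the
        undulator field is even in x, the lobes are symmetric)."""
        und = make_undulator()
        for coil in make_receiver_array():
            lobe_scale = abs(
                primary_coupling(und, _single_lobe(coil, x_offset=0.0))
            ) + abs(primary_coupling(und, _single_lobe(coil, x_offset=2.75)))
            assert abs(primary_coupling(und, coil)) <= 1e-12 * max(lobe_scale, 1.0)

    @pytest.mark.parametrize("x_offset", [2.75, 5.5])
    def test_gradiometric_rejection_misaligned(self, x_offset):
        """Even displaced off the midline, primary coupling into each
        butterfly stays >= 20 dB below a single lobe of the same size."""
        und = make_undulator()
        for coil in make_receiver_array():
            shifted = _shift_coil(coil, x_offset)
            butterfly = abs(primary_coupling(und, shifted))
            lobe = abs(primary_coupling(und, _single_lobe(coil, x_offset)))
            assert butterfly < lobe * 10 ** (-20 / 20), (coil.label, x_offset)


class TestScanFieldTable:
    def test_cache_matches_direct_evaluation(self):
        grid = make_body_grid((6, 4, 4), 1)
        und = make_undulator(n_wires=3, pitch_cm=2.0, wire_length_cm=10.0,
                             z_cm=-2.0, y_center_cm=2.0)
        offsets = np.arange(-5.0, 6.0, 1.0)
        for lattice in ("centers", "edges_x", "edges_y", "edges_z"):
            table = ScanFieldTable(und, grid, offsets, lattice)
            for p in (0, 3, len(offsets) - 1):
                assert np.allclose(table.at(p), table.direct(p), rtol=1e-12), (
                    lattice, p,
                )

    def test_lattice_step_offset_shift(self):
        """Offsets one voxel apart give maps related by an x index shift."""
        grid = make_body_grid((6, 4, 4), 1)
        und = make_undulator(n_wires=3, pitch_cm=2.0, wire_length_cm=10.0,
                             z_cm=-2.0, y_center_cm=2.0)
        table = ScanFieldTable(und, grid, np.arange(-3.0, 4.0, 1.0), "centers")
        a, b = table.at(2), table.at(3)
        assert np.allclose(a[1:], b[:-1])

    def test_coarser_voxels_than_step(self):
        grid = make_body_grid((6, 4, 4), 2)
        und = make_undulator(n_wires=3, pitch_cm=2.0, wire_length_cm=10.0,
                             z_cm=-2.0, y_center_cm=2.0)
        offsets = np.arange(-2.0, 3.0, 1.0)
        table = ScanFieldTable(und, grid, offsets, "centers")
        for p in range(len(offsets)):
            assert np.allclose(table.at(p), table.direct(p), rtol=1e-12)

    def test_receiver_cache_size(self, mini_geometry):
        grid, _, receivers = mini_geometry
        offsets = np.arange(-2.0, 3.0, 1.0)
        maps = coils.precompute_receiver_maps(receivers, grid, offsets)
        assert len(maps) == 6
        assert maps[0].at(0).shape == grid.shape + (3,)
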