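import numpy as np
import pytest

from mitreco import coils, forward, grids


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mini_geometry():
    """A very small body + coil set for fast physics tests."""
    grid = grids.make_body_grid((8.0, 6.0, 6.0), 1.0)
    exciter = coils.make_undulator(
        n_wires=5, pitch_cm=2.0, wire_length_cm=16.0, z_cm=-3.0, y_center_cm=3.0
    )
    receivers = coils.make_receiver_array(
        (8.0, 6.0, 6.0),
        wide_lobe_cm=4.0,
        narrow_lobe_cm=1.5,
        wide_z_offset_cm=3.0,
        narrow_z_offset_cm=4.5,
    )
    return grid, exciter, receivers


@pytest.fixture(scope="session")
def mini_context(mini_geometry):
    grid, exciter, receivers = mini_geometry
    scan = forward.ScanConfig(positions=24, trim=4)
    return forward.ForwardContext(
        grid, exciter, receivers, forward.PhysicsParams(), scan
    )
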