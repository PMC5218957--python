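import numpy as np
import pytest

from luquant import phantoms as ph
from luquant.projector import AcquisitionSpec
from luquant.scatter import ScatterParams
from luquant.simulate import simulate_acquisition


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mini_setup():
    """Small matched-grid phantom + acquisition for fast reconstruction tests.

    Simulation runs on the reconstruction grid itself (a deliberate
    inverse-crime control: the system model is exact), with two spheres in
    a water cylinder cropped to the small field of view.
    """
    n, nz, nv = 32, 16, 30
    grid = ph.VoxelGrid((n, n, nz), 4.8)
    cfg = ph.StudyConfig(
        "mini",
        [ph.InsertSpec("sphere", (25.0, 0.0, 0.0), 30.0, 2.0, "A"),
         ph.InsertSpec("sphere", (-35.0, 15.0, 0.0), 10.0, 3.0, "B")],
        0.0, 10.0, "cold_water")
    phantom = ph.build_phantom(cfg, grid)
    acq = AcquisitionSpec(n_projections=nv, detector_shape=(n, nz), bin_size=4.8,
                          t_p=10.0, sensitivity=10.0)
    sim = simulate_acquisition(phantom, acq,
                               ScatterParams(self_scatter_fraction=0.2))
    return phantom, acq, sim
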