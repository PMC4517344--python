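import numpy as np
import pytest

from rdtsim.phantom import analytic_tube_phantom, default_params, generate_phantom
from rdtsim.pipeline import RunConfig, run_pipeline
from rdtsim.volume import CANAL, DENTIN, ToothVolume


@pytest.fixture(scope="session")
def annulus():
    """Hollow cylinder, inner 1.0 mm / outer 1.5 mm: wall 500 μm everywhere."""
    return analytic_tube_phantom(1000, 1500, 6000, 30)


@pytest.fixture(scope="session")
def default_phantom():
    """The study-condition phantom at 60 μm (two roots, curved canal,
    furcal concavity)."""
    return generate_phantom(default_params(60.0), seed=1)


def make_two_cylinder_volume(dx_um=0.0, dy_um=6000.0, voxel_um=100.0, flip_y=False):
    """Two parallel vertical cylinders (r = 1 mm) for parallax oracles.

    Cylinder A at the origin, cylinder B displaced by (dx, dy); at dy along
    the ray direction their 0° silhouettes coincide, separating at
    asin((r_a + r_b)/offset) under rotation.
    """
    r = 1000.0
    if flip_y:
        dy_um = -dy_um
    xmin, xmax = min(0, dx_um) - r - 300, max(0, dx_um) + r + 300
    ymin, ymax = min(0, dy_um) - r - 300, max(0, dy_um) + r + 300
    xs = np.arange(xmin, xmax + voxel_um, voxel_um)
    ys = np.arange(ymin, ymax + voxel_um, voxel_um)
    nz = int(3000 / voxel_um)
    X, Y = xs[:, None, None], ys[None, :, None]
    a = ((X - 0.0) ** 2 + (Y - 0.0) ** 2 <= r**2) & np.ones((1, 1, nz), bool)
    b = ((X - dx_um) ** 2 + (Y - dy_um) ** 2 <= r**2) & np.ones((1, 1, nz), bool)
    labels = np.zeros(a.shape, np.uint8)
    labels[a | b] = DENTIN
    return ToothVolume(
        labels=labels,
        voxel_size_um=voxel_um,
        origin_um=(float(xs[0]), float(ys[0]), 0.0),
        structures={"a": a, "b": b},
    )


@pytest.fixture(scope="session")
def two_cylinders():
    return make_two_cylinder_volume()


@pytest.fixture(scope="session")
def population_result(tmp_path_factory):
    """The default seeded 36-phantom study at 60 μm voxels (run once)."""
    out = tmp_path_factory.mktemp("population")
    cfg = RunConfig(n_phantoms=36, seed=1, voxel_size_um=60.0, out_dir=str(out))
    return run_pipeline(cfg)
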