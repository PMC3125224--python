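import numpy as np
import pytest

from lbstereo.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A small but fully featured phantom shared by read-only tests."""
    cfg = PhantomConfig(n_cells=40, lung_volume_cm3=2.0e-7, seed=11)
    return generate_phantom(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def sphere_cell(radius=5.0, lb_radii=(), luminal_fraction=0.5):
    """A hand-built spherical cell for analytic checks."""
    from lbstereo.phantom import Cell
    from lbstereo import geometry as geo

    lb_radii = np.asarray(lb_radii, dtype=float)
    k = len(lb_radii)
    centers = np.zeros((k, 3))
    if k:
        # place along x axis, non-overlapping, inside the cell
        x = np.cumsum(2.0 * lb_radii + 0.05) - lb_radii + 0.5 - radius / 2.0
        centers[:, 0] = x
    cos_cap = float(np.cos(geo.solve_cap_angle((1.0, 1.0, 1.0), luminal_fraction)))
    return Cell(
        id=0,
        center=np.zeros(3),
        axes=np.array([radius] * 3),
        rotation=np.eye(3),
        nucleus_center=np.array([0.0, 0.0, radius / 2.5]),
        nucleus_radius=radius / 4.0,
        nucleolus_center=np.array([0.0, 0.0, radius / 2.5]),
        nucleolus_radius=radius / 10.0,
        lb_centers=centers,
        lb_radii=lb_radii,
        luminal_cos_cap=cos_cap,
    )
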