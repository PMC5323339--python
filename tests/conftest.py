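import numpy as np
import pytest

from spectseg.fourier_surface import FourierSurface, n_coefficients
from spectseg.imaging_core import BinaryMask3D, ScalarImage3D, VoxelGrid


@pytest.fixture
def unit_sphere_surface() -> FourierSurface:
    """Order-2 coefficients tracing the unit sphere at the origin."""
    c = np.zeros((3, n_coefficients(2)))
    c[2, 1] = 0.5  # a_{z,0,1}
    c[0, 3] = 0.25  # c_{x,1,1}
    c[1, 4] = 0.25  # d_{y,1,1}
    return FourierSurface(2, c)


def sphere_image(
    radius_mm: float = 20.0,
    spacing_mm: float = 2.5,
    n: int = 40,
    inside: float = 100.0,
    outside: float = 0.0,
):
    """Binary-valued sphere centred in an n^3 grid; returns (image, truth mask)."""
    grid = VoxelGrid((n, n, n), (spacing_mm,) * 3)
    centre = spacing_mm * (n - 1) / 2.0
    xs, ys, zs = grid.world_coordinates()
    r = np.sqrt((xs - centre) ** 2 + (ys - centre) ** 2 + (zs - centre) ** 2)
    member = r <= radius_mm
    values = np.where(member, inside, outside)
    return ScalarImage3D(grid, values), BinaryMask3D(grid, member)


@pytest.fixture
def random_surfaces():
    """Seeded random coefficient sets of orders 2-4 for property tests."""
    rng = np.random.default_rng(42)
    surfaces = []
    for _ in range(20):
        order = int(rng.integers(2, 5))
        coeffs = rng.normal(0.0, 3.0, (3, n_coefficients(order)))
        surfaces.append(FourierSurface(order, coeffs))
    return surfaces
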