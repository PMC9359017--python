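import numpy as np
import pytest

from e2eqa import BinaryMask, Geometry, ImageVolume, PhantomConfig, build_phantom


@pytest.fixture
def unit_geometry():
    """12^3 grid at 1 mm isotropic spacing, origin at zero."""
    return Geometry(np.zeros(3), np.ones(3), np.full(3, 12))


@pytest.fixture(scope="session")
def phantom():
    """Default digital pelvis phantom (shared, treated as read-only)."""
    return build_phantom(PhantomConfig())


def random_mask(geometry: Geometry, rng, p: float = 0.3, ensure_nonempty: bool = True) -> BinaryMask:
    inside = rng.random(geometry.shape) < p
    if ensure_nonempty and not inside.any():
        inside[tuple(d // 2 for d in geometry.shape)] = True
    return BinaryMask(geometry, inside)


def random_blob(geometry: Geometry, rng) -> BinaryMask:
    """A random ellipsoid-ish connected mask (more surface-like than noise)."""
    shape = np.array(geometry.shape)
    center = geometry.origin + geometry.spacing * (shape - 1) * rng.uniform(0.3, 0.7, 3)
    radii = rng.uniform(0.15, 0.4, 3) * shape * geometry.spacing
    xs = geometry.axis_coords(0)[:, None, None]
    ys = geometry.axis_coords(1)[None, :, None]
    zs = geometry.axis_coords(2)[None, None, :]
    inside = (
        ((xs - center[0]) / radii[0]) ** 2
        + ((ys - center[1]) / radii[1]) ** 2
        + ((zs - center[2]) / radii[2]) ** 2
        <= 1.0
    )
    if not inside.any():
        inside[tuple(shape // 2)] = True
    return BinaryMask(geometry, inside)


def ramp_image(geometry: Geometry, axis: int = 0) -> ImageVolume:
    """f(x, y, z) = world coordinate along one axis."""
    coords = geometry.axis_coords(axis)
    shape = [1, 1, 1]
    shape[axis] = len(coords)
    values = np.broadcast_to(coords.reshape(shape), geometry.shape).astype(float)
    return ImageVolume(geometry, values.copy())
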