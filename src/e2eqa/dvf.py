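"""Synthetic 3-D Gaussian deformations: sampling, rendering, and warping.

The deformation model is a single isotropic Gaussian bump.  With per-axis
magnitude vector ``m`` (mm), center ``c`` (world mm) and standard deviation
``sigma`` (mm, the falloff of the deformation from its center), the
displacement at world point ``r`` is

    d(r) = m * exp(-||r - c||^2 / (2 sigma^2))        (per axis, mm)

so the displacement at the center equals the printed magnitude exactly.
Specifications are sampled with the center uniform inside a rectangular
parallelepiped anchored on the target (PTV) centroid, one magnitude scalar
uniform in [10, 20] mm shared across the three axes with independent random
signs, and sigma uniform in [15, 25] mm.

Warping uses the pull-back (resampling) convention of common registration
toolkits: ``output(x) = input(x + d(x))``, linear or nearest-neighbor.

A note on invertibility: the Gaussian field's Jacobian ``I + A`` has rank-1
``A``, so ``det = 1 - w(r)/sigma^2 * m.(r - c)``, minimized on the line
through ``c`` along ``m`` at distance ``sigma``, where it equals
``1 - |m| e^{-1/2} / sigma``.  Fields with ``|m| e^{-1/2} >= sigma`` fold;
with equal per-axis magnitudes this is ``sqrt(3) |m_axis| e^{-1/2} >= sigma``,
which large-magnitude/small-sigma draws from the default ranges can reach.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .errors import ValidationError
from .volumes import BinaryMask, Geometry, ImageVolume

MAGNITUDE_RANGE_MM = (10.0, 20.0)
SIGMA_RANGE_MM = (15.0, 25.0)
#: Inscribed sampling box extents: left-right, anterior-posterior,
#: superior-inferior (mm).
DEFAULT_BOX_EXTENTS_MM = (22.3, 10.6, 62.0)


@dataclass(frozen=True)
class GaussianDeformationSpec:
    """One Gaussian deformation: per-axis magnitude, center, falloff."""

    magnitude: np.ndarray  # signed mm 3-vector
    center: np.ndarray  # world mm 3-vector
    sigma: float  # mm, > 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "magnitude", np.asarray(self.magnitude, dtype=float).copy())
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).copy())
        if self.magnitude.shape != (3,) or self.center.shape != (3,):
            raise ValidationError("magnitude and center must be 3-vectors")
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValidationError("sigma must be finite and > 0")

    def to_dict(self) -> dict:
        return {
            "magnitude": [float(v) for v in self.magnitude],
            "center": [float(v) for v in self.center],
            "sigma": float(self.sigma),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GaussianDeformationSpec":
        return cls(np.asarray(data["magnitude"]), np.asarray(data["center"]), float(data["sigma"]))

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str | Path) -> "GaussianDeformationSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class SamplingBounds:
    """Randomization bounds for deformation specs.

    ``box_center``/``box_extents`` define the rectangular parallelepiped
    containing the Gaussian center; extents are full widths in mm.
    """

    box_center: np.ndarray
    box_extents: np.ndarray = field(default_factory=lambda: np.asarray(DEFAULT_BOX_EXTENTS_MM))
    magnitude_range: tuple[float, float] = MAGNITUDE_RANGE_MM
    sigma_range: tuple[float, float] = SIGMA_RANGE_MM

    def __post_init__(self) -> None:
        object.__setattr__(self, "box_center", np.asarray(self.box_center, dtype=float).copy())
        object.__setattr__(self, "box_extents", np.asarray(self.box_extents, dtype=float).copy())
        if np.any(self.box_extents <= 0):
            raise ValidationError("box extents must be > 0")
        for lo, hi in (self.magnitude_range, self.sigma_range):
            if hi < lo:
                raise ValidationError("ranges must have lo <= hi")


@dataclass
class DisplacementField:
    """Per-voxel mm displacement 3-vectors on a geometry."""

    geometry: Geometry
    vectors: np.ndarray  # shape (*geometry.shape, 3), mm

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape != self.geometry.shape + (3,):
            raise ValidationError("DVF shape must be geometry.shape + (3,)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValidationError("DVF components must be finite")


def sample_deformation_spec(bounds: SamplingBounds, seed: int) -> GaussianDeformationSpec:
    """Draw one deformation spec: center uniform in the box, one magnitude
    scalar shared across axes with independent random signs, sigma uniform."""
    rng = np.random.default_rng(seed)
    center = bounds.box_center + (rng.uniform(-0.5, 0.5, size=3) * bounds.box_extents)
    scalar = rng.uniform(*bounds.magnitude_range)
    signs = rng.integers(0, 2, size=3) * 2 - 1
    sigma = rng.uniform(*bounds.sigma_range)
    return GaussianDeformationSpec(signs * scalar, center, sigma)


def render_displacement_field(spec: GaussianDeformationSpec, geometry: Geometry) -> DisplacementField:
    """Evaluate the Gaussian displacement at every voxel center."""
    xs, ys, zs = geometry.coordinate_grids()
    d2 = (xs - spec.center[0]) ** 2 + (ys - spec.center[1]) ** 2 + (zs - spec.center[2]) ** 2
    weight = np.exp(-d2 / (2.0 * spec.sigma**2))
    vectors = weight[..., None] * spec.magnitude[None, None, None, :]
    return DisplacementField(geometry, vectors)


def grid_containing(center: np.ndarray, spacing_mm: float = 1.0, half_extent_voxels: int = 8) -> Geometry:
    """A small isotropic grid whose central voxel center sits exactly at
    ``center`` — convenient for evaluating a field at its Gaussian center."""
    center = np.asarray(center, dtype=float)
    n = 2 * half_extent_voxels + 1
    origin = center - half_extent_voxels * spacing_mm
    return Geometry(origin, np.full(3, spacing_mm), np.full(3, n))


def _pullback_coordinates(dvf: DisplacementField) -> list[np.ndarray]:
    """Fractional index coordinates of the pull-back sample points."""
    geometry = dvf.geometry
    coords = []
    for axis in range(3):
        shape = [1, 1, 1]
        shape[axis] = geometry.shape[axis]
        idx = np.arange(geometry.shape[axis], dtype=float).reshape(shape)
        coords.append(idx + dvf.vectors[..., axis] / geometry.spacing[axis])
    return [np.broadcast_to(c, geometry.shape) for c in coords]


def warp_image(
    image: ImageVolume,
    dvf: DisplacementField,
    interpolation: str = "linear",
    fill_value: float | None = None,
) -> ImageVolume:
    """Pull-back resampling: ``output(x) = input(x + d(x))``.

    Sample points falling outside the grid take ``fill_value`` (default:
    the minimum of the input image).
    """
    if image.geometry != dvf.geometry:
        raise ValidationError("image and DVF geometries differ")
    order = {"linear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise ValidationError(f"unknown interpolation {interpolation!r}")
    if fill_value is None:
        fill_value = float(np.min(image.values))
    warped = ndimage.map_coordinates(
        image.values.astype(float),
        _pullback_coordinates(dvf),
        order=order,
        mode="constant",
        cval=fill_value,
    )
    return ImageVolume(image.geometry, warped)


def warp_mask(mask: BinaryMask, dvf: DisplacementField) -> BinaryMask:
    """Nearest-neighbor pull-back of a binary mask."""
    if mask.geometry != dvf.geometry:
        raise ValidationError("mask and DVF geometries differ")
    warped = ndimage.map_coordinates(
        mask.inside.astype(np.uint8),
        _pullback_coordinates(dvf),
        order=0,
        mode="constant",
        cval=0,
    )
    return BinaryMask(mask.geometry, warped.astype(bool))


def jacobian_determinant(dvf: DisplacementField) -> np.ndarray:
    """Central-difference estimate of det(I + grad d) at every voxel.

    Values <= 0 indicate local folding (non-invertibility).
    """
    geometry = dvf.geometry
    grad = np.empty(geometry.shape + (3, 3))
    for a in range(3):  # displacement component
        for b in range(3):  # derivative axis
            grad[..., a, b] = np.gradient(dvf.vectors[..., a], geometry.spacing[b], axis=b)
    jac = grad + np.eye(3)
    return np.linalg.det(jac)


# -- MetaImage persistence of 3-component vector fields ---------------------

def write_displacement_field(dvf: DisplacementField, path: str | Path) -> None:
    import SimpleITK as sitk

    arr = np.ascontiguousarray(np.transpose(dvf.vectors, (2, 1, 0, 3)))
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetOrigin(tuple(dvf.geometry.origin))
    img.SetSpacing(tuple(dvf.geometry.spacing))
    sitk.WriteImage(img, str(path), useCompression=True)


def load_displacement_field(path: str | Path) -> DisplacementField:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    geometry = Geometry(np.asarray(img.GetOrigin()), np.asarray(img.GetSpacing()), np.asarray(img.GetSize()))
    arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0, 3))
    return DisplacementField(geometry, arr)
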