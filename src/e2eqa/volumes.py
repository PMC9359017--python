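"""Axis-aligned 3-D volume containers, mask geometry utilities, and file I/O.

All volumes in the toolkit live on a shared :class:`Geometry`: an axis-aligned
grid with 0-based indices and voxel-center sampling, axes ordered
(X = left-right, Y = anterior-posterior, Z = superior-inferior).  Arrays are
indexed ``[ix, iy, iz]`` so that the world coordinate of voxel ``i`` is
``origin + i * spacing`` (mm).  Oblique direction matrices are out of scope:
files with a non-identity direction are rejected at load time.

MetaImage (.mha) and NIfTI-1 (.nii/.nii.gz) are supported through SimpleITK.
Structure sets are stored on disk as a single uint8 label map plus a YAML
name table ``{label: roi_name}``, which enforces the shared-geometry
invariant at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import SimpleITK as sitk
import yaml
from scipy import ndimage

from .errors import FormatError, MappingError, ValidationError

#: Canonical ROI names of the pelvis study protocol.
CANONICAL_ROIS = (
    "Prostate",
    "SeminalVesicles",
    "Bladder",
    "Rectum",
    "Bowel",
    "Femur_L",
    "Femur_R",
    "CTV_7000",
    "PTV_7000",
    "Body",
)

#: The eight ROIs entering the contour-reproducibility report.
REPORT_ROIS = (
    "Bladder",
    "Bowel",
    "CTV_7000",
    "Femur_L",
    "Femur_R",
    "Prostate",
    "PTV_7000",
    "Rectum",
)

_GEOM_TOL_MM = 1e-6


@dataclass(frozen=True)
class Geometry:
    """Axis-aligned 3-D sampling grid.

    Parameters
    ----------
    origin : (3,) float
        World coordinate (mm) of the center of voxel (0, 0, 0).
    spacing : (3,) float
        Voxel edge lengths in mm, each > 0.
    size : (3,) int
        Number of voxels along (X, Y, Z), each >= 1.
    """

    origin: np.ndarray
    spacing: np.ndarray
    size: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).copy())
        object.__setattr__(self, "spacing", np.asarray(self.spacing, dtype=float).copy())
        object.__setattr__(self, "size", np.asarray(self.size, dtype=int).copy())
        for name in ("origin", "spacing", "size"):
            if getattr(self, name).shape != (3,):
                raise ValidationError(f"Geometry.{name} must be a 3-vector")
        if np.any(self.spacing <= 0):
            raise ValidationError("Geometry.spacing must be strictly positive")
        if np.any(self.size < 1):
            raise ValidationError("Geometry.size must be >= 1 along every axis")

    # -- equality within 1e-6 mm -------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Geometry):
            return NotImplemented
        return bool(
            np.array_equal(self.size, other.size)
            and np.allclose(self.origin, other.origin, atol=_GEOM_TOL_MM, rtol=0)
            and np.allclose(self.spacing, other.spacing, atol=_GEOM_TOL_MM, rtol=0)
        )

    def __hash__(self) -> int:  # frozen dataclass with arrays
        return hash((tuple(self.size), tuple(np.round(self.origin, 6)), tuple(np.round(self.spacing, 6))))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(int(n) for n in self.size)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.size[axis])

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(index, dtype=float) * self.spacing

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel index of a world point."""
        return (np.asarray(world, dtype=float) - self.origin) / self.spacing

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable world-coordinate grids (xs, ys, zs)."""
        xs = self.axis_coords(0)[:, None, None]
        ys = self.axis_coords(1)[None, :, None]
        zs = self.axis_coords(2)[None, None, :]
        return xs, ys, zs


def _check_shape(geometry: Geometry, array: np.ndarray, what: str) -> None:
    if array.shape[:3] != geometry.shape:
        raise ValidationError(
            f"{what} shape {array.shape} does not match geometry size {geometry.shape}"
        )


@dataclass
class ImageVolume:
    """A scalar volume (HU for CT, Gy for dose) on a :class:`Geometry`."""

    geometry: Geometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        _check_shape(self.geometry, self.values, "ImageVolume.values")

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.geometry, self.values.copy())


@dataclass
class BinaryMask:
    """A boolean volume marking one region of interest."""

    geometry: Geometry
    inside: np.ndarray

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside).astype(bool)
        _check_shape(self.geometry, self.inside, "BinaryMask.inside")

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.inside))

    def is_empty(self) -> bool:
        return not self.inside.any()

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.geometry, self.inside.copy())


@dataclass
class StructureSet:
    """Named binary masks sharing one geometry."""

    geometry: Geometry
    masks: dict[str, BinaryMask] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mask in self.masks.items():
            if mask.geometry != self.geometry:
                raise ValidationError(f"mask {name!r} geometry differs from the set's")

    def __getitem__(self, name: str) -> BinaryMask:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __iter__(self) -> Iterator[str]:
        return iter(self.masks)

    def add(self, name: str, mask: BinaryMask) -> None:
        if mask.geometry != self.geometry:
            raise ValidationError(f"mask {name!r} geometry differs from the set's")
        self.masks[name] = mask

    def names(self) -> list[str]:
        return list(self.masks)


# ---------------------------------------------------------------------------
# File I/O (SimpleITK; identity direction only)
# ---------------------------------------------------------------------------

def _to_sitk(geometry: Geometry, array: np.ndarray) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(array, (2, 1, 0))))
    img.SetOrigin(tuple(geometry.origin))
    img.SetSpacing(tuple(geometry.spacing))
    return img


def _from_sitk(img: sitk.Image) -> tuple[Geometry, np.ndarray]:
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise ValidationError("oblique (non-identity direction) volumes are not supported")
    geometry = Geometry(np.asarray(img.GetOrigin()), np.asarray(img.GetSpacing()), np.asarray(img.GetSize()))
    array = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return geometry, array


def write_volume(volume: ImageVolume | BinaryMask, path: str | Path, compress: bool = True) -> None:
    """Write a scalar volume or a mask (as uint8) to .mha/.nii/.nii.gz."""
    if isinstance(volume, BinaryMask):
        array: np.ndarray = volume.inside.astype(np.uint8)
    else:
        array = volume.values
    sitk.WriteImage(_to_sitk(volume.geometry, array), str(path), useCompression=compress)


def write_structure_set(
    structures: StructureSet, labels_path: str | Path, names_path: str | Path
) -> dict[int, str]:
    """Write a structure set as one uint8 label map plus a YAML name table.

    Overlapping masks are painted in insertion order (later masks win), so a
    label map round-trips exactly only for disjoint sets; use per-ROI
    :func:`write_volume` files when overlap matters (e.g. CTV/PTV).
    """
    labels = np.zeros(structures.geometry.shape, dtype=np.uint8)
    table: dict[int, str] = {}
    for label, (name, mask) in enumerate(structures.masks.items(), start=1):
        labels[mask.inside] = label
        table[label] = name
    sitk.WriteImage(_to_sitk(structures.geometry, labels), str(labels_path), useCompression=True)
    with open(names_path, "w") as fh:
        yaml.safe_dump(table, fh)
    return table


def load_volume(
    path: str | Path,
    kind: str = "scalar",
    name_table: Mapping[int, str] | str | Path | None = None,
) -> ImageVolume | BinaryMask | StructureSet:
    """Load a volume from MetaImage or NIfTI.

    Parameters
    ----------
    kind : {"scalar", "mask", "labelmap"}
        ``scalar`` returns an :class:`ImageVolume`; ``mask`` a
        :class:`BinaryMask` (nonzero = inside); ``labelmap`` a
        :class:`StructureSet` where each nonzero label becomes one named mask
        (label 0 is background).
    name_table
        Required for ``labelmap``: a ``{label: name}`` mapping or the path of
        a YAML file holding one.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # unreadable header
        raise FormatError(f"cannot read {path}: {exc}") from exc
    geometry, array = _from_sitk(img)

    if kind == "scalar":
        return ImageVolume(geometry, array.astype(float))
    if kind == "mask":
        return BinaryMask(geometry, array != 0)
    if kind == "labelmap":
        if name_table is None:
            raise MappingError("labelmap loading requires a name table")
        if isinstance(name_table, (str, Path)):
            with open(name_table) as fh:
                name_table = {int(k): str(v) for k, v in yaml.safe_load(fh).items()}
        labels = array.astype(np.int64)
        structures = StructureSet(geometry)
        for label in sorted(np.unique(labels)):
            if label == 0:
                continue
            if label not in name_table:
                raise MappingError(f"label {label} has no entry in the name table")
            structures.add(name_table[label], BinaryMask(geometry, labels == label))
        return structures
    raise ValidationError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# Mask geometry utilities
# ---------------------------------------------------------------------------

def expand_margin(mask: BinaryMask, margin: float) -> BinaryMask:
    """Isotropic margin expansion in world space (mm), spacing-aware.

    A voxel of the output is inside iff the Euclidean distance from its
    center to the nearest inside voxel center of the input is <= ``margin``.
    This is the clinical CTV-to-PTV margin semantics (e.g. PTV = prostate
    + 5 mm).
    """
    if not np.isfinite(margin) or margin < 0:
        raise ValidationError("margin must be finite and >= 0")
    if mask.is_empty():
        raise ValidationError("cannot expand an empty mask")
    if margin == 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask.inside, sampling=mask.geometry.spacing)
    return BinaryMask(mask.geometry, dist <= margin + 1e-9)


def mask_volume_cc(mask: BinaryMask) -> float:
    """Physical volume of a mask in cm^3 (voxel count x voxel volume)."""
    return mask.voxel_count * mask.geometry.voxel_volume_mm3 / 1000.0


def mask_bounding_box(mask: BinaryMask, pad_voxels: int = 0) -> tuple[slice, slice, slice]:
    """Tight index bounding box of a non-empty mask, padded and clipped."""
    if mask.is_empty():
        raise ValidationError("empty mask has no bounding box")
    slices = []
    for axis in range(3):
        proj = np.any(mask.inside, axis=tuple(a for a in range(3) if a != axis))
        idx = np.nonzero(proj)[0]
        lo = max(int(idx[0]) - pad_voxels, 0)
        hi = min(int(idx[-1]) + 1 + pad_voxels, int(mask.geometry.size[axis]))
        slices.append(slice(lo, hi))
    return tuple(slices)


def crop_geometry(geometry: Geometry, box: tuple[slice, slice, slice]) -> Geometry:
    """Geometry of a sub-grid selected by index slices (step 1)."""
    starts = np.array([s.start for s in box])
    stops = np.array([s.stop for s in box])
    return Geometry(geometry.origin + starts * geometry.spacing, geometry.spacing, stops - starts)
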