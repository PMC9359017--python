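"""Digital pelvis phantom and surrogate of the online adaptive system.

The real study images a rigid anthropomorphic pelvis phantom and exercises a
proprietary auto-segmentation and plan re-optimization engine.  Neither is
available here, so this module provides a parametric stand-in with the same
observable structure:

* :func:`build_phantom` — a CT-like volume with the eight study ROIs built
  from geometric primitives (ellipsoid prostate/bladder/seminal vesicles,
  tubular rectum, bowel region, spherical femoral heads, elliptic-cylinder
  body), CTV = prostate + seminal vesicles, PTV = prostate + 5 mm margin.
* :func:`simulate_autoseg` — repeated noisy re-segmentation of fixed anatomy:
  the truth mask is warped by a smooth random displacement field with a given
  boundary-displacement amplitude (mm) and correlation length.  Manual
  correction is emulated as a lower-amplitude regime for target structures
  and bladder.
* :func:`simulate_dose` — a conformal dose surrogate: prescription inside the
  PTV with a Gaussian penumbra applied to the PTV distance map, in two plan
  styles (IMRT-like vs VMAT-like penumbra/coverage trade-off).
* :func:`run_virtual_study` — the full experiment layout: 5 deformations x
  26 fractions, 13 IMRT / 13 VMAT, 3+3 AI-only and 10+10 manually-corrected
  fractions per deformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage

from .dvf import DEFAULT_BOX_EXTENTS_MM, GaussianDeformationSpec, SamplingBounds, sample_deformation_spec
from .errors import ValidationError
from .volumes import (
    REPORT_ROIS,
    BinaryMask,
    Geometry,
    ImageVolume,
    StructureSet,
    crop_geometry,
    expand_margin,
    mask_bounding_box,
)

PTV_MARGIN_MM = 5.0


def default_phantom_geometry(spacing_mm: float = 2.0, size=(128, 128, 96)) -> Geometry:
    """Grid centered on the world origin (axes: X left, Y posterior, Z superior)."""
    size = np.asarray(size, dtype=int)
    spacing = np.full(3, float(spacing_mm))
    origin = -(size - 1) * spacing / 2.0
    return Geometry(origin, spacing, size)


@dataclass(frozen=True)
class PhantomConfig:
    """Shape, HU, and noise parameters of the digital pelvis phantom.

    Organ primitives are specified in world mm on the phantom frame; HU
    values are nominal tissue classes with additive Gaussian image noise.
    """

    geometry: Geometry = field(default_factory=default_phantom_geometry)
    body_semiaxes: tuple[float, float] = (115.0, 95.0)
    prostate_center: tuple[float, float, float] = (0.0, 0.0, -10.0)
    prostate_radii: tuple[float, float, float] = (22.0, 20.0, 18.0)
    sv_center: tuple[float, float, float] = (0.0, 14.0, 12.0)
    sv_radii: tuple[float, float, float] = (16.0, 9.0, 10.0)
    bladder_center: tuple[float, float, float] = (0.0, -28.0, 24.0)
    bladder_radii: tuple[float, float, float] = (30.0, 25.0, 24.0)
    rectum_center_xy: tuple[float, float] = (0.0, 40.0)
    rectum_radius: float = 14.0
    rectum_z_range: tuple[float, float] = (-70.0, 60.0)
    bowel_center: tuple[float, float, float] = (0.0, 5.0, 62.0)
    bowel_radii: tuple[float, float, float] = (75.0, 55.0, 28.0)
    femur_abs_x: float = 82.0
    femur_center_yz: tuple[float, float] = (8.0, -8.0)
    femur_radius: float = 22.0
    hu: dict = field(
        default_factory=lambda: {
            "background": -1000.0,
            "Body": 20.0,
            "Bowel": 0.0,
            "Bladder": 5.0,
            "Rectum": -30.0,
            "SeminalVesicles": 35.0,
            "Prostate": 40.0,
            "Femur": 600.0,
        }
    )
    noise_sd_hu: float = 15.0
    seed: int = 0


def _ellipsoid(geometry: Geometry, center, radii) -> np.ndarray:
    xs, ys, zs = geometry.coordinate_grids()
    cx, cy, cz = center
    rx, ry, rz = radii
    return ((xs - cx) / rx) ** 2 + ((ys - cy) / ry) ** 2 + ((zs - cz) / rz) ** 2 <= 1.0


def build_phantom(config: PhantomConfig) -> tuple[ImageVolume, StructureSet]:
    """Render the phantom CT and its structure set. Deterministic given seed."""
    geom = config.geometry
    xs, ys, zs = geom.coordinate_grids()

    bx, by = config.body_semiaxes
    body = np.broadcast_to((xs / bx) ** 2 + (ys / by) ** 2 <= 1.0, geom.shape).copy()

    prostate = _ellipsoid(geom, config.prostate_center, config.prostate_radii)
    sv = _ellipsoid(geom, config.sv_center, config.sv_radii)
    bladder = _ellipsoid(geom, config.bladder_center, config.bladder_radii)

    rcx, rcy = config.rectum_center_xy
    zlo, zhi = config.rectum_z_range
    rectum = ((xs - rcx) ** 2 + (ys - rcy) ** 2 <= config.rectum_radius**2) & (zs >= zlo) & (zs <= zhi)
    rectum = np.broadcast_to(rectum, geom.shape).copy()

    bowel = _ellipsoid(geom, config.bowel_center, config.bowel_radii)
    # bowel wraps around, not into, the other soft-tissue organs
    bowel &= ~(bladder | rectum | prostate | sv)

    fy, fz = config.femur_center_yz
    femur_l = _ellipsoid(geom, (config.femur_abs_x, fy, fz), (config.femur_radius,) * 3)
    femur_r = _ellipsoid(geom, (-config.femur_abs_x, fy, fz), (config.femur_radius,) * 3)

    organs = {
        "Prostate": prostate,
        "SeminalVesicles": sv,
        "Bladder": bladder,
        "Rectum": rectum,
        "Bowel": bowel,
        "Femur_L": femur_l,
        "Femur_R": femur_r,
    }
    for name, arr in organs.items():
        if np.any(arr & ~body):
            raise ValidationError(f"organ {name} escapes the body outline")
    for a, b in (("Prostate", "Bladder"), ("Prostate", "Rectum"), ("Bladder", "Rectum")):
        if np.any(organs[a] & organs[b]):
            raise ValidationError(f"organs {a} and {b} overlap")

    structures = StructureSet(geom)
    for name, arr in organs.items():
        structures.add(name, BinaryMask(geom, arr))
    structures.add("CTV_7000", BinaryMask(geom, prostate | sv))
    structures.add("PTV_7000", expand_margin(structures["Prostate"], PTV_MARGIN_MM))
    structures.add("Body", BinaryMask(geom, body))

    hu = np.full(geom.shape, config.hu["background"])
    hu[body] = config.hu["Body"]
    for name in ("Bowel", "Bladder", "Rectum", "SeminalVesicles", "Prostate"):
        hu[organs[name]] = config.hu[name]
    hu[femur_l | femur_r] = config.hu["Femur"]
    rng = np.random.default_rng(config.seed)
    hu = hu + rng.normal(0.0, config.noise_sd_hu, size=geom.shape)
    return ImageVolume(geom, hu), structures


# ---------------------------------------------------------------------------
# Auto-segmentation surrogate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegPerturbationModel:
    """Smooth random boundary perturbation emulating re-segmentation noise.

    ``sd_mm`` sets the per-axis standard deviation of the displacement applied
    to the truth surface; ``correlation_mm`` the smoothness (Gaussian filter
    length) of that random field.  ``mode='corrected'`` is the lower-noise
    regime used for manually reviewed structures.
    """

    sd_mm: float
    correlation_mm: float = 8.0
    mode: str = "ai"
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.sd_mm) or self.sd_mm < 0:
            raise ValidationError("sd_mm must be finite and >= 0")
        if self.correlation_mm <= 0:
            raise ValidationError("correlation_mm must be > 0")
        if self.mode not in ("ai", "corrected"):
            raise ValidationError("mode must be 'ai' or 'corrected'")


def _smooth_noise_field(shape, spacing, correlation_mm, sd_mm, rng) -> np.ndarray:
    """(…, 3) random field, each axis Gaussian-correlated with std sd_mm."""
    sigmas = correlation_mm / np.asarray(spacing)
    out = np.empty(tuple(shape) + (3,))
    for axis in range(3):
        white = rng.standard_normal(shape)
        smooth = ndimage.gaussian_filter(white, sigma=sigmas)
        std = smooth.std()
        if std < 1e-12:
            smooth = np.zeros_like(smooth)
        else:
            smooth = smooth * (sd_mm / std)
        out[..., axis] = smooth
    return out


def simulate_autoseg(truth: BinaryMask, model: SegPerturbationModel) -> BinaryMask:
    """One simulated re-segmentation of a fixed truth mask.

    The truth is warped by a smooth random displacement field (pull-back,
    nearest neighbor).  Computation is restricted to a padded bounding box of
    the truth; the field is identically zero elsewhere, which is exact
    because displacements beyond the pad cannot move the mask into view.
    """
    if truth.is_empty():
        raise ValidationError("truth mask is empty")
    if model.sd_mm == 0:
        return truth.copy()
    geom = truth.geometry
    pad = int(np.ceil((4 * model.sd_mm + 2 * model.correlation_mm) / float(np.min(geom.spacing)))) + 1
    box = mask_bounding_box(truth, pad_voxels=pad)
    sub = truth.inside[box].astype(np.uint8)
    rng = np.random.default_rng(model.seed)
    noise = _smooth_noise_field(sub.shape, geom.spacing, model.correlation_mm, model.sd_mm, rng)
    coords = [
        np.arange(sub.shape[a], dtype=float).reshape([-1 if i == a else 1 for i in range(3)])
        + noise[..., a] / geom.spacing[a]
        for a in range(3)
    ]
    warped = ndimage.map_coordinates(sub, coords, order=0, mode="constant", cval=0)
    out = np.zeros(geom.shape, dtype=bool)
    out[box] = warped.astype(bool)
    return BinaryMask(geom, out)


# ---------------------------------------------------------------------------
# Dose surrogate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseModel:
    """Conformal dose surrogate parameters.

    Dose equals ``rx_gy * target_scale`` inside the PTV and falls off as a
    Gaussian of ``penumbra_mm`` applied to the Euclidean distance from the
    PTV surface, plus smooth seeded noise of relative amplitude
    ``noise_frac`` (<= 1% of Rx).  Style defaults encode the observed
    trade-off: IMRT-like plans spare normal tissue more (narrower penumbra),
    VMAT-like plans cover the target slightly better.
    """

    rx_gy: float = 70.0
    plan_style: str = "IMRT"
    penumbra_mm: float | None = None
    target_scale: float | None = None
    noise_frac: float = 0.0015
    noise_correlation_mm: float = 3.0
    seed: int = 0

    _STYLE_DEFAULTS = {"IMRT": (9.0, 1.004), "VMAT": (11.0, 1.006)}

    def __post_init__(self) -> None:
        if self.rx_gy <= 0:
            raise ValidationError("prescription must be > 0")
        if self.plan_style not in self._STYLE_DEFAULTS:
            raise ValidationError("plan_style must be 'IMRT' or 'VMAT'")
        pen, scale = self._STYLE_DEFAULTS[self.plan_style]
        if self.penumbra_mm is None:
            object.__setattr__(self, "penumbra_mm", pen)
        if self.target_scale is None:
            object.__setattr__(self, "target_scale", scale)
        if self.penumbra_mm <= 0:
            raise ValidationError("penumbra_mm must be > 0")
        if not (0 <= self.noise_frac <= 0.01):
            raise ValidationError("noise_frac must be within [0, 0.01]")


def simulate_dose(
    structures: StructureSet, model: DoseModel, include_noise: bool = True
) -> ImageVolume:
    """Simulate one adapted-plan dose distribution (Gy). Deterministic given seed."""
    if "PTV_7000" not in structures:
        raise ValidationError("structure set has no PTV_7000")
    ptv = structures["PTV_7000"]
    if ptv.is_empty():
        raise ValidationError("PTV_7000 is empty")
    geom = structures.geometry
    dist = ndimage.distance_transform_edt(~ptv.inside, sampling=geom.spacing)
    dose = model.rx_gy * model.target_scale * np.exp(-(dist**2) / (2.0 * model.penumbra_mm**2))
    if include_noise and model.noise_frac > 0:
        rng = np.random.default_rng(model.seed)
        sig = model.noise_correlation_mm / geom.spacing
        noise = ndimage.gaussian_filter(rng.standard_normal(geom.shape), sigma=sig)
        std = noise.std()
        if std > 1e-12:
            dose = dose + (model.noise_frac * model.rx_gy / std) * noise
    return ImageVolume(geom, np.maximum(dose, 0.0).astype(np.float64))


# ---------------------------------------------------------------------------
# Virtual study
# ---------------------------------------------------------------------------

#: Boundary-noise amplitude (mm) per ROI and correction mode.  Manual
#: correction lowers noise for the prostate/target structures and bladder and
#: leaves bowel and femurs at the AI level.
DEFAULT_SEG_SD_MM = {
    "ai": {
        "Prostate": 2.5,
        "SeminalVesicles": 2.2,
        "Bladder": 2.2,
        "Rectum": 1.0,
        "Bowel": 0.5,
        "Femur_L": 0.4,
        "Femur_R": 0.4,
    },
    "corrected": {
        "Prostate": 1.2,
        "SeminalVesicles": 1.2,
        "Bladder": 1.0,
        "Rectum": 0.9,
        "Bowel": 0.5,
        "Femur_L": 0.4,
        "Femur_R": 0.4,
    },
}

#: ROIs that are independently re-segmented each fraction; CTV/PTV are
#: derived from the simulated prostate and seminal vesicles.
BASE_SEG_ROIS = ("Prostate", "SeminalVesicles", "Bladder", "Rectum", "Bowel", "Femur_L", "Femur_R")


@dataclass(frozen=True)
class StudyConfig:
    """Layout and noise parameters of the virtual end-to-end study."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    n_deformations: int = 5
    n_fractions: int = 26
    ai_fractions_per_plan: int = 3  # leading AI-only fractions per plan type
    seg_sd_mm: dict = field(default_factory=lambda: {m: dict(v) for m, v in DEFAULT_SEG_SD_MM.items()})
    seg_correlation_mm: float = 8.0
    rx_gy: float = 70.0

    def __post_init__(self) -> None:
        if self.n_deformations < 1 or self.n_fractions < 1:
            raise ValidationError("counts must be >= 1")
        if self.n_fractions % 2 != 0:
            raise ValidationError("n_fractions must split evenly between IMRT and VMAT")
        if 2 * self.ai_fractions_per_plan > self.n_fractions:
            raise ValidationError("too many AI-only fractions")


@dataclass
class FractionRecord:
    """One delivered adaptive fraction of the virtual study."""

    deformation_id: int
    fraction: int
    plan_type: str  # IMRT | VMAT
    mode: str  # ai | corrected
    masks: StructureSet
    dose: ImageVolume


@dataclass
class VirtualStudy:
    """Materialized layout plus lazy per-fraction simulation."""

    config: StudyConfig
    master_seed: int
    image: ImageVolume
    truth: StructureSet
    deformations: list[GaussianDeformationSpec]
    layout: pd.DataFrame  # deformation_id, fraction, plan_type, mode, seg_seed, dose_seed

    def fraction_records(self, deformation_id: int | None = None) -> Iterator[FractionRecord]:
        """Yield fraction records (optionally one deformation's) lazily."""
        rows = self.layout
        if deformation_id is not None:
            rows = rows[rows.deformation_id == deformation_id]
        for row in rows.itertuples(index=False):
            yield self._simulate_fraction(row)

    def materialize(self) -> list[FractionRecord]:
        return list(self.fraction_records())

    def _simulate_fraction(self, row) -> FractionRecord:
        cfg = self.config
        geom = self.truth.geometry
        masks = StructureSet(geom)
        sd_table = cfg.seg_sd_mm[row.mode]
        for i, roi in enumerate(BASE_SEG_ROIS):
            model = SegPerturbationModel(
                sd_mm=float(sd_table[roi]),
                correlation_mm=cfg.seg_correlation_mm,
                mode=row.mode,
                seed=int(row.seg_seed) + i,
            )
            masks.add(roi, simulate_autoseg(self.truth[roi], model))
        masks.add("CTV_7000", BinaryMask(geom, masks["Prostate"].inside | masks["SeminalVesicles"].inside))
        masks.add("PTV_7000", expand_margin(masks["Prostate"], PTV_MARGIN_MM))
        dose = simulate_dose(
            masks, DoseModel(rx_gy=cfg.rx_gy, plan_style=row.plan_type, seed=int(row.dose_seed))
        )
        return FractionRecord(int(row.deformation_id), int(row.fraction), row.plan_type, row.mode, masks, dose)


def study_layout(config: StudyConfig, master_seed: int) -> pd.DataFrame:
    """Enumerate the per-fraction design without simulating anything.

    Per deformation: fractions alternate between a leading AI-only block
    (``ai_fractions_per_plan`` per plan type) and the corrected remainder,
    split evenly between IMRT and VMAT.
    """
    rng = np.random.default_rng(master_seed)
    per_plan = config.n_fractions // 2
    rows = []
    for d in range(1, config.n_deformations + 1):
        fraction = 0
        for plan in ("IMRT", "VMAT"):
            for k in range(per_plan):
                fraction += 1
                mode = "ai" if k < config.ai_fractions_per_plan else "corrected"
                rows.append(
                    {
                        "deformation_id": d,
                        "fraction": fraction,
                        "plan_type": plan,
                        "mode": mode,
                        "seg_seed": int(rng.integers(2**31)),
                        "dose_seed": int(rng.integers(2**31)),
                    }
                )
    return pd.DataFrame(rows)


def run_virtual_study(config: StudyConfig, master_seed: int = 0) -> VirtualStudy:
    """Build the phantom, sample the deformation specs, and lay out the study.

    Fraction-level simulation is lazy (see :meth:`VirtualStudy.fraction_records`)
    so the full default design (5 x 26 fractions) never has to be resident in
    memory at once.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(master_seed), 0xD0]))
    phantom_cfg = replace(config.phantom, seed=int(rng.integers(2**31)))
    image, truth = build_phantom(phantom_cfg)

    ptv_centroid = np.mean(
        np.column_stack(
            [g[truth["PTV_7000"].inside] for g in np.broadcast_arrays(*truth.geometry.coordinate_grids())]
        ),
        axis=0,
    )
    bounds = SamplingBounds(box_center=ptv_centroid, box_extents=np.asarray(DEFAULT_BOX_EXTENTS_MM))
    deformations = [
        sample_deformation_spec(bounds, seed=int(rng.integers(2**31)))
        for _ in range(config.n_deformations)
    ]
    layout = study_layout(config, master_seed=int(rng.integers(2**31)))
    return VirtualStudy(config, int(master_seed), image, truth, deformations, layout)
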