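"""Segmentation reproducibility metrics: Dice, mean symmetric surface
distance, STAPLE consensus, and the per-repetition comparison table.

Conventions
-----------
Surfaces are voxel sets: an inside voxel with at least one face-adjacent
outside voxel (array borders count as outside).  Distances are Euclidean in
world space between voxel centers, computed with spacing-aware distance
transforms; no sub-voxel meshing.  mSSD is the pooled symmetric mean: one
mean over the union of both directed surface-distance samples.  Both metrics
are 3-D.

STAPLE is the classical EM estimator of a consensus segmentation together
with per-rater sensitivity p_j and specificity q_j.  The E-step computes the
per-voxel posterior foreground weight from the current (p_j, q_j) and the
foreground prior; the M-step re-estimates each rater's (p_j, q_j) from the
weights.  Initialization p_j = q_j = 0.99; a posterior weight of exactly 0.5
counts as foreground; ``prior='auto'`` uses the mean foreground fraction of
the input masks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import UndefinedInputError, ValidationError
from .volumes import REPORT_ROIS, BinaryMask, crop_geometry, mask_bounding_box

logger = logging.getLogger(__name__)

_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _check_same_geometry(a: BinaryMask, b: BinaryMask) -> None:
    if a.geometry != b.geometry:
        raise ValidationError("masks live on different geometries")


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|).

    Two empty masks agree perfectly on absence and score 1.0.
    """
    _check_same_geometry(a, b)
    na, nb = a.voxel_count, b.voxel_count
    if na + nb == 0:
        return 1.0
    inter = int(np.count_nonzero(a.inside & b.inside))
    return 2.0 * inter / (na + nb)


def surface_voxels(mask: BinaryMask) -> np.ndarray:
    """Boolean array of inside voxels with >=1 face-adjacent outside voxel."""
    eroded = ndimage.binary_erosion(mask.inside, structure=_FACE_STRUCTURE, border_value=0)
    return mask.inside & ~eroded


def mean_symmetric_surface_distance(a: BinaryMask, b: BinaryMask) -> float:
    """Pooled symmetric mean surface distance in mm.

    Mean, over the union of both surface voxel sets, of each surface voxel
    center's Euclidean distance to the nearest voxel center of the *other*
    surface.  Zero iff the two surface sets coincide.
    """
    _check_same_geometry(a, b)
    if a.is_empty() or b.is_empty():
        raise UndefinedInputError("mSSD is undefined for empty masks")
    # exact after cropping: both surfaces lie fully inside the union box
    union = BinaryMask(a.geometry, a.inside | b.inside)
    box = mask_bounding_box(union, pad_voxels=1)
    spacing = a.geometry.spacing
    sub_a = BinaryMask(crop_geometry(a.geometry, box), a.inside[box])
    sub_b = BinaryMask(crop_geometry(b.geometry, box), b.inside[box])
    surf_a = surface_voxels(sub_a)
    surf_b = surface_voxels(sub_b)
    dist_to_b = ndimage.distance_transform_edt(~surf_b, sampling=spacing)
    dist_to_a = ndimage.distance_transform_edt(~surf_a, sampling=spacing)
    samples = np.concatenate([dist_to_b[surf_a], dist_to_a[surf_b]])
    return float(samples.mean())


# ---------------------------------------------------------------------------
# STAPLE
# ---------------------------------------------------------------------------

@dataclass
class StapleResult:
    """Consensus mask plus per-rater performance estimates."""

    consensus: BinaryMask
    sensitivity: np.ndarray  # p_j per rater
    specificity: np.ndarray  # q_j per rater
    iterations: int
    converged: bool
    prior: float
    weights: np.ndarray | None = None  # per-voxel posterior foreground probability


def staple(
    masks: Sequence[BinaryMask],
    prior: str | float = "auto",
    tol: float = 1e-6,
    max_iter: int = 100,
    init_pq: float = 0.99,
    keep_weights: bool = False,
) -> StapleResult:
    """Simultaneous truth and performance level estimation (EM).

    ``max_iter=0`` performs a single E-step at the initial (p, q), which for
    symmetric initialization and ``prior=0.5`` reduces to a voxelwise
    majority vote (ties to foreground).  Non-convergence within ``max_iter``
    is reported via ``converged=False``, not raised.
    """
    if len(masks) == 0:
        raise ValidationError("staple requires at least one mask")
    geometry = masks[0].geometry
    for m in masks[1:]:
        if m.geometry != geometry:
            raise ValidationError("all masks must share one geometry")

    d = np.stack([m.inside.ravel() for m in masks]).astype(bool)  # (raters, voxels)
    n_raters, n_vox = d.shape
    if prior == "auto":
        prior_val = float(d.mean())
    else:
        prior_val = float(prior)
    if not (0.0 < prior_val < 1.0):
        # degenerate unanimous-empty/full input: consensus is that unanimity
        consensus = BinaryMask(geometry, d[0].reshape(geometry.shape).copy())
        ones = np.ones(n_raters)
        return StapleResult(consensus, ones, ones, 0, True, prior_val)

    eps = 1e-7
    p = np.full(n_raters, init_pq)
    q = np.full(n_raters, init_pq)
    w_old = np.full(n_vox, prior_val)
    converged = False
    iterations = 0

    def e_step() -> np.ndarray:
        log_f = np.log(prior_val) + d.T @ np.log(p) + (~d).T @ np.log(1.0 - p)
        log_g = np.log1p(-prior_val) + d.T @ np.log(1.0 - q) + (~d).T @ np.log(q)
        m = np.maximum(log_f, log_g)
        f = np.exp(log_f - m)
        g = np.exp(log_g - m)
        return f / (f + g)

    w = e_step()
    for iterations in range(1, max_iter + 1):
        sum_w = w.sum()
        sum_not_w = n_vox - sum_w
        p = np.clip((d @ w) / max(sum_w, eps), eps, 1.0 - eps)
        q = np.clip(((~d) @ (1.0 - w)) / max(sum_not_w, eps), eps, 1.0 - eps)
        w_old = w
        w = e_step()
        if np.mean(np.abs(w - w_old)) < tol:
            converged = True
            break
    if max_iter == 0:
        converged = True

    consensus = BinaryMask(geometry, (w >= 0.5).reshape(geometry.shape))
    return StapleResult(
        consensus,
        p,
        q,
        iterations,
        converged,
        prior_val,
        weights=w.reshape(geometry.shape) if keep_weights else None,
    )


# ---------------------------------------------------------------------------
# Per-repetition comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonRecord:
    """One repetition's agreement with its group consensus."""

    roi: str
    deformation_id: int
    plan_type: str
    mode: str
    fraction: int
    dsc: float
    mssd_mm: float


COMPARISON_COLUMNS = ["roi", "deformation_id", "plan_type", "mode", "fraction", "dsc", "mssd_mm"]


def comparisons_to_frame(records: Iterable[ComparisonRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=COMPARISON_COLUMNS)


def compare_repetitions(
    fraction_records: Iterable,
    rois: Sequence[str] = REPORT_ROIS,
    staple_kwargs: dict | None = None,
) -> list[ComparisonRecord]:
    """Compare every repetition against its group's STAPLE consensus.

    Groups are keyed by (roi, deformation, plan type, correction mode) —
    the repetition sets of the study design.  Within each group a STAPLE
    consensus is built over the repeated masks (on the padded union bounding
    box, which leaves the consensus and both metrics unchanged while keeping
    the EM problem small), then each repetition contributes one record with
    its Dice and mSSD versus that consensus.  Groups of size 1 are skipped
    with a warning.
    """
    staple_kwargs = staple_kwargs or {}
    groups: dict[tuple, list] = {}
    for rec in fraction_records:
        for roi in rois:
            key = (roi, rec.deformation_id, rec.plan_type, rec.mode)
            groups.setdefault(key, []).append((rec.fraction, rec.masks[roi]))

    out: list[ComparisonRecord] = []
    for key in sorted(groups, key=lambda k: (k[0], k[1], k[2], k[3])):
        roi, deformation_id, plan_type, mode = key
        members = sorted(groups[key], key=lambda t: t[0])
        if len(members) < 2:
            logger.warning("group %s has a single repetition; skipped", key)
            continue
        geometry = members[0][1].geometry
        union = np.zeros(geometry.shape, dtype=bool)
        for _, m in members:
            union |= m.inside
        if not union.any():
            logger.warning("group %s is entirely empty; skipped", key)
            continue
        box = mask_bounding_box(BinaryMask(geometry, union), pad_voxels=2)
        sub_geom = crop_geometry(geometry, box)
        sub_masks = [BinaryMask(sub_geom, m.inside[box]) for _, m in members]
        consensus = staple(sub_masks, **staple_kwargs).consensus
        for (fraction, _), sub in zip(members, sub_masks):
            out.append(
                ComparisonRecord(
                    roi,
                    int(deformation_id),
                    plan_type,
                    mode,
                    int(fraction),
                    dice(sub, consensus),
                    mean_symmetric_surface_distance(sub, consensus),
                )
            )
    return out
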