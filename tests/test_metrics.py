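"""Dice, mean symmetric surface distance, STAPLE, and repetition comparison."""

import numpy as np
import pytest
import SimpleITK as sitk
from scipy import ndimage

from e2eqa import (
    BinaryMask,
    Geometry,
    StructureSet,
    UndefinedInputError,
    ValidationError,
    compare_repetitions,
    comparisons_to_frame,
    dice,
    mean_symmetric_surface_distance,
    staple,
)
from e2eqa.metrics import surface_voxels
from conftest import random_blob, random_mask


def brute_force_mssd(a: BinaryMask, b: BinaryMask) -> float:
    """All-pairs surface-distance oracle (pooled symmetric mean)."""
    spacing = a.geometry.spacing
    pa = np.argwhere(surface_voxels(a)) * spacing
    pb = np.argwhere(surface_voxels(b)) * spacing
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    return float(np.concatenate([d.min(axis=1), d.min(axis=0)]).mean())


class TestDice:
    def test_identities(self, unit_geometry):
        g = unit_geometry
        a = random_mask(g, np.random.default_rng(0))
        assert dice(a, a) == 1.0
        empty = BinaryMask(g, np.zeros(g.shape, bool))
        left = np.zeros(g.shape, bool)
        left[:6] = True
        right = ~left
        assert dice(BinaryMask(g, left), BinaryMask(g, right)) == 0.0
        assert dice(empty, empty) == 1.0

    def test_half_overlap_formula(self, unit_geometry):
        g = unit_geometry
        a = np.zeros(g.shape, bool)
        b = np.zeros(g.shape, bool)
        a.ravel()[:100] = True
        b.ravel()[50:150] = True
        assert dice(BinaryMask(g, a), BinaryMask(g, b)) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry(self, unit_geometry, seed):
        rng = np.random.default_rng(seed)
        a = random_mask(unit_geometry, rng)
        b = random_mask(unit_geometry, rng)
        assert dice(a, b) == dice(b, a)

    def test_geometry_mismatch_rejected(self, unit_geometry):
        other = Geometry([0, 0, 0], [2, 2, 2], [12, 12, 12])
        with pytest.raises(ValidationError):
            dice(random_mask(unit_geometry, np.random.default_rng(0)),
                 random_mask(other, np.random.default_rng(0)))


class TestMSSD:
    def test_identical_masks_have_zero_distance(self, unit_geometry):
        m = random_blob(unit_geometry, np.random.default_rng(1))
        assert mean_symmetric_surface_distance(m, m) == 0.0

    def test_two_single_voxels_three_mm_apart(self):
        g = Geometry([0, 0, 0], [1, 1, 1], [8, 8, 8])
        a = np.zeros(g.shape, bool)
        b = np.zeros(g.shape, bool)
        a[2, 4, 4] = True
        b[5, 4, 4] = True
        assert mean_symmetric_surface_distance(BinaryMask(g, a), BinaryMask(g, b)) == pytest.approx(3.0)

    def test_offset_slabs_match_brute_force_exactly(self):
        g = Geometry([0, 0, 0], [1, 1, 1], [10, 8, 3])
        a = np.zeros(g.shape, bool)
        b = np.zeros(g.shape, bool)
        a[1:6, 1:6, 1] = True
        b[3:8, 1:6, 1] = True
        ma, mb = BinaryMask(g, a), BinaryMask(g, b)
        assert mean_symmetric_surface_distance(ma, mb) == pytest.approx(brute_force_mssd(ma, mb), abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        g = Geometry([0, 0, 0], rng.uniform(0.8, 2.5, 3), [14, 14, 14])
        a, b = random_blob(g, rng), random_blob(g, rng)
        got = mean_symmetric_surface_distance(a, b)
        assert got == pytest.approx(brute_force_mssd(a, b), abs=1e-9)
        assert got == pytest.approx(mean_symmetric_surface_distance(b, a), abs=1e-12)

    def test_empty_mask_rejected(self, unit_geometry):
        m = random_blob(unit_geometry, np.random.default_rng(2))
        empty = BinaryMask(unit_geometry, np.zeros(unit_geometry.shape, bool))
        with pytest.raises(UndefinedInputError):
            mean_symmetric_surface_distance(m, empty)


def sphere_mask(geometry: Geometry, center_mm, radius_mm) -> BinaryMask:
    xs = geometry.axis_coords(0)[:, None, None]
    ys = geometry.axis_coords(1)[None, :, None]
    zs = geometry.axis_coords(2)[None, None, :]
    r2 = (xs - center_mm[0]) ** 2 + (ys - center_mm[1]) ** 2 + (zs - center_mm[2]) ** 2
    return BinaryMask(geometry, r2 <= radius_mm**2)


def simulate_raters(truth: BinaryMask, n_raters, p, q, seed):
    """Raters with per-voxel miss rate 1-p (foreground) and false-alarm 1-q."""
    rng = np.random.default_rng(seed)
    raters = []
    for _ in range(n_raters):
        u = rng.random(truth.geometry.shape)
        obs = np.where(truth.inside, u < p, u > q)
        raters.append(BinaryMask(truth.geometry, obs))
    return raters


class TestStaple:
    def test_unanimous_raters_recover_the_mask_and_perfect_performance(self, unit_geometry):
        m = random_blob(unit_geometry, np.random.default_rng(3))
        res = staple([m.copy() for _ in range(5)])
        assert np.array_equal(res.consensus.inside, m.inside)
        assert np.all(res.sensitivity > 1 - 1e-3)
        assert np.all(res.specificity > 1 - 1e-3)
        assert res.converged

    def test_recovers_rater_performance_from_noisy_sphere(self):
        g = Geometry([0, 0, 0], [2, 2, 2], [32, 32, 32])
        truth = sphere_mask(g, (32, 32, 32), 20.0)
        raters = simulate_raters(truth, 5, p=0.90, q=0.98, seed=0)
        res = staple(raters)
        assert np.all(np.abs(res.sensitivity - 0.90) <= 0.05)
        assert np.all(np.abs(res.specificity - 0.98) <= 0.02)
        assert dice(res.consensus, truth) > 0.95

    def test_majority_pair_dominates_one_bad_rater(self, unit_geometry):
        g = unit_geometry
        good = sphere_mask(g, (6, 6, 6), 4.0)
        bad = sphere_mask(g, (2, 2, 2), 1.5)
        assert dice(good, bad) < 0.2
        res = staple([good.copy(), good.copy(), bad])
        assert dice(res.consensus, good) > 0.99

    @pytest.mark.parametrize("n_raters", [3, 5, 4])
    def test_single_e_step_with_flat_prior_is_majority_vote(self, n_raters):
        rng = np.random.default_rng(17)
        g = Geometry([0, 0, 0], [1, 1, 1], [16, 16, 16])
        raters = [random_mask(g, rng, p=0.4) for _ in range(n_raters)]
        res = staple(raters, prior=0.5, max_iter=0)
        votes = np.sum([r.inside for r in raters], axis=0)
        majority = votes * 2 >= n_raters  # ties count as foreground
        assert np.array_equal(res.consensus.inside, majority)

    def test_agrees_with_independent_em_implementation(self):
        g = Geometry([0, 0, 0], [2, 2, 2], [24, 24, 24])
        truth = sphere_mask(g, (24, 24, 24), 14.0)
        raters = simulate_raters(truth, 5, p=0.92, q=0.97, seed=3)
        ours = staple(raters).consensus
        imgs = [sitk.GetImageFromArray(r.inside.astype(np.uint8).transpose(2, 1, 0)) for r in raters]
        ref = sitk.GetArrayFromImage(sitk.STAPLE(imgs, 1.0)).transpose(2, 1, 0) >= 0.5
        assert dice(ours, BinaryMask(g, ref)) > 0.99

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            staple([])


class _Rec:
    def __init__(self, deformation_id, plan_type, mode, fraction, masks):
        self.deformation_id = deformation_id
        self.plan_type = plan_type
        self.mode = mode
        self.fraction = fraction
        self.masks = masks


class TestCompareRepetitions:
    def _records(self, masks_by_fraction, roi="Prostate"):
        recs = []
        for f, mask in enumerate(masks_by_fraction, start=1):
            recs.append(_Rec(1, "IMRT", "corrected", f, {roi: mask}))
        return recs

    def test_identical_group_yields_perfect_agreement(self, unit_geometry):
        m = random_blob(unit_geometry, np.random.default_rng(4))
        recs = self._records([m.copy() for _ in range(5)])
        out = compare_repetitions(recs, rois=("Prostate",))
        assert len(out) == 5
        assert all(r.dsc == 1.0 and r.mssd_mm == 0.0 for r in out)

    def test_perturbed_group_scores_below_perfect(self, phantom):
        from e2eqa import SegPerturbationModel, simulate_autoseg

        _, ss = phantom
        masks = [
            simulate_autoseg(ss["Prostate"], SegPerturbationModel(sd_mm=1.0, seed=40 + i))
            for i in range(4)
        ]
        out = compare_repetitions(self._records(masks), rois=("Prostate",))
        assert len(out) == 4
        assert all(r.dsc < 1.0 and r.mssd_mm > 0.0 for r in out)
        assert all(r.dsc > 0.8 for r in out)  # still the same organ

    def test_singleton_groups_are_skipped(self, unit_geometry):
        m = random_blob(unit_geometry, np.random.default_rng(5))
        out = compare_repetitions(self._records([m]), rois=("Prostate",))
        assert out == []

    def test_bookkeeping_one_record_per_repetition_per_roi(self, unit_geometry):
        rng = np.random.default_rng(6)
        masks = {roi: random_blob(unit_geometry, rng) for roi in ("A", "B")}
        recs = []
        for d in (1, 2):
            for f in (1, 2, 3):
                recs.append(_Rec(d, "VMAT", "ai", f, masks))
        frame = comparisons_to_frame(compare_repetitions(recs, rois=("A", "B")))
        assert len(frame) == 2 * 3 * 2  # deformations x fractions x rois
        assert set(frame.roi) == {"A", "B"}
        assert (frame.groupby(["roi", "deformation_id"]).size() == 3).all()
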