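"""Gaussian deformation sampling, rendering, warping, and invertibility."""

import numpy as np
import pytest
from scipy import ndimage

from e2eqa import (
    BinaryMask,
    DisplacementField,
    GaussianDeformationSpec,
    Geometry,
    SamplingBounds,
    ValidationError,
    jacobian_determinant,
    render_displacement_field,
    sample_deformation_spec,
    warp_image,
    warp_mask,
)
from e2eqa.dvf import grid_containing
from conftest import ramp_image

# The five deformation parameter sets of the pelvis study protocol:
# per-axis magnitudes (mm), center (world mm), standard deviation (mm).
STUDY_DEFORMATIONS = [
    ((10.9, 10.9, 10.9), (-13.4, 119.6, 707.7), 18.7),
    ((-14.2, 14.2, -14.2), (-21.1, 118.6, 700.6), 29.4),
    ((18.8, -18.8, -18.8), (-6.2, 119.8, 708.1), 15.6),
    ((-17.8, -17.8, 17.8), (-3.2, 116.4, 707.3), 29.3),
    ((10.9, -10.9, 10.9), (-17.3, 124.7, 699.8), 15.8),
]


def make_spec(row) -> GaussianDeformationSpec:
    m, c, s = row
    return GaussianDeformationSpec(np.asarray(m), np.asarray(c), s)


class TestSampling:
    def test_draws_respect_bounds_and_seed_determinism(self):
        bounds = SamplingBounds(box_center=np.array([0.0, 100.0, 700.0]))
        specs = [sample_deformation_spec(bounds, seed=s) for s in range(100)]
        for spec in specs:
            mags = np.abs(spec.magnitude)
            assert np.allclose(mags, mags[0])  # shared scalar, signs only
            assert 10.0 <= mags[0] <= 20.0
            assert 15.0 <= spec.sigma <= 25.0
            lo = bounds.box_center - bounds.box_extents / 2
            hi = bounds.box_center + bounds.box_extents / 2
            assert np.all(spec.center >= lo) and np.all(spec.center <= hi)
        again = sample_deformation_spec(bounds, seed=42)
        first = sample_deformation_spec(bounds, seed=42)
        assert np.array_equal(again.magnitude, first.magnitude)
        assert np.array_equal(again.center, first.center)
        assert again.sigma == first.sigma

    def test_centers_spread_over_most_of_the_box(self):
        bounds = SamplingBounds(box_center=np.zeros(3))
        centers = np.array([sample_deformation_spec(bounds, seed=s).center for s in range(100)])
        span = centers.max(axis=0) - centers.min(axis=0)
        assert np.all(span > 0.8 * bounds.box_extents)

    def test_degenerate_ranges_collapse_exactly(self):
        bounds = SamplingBounds(
            box_center=np.zeros(3), magnitude_range=(12.0, 12.0), sigma_range=(20.0, 20.0)
        )
        spec = sample_deformation_spec(bounds, seed=7)
        assert np.allclose(np.abs(spec.magnitude), 12.0)
        assert spec.sigma == 20.0


class TestRender:
    @pytest.mark.parametrize("row", STUDY_DEFORMATIONS)
    def test_displacement_at_center_equals_magnitude(self, row):
        spec = make_spec(row)
        geom = grid_containing(spec.center, spacing_mm=1.0, half_extent_voxels=8)
        field = render_displacement_field(spec, geom)
        center_idx = (8, 8, 8)
        assert np.allclose(field.vectors[center_idx], spec.magnitude, atol=1e-12)

    def test_displacement_at_one_sigma_is_magnitude_times_exp_minus_half(self):
        sigma = 7.0
        spec = GaussianDeformationSpec(np.array([12.0, -15.0, 9.0]), np.zeros(3), sigma)
        geom = grid_containing(spec.center, spacing_mm=1.0, half_extent_voxels=8)
        field = render_displacement_field(spec, geom)
        at_sigma = field.vectors[8 + 7, 8, 8]  # voxel exactly sigma away along X
        assert np.allclose(at_sigma, spec.magnitude * np.exp(-0.5), rtol=1e-12)

    def test_far_field_vanishes(self):
        spec = GaussianDeformationSpec(np.full(3, 20.0), np.zeros(3), 1.0)
        geom = Geometry([10.0, 0.0, 0.0], np.ones(3), [4, 4, 4])  # >= 10 sigma away
        field = render_displacement_field(spec, geom)
        assert np.all(np.linalg.norm(field.vectors, axis=-1) < 1e-8)

    def test_magnitude_is_radially_non_increasing(self):
        spec = make_spec(STUDY_DEFORMATIONS[1])
        geom = grid_containing(spec.center, spacing_mm=4.0, half_extent_voxels=10)
        field = render_displacement_field(spec, geom)
        xs, ys, zs = geom.coordinate_grids()
        r = np.sqrt(
            (xs - spec.center[0]) ** 2 + (ys - spec.center[1]) ** 2 + (zs - spec.center[2]) ** 2
        )
        mag = np.linalg.norm(field.vectors, axis=-1)
        order = np.argsort(r.ravel())
        assert np.all(np.diff(mag.ravel()[order]) <= 1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValidationError):
            GaussianDeformationSpec(np.ones(3), np.zeros(3), 0.0)


def constant_field(geometry: Geometry, d) -> DisplacementField:
    vectors = np.broadcast_to(np.asarray(d, float), geometry.shape + (3,)).copy()
    return DisplacementField(geometry, vectors)


class TestWarp:
    def test_zero_field_is_identity(self, unit_geometry):
        rng = np.random.default_rng(0)
        from e2eqa import ImageVolume

        img = ImageVolume(unit_geometry, rng.normal(size=unit_geometry.shape))
        out = warp_image(img, constant_field(unit_geometry, (0, 0, 0)))
        assert np.array_equal(out.values, img.values)

    def test_constant_shift_on_linear_ramp_is_exact_in_the_interior(self, unit_geometry):
        img = ramp_image(unit_geometry, axis=0)
        out = warp_image(img, constant_field(unit_geometry, (5.0, 0.0, 0.0)))
        interior = out.values[:6]  # sample points stay inside the grid
        expected = img.values[:6] + 5.0
        assert np.allclose(interior, expected, atol=1e-9)

    def test_integer_shift_then_inverse_restores_interior(self, unit_geometry):
        rng = np.random.default_rng(1)
        from e2eqa import ImageVolume

        img = ImageVolume(unit_geometry, rng.normal(size=unit_geometry.shape))
        fwd = warp_image(img, constant_field(unit_geometry, (3.0, 0.0, 0.0)))
        back = warp_image(fwd, constant_field(unit_geometry, (-3.0, 0.0, 0.0)))
        assert np.allclose(back.values[3:9], img.values[3:9], atol=1e-9)

    def test_linear_interpolation_respects_value_bounds(self, unit_geometry):
        rng = np.random.default_rng(2)
        from e2eqa import ImageVolume

        img = ImageVolume(unit_geometry, rng.uniform(10, 20, size=unit_geometry.shape))
        spec = GaussianDeformationSpec(np.array([3.0, -2.0, 4.0]), np.array([6.0, 6.0, 6.0]), 5.0)
        out = warp_image(img, render_displacement_field(spec, unit_geometry))
        assert out.values.min() >= img.values.min() - 1e-12
        assert out.values.max() <= img.values.max() + 1e-12

    def test_geometry_mismatch_rejected(self, unit_geometry):
        other = Geometry([0, 0, 0], [2, 2, 2], [12, 12, 12])
        img = ramp_image(unit_geometry)
        with pytest.raises(ValidationError):
            warp_image(img, constant_field(other, (1, 0, 0)))

    def test_mask_constant_shift_matches_index_arithmetic(self):
        g = Geometry([0, 0, 0], [2.0, 2.0, 2.0], [16, 16, 16])
        inside = np.zeros(g.shape, bool)
        inside[6:10, 6:10, 6:10] = True
        mask = BinaryMask(g, inside)
        # pull-back of d = (-2*spacing_x, 0, 0) translates the mask +2 voxels in X
        out = warp_mask(mask, constant_field(g, (-4.0, 0.0, 0.0)))
        expected = np.zeros_like(inside)
        expected[8:12, 6:10, 6:10] = True
        assert np.array_equal(out.inside, expected)

    @pytest.mark.parametrize("row", STUDY_DEFORMATIONS)
    def test_sphere_stays_connected_under_locally_invertible_study_fields(self, row):
        spec = make_spec(row)
        # folding threshold of the rank-1 Gaussian Jacobian (see TestJacobian)
        folds = np.linalg.norm(spec.magnitude) * np.exp(-0.5) >= spec.sigma
        geom = grid_containing(spec.center, spacing_mm=2.0, half_extent_voxels=24)
        xs, ys, zs = geom.coordinate_grids()
        r2 = (xs - spec.center[0]) ** 2 + (ys - spec.center[1]) ** 2 + (zs - spec.center[2]) ** 2
        sphere = BinaryMask(geom, r2 <= 20.0**2)
        warped = warp_mask(sphere, render_displacement_field(spec, geom))
        labels, _ = ndimage.label(warped.inside, structure=ndimage.generate_binary_structure(3, 1))
        sizes = np.sort(np.bincount(labels.ravel())[1:])[::-1]
        # nearest-neighbor resampling may shed single-voxel satellites at the
        # boundary; the warped sphere must stay one dominant 6-connected body
        assert sizes[0] >= 0.995 * sizes.sum()
        assert np.all(sizes[1:] <= 1)
        if not folds:
            n26 = ndimage.label(warped.inside, structure=np.ones((3, 3, 3)))[1]
            assert n26 == 1


class TestJacobian:
    @pytest.mark.parametrize("row", STUDY_DEFORMATIONS)
    def test_determinant_matches_rank_one_closed_form(self, row):
        spec = make_spec(row)
        geom = grid_containing(spec.center, spacing_mm=2.0, half_extent_voxels=20)
        det = jacobian_determinant(render_displacement_field(spec, geom))
        xs, ys, zs = geom.coordinate_grids()
        diff = np.stack(
            np.broadcast_arrays(xs - spec.center[0], ys - spec.center[1], zs - spec.center[2]), axis=-1
        )
        r2 = (diff**2).sum(axis=-1)
        w = np.exp(-r2 / (2 * spec.sigma**2))
        closed = 1.0 - w / spec.sigma**2 * (diff @ spec.magnitude)
        interior = (slice(2, -2),) * 3
        assert np.allclose(det[interior], closed[interior], atol=0.02)

    @pytest.mark.parametrize("row", STUDY_DEFORMATIONS)
    def test_fold_free_exactly_when_peak_gradient_below_one(self, row):
        spec = make_spec(row)
        geom = grid_containing(spec.center, spacing_mm=2.0, half_extent_voxels=24)
        det = jacobian_determinant(render_displacement_field(spec, geom))
        should_fold = np.linalg.norm(spec.magnitude) * np.exp(-0.5) >= spec.sigma
        assert (det.min() <= 0.0) == should_fold
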