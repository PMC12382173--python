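"""Lesion tracing, compartment volumetry, ratios, and size filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from washmap.volume import Volume3D, centered_affine
from washmap.volumetry import (
    LesionMeasurement,
    adc_ratio,
    bounding_extents_mm,
    compartment_volumes,
    largest_area_slices,
    rcbv_ratio,
    size_filters,
    trace_lesion,
    washout_ratio,
)
from washmap.washout import compute_map


def make_volume(values, spacing=(1.0, 1.0, 1.0)):
    values = np.asarray(values, dtype=float)
    return Volume3D(values, centered_affine(values.shape, spacing))


@pytest.fixture(scope="module")
def sphere_volume():
    """Uniform intensity-2 sphere in zero background on a 24^3 1 mm grid."""
    shape = (24, 24, 24)
    grid = np.stack(np.meshgrid(*(np.arange(n) for n in shape), indexing="ij"), axis=-1)
    center = np.array([11.5, 11.5, 11.5])
    inside = np.linalg.norm(grid - center, axis=-1) <= 8.0
    values = np.where(inside, 2.0, 0.0)
    return make_volume(values), inside


class TestTraceLesion:
    def test_uniform_sphere_traced_exactly(self, sphere_volume):
        vol, inside = sphere_volume
        mask = trace_lesion(vol, (11, 11, 11), (1.0, 3.0))
        np.testing.assert_array_equal(mask, inside)

    def test_band_excluding_seed_rejected(self, sphere_volume):
        vol, _ = sphere_volume
        with pytest.raises(ValueError, match="band"):
            trace_lesion(vol, (11, 11, 11), (3.0, 4.0))

    def test_seed_outside_grid_rejected(self, sphere_volume):
        vol, _ = sphere_volume
        with pytest.raises(ValueError, match="outside grid"):
            trace_lesion(vol, (50, 0, 0), (1.0, 3.0))

    def test_disjoint_spheres_only_seeded_one_returned(self):
        values = np.zeros((30, 16, 16))
        values[2:8, 4:10, 4:10] = 2.0
        values[20:26, 4:10, 4:10] = 2.0
        vol = make_volume(values)
        mask = trace_lesion(vol, (4, 6, 6), (1.0, 3.0))
        assert mask[2:8].sum() == 6 * 6 * 6
        assert mask[20:26].sum() == 0

    def test_fill_holes_closes_interior(self):
        values = np.zeros((10, 12, 12))
        values[4:7, 2:10, 2:10] = 2.0
        values[5, 5, 5] = 0.0  # interior dropout
        vol = make_volume(values)
        open_mask = trace_lesion(vol, (5, 3, 3), (1.0, 3.0))
        closed = trace_lesion(vol, (5, 3, 3), (1.0, 3.0), fill_holes=True)
        assert not open_mask[5, 5, 5]
        assert closed[5, 5, 5]


class TestCompartmentVolumes:
    def test_plain_counting(self):
        early = make_volume(np.full((10, 10, 10), 1.5))
        late_values = np.full((10, 10, 10), 1.5)
        late_values[:1] = 1.0  # 100 voxels washed out
        wmap = compute_map(early, make_volume(late_values), epsilon=5.0)
        lesion = np.ones((10, 10, 10), dtype=bool)
        v_wash, v_late, v_enh = compartment_volumes(lesion, wmap, 1.0)
        assert v_wash == 100.0
        assert v_late == 0.0
        assert v_enh == 100.0

    def test_all_neutral_lesion_flags_ratio_undefined(self):
        early = make_volume(np.full((8, 8, 8), 1.0))
        wmap = compute_map(early, early, epsilon=5.0)
        lesion = np.ones((8, 8, 8), dtype=bool)
        v_wash, v_late, v_enh = compartment_volumes(lesion, wmap, 1.0)
        assert (v_wash, v_late, v_enh) == (0.0, 0.0, 0.0)
        assert np.isnan(washout_ratio(v_wash, v_late))

    def test_empty_mask_rejected(self):
        early = make_volume(np.full((8, 8, 8), 1.0))
        wmap = compute_map(early, early)
        with pytest.raises(ValueError, match="empty"):
            compartment_volumes(np.zeros((8, 8, 8), dtype=bool), wmap)


class TestWashoutRatio:
    def test_table_group_mean_volumes(self):
        # ratio of the group-mean volumes; note this is NOT the group's
        # mean per-lesion ratio (means of ratios and ratios of means differ)
        assert washout_ratio(3836.0, 9156.0) == pytest.approx(0.2953, abs=5e-5)

    @pytest.mark.parametrize("v_wash,v_late,expected", [(10.0, 0.0, 1.0), (0.0, 10.0, 0.0)])
    def test_boundaries(self, v_wash, v_late, expected):
        assert washout_ratio(v_wash, v_late) == expected

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            washout_ratio(-1.0, 5.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.1, 1e6), st.floats(0.1, 1e6), st.floats(1e-3, 1e3))
    def test_scale_invariance(self, v_wash, v_late, c):
        assert washout_ratio(c * v_wash, c * v_late) == pytest.approx(
            washout_ratio(v_wash, v_late), rel=1e-9
        )


class TestSizeFilters:
    @staticmethod
    def lesion(extents, v_enh):
        return LesionMeasurement(
            "L", v_enhancing_mm3=v_enh, v_washout_mm3=v_enh / 2, v_late_mm3=v_enh / 2,
            washout_ratio=0.5, bbox_extents_mm=extents,
        )

    def test_below_minimum_extent_excluded(self):
        kept = size_filters([self.lesion((2.0, 5.0, 5.0), 2000.0)])
        assert kept == []

    def test_exact_3mm_boundary_retained(self):
        kept = size_filters([self.lesion((3.0, 3.0, 3.0), 2000.0)])
        assert len(kept) == 1
        assert "below_min_size" not in kept[0].flags

    def test_sub_1cm3_flagged_but_retained(self):
        kept = size_filters([self.lesion((10.0, 10.0, 10.0), 999.0)])
        assert len(kept) == 1
        assert "below_1cm3" in kept[0].flags

    def test_exact_1cm3_not_flagged(self):
        kept = size_filters([self.lesion((10.0, 10.0, 10.0), 1000.0)])
        assert "below_1cm3" not in kept[0].flags

    def test_undefined_ratio_flagged(self):
        m = LesionMeasurement("L", v_enhancing_mm3=2000.0, washout_ratio=float("nan"),
                              bbox_extents_mm=(10.0, 10.0, 10.0))
        kept = size_filters([m])
        assert "ratio_undefined" in kept[0].flags


class TestROIRatios:
    @staticmethod
    def slab_rois():
        rois = []
        for k in (3, 5, 7):
            roi = np.zeros((16, 16, 12), dtype=bool)
            roi[6:9, 6:9, k] = True
            rois.append(roi)
        contra = np.zeros((16, 16, 12), dtype=bool)
        contra[2:5, 2:5, 3:8] = True
        return rois, contra

    def test_three_slice_mean_over_contralateral(self):
        rois, contra = self.slab_rois()
        values = np.ones((16, 16, 12))
        for roi, level in zip(rois, (3.0, 3.5, 4.0)):
            values[roi] = level
        vol = make_volume(values)
        assert rcbv_ratio(vol, rois, contra) == pytest.approx(3.5)

    def test_identical_tissue_gives_unit_ratio(self):
        rois, contra = self.slab_rois()
        vol = make_volume(np.full((16, 16, 12), 2.0))
        assert rcbv_ratio(vol, rois, contra) == pytest.approx(1.0)

    def test_roi_count_and_slice_distinctness_enforced(self):
        rois, contra = self.slab_rois()
        vol = make_volume(np.ones((16, 16, 12)))
        with pytest.raises(ValueError, match="3 tumor ROIs"):
            rcbv_ratio(vol, rois[:2], contra)
        with pytest.raises(ValueError, match="distinct"):
            rcbv_ratio(vol, [rois[0], rois[0], rois[1]], contra)

    def test_empty_and_nonpositive_contralateral_rejected(self):
        rois, contra = self.slab_rois()
        vol = make_volume(np.ones((16, 16, 12)))
        with pytest.raises(ValueError, match="empty"):
            rcbv_ratio(vol, [rois[0], rois[1], np.zeros_like(rois[2])], contra)
        neg = make_volume(np.full((16, 16, 12), -1.0))
        with pytest.raises(ValueError, match="positive"):
            rcbv_ratio(neg, rois, contra)

    def test_adc_ratio_examples(self):
        tumor = np.zeros((10, 10, 10), dtype=bool)
        tumor[5:8, 5:8, 5:8] = True
        contra = np.zeros_like(tumor)
        contra[1:4, 1:4, 1:4] = True
        values = np.ones((10, 10, 10))
        values[tumor] = 1.41
        vol = make_volume(values)
        assert adc_ratio(vol, tumor, contra) == pytest.approx(1.41)
        assert adc_ratio(make_volume(np.ones((10, 10, 10))), tumor, contra) == 1.0


class TestGeometryHelpers:
    def test_bounding_extents(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[2:4, 3:8, 5] = True
        assert bounding_extents_mm(mask, (2.0, 1.0, 3.0)) == (4.0, 5.0, 3.0)

    def test_largest_area_slices_single_slice_each(self):
        mask = np.zeros((12, 12, 8), dtype=bool)
        mask[2:10, 2:10, 3] = True
        mask[3:9, 3:9, 4] = True
        mask[4:8, 4:8, 5] = True
        mask[5:6, 5:6, 6] = True
        rois = largest_area_slices(mask, n=3)
        ks = [np.unique(np.nonzero(r)[2]) for r in rois]
        assert [k.item() for k in ks] == [3, 4, 5]
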