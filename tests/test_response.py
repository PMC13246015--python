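"""Diameter measurement, longitudinal indexes, and categorization."""

import numpy as np
import pytest

from regresponse import (
    DeformationField,
    LabelMask,
    build_response_records,
    longest_axial_diameter,
    percent_change,
    perpendicular_diameter,
    recist_category,
    registered_post_volume,
    tumor_burden_change,
    who_category,
)
from regresponse.imaging import mask_volume
from conftest import random_blob_mask


def brute_force_longest(mask: LabelMask) -> float:
    """O(m²) oracle: max pairwise center distance over every axial slice."""
    sx, sy, _ = mask.spacing
    best = 0.0
    for k in range(mask.shape[2]):
        pts = np.argwhere(mask.voxels[:, :, k]).astype(float) * [sx, sy]
        for i in range(len(pts)):
            d = np.sqrt(((pts - pts[i]) ** 2).sum(axis=1)).max() if len(pts) else 0.0
            best = max(best, float(d))
    return best


class TestLongestDiameter:
    @pytest.mark.parametrize("seed", range(12))
    def test_equals_brute_force_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        vox = random_blob_mask(rng)
        mask = LabelMask(vox.astype(np.uint8), (0.8, 0.7, 2.0))
        result = longest_axial_diameter(mask)
        assert result.length == pytest.approx(brute_force_longest(mask), abs=1e-9)

    def test_rasterized_sphere(self):
        # radius 10 mm at 1 mm in-plane spacing: diameter 20 mm +- 1 voxel
        shape = (25, 25, 12)
        pos = np.indices(shape).astype(float) * np.array([1.0, 1.0, 2.0]).reshape(3, 1, 1, 1)
        center = np.array([12.0, 12.0, 12.0]).reshape(3, 1, 1, 1)
        ball = ((pos - center) ** 2).sum(axis=0) <= 100.0
        mask = LabelMask(ball.astype(np.uint8), (1.0, 1.0, 2.0))
        result = longest_axial_diameter(mask)
        assert result.length == pytest.approx(20.0, abs=1.0)

    def test_single_voxel_is_zero(self):
        vox = np.zeros((8, 8, 4), dtype=np.uint8)
        vox[4, 4, 2] = 1
        assert longest_axial_diameter(LabelMask(vox, (1, 1, 1))).length == 0.0

    def test_collinear_segment(self):
        vox = np.zeros((16, 8, 4), dtype=np.uint8)
        vox[3:10, 4, 1] = 1  # 7 voxels in a row along x
        mask = LabelMask(vox, (0.6, 1.0, 1.0))
        assert longest_axial_diameter(mask).length == pytest.approx(6 * 0.6)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            longest_axial_diameter(LabelMask(np.zeros((8, 8, 4), dtype=np.uint8), (1, 1, 1)))


class TestPerpendicularDiameter:
    def test_rectangle_matches_projection_oracle(self):
        vox = np.zeros((20, 20, 4), dtype=np.uint8)
        vox[4:14, 6:10, 1] = 1  # 10 x 4 voxel rectangle
        mask = LabelMask(vox, (1.0, 1.0, 1.0))
        longest = longest_axial_diameter(mask)
        # oracle: project all voxel centers onto the unit normal of the
        # longest chord (the rectangle diagonal) and take the extent
        pts = np.argwhere(vox[:, :, 1]).astype(float)
        (p1, p2) = longest.endpoints
        v = np.array(p2) - np.array(p1)
        perp = np.array([-v[1], v[0]]) / np.linalg.norm(v)
        expected = (pts @ perp).max() - (pts @ perp).min()
        assert perpendicular_diameter(mask, longest) == pytest.approx(expected, abs=1e-9)

    def test_disk_perpendicular_close_to_longest(self):
        shape = (25, 25, 4)
        ii, jj = np.indices(shape[:2]).astype(float)
        disk = ((ii - 12) ** 2 + (jj - 12) ** 2 <= 81)[:, :, None] & np.ones((1, 1, 4), bool)
        mask = LabelMask(disk.astype(np.uint8), (1.0, 1.0, 1.0))
        longest = longest_axial_diameter(mask)
        assert perpendicular_diameter(mask, longest) == pytest.approx(longest.length, abs=1.0)

    def test_thin_segment_is_zero(self):
        vox = np.zeros((16, 8, 4), dtype=np.uint8)
        vox[3:10, 4, 1] = 1
        mask = LabelMask(vox, (1.0, 1.0, 1.0))
        assert perpendicular_diameter(mask, longest_axial_diameter(mask)) == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_never_exceeds_longest(self, seed):
        rng = np.random.default_rng(100 + seed)
        mask = LabelMask(random_blob_mask(rng).astype(np.uint8), (0.9, 1.1, 2.5))
        longest = longest_axial_diameter(mask)
        assert perpendicular_diameter(mask, longest) <= longest.length + 1e-9


class TestScalarIndexes:
    @pytest.mark.parametrize("pre,post,expected", [(10, 7, -30), (10, 10, 0), (100, 60, -40)])
    def test_percent_change(self, pre, post, expected):
        assert percent_change(pre, post) == pytest.approx(expected)

    def test_percent_change_requires_positive_baseline(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 5.0)

    @pytest.mark.parametrize(
        "args,expected",
        [((10, 100, 5, 100), -5.0), ((10, 100, 20, 200), 0.0), ((10, 100, 10, 50), 10.0)],
    )
    def test_tumor_burden_change(self, args, expected):
        assert tumor_burden_change(*args) == pytest.approx(expected)

    def test_burden_requires_positive_pancreas(self):
        with pytest.raises(ValueError):
            tumor_burden_change(10, 0, 5, 100)


class TestCategoryProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        pre=st.floats(min_value=1e-3, max_value=1e4, allow_nan=False),
        post=st.floats(min_value=0.0, max_value=1e4, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_recist_consistent_with_percent_change(self, pre, post):
        pct = percent_change(pre, post)
        cat = recist_category(pct, post)
        if post == 0:
            assert cat == "CR"
        elif pct >= 20:
            assert cat == "PD"
        elif pct <= -30:
            assert cat == "PR"
        else:
            assert cat == "SD"

    @given(
        vt_pre=st.floats(0, 1e3),
        vt_post=st.floats(0, 1e3),
        vp=st.floats(1.0, 1e5),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_burden_change_antisymmetric_in_time(self, vt_pre, vt_post, vp):
        fwd = tumor_burden_change(vt_pre, vp, vt_post, vp)
        rev = tumor_burden_change(vt_post, vp, vt_pre, vp)
        assert fwd == pytest.approx(-rev, abs=1e-9)


class TestCategories:
    @pytest.mark.parametrize(
        "pct,post,expected",
        [
            (-35, 1.0, "PR"),
            (25, 1.0, "PD"),
            (-10, 1.0, "SD"),
            (-30, 1.0, "PR"),  # inclusive boundary
            (20, 1.0, "PD"),  # inclusive boundary
            (-100, 0.0, "CR"),
            (50, 0.0, "CR"),  # disappearance dominates
        ],
    )
    def test_recist(self, pct, post, expected):
        assert recist_category(pct, post) == expected

    @pytest.mark.parametrize(
        "pct,post,expected",
        [(-60, 1.0, "PR"), (30, 1.0, "PD"), (-40, 1.0, "SD"), (-50, 1.0, "PR"), (25, 1.0, "PD"), (0, 0.0, "CR")],
    )
    def test_who(self, pct, post, expected):
        assert who_category(pct, post) == expected

    def test_monotone_in_index(self):
        grid = np.linspace(-100, 100, 401)
        cats = [recist_category(v, 1.0) for v in grid]
        # PR region, then SD, then PD, with no interleaving
        changes = [c for c, _ in __import__("itertools").groupby(cats)]
        assert changes == ["PR", "SD", "PD"]


class TestRecordAssembly:
    def _identity_field(self, mask):
        return DeformationField.identity(mask.shape, mask.spacing)

    def test_registered_volume_identity_field(self, small_cohort):
        p = small_cohort.patients[0]
        tum = p.truth.true_tumor_pre
        assert registered_post_volume(tum, self._identity_field(tum)) == pytest.approx(mask_volume(tum))

    def test_cardinality_and_consistency(self, small_cohort):
        fields = {
            p.patient_id: p.truth.true_deformation for p in small_cohort.patients
        }
        records = build_response_records(small_cohort.annotation_mapping(), fields)
        assert len(records) == 4 * 4  # patients x readers
        for r in records:
            assert r.pct_dv_seg == pytest.approx(
                (r.v_tumor_post_seg - r.v_tumor_pre) / r.v_tumor_pre * 100, abs=1e-9
            )
            assert r.recist_vreg == recist_category(r.pct_dv_reg, r.v_tumor_post_reg)

    def test_burden_routes_agree_when_masks_agree(self, small_cohort):
        # with an identity field and the post segmentation equal to the pre
        # segmentation, the registered and segmented burden changes coincide
        p = small_cohort.patients[0]
        ann = {}
        for (rid, tp), a in p.annotations.items():
            ann[(p.patient_id, rid, tp)] = a
        # overwrite post annotations with the pre ones (same masks)
        for rid in {k[1] for k in ann}:
            pre = ann[(p.patient_id, rid, "pre")]
            ann[(p.patient_id, rid, "post")] = type(pre)(
                reader_id=pre.reader_id,
                experience=pre.experience,
                timepoint="post",
                pancreas_mask=pre.pancreas_mask,
                tumor_mask=pre.tumor_mask,
                longest_diameter=pre.longest_diameter,
                perpendicular_diameter=pre.perpendicular_diameter,
                slice_index=pre.slice_index,
            )
        fields = {p.patient_id: self._identity_field(p.truth.true_tumor_pre)}
        records = build_response_records(ann, fields)
        for r in records:
            assert r.db_seg == pytest.approx(r.db_reg, abs=1e-9)
            assert r.pct_dv_seg == pytest.approx(0.0, abs=1e-9)

    def test_missing_annotation_raises(self, small_cohort):
        mapping = small_cohort.annotation_mapping()
        key = next(iter(mapping))
        del mapping[(key[0], key[1], "post")]
        fields = {p.patient_id: p.truth.true_deformation for p in small_cohort.patients}
        with pytest.raises(KeyError, match="missing annotation"):
            build_response_records(mapping, fields)
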