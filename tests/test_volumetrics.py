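"""Volumetry, bidimensional measurement, and 2D-vs-3D scaling arithmetic."""

import numpy as np
import pytest

from gliogrow.errors import InvalidInputError
from gliogrow.volumetrics import (
    BidimConfig,
    MaskSeries,
    Segment,
    SegmentationLabeling,
    UNDEFINED_RATIO,
    bidim_progression,
    bidimensional_product,
    combine_segments,
    compute_volume,
    homogeneous_scaling,
    perpendicular_diameters,
    slice_growth_profile,
    volume_from_areas,
)


def _segments(intensities, shape=(8, 8)):
    segs = []
    for k, inten in enumerate(intensities):
        mask = np.zeros(shape, dtype=bool)
        mask[k, :] = True
        segs.append(Segment(mask, inten))
    return segs


class TestCombineSegments:
    def test_unions_exactly_the_segments_above_gray_level(self):
        intensities = [200, 180, 150, 120, 100, 90, 80, 70]
        lab = SegmentationLabeling(_segments(intensities), gray_matter_level=110)
        out = combine_segments(lab)
        expected = np.zeros((8, 8), dtype=bool)
        expected[:4, :] = True  # first four segments qualify
        assert np.array_equal(out, expected)

    def test_all_below_gray_level_gives_empty_mask(self):
        lab = SegmentationLabeling(_segments([100, 90, 80]), gray_matter_level=110)
        assert not combine_segments(lab).any()

    def test_intensity_equal_to_gray_level_is_excluded(self):
        lab = SegmentationLabeling(_segments([110]), gray_matter_level=110)
        assert not combine_segments(lab).any()

    def test_empty_segment_list_errors(self):
        with pytest.raises(InvalidInputError):
            combine_segments(SegmentationLabeling((), gray_matter_level=100))


class TestComputeVolume:
    def test_single_slice_area_times_distance(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[:2, :5] = True  # area 10
        ms = MaskSeries((mask,), slice_distance=5.0)
        assert compute_volume(ms) == 50.0

    def test_published_slice_areas_sum(self):
        # per-slice areas of a real tumor at baseline, 5-px slice spacing
        assert volume_from_areas([268, 1174, 1240, 962, 246], 5.0) == 19450.0

    def test_empty_masks_give_zero(self):
        ms = MaskSeries((np.zeros((4, 4), bool), np.zeros((4, 4), bool)))
        assert compute_volume(ms) == 0.0

    def test_invalid_slice_distance_errors(self):
        with pytest.raises(InvalidInputError):
            MaskSeries((np.ones((2, 2), bool),), slice_distance=0.0)

    def test_volume_scales_with_inplane_magnification_and_slice_distance(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[3:9, 4:12] = True
        k = 3
        big = np.kron(mask, np.ones((k, k), dtype=bool))
        v1 = compute_volume(MaskSeries((mask,), slice_distance=2.0))
        vk = compute_volume(MaskSeries((big,), slice_distance=2.0))
        assert vk == pytest.approx(v1 * k**2)
        v_d = compute_volume(MaskSeries((mask,), slice_distance=6.0))
        assert v_d == pytest.approx(3 * v1)


class TestSliceGrowthProfile:
    def test_growth_away_from_largest_slice_is_flagged(self):
        prof = slice_growth_profile([268, 1174, 1240, 962, 246], [718, 1262, 1764, 994, 282])
        assert prof.max_growth_slice == 0
        assert prof.largest_baseline_slice == 2
        assert prof.nonhomogeneous
        assert prof.fractional_change[0] == pytest.approx((718 - 268) / 268)  # ~ +168%
        assert prof.fractional_change[0] == pytest.approx(1.679, abs=5e-3)

    def test_identical_series_all_zero_flag_unset(self):
        prof = slice_growth_profile([268, 1174, 1240], [268, 1174, 1240])
        assert np.all(prof.fractional_change == 0)
        assert not prof.nonhomogeneous

    def test_uniform_growth_flag_unset(self):
        a0 = np.array([100.0, 400.0, 200.0])
        prof = slice_growth_profile(a0, a0 * 1.1)
        assert prof.fractional_change == pytest.approx([0.1, 0.1, 0.1])
        assert not prof.nonhomogeneous

    def test_zero_baseline_with_growth_reports_sentinel(self):
        prof = slice_growth_profile([0.0, 100.0], [50.0, 100.0])
        assert prof.fractional_change[0] == UNDEFINED_RATIO
        assert prof.nonhomogeneous

    def test_mismatched_slice_counts_error(self):
        with pytest.raises(InvalidInputError):
            slice_growth_profile([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_growth_off_the_largest_slice_of_mask_stacks(self):
        base = [np.zeros((32, 32), bool) for _ in range(3)]
        follow = [np.zeros((32, 32), bool) for _ in range(3)]
        base[1][8:24, 8:24] = True  # largest slice
        base[0][14:18, 14:18] = True
        follow[1][8:24, 8:24] = True  # unchanged
        follow[0][10:22, 10:22] = True  # small slice triples
        prof = slice_growth_profile(MaskSeries(tuple(base)), MaskSeries(tuple(follow)))
        assert prof.nonhomogeneous


def _disk(radius, size=None):
    size = size or (2 * radius + 5)
    yy, xx = np.mgrid[:size, :size]
    c = (size - 1) / 2
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def _ellipse(a, b, angle_deg=0.0, size=None):
    size = size or (2 * max(a, b) + 7)
    yy, xx = np.mgrid[:size, :size]
    c = (size - 1) / 2
    th = np.deg2rad(angle_deg)
    u = (xx - c) * np.cos(th) + (yy - c) * np.sin(th)
    v = -(xx - c) * np.sin(th) + (yy - c) * np.cos(th)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _brute_force_product(mask):
    """Independent oracle: scan every pixel pair (no boundary/hull reduction)
    for the longest diameter, then for the largest perpendicular component
    among pairs perpendicular within 1 degree or one pixel of shear."""
    pts = np.argwhere(mask).astype(float)
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    d1 = dist.max()
    if d1 == 0:
        return 1.0
    sin1 = np.sin(np.deg2rad(1.0))
    best = 0.0
    for i, j in np.argwhere(dist >= d1 - 1e-9):
        if i >= j:
            continue
        u = diff[i, j] / dist[i, j]
        par = np.abs(diff @ u)
        perp = np.sqrt(np.maximum(dist**2 - par**2, 0.0))
        ok = (par <= dist * sin1) | (par <= 1.0)
        best = max(best, perp[ok].max())
    return d1 * max(best, 1.0)


class TestBidimensionalProduct:
    def test_disk_product_is_four_r_squared(self):
        r = 12
        prod = bidimensional_product(_disk(r))
        assert prod == pytest.approx(4 * r**2, rel=0.06)  # rasterization error

    def test_single_pixel_convention(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        assert bidimensional_product(mask) == 1.0

    def test_empty_mask_errors(self):
        with pytest.raises(InvalidInputError):
            bidimensional_product(np.zeros((4, 4), bool))

    def test_axis_aligned_ellipse_matches_brute_force(self):
        mask = _ellipse(10, 5)  # full axes 20 and 10 px
        prod = bidimensional_product(mask)
        assert prod == pytest.approx(_brute_force_product(mask), rel=1e-9)
        assert prod == pytest.approx(200.0, rel=0.1)

    def test_rotation_tolerance_under_five_percent(self):
        ref = bidimensional_product(_ellipse(30, 15, 0.0, size=69))
        for angle in (15, 30, 45, 60, 75, 90):
            prod = bidimensional_product(_ellipse(30, 15, angle, size=69))
            assert abs(prod - ref) / ref < 0.05

    def test_collinear_mask_perpendicular_fallback(self):
        mask = np.zeros((9, 9), bool)
        mask[4, 1:8] = True  # a 1-px-thick line
        d1, d2 = perpendicular_diameters(mask)
        assert d1 == 6.0 and d2 == 1.0


class TestBidimProgression:
    @pytest.mark.parametrize(
        "baseline,current,expected",
        [(40.0, 50.0, True), (40.0, 49.0, False), (100.0, 125.0, True)],
    )
    def test_threshold_is_inclusive(self, baseline, current, expected):
        assert bidim_progression(baseline, current) is expected

    def test_nonpositive_baseline_errors(self):
        with pytest.raises(InvalidInputError):
            bidim_progression(0.0, 10.0)

    def test_custom_fraction(self):
        assert bidim_progression(100.0, 110.0, BidimConfig(progression_fraction=0.1))


class TestHomogeneousScaling:
    @pytest.mark.parametrize(
        "d,n,printed_pct",
        [(0.12, 2, 25), (0.12, 3, 41), (0.20, 3, 73), (0.25, 3, 95)],
    )
    def test_per_dimension_growth_to_measure_growth(self, d, n, printed_pct):
        # printed values are integer percents (41 for 1.12^3 = 1.404928)
        assert abs(100 * homogeneous_scaling(d, n) - printed_pct) <= 1.0

    def test_forty_four_percent_per_dimension_triples_volume(self):
        assert 1 + homogeneous_scaling(0.44, 3) == pytest.approx(3.0, abs=0.05)

    def test_zero_increase_identity(self):
        assert homogeneous_scaling(0.0, 3) == 0.0

    def test_invalid_dimensions_error(self):
        with pytest.raises(InvalidInputError):
            homogeneous_scaling(0.1, 4)

    def test_cuboid_mask_volume_composes_per_dimension(self):
        # applying (1+d) per dimension changes the measured volume by
        # (1+d)^3 up to rasterization error
        d = 0.25
        base = np.zeros((40, 40), bool)
        base[10:30, 8:24] = True  # 20 x 16
        grown = np.zeros((40, 40), bool)
        grown[8:33, 6:26] = True  # 25 x 20
        v0 = compute_volume(MaskSeries((base,) * 8, slice_distance=1.0))
        v1 = compute_volume(MaskSeries((grown,) * 10, slice_distance=1.0))
        assert v1 / v0 == pytest.approx((1 + d) ** 3, rel=0.02)
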