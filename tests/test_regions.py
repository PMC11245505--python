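"""Geometry operations against brute-force per-pixel oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis.extra import numpy as hnp

from ulcerquant import (
    EyeRegionSet,
    area_ratio,
    centroid,
    overlap_indicator,
    quadrant_count,
    quadrant_partition,
    region_area,
    vertical_extent_ratio,
)
from ulcerquant.regions import AnnotationError, EmptyRegionError, MaskShapeError

from conftest import make_disc


# -- brute-force oracles -----------------------------------------------------

def loop_area(mask):
    return sum(bool(mask[r, c]) for r in range(mask.shape[0]) for c in range(mask.shape[1]))


def loop_centroid(mask):
    pts = [(r, c) for r in range(mask.shape[0]) for c in range(mask.shape[1]) if mask[r, c]]
    return (sum(p[0] for p in pts) / len(pts), sum(p[1] for p in pts) / len(pts))


def loop_quadrant_index(r, c, orow, ocol):
    if r <= orow:
        return 0 if c <= ocol else 1
    return 3 if c <= ocol else 2


# -- area and ratio ----------------------------------------------------------

def test_region_area_trivial_grids():
    assert region_area(np.zeros((10, 10), dtype=bool)) == 0
    assert region_area(np.ones((10, 10), dtype=bool)) == 100


def test_region_area_rasterized_disc_near_pi_r_squared():
    disc = make_disc(101, (50, 50), 20)
    assert region_area(disc) == pytest.approx(np.pi * 20**2, rel=0.02)


def test_area_ratio_self_disjoint_and_partial():
    cornea = np.zeros((4, 4), dtype=bool)
    cornea[:3, :] = True  # 12 pixels
    assert area_ratio(cornea, cornea) == 1.0
    disjoint = np.zeros_like(cornea)
    disjoint[3, :] = True
    assert area_ratio(disjoint, cornea) == 0.0
    lesion = np.zeros_like(cornea)
    lesion[0, :3] = True  # 3 of 12 cornea pixels
    assert area_ratio(lesion, cornea) == 0.25


def test_area_ratio_clips_lesion_outside_cornea():
    cornea = make_disc(32, (15, 15), 8)
    lesion = np.ones((32, 32), dtype=bool)  # spills far past the limbus
    assert area_ratio(lesion, cornea) == 1.0


def test_area_ratio_empty_cornea_errors():
    with pytest.raises(EmptyRegionError):
        area_ratio(np.zeros((4, 4), dtype=bool), np.zeros((4, 4), dtype=bool))


def test_area_ratio_monotone_under_added_lesion_pixels(rng):
    cornea = make_disc(48, (23, 23), 20)
    lesion = make_disc(48, (18, 18), 6) & cornea
    r0 = area_ratio(lesion, cornea)
    grown = lesion.copy()
    free = np.transpose(np.nonzero(cornea & ~lesion))
    for r, c in free[rng.permutation(len(free))[:30]]:
        grown[r, c] = True
    assert area_ratio(grown, cornea) >= r0


# -- centroid ---------------------------------------------------------------

def test_centroid_examples():
    m = np.zeros((6, 6), dtype=bool)
    m[3, 4] = True
    assert centroid(m) == (3.0, 4.0)
    m2 = np.zeros((4, 4), dtype=bool)
    m2[0:2, 0:2] = True
    assert centroid(m2) == (0.5, 0.5)
    # L-shaped pentomino
    m3 = np.zeros((5, 5), dtype=bool)
    pts = [(0, 0), (1, 0), (2, 0), (3, 0), (3, 1)]
    for r, c in pts:
        m3[r, c] = True
    assert centroid(m3) == loop_centroid(m3)
    with pytest.raises(EmptyRegionError):
        centroid(np.zeros((3, 3), dtype=bool))


# -- quadrants ---------------------------------------------------------------

def test_quadrant_partition_is_exact_partition(rng):
    for _ in range(20):
        cornea = rng.random((64, 64)) < 0.3
        if not cornea.any():
            continue
        part = quadrant_partition(cornea)
        union = np.zeros_like(cornea)
        for i, qi in enumerate(part.masks):
            union |= qi
            for qj in part.masks[i + 1 :]:
                assert not np.any(qi & qj)
        assert np.array_equal(union, cornea)


def test_quadrant_partition_matches_per_pixel_rule(rng):
    cornea = rng.random((64, 64)) < 0.4
    part = quadrant_partition(cornea)
    orow, ocol = part.origin
    for r, c in np.transpose(np.nonzero(cornea)):
        k = loop_quadrant_index(r, c, orow, ocol)
        assert part.masks[k][r, c]


def test_quadrant_partition_centered_disc_quarters():
    # center between pixels so no pixel sits exactly on a partition axis
    cornea = make_disc(102, (50.5, 50.5), 40)
    part = quadrant_partition(cornea)
    target = region_area(cornea) / 4
    for q in part.masks:
        assert region_area(q) == pytest.approx(target, rel=0.01)


def test_single_pixel_cornea_lands_in_one_quadrant():
    cornea = np.zeros((9, 9), dtype=bool)
    cornea[4, 4] = True
    part = quadrant_partition(cornea)
    assert [region_area(q) for q in part.masks] == [1, 0, 0, 0]


def test_quadrant_count_range_cases():
    cornea = make_disc(64, (31, 31), 25)
    part = quadrant_partition(cornea)
    assert quadrant_count(cornea, part) == 4
    assert quadrant_count(np.zeros_like(cornea), part) == 0
    inside = make_disc(64, (15, 15), 5) & part.masks[0]
    assert quadrant_count(inside, part) == 1


# -- overlap -----------------------------------------------------------------

def test_overlap_indicator_branches_and_symmetry(rng):
    a = np.zeros((8, 8), dtype=bool)
    b = np.zeros((8, 8), dtype=bool)
    a[0, 0] = True
    b[7, 7] = True
    assert overlap_indicator(a, b) == 0
    b[0, 0] = True  # one shared pixel
    assert overlap_indicator(a, b) == 1
    assert overlap_indicator(np.zeros_like(a), b) == 0
    for _ in range(20):
        x = rng.random((16, 16)) < 0.2
        y = rng.random((16, 16)) < 0.2
        assert overlap_indicator(x, y) == overlap_indicator(y, x)
        assert overlap_indicator(x, y) == int(region_area(x & y) > 0)


# -- vertical extent ---------------------------------------------------------

def test_vertical_extent_full_empty_and_partial():
    cornea = make_disc(64, (31, 31), 20)
    assert vertical_extent_ratio(cornea, cornea) == 1.0
    assert vertical_extent_ratio(np.zeros_like(cornea), cornea) == 0.0
    crows = np.unique(np.nonzero(cornea)[0])
    band = np.zeros_like(cornea)
    band[crows[-len(crows) // 4 :], :] = True
    band &= cornea
    n = len(np.unique(np.nonzero(band)[0]))
    assert vertical_extent_ratio(band, cornea) == pytest.approx(n / len(crows))


def test_vertical_extent_ignores_lesion_outside_column_span():
    cornea = np.zeros((20, 20), dtype=bool)
    cornea[5:15, 5:15] = True  # 10 rows, cols 5..14
    lesion = np.zeros_like(cornea)
    lesion[0:20, 0] = True  # entirely outside the cornea's column span
    assert vertical_extent_ratio(lesion, cornea) == 0.0
    lesion[7, 7] = True
    assert vertical_extent_ratio(lesion, cornea) == pytest.approx(0.1)


# -- EyeRegionSet validation -------------------------------------------------

def test_eye_region_set_rejects_shape_mismatch():
    with pytest.raises(MaskShapeError):
        EyeRegionSet(np.ones((4, 4), dtype=bool), np.ones((5, 5), dtype=bool))


def test_pupil_outside_cornea_strict_vs_clip():
    cornea = make_disc(32, (15, 15), 10)
    pupil = make_disc(32, (15, 28), 4)  # partly outside the cornea
    with pytest.raises(AnnotationError):
        EyeRegionSet(cornea, pupil)
    eye = EyeRegionSet.from_masks(cornea, pupil, pupil_policy="clip")
    assert np.all(eye.cornea[eye.pupil])


@given(mask=hnp.arrays(bool, (16, 16)))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_partition_property_holds_for_arbitrary_masks(mask):
    if not mask.any():
        return
    part = quadrant_partition(mask)
    union = np.zeros_like(mask)
    for i, qi in enumerate(part.masks):
        assert not np.any(qi & union)
        union |= qi
    assert np.array_equal(union, mask)


@given(
    mask=hnp.arrays(bool, (12, 12)), other=hnp.arrays(bool, (12, 12))
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_overlap_indicator_symmetric_for_arbitrary_masks(mask, other):
    assert overlap_indicator(mask, other) == overlap_indicator(other, mask)
    assert overlap_indicator(mask, other) == int(region_area(mask & other) > 0)


def test_geometry_agrees_with_loops_on_random_masks(rng):
    for _ in range(10):
        m = rng.random((64, 64)) < 0.3
        assert region_area(m) == loop_area(m)
        if m.any():
            assert centroid(m) == pytest.approx(loop_centroid(m))
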