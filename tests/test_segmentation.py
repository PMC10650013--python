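import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaqueindex import (
    CTVolume,
    ContourSet,
    MaskVolume,
    SegmentationParams,
    auto_keyframe_contours,
    compute_api,
    interpolate_contours,
    region_grow,
    segment_aorta_plaque,
)
from plaqueindex.segmentation import (
    SegmentationError,
    SegmentationResult,
    read_contours,
    write_contours,
)

from conftest import bfs_flood_fill


def _circle(cy, cx, r, n=48):
    a = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cy + r * np.sin(a), cx + r * np.cos(a)])


# ---------------------------------------------------------------------------
# contour interpolation


def test_equal_keyframes_interpolate_to_identity():
    cs = ContourSet([(0, _circle(16, 16, 8)), (10, _circle(16, 16, 8))])
    tube = interpolate_contours(cs, (11, 32, 32), (1, 1, 1))
    ref = tube.mask.voxels[0]
    assert ref.sum() > 0
    for k in range(11):
        np.testing.assert_array_equal(tube.mask.voxels[k], ref)


def test_midway_slice_of_growing_circle_has_mid_radius():
    """SDT blending of concentric circles r=5 and r=15 gives ~r=10 midway."""
    cs = ContourSet([(0, _circle(20, 20, 5)), (10, _circle(20, 20, 15))])
    tube = interpolate_contours(cs, (11, 40, 40), (1, 1, 1))
    a0 = tube.mask.voxels[0].sum()
    a10 = tube.mask.voxels[10].sum()
    a5 = tube.mask.voxels[5].sum()
    assert a0 < a5 < a10
    assert a5 == pytest.approx(np.pi * 10 ** 2, rel=0.10)


def test_translated_keyframes_yield_single_connected_regions():
    cs = ContourSet([(0, _circle(12, 12, 6)), (12, _circle(28, 28, 6))])
    tube = interpolate_contours(cs, (13, 40, 40), (1, 1, 1))
    from scipy import ndimage

    for k in range(13):
        sl = tube.mask.voxels[k]
        assert sl.sum() > 0
        _, n = ndimage.label(sl)
        assert n == 1


def test_slices_outside_keyframe_range_empty():
    cs = ContourSet([(3, _circle(16, 16, 6)), (7, _circle(16, 16, 6))])
    tube = interpolate_contours(cs, (12, 32, 32), (1, 1, 1))
    assert not tube.mask.voxels[:3].any()
    assert not tube.mask.voxels[8:].any()
    assert tube.mask.voxels[3:8].all(axis=(1, 2)).shape  # slices 3..7 populated
    assert tube.mask.voxels[5].sum() > 0


def test_contour_validation():
    with pytest.raises(SegmentationError, match="at least 2"):
        ContourSet([(0, _circle(10, 10, 4))])
    with pytest.raises(SegmentationError, match="increasing"):
        ContourSet([(5, _circle(10, 10, 4)), (5, _circle(10, 10, 4))])
    bowtie = np.array([[0, 0], [4, 4], [0, 4], [4, 0]], float)
    with pytest.raises(SegmentationError, match="self-intersecting"):
        ContourSet([(0, bowtie), (5, _circle(10, 10, 4))])


def test_contour_text_format_roundtrip(tmp_path):
    cs = ContourSet([(0, _circle(10, 10, 4, n=8)), (9, _circle(12, 12, 5, n=8))])
    p = tmp_path / "contours.txt"
    write_contours(cs, p)
    back = read_contours(p)
    assert back.keyframes == cs.keyframes
    for (_, a), (_, b) in zip(cs.contours, back.contours):
        np.testing.assert_allclose(a, b, atol=1e-3)


def test_contour_parse_error_names_line(tmp_path):
    p = tmp_path / "bad.txt"
    p.write_text("0 1.0 2.0\n0 oops 3.0\n")
    with pytest.raises(SegmentationError, match="line 2"):
        read_contours(p)


# ---------------------------------------------------------------------------
# automatic keyframing


def _cylinder_volume(r=10.0, nz=40, ny=48, nx=48, hu_in=250.0, hu_out=30.0):
    yy, xx = np.mgrid[0:ny, 0:nx]
    d2 = (yy + 0.5 - ny / 2) ** 2 + (xx + 0.5 - nx / 2) ** 2
    sl = np.where(d2 <= r * r, hu_in, hu_out)
    return CTVolume(voxels=np.broadcast_to(sl, (nz, ny, nx)).copy(), spacing=(1, 1, 1))


def test_auto_contours_recover_circle_area():
    vol = _cylinder_volume()
    cs = auto_keyframe_contours(vol, stride=10, hu_floor=100)
    tube = interpolate_contours(cs, vol.shape, vol.spacing)
    for k in (0, 10, 20, 39):
        assert tube.mask.voxels[k].sum() == pytest.approx(np.pi * 100, rel=0.10)


def test_auto_contours_on_background_volume_errors():
    vol = CTVolume(voxels=np.full((10, 16, 16), 30.0), spacing=(1, 1, 1))
    with pytest.raises(SegmentationError, match="slice 0"):
        auto_keyframe_contours(vol, stride=5, hu_floor=100)


def test_stride_beyond_stack_falls_back_to_first_and_last():
    vol = _cylinder_volume(nz=7)
    cs = auto_keyframe_contours(vol, stride=100, hu_floor=100)
    assert cs.keyframes == [0, 6]


# ---------------------------------------------------------------------------
# region growing


def test_uniform_volume_full_flood():
    vol = CTVolume(voxels=np.full((6, 6, 6), 200.0), spacing=(1, 1, 1))
    cons = MaskVolume(voxels=np.ones((6, 6, 6), np.uint8), spacing=(1, 1, 1))
    out = region_grow(vol, [(0, 0, 0)], 100, 300, cons)
    assert out.voxels.all()


def test_seed_outside_band_rejected():
    vol = CTVolume(voxels=np.full((4, 4, 4), 500.0), spacing=(1, 1, 1))
    cons = MaskVolume(voxels=np.ones((4, 4, 4), np.uint8), spacing=(1, 1, 1))
    with pytest.raises(SegmentationError, match="invalid seeds"):
        region_grow(vol, [(0, 0, 0)], 100, 300, cons)


@pytest.mark.parametrize("connectivity", [6, 26])
def test_region_grow_matches_bfs_oracle_on_random_volumes(connectivity):
    rng = np.random.default_rng(7 + connectivity)
    for _ in range(25):
        vox = rng.uniform(0, 400, (12, 12, 12))
        cons = rng.random((12, 12, 12)) < 0.8
        lo, hi = sorted(rng.uniform(0, 400, 2))
        eligible = np.argwhere(cons & (vox >= lo) & (vox < hi))
        if len(eligible) == 0:
            continue
        seeds = [tuple(eligible[i]) for i in rng.choice(len(eligible),
                                                        min(3, len(eligible)), replace=False)]
        got = region_grow(CTVolume(voxels=vox, spacing=(1, 1, 1)), seeds, lo, hi,
                          MaskVolume(voxels=cons.astype(np.uint8), spacing=(1, 1, 1)),
                          connectivity)
        want = bfs_flood_fill(vox, seeds, lo, hi, cons, connectivity)
        np.testing.assert_array_equal(got.voxels.astype(bool), want)


# ---------------------------------------------------------------------------
# full segmentation + volumetry


def test_zero_plaque_phantom_has_empty_plaque_and_zero_api(segmented_suite):
    spec, truth, seg, api = segmented_suite[0]
    assert truth.api_percent == 0
    assert seg.plaque.voxels.sum() == 0
    assert api.api_percent == 0


def test_suite_masks_disjoint_and_lumen_volume_recovered(segmented_suite):
    for spec, truth, seg, api in segmented_suite:
        assert not np.any(seg.lumen.voxels & seg.plaque.voxels)
        assert api.lumen_mm3 == pytest.approx(truth.lumen_volume_mm3, rel=0.05)


def test_overlapping_masks_rejected():
    m = MaskVolume(voxels=np.ones((2, 2, 2), np.uint8), spacing=(1, 1, 1))
    with pytest.raises(SegmentationError, match="overlap"):
        SegmentationResult(lumen=m, plaque=m, params=SegmentationParams())


def test_band_params_must_be_disjoint():
    with pytest.raises(SegmentationError, match="disjoint"):
        SegmentationParams(t_lumen_lo=100, t_lumen_hi=500, t_plaque_lo=400)


def test_no_lumen_seeds_raises():
    vol = CTVolume(voxels=np.full((6, 16, 16), 30.0), spacing=(1, 1, 1))
    tube = interpolate_contours(
        ContourSet([(0, _circle(8, 8, 5)), (5, _circle(8, 8, 5))]), vol.shape, vol.spacing)
    with pytest.raises(SegmentationError, match="no lumen seeds"):
        segment_aorta_plaque(vol, tube)


def test_api_arithmetic_and_empty_error():
    mk = lambda n: MaskVolume(
        voxels=np.r_[np.ones(n, np.uint8), np.zeros(1000 - n, np.uint8)].reshape(10, 10, 10),
        spacing=(1, 1, 1))
    seg = SegmentationResult(lumen=mk(0), plaque=mk(0), params=SegmentationParams())
    with pytest.raises(SegmentationError, match="empty"):
        compute_api(seg)

    lumen = np.zeros((10, 10, 10), np.uint8)
    plaque = np.zeros((10, 10, 10), np.uint8)
    lumen[:5] = 1
    plaque[5:] = 1
    seg = SegmentationResult(
        lumen=MaskVolume(voxels=lumen, spacing=(1, 1, 1)),
        plaque=MaskVolume(voxels=plaque, spacing=(1, 1, 1)),
        params=SegmentationParams(),
    )
    assert compute_api(seg).api_percent == pytest.approx(50.0)  # Vp == Vl


@given(scale=st.floats(0.25, 4.0))
@settings(max_examples=10)
def test_api_is_scale_invariant(scale):
    """Multiplying all spacings by a constant leaves the volume ratio unchanged."""
    rng = np.random.default_rng(3)
    lumen = (rng.random((8, 8, 8)) < 0.5).astype(np.uint8)
    plaque = ((rng.random((8, 8, 8)) < 0.3) & ~lumen.astype(bool)).astype(np.uint8)
    if plaque.sum() == 0 or lumen.sum() == 0:
        return
    base = SegmentationResult(
        lumen=MaskVolume(voxels=lumen, spacing=(1, 1, 1)),
        plaque=MaskVolume(voxels=plaque, spacing=(1, 1, 1)),
        params=SegmentationParams(),
    )
    a = compute_api(base, spacing=(1, 1, 1))
    b = compute_api(base, spacing=(scale, scale, scale))
    assert a.api_percent == pytest.approx(b.api_percent, rel=1e-12)
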