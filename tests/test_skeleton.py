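"""Thinning, trunk selection, smoothing and contour extension."""

import numpy as np
import pytest
from shapely.geometry import Point

from cucumorph.config import SkeletonConfig
from cucumorph.errors import DegenerateSkeletonError, NoObjectError, SkeletonTopologyError
from cucumorph.preprocessing import _component_contour
from cucumorph.skeleton import (
    SkeletonPolyline,
    extend_to_contour,
    extract_trunk,
    find_endpoints,
    optimized_centerline,
    smooth_skeleton,
    thin,
)
from cucumorph.synthetic import FrontalSpec, generate_frontal

from conftest import disk_mask, make_config


def test_thin_bar_gives_centerline():
    mask = np.zeros((15, 110), dtype=bool)
    mask[5:10, 5:105] = True
    sk = thin(mask)
    trunk = extract_trunk(sk)
    assert 90 <= trunk.arc_length_px <= 105
    # 1-px wide: no skeleton column holds more than 2 pixels
    assert max(sk[:, c].sum() for c in range(10, 100)) <= 2


def test_thin_single_pixel_is_fixed_point():
    mask = np.zeros((9, 9), dtype=bool)
    mask[4, 4] = True
    assert thin(mask).sum() == 1


def test_thin_disk_collapses_to_near_point():
    sk = thin(disk_mask(20))
    assert 1 <= sk.sum() <= 5


def test_thin_empty_mask_is_error():
    with pytest.raises(NoObjectError):
        thin(np.zeros((10, 10), dtype=bool))


def _line(r0, c0, r1, c1):
    """8-connected digital segment as a pixel list."""
    n = max(abs(r1 - r0), abs(c1 - c0))
    return [(round(r0 + (r1 - r0) * i / n), round(c0 + (c1 - c0) * i / n))
            for i in range(n + 1)]


def _raster(pixels, shape=(140, 140)):
    sk = np.zeros(shape, dtype=bool)
    for r, c in pixels:
        sk[r, c] = True
    return sk


def test_find_endpoints_line_y_ring():
    line = _raster(_line(10, 10, 10, 60))
    assert len(find_endpoints(line)) == 2
    y = _raster(_line(60, 60, 60, 10) + _line(60, 60, 20, 100) + _line(60, 60, 100, 100))
    assert len(find_endpoints(y)) == 3
    ring = np.zeros((30, 30), dtype=bool)
    for t in np.linspace(0, 2 * np.pi, 200):
        ring[int(15 + 9 * np.sin(t)), int(15 + 9 * np.cos(t))] = True
    ring = thin(ring)
    assert find_endpoints(ring) == []


def test_extract_trunk_takes_longest_geodesic_pair():
    # Y with arm geodesic lengths ~50 / ~40 / ~30: trunk joins the two longest
    y = _raster(
        _line(70, 70, 70, 20)      # 50 px west arm
        + _line(70, 70, 30, 70)    # 40 px north arm
        + _line(70, 70, 100, 70)   # 30 px south arm
    )
    trunk = extract_trunk(y)
    assert trunk.arc_length_px == pytest.approx(90, abs=3)
    ends = {tuple(trunk.points[0].astype(int)), tuple(trunk.points[-1].astype(int))}
    assert ends == {(70, 20), (30, 70)}


def test_extract_trunk_straight_line_identity():
    line = _raster(_line(10, 10, 10, 90))
    trunk = extract_trunk(line)
    assert trunk.arc_length_px == pytest.approx(80, abs=1)
    assert np.all(trunk.points[:, 0] == 10)


def test_extract_trunk_needs_two_endpoints():
    ring = np.zeros((30, 30), dtype=bool)
    for t in np.linspace(0, 2 * np.pi, 400):
        ring[int(15 + 9 * np.sin(t)), int(15 + 9 * np.cos(t))] = True
    with pytest.raises(SkeletonTopologyError):
        extract_trunk(thin(ring))


def test_smooth_skeleton_preserves_collinear_points():
    pts = np.column_stack([np.full(60, 20.0), np.arange(60.0)])
    out = smooth_skeleton(SkeletonPolyline(points=pts), SkeletonConfig())
    assert np.allclose(out.points[:, 0], 20.0, atol=1e-6)


def test_smooth_skeleton_reduces_zigzag():
    cols = np.arange(0.0, 300.0)
    rows = 50.0 + 2.0 * (np.arange(300) % 2)  # +-1 px zigzag about 51
    out = smooth_skeleton(SkeletonPolyline(points=np.column_stack([rows, cols])))
    assert np.abs(out.points[:, 0] - 51.0).max() < 2.0
    assert np.abs(out.points[:, 0] - 51.0).mean() < np.abs(rows - 51.0).mean()


def test_smooth_skeleton_too_short_is_degenerate():
    pts = np.column_stack([np.full(10, 5.0), np.arange(10.0)])
    with pytest.raises(DegenerateSkeletonError):
        smooth_skeleton(SkeletonPolyline(points=pts), SkeletonConfig(step=5))


def test_extend_to_contour_reaches_rectangle_short_sides():
    mask = np.zeros((60, 220), dtype=bool)
    mask[10:50, 10:210] = True
    contour = _component_contour(mask)
    trunk = SkeletonPolyline(
        points=np.column_stack([np.full(120, 29.5), np.arange(50.0, 170.0)])
    )
    ext = extend_to_contour(trunk, contour, SkeletonConfig())
    assert ext.arc_length_px == pytest.approx(200, abs=2)


def test_extend_to_contour_touching_is_unchanged():
    mask = np.zeros((60, 120), dtype=bool)
    mask[10:50, 10:110] = True
    contour = _component_contour(mask)
    pts = np.column_stack([np.full(50, 30.0), np.linspace(9.6, 109.4, 50)])
    ext = extend_to_contour(SkeletonPolyline(points=pts), contour, SkeletonConfig())
    assert ext.arc_length_px == pytest.approx(99.8, abs=2)


def test_capsule_centerline_endpoints_near_truth():
    spec = FrontalSpec(silhouette="capsule", length_cm=18, body_diameter_cm=4,
                       curvature_arc=1.0, seed=4)
    image, truth = generate_frontal(spec)
    from cucumorph.preprocessing import preprocess_frontal

    cfg = make_config()
    fruit, _ = preprocess_frontal(image, cfg.preprocess)
    ext = optimized_centerline(fruit.mask, fruit, cfg.skeleton)
    for meas, true in ((ext.points[0], truth.centerline[0]),
                       (ext.points[-1], truth.centerline[-1])):
        lo = min(np.hypot(*(meas - truth.centerline[0])),
                 np.hypot(*(meas - truth.centerline[-1])))
        assert lo < 3.0


def test_extended_centerline_stays_inside_contour(frontal_scene):
    _, _, analysis = frontal_scene
    poly = analysis.contour.polygon.buffer(0.6)  # endpoints sit ON the boundary
    assert all(poly.covers(Point(*p)) for p in analysis.polyline.points)


def test_straight_rod_length_recovered_within_2pct():
    spec = FrontalSpec(silhouette="capsule", length_cm=20, body_diameter_cm=3.5,
                       curvature_arc=1.0, seed=6)
    image, truth = generate_frontal(spec)
    from cucumorph.pipeline import analyze_frontal

    analysis = analyze_frontal(image, make_config())
    assert analysis.traits.Fl == pytest.approx(truth.length_cm, rel=0.02)
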