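"""Sarcocarp selection, smoothness, flesh geometry and carpel counting."""

import math

import numpy as np
import pytest
from shapely.geometry import Polygon

from cucumorph.cross_section import (
    CARPEL_CLASSES,
    count_carpels,
    flesh_traits,
    pick_sarcocarp_contour,
    radial_signature,
    segment_endocarp_baseline,
    smoothness_traits,
)
from cucumorph.errors import GeometryError, NoObjectError
from cucumorph.preprocessing import Contour, ScaleCalibration, _component_contour
from cucumorph.synthetic import CrossSpec, generate_cross

from conftest import disk_mask

SCALE = ScaleCalibration(px_per_cm=10.0, card_length_cm=3.0)


def _polar_contour(radius_fn, center=(300.0, 300.0), n=1440):
    """Analytic star-shaped contour r(theta) as a Contour (no raster)."""
    theta = np.linspace(0, 2 * math.pi, n, endpoint=False)
    r = radius_fn(theta)
    pts = np.column_stack([center[0] + r * np.sin(theta), center[1] + r * np.cos(theta)])
    poly = Polygon(pts)
    return Contour(points=pts, area_px=poly.area, perimeter_px=poly.length)


def test_carpel_taxonomy_has_four_classes():
    assert CARPEL_CLASSES == (2, 3, 4, 5)


def test_pick_sarcocarp_prefers_circular_object():
    # disk on the left, square card on the right
    mask = np.zeros((300, 560), dtype=bool)
    d = disk_mask(100, pad=20)
    mask[30:270, 20:260] = d
    mask[50:250, 330:530] = True
    chosen = pick_sarcocarp_contour(mask)
    assert chosen.centroid[1] < 280  # the disk side


def test_pick_sarcocarp_single_component():
    mask = np.zeros((200, 200), dtype=bool)
    mask[40:160, 40:160] = True
    assert pick_sarcocarp_contour(mask).area_px == pytest.approx(120 * 120, rel=0.02)


def test_smoothness_of_perfect_disk():
    contour = _polar_contour(lambda th: np.full_like(th, 100.0))
    t = smoothness_traits(contour, SCALE)
    assert t.Rl_s == pytest.approx(1.0, abs=0.02)
    assert t.Hr_s == pytest.approx(1.0, abs=0.01)
    assert t.Cr_s == pytest.approx(1.0, abs=0.02)
    assert t.Cdv < 1e-3


def test_lobed_flower_cdv_matches_radial_variance():
    R = 100.0  # px; 10 cm at this scale -> R_cm = 10
    contour = _polar_contour(lambda th: R * (1 + 0.1 * np.sin(10 * th)))
    t = smoothness_traits(contour, SCALE)
    # var(0.1 * R * sin) = 0.005 R^2 -> in cm^2: 0.005 * 10^2 = 0.5
    assert t.Cdv == pytest.approx(0.5, rel=0.10)


def test_lobed_shape_rougher_than_smooth_counterpart():
    smooth = smoothness_traits(_polar_contour(lambda th: np.full_like(th, 100.0)), SCALE)
    lobed = smoothness_traits(
        _polar_contour(lambda th: 100 * (1 + 0.08 * np.sin(10 * th))), SCALE)
    assert lobed.Hr_s < smooth.Hr_s
    assert lobed.Cr_s < smooth.Cr_s
    assert lobed.Rl_s < smooth.Rl_s
    assert lobed.Cf_s < smooth.Cf_s
    assert lobed.Cdv > smooth.Cdv


def test_flesh_traits_circular_equivalent_formulas():
    # Ss = 3*pi cm^2, Se = pi cm^2 -> Re = 1 cm, Tm = 1 cm, Ptr = 1, Pe = 1/3
    ppcm2 = SCALE.px_per_cm**2
    meso = np.zeros((200, 200), dtype=bool)
    endo = np.zeros((200, 200), dtype=bool)
    rr, cc = np.mgrid[:200, :200]
    r2 = (rr - 100.0) ** 2 + (cc - 100.0) ** 2
    endo[r2 <= (10.0) ** 2] = True          # ~ pi cm^2 at 10 px/cm
    meso[(r2 > 10.0**2) & (r2 <= 20.0**2)] = True
    t = flesh_traits(meso, endo, SCALE)
    assert t.Re == pytest.approx(1.0, rel=0.02)
    assert t.Tm == pytest.approx(1.0, rel=0.03)
    assert t.Ptr == pytest.approx(1.0, rel=0.05)
    assert t.Pe == pytest.approx(1 / 3, rel=0.05)


def test_annulus_mesocarp_thickness():
    # outer R = 4 cm, inner r = 2 cm at 30 px/cm: Tm = R - r = 2 cm
    scale = ScaleCalibration(px_per_cm=30.0, card_length_cm=3.0)
    size = 300
    rr, cc = np.mgrid[:size, :size]
    r2 = (rr - 150.0) ** 2 + (cc - 150.0) ** 2
    endo = r2 <= 60.0**2
    meso = (r2 > 60.0**2) & (r2 <= 120.0**2)
    t = flesh_traits(meso, endo, scale)
    assert t.Tm == pytest.approx(2.0, rel=0.02)


def test_missing_endocarp_gives_missing_values():
    meso = np.zeros((50, 50), dtype=bool)
    meso[10:40, 10:40] = True
    t = flesh_traits(meso, None, SCALE)
    assert math.isnan(t.Tm) and math.isnan(t.Se) and t.Nc is None


@pytest.mark.parametrize("k", [2, 3, 4, 5])
def test_count_carpels_star_masks(k):
    size = 400
    rr, cc = np.mgrid[:size, :size]
    th = np.arctan2(rr - 200.0, cc - 200.0)
    r = np.hypot(rr - 200.0, cc - 200.0)
    mask = r <= 120 * (1 + 0.25 * np.sin(k * th))
    assert count_carpels(mask) == k


def test_count_carpels_circle_is_unclassified():
    assert count_carpels(disk_mask(80)) is None


def test_count_carpels_empty_is_error():
    with pytest.raises(NoObjectError):
        count_carpels(np.zeros((10, 10), dtype=bool))


def test_endocarp_baseline_iou_against_truth(cross_scene, cfg):
    image, truth, _ = cross_scene
    meso, endo = segment_endocarp_baseline(image, truth.sarcocarp_mask)
    assert endo is not None
    inter = (endo & truth.endocarp_mask).sum()
    union = (endo | truth.endocarp_mask).sum()
    assert inter / union >= 0.85
    assert not (meso & endo).any()


def test_uniform_section_flags_missing_endocarp():
    image = np.zeros((120, 120, 3), dtype=np.uint8)
    image[:] = (150, 200, 140)
    mask = np.zeros((120, 120), dtype=bool)
    mask[20:100, 20:100] = True
    meso, endo = segment_endocarp_baseline(image, mask)
    assert endo is None
    assert np.array_equal(meso, mask)


def test_cross_pipeline_mass_conservation(cross_scene):
    _, truth, row = cross_scene
    measured = row["Ss"] + row["Se"]
    true_total = truth.Ss_cm2 + truth.Se_cm2
    assert measured == pytest.approx(true_total, rel=0.01)
    assert row["Nc"] == truth.spec.carpel_count
    assert row["Tm"] >= 0
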