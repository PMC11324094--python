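"""Contour, curvature, diameter and neck/tip trait formulas against analytic oracles."""

import math

import numpy as np
import pytest

from cucumorph.preprocessing import ScaleCalibration, _component_contour
from cucumorph.profiles import DiameterProfile, FruitSegmentation
from cucumorph.skeleton import SkeletonPolyline
from cucumorph.traits import (
    FrontalTraits,
    contour_traits,
    curvature,
    diameter_traits,
    end_descriptors,
)
from cucumorph.pipeline import analyze_frontal
from cucumorph.synthetic import FrontalSpec, generate_frontal

from conftest import disk_mask, make_config

UNIT10 = ScaleCalibration(px_per_cm=10.0, card_length_cm=3.0)


def test_disk_contour_traits_match_circle_formulas():
    t = contour_traits(_component_contour(disk_mask(100, pad=10)), UNIT10)
    assert t.S == pytest.approx(math.pi * 10**2, rel=0.01)      # r = 10 cm
    assert t.Rl_f == pytest.approx(1.0, abs=0.03)
    assert t.Hr_f == pytest.approx(1.0, abs=0.01)
    assert t.Cr_f == pytest.approx(1.0, abs=0.03)
    assert t.Cf_f == pytest.approx(1.0, abs=0.03)
    assert t.Er_f == pytest.approx(1.0, abs=0.03)
    assert t.Ll == pytest.approx(20.0, rel=0.02)


def test_square_contour_traits():
    mask = np.zeros((220, 220), dtype=bool)
    mask[10:210, 10:210] = True
    t = contour_traits(_component_contour(mask), UNIT10)
    assert t.Dr == pytest.approx(1.0, abs=0.02)
    assert t.Cr_f == pytest.approx(2 / math.pi, abs=0.02)
    assert t.Hr_f == pytest.approx(1.0, abs=0.01)  # convex shape


@pytest.mark.parametrize(
    "builder, expected",
    [
        # straight rod
        (lambda: np.column_stack([np.full(100, 5.0), np.linspace(0, 200, 100)]), 1.0),
        # semicircular centerline: arc/chord = pi/2
        (lambda: np.column_stack(
            [100 - 100 * np.sin(np.linspace(0, np.pi, 200)),
             100 * np.cos(np.linspace(0, np.pi, 200))]), math.pi / 2),
        # quarter circle: (pi/2)/sqrt(2)
        (lambda: np.column_stack(
            [100 - 100 * np.cos(np.linspace(0, np.pi / 2, 200)),
             100 * np.sin(np.linspace(0, np.pi / 2, 200))]), (math.pi / 2) / math.sqrt(2)),
    ],
)
def test_curvature_arc_chord_oracles(builder, expected):
    assert curvature(SkeletonPolyline(points=builder())) == pytest.approx(expected, rel=0.02)


def _rod_profile_and_segmentation(n=100, diam=40.0, length=400.0):
    positions = np.linspace(0, length, n)
    diams = np.full(n, diam)
    chords = np.stack([np.stack([np.column_stack([np.zeros(n), positions])[i],
                                 np.column_stack([np.full(n, diam), positions])[i]])
                       for i in range(n)])
    profile = DiameterProfile(positions=positions, diameters=diams, chords=chords,
                              min_dists=diams / 2, point_index=np.arange(n))
    labels = np.array(
        ["stalk"] * 10 + ["neck"] * 15 + ["body"] * 50 + ["tip"] * 15 + ["stem"] * 10,
        dtype=object)
    edges = positions[[10, 25, 75, 90]]
    lengths = {"stalk": edges[0] / 10, "neck": (edges[1] - edges[0]) / 10,
               "body": (edges[2] - edges[1]) / 10, "tip": (edges[3] - edges[2]) / 10,
               "stem": (length - edges[3]) / 10}
    seg = FruitSegmentation(boundaries=edges, lengths_cm=lengths, labels=labels)
    return profile, seg


def test_diameter_traits_arithmetic():
    profile, seg = _rod_profile_and_segmentation()
    line = SkeletonPolyline(points=np.column_stack(
        [np.full(100, 20.0), np.linspace(0, 400, 100)]))
    t = diameter_traits(profile, seg, line, UNIT10)
    assert t.Fd == pytest.approx(4.0)              # 40 px at 10 px/cm
    assert t.Dr_f == pytest.approx(0.0, abs=1e-9)  # constant width
    assert t.Dr_n == pytest.approx(1.0, abs=0.01)
    assert t.Dr_t == pytest.approx(1.0, abs=0.01)
    assert t.Nr == pytest.approx(seg.lengths_cm["neck"] / seg.lengths_cm["body"])
    assert t.Tr == pytest.approx(seg.lengths_cm["tip"] / seg.lengths_cm["body"])
    assert t.V == pytest.approx(math.pi * (t.Fd / 2) ** 2 * t.Fl, rel=1e-9)


def test_volume_formula_on_generator_fruit(frontal_scene):
    _, truth, analysis = frontal_scene
    t = analysis.traits
    spec = truth.spec
    expected = math.pi * (spec.body_diameter_cm / 2) ** 2 * spec.length_cm
    assert t.V == pytest.approx(expected, rel=0.03)


def _triangular_tip():
    """Isoceles tip: base 2 cm wide at the widest chord, apex 2 cm beyond."""
    n = 41
    positions = np.linspace(0.0, 20.0, n)           # px at 10 px/cm -> 2 cm
    halfw = np.linspace(10.0, 0.25, n)              # tapers to the apex
    diams = 2 * halfw
    chords = np.stack([
        np.stack([[ -halfw[i], positions[i]], [halfw[i], positions[i]]])
        for i in range(n)])
    profile = DiameterProfile(positions=positions, diameters=diams, chords=chords,
                              min_dists=halfw, point_index=np.arange(n))
    labels = np.array(["tip"] * n, dtype=object)
    seg = FruitSegmentation(
        boundaries=np.array([0.0, 0.0, 0.0, 20.0]),
        lengths_cm={"stalk": 0, "neck": 0, "body": 0, "tip": 2.0, "stem": 0},
        labels=labels, degenerate={"stalk", "neck", "stem"}, neck_side_left=True)
    line = SkeletonPolyline(points=np.column_stack([np.zeros(n), positions]))
    return profile, seg, line


def test_tip_descriptors_triangle_oracle():
    profile, seg, line = _triangular_tip()
    t = end_descriptors(seg, profile, line, "tip", UNIT10)
    # angle at the apex subtended by the 2-cm base, apex 2 cm away:
    assert t.Ta == pytest.approx(math.degrees(2 * math.atan(1 / 2)), abs=2.0)
    assert t.Ti == pytest.approx(2.0 / 2.0, rel=0.01)   # Lt / Dmax = 2 cm / 2 cm
    assert t.Tp == pytest.approx(1.0, abs=0.02)         # monotone taper: all distal


def test_neck_descriptors_missing_for_degenerate_segment():
    profile, seg, line = _triangular_tip()
    t = end_descriptors(seg, profile, line, "neck", UNIT10)
    assert math.isnan(t.Na) and math.isnan(t.Ni) and math.isnan(t.Np)


def test_rotation_invariance_of_traits(cfg, frontal_scene):
    image, _, analysis = frontal_scene
    rotated = analyze_frontal(np.rot90(image).copy(), cfg)
    a, b = analysis.traits, rotated.traits
    for name in ("Fl", "Fd", "S", "Lc", "Lout", "Wout"):
        assert getattr(b, name) == pytest.approx(getattr(a, name), rel=0.01), name
    for name in ("Dr", "Hr_f", "Cr_f", "Cf_f", "Rl_f", "Cv", "Ar", "Er_f"):
        assert getattr(b, name) == pytest.approx(getattr(a, name), rel=0.02), name


def test_scale_invariance_of_dimensionless_traits(cfg):
    from skimage.transform import rescale

    image, _ = generate_frontal(FrontalSpec(seed=21))
    big = (rescale(image, (2, 2, 1), order=0, preserve_range=True)).astype(np.uint8)
    a = analyze_frontal(image, cfg).traits
    b = analyze_frontal(big, cfg).traits
    for name in ("Fl", "Fd", "S"):
        assert getattr(b, name) == pytest.approx(getattr(a, name), rel=0.01), name
    for name in ("Dr", "Hr_f", "Cr_f", "Cf_f", "Rl_f", "Cv"):
        assert getattr(b, name) == pytest.approx(getattr(a, name), rel=0.02), name
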