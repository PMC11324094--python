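"""Foreground extraction, card/fruit assignment and metric calibration."""

import numpy as np
import pytest
from skimage.transform import rescale

from cucumorph.config import PreprocessConfig
from cucumorph.errors import (
    AmbiguousSceneError,
    ConfigError,
    InvalidImageError,
    MissingReferenceError,
    NoObjectError,
)
from cucumorph.preprocessing import (
    _component_contour,
    assign_card_and_fruit,
    calibrate_scale,
    rectangularity,
    segment_foreground,
    supergreen_transform,
    two_largest_contours,
)
from cucumorph.synthetic import FrontalSpec, generate_frontal

from conftest import disk_mask, make_config


@pytest.mark.parametrize(
    "rgb, expected",
    [((0, 255, 0), 255), ((255, 0, 0), 0), ((100, 100, 100), 0), ((10, 200, 30), 255)],
)
def test_supergreen_pixel_values(rgb, expected):
    img = np.zeros((32, 32, 3), dtype=np.uint8)
    img[:] = rgb
    assert supergreen_transform(img)[0, 0] == expected


def test_supergreen_rejects_non_rgb():
    with pytest.raises(InvalidImageError):
        supergreen_transform(np.zeros((40, 40), dtype=np.uint8))
    with pytest.raises(InvalidImageError):
        supergreen_transform(np.zeros((40, 40, 4), dtype=np.uint8))


def test_supergreen_range_invariant():
    rng = np.random.default_rng(0)
    img = rng.integers(0, 256, size=(48, 48, 3), dtype=np.uint8)
    out = supergreen_transform(img)
    assert out.min() >= 0 and out.max() <= 255


def test_segment_foreground_recovers_disk_and_drops_speckles():
    truth = disk_mask(60, pad=20)
    gray = np.where(truth, 200, 5).astype(np.uint8)
    rng = np.random.default_rng(1)
    # 3-px speckles sprinkled on the background
    for _ in range(12):
        r, c = rng.integers(5, 150, size=2)
        if not truth[r - 2:r + 2, c - 2:c + 2].any():
            gray[r:r + 2, c:c + 2] = 220
    mask = segment_foreground(gray, PreprocessConfig(card_length_cm=3.0))
    recovered = (mask & truth).sum() / truth.sum()
    spurious = (mask & ~truth).sum() / truth.sum()
    assert recovered >= 0.98
    assert spurious <= 0.01
    from scipy import ndimage

    assert ndimage.label(mask)[1] == 1  # speckles gone


def test_segment_foreground_all_dark_is_error():
    with pytest.raises(NoObjectError):
        segment_foreground(np.zeros((64, 64), dtype=np.uint8))


def _two_blob_mask():
    mask = np.zeros((220, 240), dtype=bool)
    mask[10:110, 10:110] = True      # area 10 000
    mask[130:170, 120:220] = True    # area 4 000
    mask[200:205, 210:220] = True    # 50 px speckle
    return mask


def test_two_largest_contours_orders_by_area():
    c1, c2 = two_largest_contours(_two_blob_mask())
    assert c1.area_px > c2.area_px
    assert c1.area_px == pytest.approx(10_000, rel=0.02)
    assert c2.area_px == pytest.approx(4_000, rel=0.03)


def test_two_largest_contours_tie_break_deterministic():
    mask = np.zeros((100, 220), dtype=bool)
    mask[40:60, 150:170] = True
    mask[40:60, 20:40] = True
    c1, _ = two_largest_contours(mask)
    # equal areas: the component whose centroid is top-left-most comes first
    assert c1.centroid[1] < 100


def test_two_largest_contours_single_object_fallback():
    mask = np.zeros((80, 80), dtype=bool)
    mask[20:60, 20:60] = True
    with pytest.raises(MissingReferenceError):
        two_largest_contours(mask, allow_single=False)
    c1, c2 = two_largest_contours(mask, allow_single=True)
    assert c2 is None and c1.area_px > 0


def _square_contour(side=100):
    mask = np.zeros((side + 20, side + 20), dtype=bool)
    mask[10:10 + side, 10:10 + side] = True
    return _component_contour(mask)


def test_rectangularity_square_disk_crescent():
    assert rectangularity(_square_contour()) == pytest.approx(1.0, abs=0.02)
    disk = _component_contour(disk_mask(60))
    assert rectangularity(disk) == pytest.approx(np.pi / 4, abs=0.02)
    # thin crescent: disk minus shifted disk
    crescent = disk_mask(60) & ~np.roll(disk_mask(60), 25, axis=1)
    cres = _component_contour(crescent)
    assert rectangularity(cres) < 0.5


def test_assign_card_and_fruit():
    square, disk = _square_contour(), _component_contour(disk_mask(60))
    card, fruit = assign_card_and_fruit((disk, square))
    assert card is square and fruit is disk
    with pytest.raises(AmbiguousSceneError):
        assign_card_and_fruit((_square_contour(), _square_contour()))


def test_calibrate_scale_square_and_oblong_cards():
    assert calibrate_scale(_square_contour(300), 3.0).px_per_cm == pytest.approx(100, rel=0.01)
    mask = np.zeros((240, 440), dtype=bool)
    mask[20:220, 20:420] = True  # 200 x 400 card
    assert calibrate_scale(_component_contour(mask), 8.0).px_per_cm == pytest.approx(50, rel=0.01)
    with pytest.raises(ConfigError):
        calibrate_scale(_square_contour(), -1.0)


def test_scale_recovered_from_generator_scene(frontal_scene):
    _, truth, analysis = frontal_scene
    assert analysis.scale.px_per_cm == pytest.approx(truth.spec.px_per_cm, rel=0.01)


def test_calibration_scale_equivariance():
    image, _ = generate_frontal(FrontalSpec(seed=9, length_cm=15.0))
    from cucumorph.preprocessing import preprocess_frontal

    cfg = make_config()
    _, scale1 = preprocess_frontal(image, cfg.preprocess)
    big = (rescale(image, (2, 2, 1), order=0, preserve_range=True)).astype(np.uint8)
    _, scale2 = preprocess_frontal(big, cfg.preprocess)
    assert scale2.px_per_cm == pytest.approx(2 * scale1.px_per_cm, rel=0.01)
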