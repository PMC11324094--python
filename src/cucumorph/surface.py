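"""Fruit-surface traits: tumor density, stripe proportion and stripe type.

The tumor ROI is the square centered at the centerline arc midpoint whose
side is the transverse diameter there.  The perception steps (tumor
detection, stripe segmentation, stripe typing) are pluggable contracts; the
bundled baselines are classical: multi-scale Laplacian-of-Gaussian blob
detection for tumors, a within-fruit Otsu split of the excess-green channel
for stripes, and connected-component statistics for the stripe taxonomy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage import morphology
from skimage.feature import blob_log
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

from .config import StripeRuleConfig
from .errors import CucumorphError, GeometryError
from .preprocessing import ScaleCalibration, supergreen_transform
from .profiles import DiameterProfile, FruitSegmentation
from .skeleton import SkeletonPolyline

__all__ = [
    "Roi",
    "TumorDetections",
    "STRIPE_LABELS",
    "midpoint_roi",
    "detect_tumors_baseline",
    "tumor_density",
    "stripe_segment_baseline",
    "stripe_proportion",
    "classify_stripe_baseline",
]

STRIPE_LABELS = (
    "small stripe at tip",
    "continuous fragmented stripe",
    "continuous connected stripe",
    "continuous linear stripe",
    "no stripe",
)


@dataclass(frozen=True)
class Roi:
    """Axis-aligned square region of interest, clipped to the image."""

    center: tuple[float, float]  # (row, col)
    side_px: float
    top: int
    bottom: int
    left: int
    right: int
    clipped: bool = False

    @property
    def area_px(self) -> float:
        return float((self.bottom - self.top) * (self.right - self.left))


@dataclass(frozen=True)
class TumorDetections:
    """Detected tumor bounding boxes (row, col, height, width)."""

    boxes: np.ndarray  # (N, 4)

    @property
    def count(self) -> int:
        return len(self.boxes)


def midpoint_roi(
    polyline: SkeletonPolyline,
    profile: DiameterProfile,
    image_shape: tuple[int, int],
) -> Roi:
    """Square ROI at the centerline arc midpoint, side = local diameter."""
    target = polyline.arc_length_px / 2.0
    if len(profile.positions) == 0:
        raise GeometryError("empty diameter profile")
    k = int(np.argmin(np.abs(profile.positions - target)))
    center = polyline.points[profile.point_index[k]]
    side = float(profile.diameters[k])
    half = side / 2.0
    top = int(round(center[0] - half))
    left = int(round(center[1] - half))
    bottom = int(round(center[0] + half))
    right = int(round(center[1] + half))
    ctop, cleft = max(0, top), max(0, left)
    cbottom, cright = min(image_shape[0], bottom), min(image_shape[1], right)
    if cbottom <= ctop or cright <= cleft:
        raise GeometryError("ROI degenerated to zero area")
    return Roi(
        center=(float(center[0]), float(center[1])),
        side_px=side,
        top=ctop,
        bottom=cbottom,
        left=cleft,
        right=cright,
        clipped=(ctop, cleft, cbottom, cright) != (top, left, bottom, right),
    )


def detect_tumors_baseline(
    image: np.ndarray,
    roi: Roi,
    fruit_mask: np.ndarray,
    min_sigma: float = 1.5,
    max_sigma: float = 8.0,
    threshold: float = 0.08,
    min_separation_px: float = 4.0,
) -> TumorDetections:
    """Laplacian-of-Gaussian blob detection on the excess-green channel.

    Restricted to ROI ∩ fruit mask; overlapping responses are suppressed by
    center distance.  Zero detections are a valid outcome.
    """
    sg = supergreen_transform(image).astype(float) / 255.0
    window = sg[roi.top:roi.bottom, roi.left:roi.right].copy()
    sub_mask = fruit_mask[roi.top:roi.bottom, roi.left:roi.right]
    if not sub_mask.any():
        return TumorDetections(boxes=np.empty((0, 4)))
    window[~sub_mask] = np.median(window[sub_mask])
    window = window - np.median(window[sub_mask])
    blobs = blob_log(
        window, min_sigma=min_sigma, max_sigma=max_sigma, num_sigma=8,
        threshold=threshold, overlap=0.3,
    )
    kept: list[np.ndarray] = []
    for b in sorted(blobs, key=lambda b: (-b[2], b[0], b[1])):
        r, c, sigma = b
        if not sub_mask[int(round(r)), int(round(c))]:
            continue
        if any(np.hypot(r - k[0], c - k[1]) < min_separation_px for k in kept):
            continue
        kept.append(b)
    boxes = []
    for r, c, sigma in kept:
        rad = sigma * np.sqrt(2.0)
        boxes.append([roi.top + r - rad, roi.left + c - rad, 2 * rad, 2 * rad])
    return TumorDetections(boxes=np.asarray(boxes) if boxes else np.empty((0, 4)))


def tumor_density(
    detections: TumorDetections, roi: Roi, scale: ScaleCalibration
) -> float:
    """Tumors per cm² of the (clipped) ROI."""
    area_cm2 = scale.to_cm2(roi.area_px)
    if area_cm2 <= 0:
        raise GeometryError("ROI has zero calibrated area")
    return detections.count / area_cm2


def stripe_segment_baseline(
    image: np.ndarray,
    fruit_mask: np.ndarray,
    min_class_gap: float = 20.0,
) -> np.ndarray:
    """Within-fruit Otsu split of the excess-green channel; lighter = stripe.

    If the two Otsu classes are closer than ``min_class_gap`` gray levels the
    fruit is considered unstriped and an empty mask is returned.
    """
    sg = supergreen_transform(image).astype(float)
    vals = sg[fruit_mask]
    if vals.size == 0 or vals.max() == vals.min():
        return np.zeros_like(fruit_mask)
    thresh = threshold_otsu(vals)
    low, high = vals[vals <= thresh], vals[vals > thresh]
    if len(low) == 0 or len(high) == 0 or high.mean() - low.mean() < min_class_gap:
        return np.zeros_like(fruit_mask)
    stripe = (sg > thresh) & fruit_mask
    stripe = morphology.opening(stripe, morphology.disk(1))
    return stripe & fruit_mask


def stripe_proportion(stripe_mask: np.ndarray, fruit_mask: np.ndarray) -> float:
    """Stripe pixel share of the fruit area, in [0, 1]."""
    if (stripe_mask & ~fruit_mask).any():
        raise CucumorphError("stripe mask extends outside the fruit mask")
    fruit_px = int(fruit_mask.sum())
    if fruit_px == 0:
        raise GeometryError("empty fruit mask")
    return float(stripe_mask.sum()) / fruit_px


def _arc_coordinate(points_rc: np.ndarray, polyline: SkeletonPolyline) -> np.ndarray:
    """Normalized arc position in [0, 1] of pixels via nearest centerline vertex."""
    tree = cKDTree(polyline.points)
    _, idx = tree.query(points_rc)
    arcs = polyline.arc_positions
    return arcs[idx] / max(arcs[-1], 1e-9)


def classify_stripe_baseline(
    stripe_mask: np.ndarray,
    seg: FruitSegmentation,
    polyline: SkeletonPolyline,
    Sr: float,
    config: StripeRuleConfig | None = None,
) -> str:
    """Deterministic stripe taxonomy from component statistics.

    ``no stripe`` below a minimal proportion; ``small stripe at tip`` when
    nearly all stripe mass sits in the tip-side quarter of the arc; then
    many small components -> fragmented, predominantly elongated components
    -> linear, otherwise connected.
    """
    config = config or StripeRuleConfig()
    if Sr < config.min_proportion:
        return "no stripe"

    pix = np.argwhere(stripe_mask)
    arc = _arc_coordinate(pix, polyline)
    tip_low_arc = not seg.neck_side_left  # tip sits opposite the neck
    in_tip = arc <= config.tip_arc_frac if tip_low_arc else arc >= 1 - config.tip_arc_frac
    if in_tip.mean() >= config.tip_mass_frac:
        return "small stripe at tip"

    comps = [p for p in regionprops(cc_label(stripe_mask, connectivity=2))
             if p.area >= config.min_component_px]
    if len(comps) >= config.fragment_count:
        return "continuous fragmented stripe"
    elongations = []
    for p in comps:
        minor = max(p.axis_minor_length, 1.0)
        elongations.append(p.axis_major_length / minor)
    if elongations and np.median(elongations) > config.elongation:
        return "continuous linear stripe"
    return "continuous connected stripe"
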