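"""Cross-section (flesh) analysis.

From a slice photograph: pick the sarcocarp among the scene objects by
circularity, score the outer contour's smoothness, split mesocarp from
endocarp (pluggable segmenter with a brightness-Otsu baseline), derive the
circular-equivalent flesh dimensions, and count carpels from the angular
spectrum of the endocarp's radial signature.

Flesh geometry follows the circular-equivalent model: with mesocarp area
``Ss`` and endocarp area ``Se`` (cm²), the endocarp radius is
``Re = sqrt(Se/pi)`` and the mesocarp thickness the difference of the two
equivalent radii, ``Tm = sqrt((Ss+Se)/pi) - Re``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import LineString, Point
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu

from .errors import GeometryError, NoObjectError
from .preprocessing import Contour, ScaleCalibration, two_largest_contours
from .traits import max_inscribed_circle_radius

__all__ = [
    "SmoothnessTraits",
    "FleshTraits",
    "CARPEL_CLASSES",
    "pick_sarcocarp_contour",
    "smoothness_traits",
    "segment_endocarp_baseline",
    "flesh_traits",
    "count_carpels",
    "radial_signature",
]

CARPEL_CLASSES = (2, 3, 4, 5)


@dataclass
class SmoothnessTraits:
    Hr_s: float
    Cr_s: float
    Rl_s: float
    Cf_s: float
    Cdv: float  # cm², variance of centroid-to-edge distance


@dataclass
class FleshTraits:
    """Circular-equivalent flesh dimensions; NaN marks missing values."""

    Ss: float = math.nan  # mesocarp area, cm²
    Se: float = math.nan  # endocarp area, cm²
    Re: float = math.nan  # endocarp equivalent radius, cm
    Tm: float = math.nan  # mesocarp thickness, cm
    Ptr: float = math.nan  # Tm / Re
    Pe: float = math.nan  # Se / Ss
    Nc: int | None = None  # carpel count


def _circularity(contour: Contour) -> float:
    return 4.0 * math.pi * contour.area_px / contour.perimeter_px**2


def pick_sarcocarp_contour(mask: np.ndarray) -> Contour:
    """The more circular of the two largest components (sarcocarp vs card)."""
    c1, c2 = two_largest_contours(mask, allow_single=True)
    if c2 is None:
        return c1
    return c1 if _circularity(c1) >= _circularity(c2) else c2


def radial_signature(contour: Contour, n_angles: int = 360) -> np.ndarray:
    """Centroid-to-boundary distance sampled at uniform angles (px).

    The nearest boundary crossing along each ray is used; for star-shaped
    sections this is the unique crossing.
    """
    poly = contour.polygon
    centroid = np.array([poly.centroid.x, poly.centroid.y])
    if not poly.covers(Point(*centroid)):
        raise GeometryError("contour centroid lies outside the contour")
    boundary = poly.exterior
    reach = float(np.hypot(*np.ptp(contour.points, axis=0))) + 2.0
    thetas = np.linspace(0.0, 2.0 * math.pi, n_angles, endpoint=False)
    dists = np.empty(n_angles)
    for i, th in enumerate(thetas):
        direction = np.array([math.cos(th), math.sin(th)])
        ray = LineString([tuple(centroid), tuple(centroid + reach * direction)])
        hits = ray.intersection(boundary)
        if hits.is_empty:
            raise GeometryError("radial ray missed the boundary")
        if hits.geom_type == "Point":
            d = np.hypot(hits.x - centroid[0], hits.y - centroid[1])
        else:
            pts = [g for g in getattr(hits, "geoms", [hits]) if g.geom_type == "Point"]
            d = min(np.hypot(g.x - centroid[0], g.y - centroid[1]) for g in pts)
        dists[i] = d
    return dists


def smoothness_traits(contour: Contour, scale: ScaleCalibration) -> SmoothnessTraits:
    """Convexity, enclosing/inscribed-circle ratios, circularity and Cdv."""
    poly = contour.polygon
    A = contour.area_px
    hull = poly.convex_hull.area
    circ = shapely.minimum_bounding_circle(poly).area
    r_in = max_inscribed_circle_radius(contour)
    sig_cm = radial_signature(contour) / scale.px_per_cm
    return SmoothnessTraits(
        Hr_s=A / hull,
        Cr_s=A / circ,
        Rl_s=4.0 * math.pi * A / contour.perimeter_px**2,
        Cf_s=math.pi * r_in**2 / A,
        Cdv=float(np.var(sig_cm)),
    )


def segment_endocarp_baseline(
    image: np.ndarray,
    sarcocarp_mask: np.ndarray,
    min_class_gap: float = 0.05,
) -> tuple[np.ndarray, np.ndarray | None]:
    """(mesocarp, endocarp) masks by a within-sarcocarp brightness Otsu.

    The endocarp is the brighter class; only its largest connected
    component is kept and hole-filled.  If the two brightness classes are
    nearly indistinguishable the endocarp is reported missing
    (``(sarcocarp, None)``) rather than invented.
    """
    gray = rgb2gray(np.asarray(image))
    vals = gray[sarcocarp_mask]
    if vals.size == 0:
        raise NoObjectError("empty sarcocarp mask")
    if vals.max() - vals.min() < min_class_gap:
        return sarcocarp_mask.copy(), None
    thresh = threshold_otsu(vals)
    low, high = vals[vals <= thresh], vals[vals > thresh]
    if len(low) == 0 or len(high) == 0 or high.mean() - low.mean() < min_class_gap:
        return sarcocarp_mask.copy(), None
    endo = (gray > thresh) & sarcocarp_mask
    labels, n = ndimage.label(endo)
    if n == 0:
        return sarcocarp_mask.copy(), None
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    endo = labels == (int(np.argmax(sizes)) + 1)
    endo = ndimage.binary_fill_holes(endo) & sarcocarp_mask
    meso = sarcocarp_mask & ~endo
    return meso, endo


def flesh_traits(
    mesocarp_mask: np.ndarray,
    endocarp_mask: np.ndarray | None,
    scale: ScaleCalibration,
) -> FleshTraits:
    """Circular-equivalent flesh dimensions from the two masks."""
    t = FleshTraits()
    if endocarp_mask is None or not endocarp_mask.any():
        return t  # flesh traits missing
    if (mesocarp_mask & endocarp_mask).any():
        raise GeometryError("mesocarp and endocarp masks overlap")
    t.Ss = scale.to_cm2(float(mesocarp_mask.sum()))
    t.Se = scale.to_cm2(float(endocarp_mask.sum()))
    t.Re = math.sqrt(t.Se / math.pi)
    t.Tm = max(0.0, math.sqrt((t.Ss + t.Se) / math.pi) - t.Re)
    t.Ptr = t.Tm / t.Re
    t.Pe = t.Se / t.Ss
    return t


def count_carpels(
    endocarp_mask: np.ndarray,
    model=None,
    noise_floor: float = 0.05,
) -> int | None:
    """Carpel count from the angular spectrum of the endocarp boundary.

    The radial signature r(θ) about the endocarp centroid is Fourier
    analyzed; the dominant harmonic among {2, 3, 4, 5} is the carpel count.
    A supplied classifier (``predict_mask(mask) -> int``) overrides the
    baseline.  Near-circular signatures (relative amplitude below
    ``noise_floor``) are unclassified (None).
    """
    if not endocarp_mask.any():
        raise NoObjectError("empty endocarp mask")
    if model is not None:
        return int(model.predict_mask(endocarp_mask))
    from .preprocessing import _component_contour

    contour = _component_contour(endocarp_mask)
    sig = radial_signature(contour)
    mean_r = sig.mean()
    spectrum = np.abs(np.fft.rfft(sig - mean_r)) * 2.0 / len(sig)
    amps = {k: spectrum[k] for k in CARPEL_CLASSES}
    best = max(amps, key=lambda k: amps[k])
    if amps[best] / max(mean_r, 1e-9) < noise_floor:
        return None
    return int(best)
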