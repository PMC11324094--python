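"""Frontal fruit-shape traits.

Computes the fruit-shape block of the trait table: contour geometry (area,
perimeter, fitted-ellipse axes, enclosing rectangle/circle, convex hull,
inscribed circle, circularity), centerline curvature, diameter-derived
ratios, and the neck/tip descriptors (angle, index, proportion).

Conventions worth stating once:

* ``Cv`` (curvature) is the ratio of centerline arc length to the Euclidean
  distance between its endpoints: 1 for a straight fruit, ``pi/2`` for a
  semicircular one.
* ``Er_f`` (ellipse filling rate) uses the fitted ellipse's *semi*-axes so
  that an elliptical fruit scores ~1; the exported ``Ll``/``Ls`` remain the
  full axis lengths.
* ``Fd`` is the transverse diameter at the arc midpoint of the body segment.
* Descriptors of a degenerate segment are reported as missing (NaN), never 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage
from skimage import measure
from skimage.draw import polygon as draw_polygon

from .errors import GeometryError, SegmentationFailureError
from .preprocessing import Contour, ScaleCalibration, _min_area_rect_sides
from .profiles import DiameterProfile, FruitSegmentation
from .skeleton import SkeletonPolyline

__all__ = [
    "FrontalTraits",
    "contour_traits",
    "curvature",
    "diameter_traits",
    "end_descriptors",
    "max_inscribed_circle_radius",
    "rasterize_contour",
]


@dataclass
class FrontalTraits:
    """Mutable record of the frontal-shape traits; NaN marks missing values."""

    # calibrated lengths / areas / volume
    Fd: float = math.nan
    Fl: float = math.nan
    Ln: float = math.nan
    Lb: float = math.nan
    Lt: float = math.nan
    Lstalk: float = math.nan
    Lstem: float = math.nan
    S: float = math.nan
    Lc: float = math.nan
    V: float = math.nan
    Ll: float = math.nan
    Ls: float = math.nan
    Lout: float = math.nan
    Wout: float = math.nan
    # dimensionless descriptors
    Dr: float = math.nan
    Hr_f: float = math.nan
    Cr_f: float = math.nan
    Er_f: float = math.nan
    Cf_f: float = math.nan
    Rl_f: float = math.nan
    Cv: float = math.nan
    Nr: float = math.nan
    Tr: float = math.nan
    Ar: float = math.nan
    Dr_f: float = math.nan
    Dr_n: float = math.nan
    Dr_t: float = math.nan
    # neck / tip descriptors
    Na: float = math.nan
    Ni: float = math.nan
    Np: float = math.nan
    Ta: float = math.nan
    Ti: float = math.nan
    Tp: float = math.nan
    # shape label
    Cf: str | None = None

    def as_dict(self) -> dict:
        out = dict(vars(self))
        return out


def rasterize_contour(contour: Contour) -> np.ndarray:
    """Filled raster of the contour polygon (used when no mask is attached)."""
    if contour.mask is not None:
        return contour.mask
    pts = contour.points
    shape = (int(np.ceil(pts[:, 0].max())) + 2, int(np.ceil(pts[:, 1].max())) + 2)
    rr, cc = draw_polygon(pts[:, 0], pts[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def max_inscribed_circle_radius(contour: Contour) -> float:
    """Radius of the maximum inscribed circle via the distance transform."""
    mask = rasterize_contour(contour)
    padded = np.pad(mask, 1)
    dist = ndimage.distance_transform_edt(padded)
    return float(dist.max())


def fitted_ellipse_axes(contour: Contour) -> tuple[float, float]:
    """(major, minor) full axis lengths of the moment-equivalent ellipse."""
    mask = rasterize_contour(contour)
    props = measure.regionprops(mask.astype(np.uint8))
    if not props:
        raise GeometryError("cannot fit an ellipse to an empty mask")
    p = props[0]
    return float(p.axis_major_length), float(p.axis_minor_length)


def contour_traits(
    fruit: Contour, scale: ScaleCalibration, traits: FrontalTraits | None = None
) -> FrontalTraits:
    """Contour-only traits: S, Lc, Ll, Ls, Lout, Wout and the fill ratios."""
    t = traits or FrontalTraits()
    poly = fruit.polygon
    if poly.is_empty or poly.area <= 0:
        raise GeometryError("degenerate fruit contour")
    S_px = fruit.area_px
    t.S = scale.to_cm2(S_px)
    t.Lc = scale.to_cm(fruit.perimeter_px)

    long_px, short_px = _min_area_rect_sides(fruit)
    t.Lout = scale.to_cm(long_px)
    t.Wout = scale.to_cm(short_px)
    t.Dr = S_px / (long_px * short_px)
    t.Ar = long_px / short_px

    t.Hr_f = S_px / poly.convex_hull.area

    circ = shapely.minimum_bounding_circle(poly)
    t.Cr_f = S_px / circ.area

    r_in = max_inscribed_circle_radius(fruit)
    t.Cf_f = math.pi * r_in**2 / S_px

    t.Rl_f = 4.0 * math.pi * S_px / fruit.perimeter_px**2

    major_px, minor_px = fitted_ellipse_axes(fruit)
    t.Ll = scale.to_cm(major_px)
    t.Ls = scale.to_cm(minor_px)
    t.Er_f = math.pi * (major_px / 2.0) * (minor_px / 2.0) / S_px
    return t


def curvature(polyline: SkeletonPolyline) -> float:
    """Arc length over endpoint chord; 1 for a straight centerline."""
    chord = float(np.hypot(*(polyline.points[-1] - polyline.points[0])))
    if chord < 1e-9:
        raise GeometryError("centerline endpoints coincide; curvature undefined")
    return max(1.0, polyline.arc_length_px / chord)


def _diameter_at(profile: DiameterProfile, position: float) -> float:
    i = int(np.argmin(np.abs(profile.positions - position)))
    return float(profile.diameters[i])


def diameter_traits(
    profile: DiameterProfile,
    seg: FruitSegmentation,
    polyline: SkeletonPolyline,
    scale: ScaleCalibration,
    traits: FrontalTraits | None = None,
) -> FrontalTraits:
    """Diameter- and segment-derived traits: Fd, V, Dr_f, Dr_n, Dr_t, Nr, Tr."""
    t = traits or FrontalTraits()
    t.Fl = scale.to_cm(polyline.arc_length_px)
    t.Cv = curvature(polyline)

    body = seg.indices("body")
    if len(body) == 0:
        raise SegmentationFailureError("empty body segment")
    body_pos = profile.positions[body]
    body_diam = profile.diameters[body]
    mid = 0.5 * (body_pos[0] + body_pos[-1])
    t.Fd = scale.to_cm(_diameter_at(profile, mid))
    t.Dr_f = float(np.std(body_diam) / np.mean(body_diam))
    t.V = math.pi * (t.Fd / 2.0) ** 2 * t.Fl

    t.Ln = seg.lengths_cm["neck"]
    t.Lb = seg.lengths_cm["body"]
    t.Lt = seg.lengths_cm["tip"]
    t.Lstalk = seg.lengths_cm["stalk"]
    t.Lstem = seg.lengths_cm["stem"]
    if t.Lb > 0:
        t.Nr = t.Ln / t.Lb
        t.Tr = t.Lt / t.Lb

    fd_px = t.Fd * scale.px_per_cm
    for name, attr in (("neck", "Dr_n"), ("tip", "Dr_t")):
        idx = seg.indices(name)
        if len(idx) and name not in seg.degenerate:
            setattr(t, attr, float(profile.diameters[idx].max()) / fd_px)
    return t


def end_descriptors(
    seg: FruitSegmentation,
    profile: DiameterProfile,
    polyline: SkeletonPolyline,
    which: str,
    scale: ScaleCalibration,
    traits: FrontalTraits | None = None,
) -> FrontalTraits:
    """Angle, index and proportion of the neck or tip.

    ``Dmax`` is the widest transverse chord within the segment; the angle is
    subtended by its two contour endpoints at the segment's distal centerline
    endpoint; the index is segment length over ``Dmax``; the proportion is
    the share of the segment's area lying distal to the ``Dmax`` chord
    (areas integrated from the diameter profile along the arc).
    """
    if which not in ("neck", "tip"):
        raise ValueError("which must be 'neck' or 'tip'")
    t = traits or FrontalTraits()
    prefix = {"neck": ("Na", "Ni", "Np"), "tip": ("Ta", "Ti", "Tp")}[which]
    if which in seg.degenerate:
        return t  # descriptors stay NaN
    idx = seg.indices(which)
    if len(idx) == 0:
        return t

    diam = profile.diameters[idx]
    k = int(np.argmax(diam))
    dmax_px = float(diam[k])
    chord = profile.chords[idx[k]]  # (2, 2) endpoints

    # distal end: the fruit end this segment faces
    segment_near_start = (which == "neck") == seg.neck_side_left
    end_point = polyline.points[0] if segment_near_start else polyline.points[-1]

    v1 = np.asarray(chord[0]) - end_point
    v2 = np.asarray(chord[1]) - end_point
    n1, n2 = np.hypot(*v1), np.hypot(*v2)
    if n1 < 1e-9 or n2 < 1e-9:
        return t
    cosang = np.clip((v1 @ v2) / (n1 * n2), -1.0, 1.0)
    angle = math.degrees(math.acos(cosang))

    seg_len_cm = seg.lengths_cm[which]
    index = seg_len_cm / scale.to_cm(dmax_px)

    # area proportion via arc integration of the diameter profile
    pos = profile.positions[idx]
    dmax_pos = pos[k]
    if segment_near_start:
        distal = pos <= dmax_pos
    else:
        distal = pos >= dmax_pos
    total_area = float(np.trapezoid(diam, pos)) if len(pos) > 1 else 0.0
    if total_area > 0:
        distal_area = float(np.trapezoid(diam[distal], pos[distal])) if distal.sum() > 1 else 0.0
        proportion = min(1.0, distal_area / total_area)
    else:
        proportion = math.nan

    setattr(t, prefix[0], angle)
    setattr(t, prefix[1], index)
    setattr(t, prefix[2], proportion)
    return t
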