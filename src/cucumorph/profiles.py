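"""Transverse-diameter profile and the stalk/neck/body/tip/stem partition.

At every centerline point a perpendicular chord to the contour gives the
local transverse diameter; the minimum point-to-contour distance gives a
taper signal.  Each fruit half (split at the arc midpoint) yields a sharp
diameter jump where the thin stalk (or stem) meets the fruit — located by
the maximum gradient of the diameter sequence — and a thin-to-thick
transition where the tapering neck (or tip) meets the body — located by an
Otsu split of the minimum-distance sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString

from .config import SegmentationConfig
from .errors import SegmentationFailureError
from .preprocessing import Contour, ScaleCalibration
from .skeleton import SkeletonPolyline

__all__ = [
    "DiameterProfile",
    "FruitSegmentation",
    "SEGMENT_LABELS",
    "transverse_profile",
    "otsu_split_threshold",
    "otsu_boundary",
    "gradient_boundary",
    "segment_fruit",
]

SEGMENT_LABELS = ("stalk", "neck", "body", "tip", "stem")


@dataclass
class DiameterProfile:
    """Per-centerline-point transverse chords and contour clearances."""

    positions: np.ndarray          # arc-length coordinate (px) of each kept point
    diameters: np.ndarray          # chord length (px)
    chords: np.ndarray             # (N, 2, 2) contour intersection pairs (row, col)
    min_dists: np.ndarray          # min distance to contour (px)
    point_index: np.ndarray        # index into the source polyline
    skipped: list[int] = field(default_factory=list)  # polyline indices w/o chord


@dataclass
class FruitSegmentation:
    """Five-segment partition of the profile with calibrated lengths."""

    boundaries: np.ndarray         # 4 arc positions: stalk|neck, neck|body, body|tip, tip|stem
    lengths_cm: dict[str, float]   # per-segment calibrated arc length
    labels: np.ndarray             # per-profile-index label (str)
    degenerate: set[str] = field(default_factory=set)
    neck_side_left: bool = True    # True if the neck is at the low-arc end

    def indices(self, label: str) -> np.ndarray:
        return np.nonzero(self.labels == label)[0]


def _tangents(points: np.ndarray, half_window_px: float = 12.0) -> np.ndarray:
    """Unit tangents from wide centered secants.

    The secant over roughly ``half_window_px`` of arc on each side averages
    out the short symmetric excursions a medial axis makes at thin-appendage
    junctions; a local finite difference there would rotate the chord
    direction and produce spuriously oblique transverse chords.
    """
    n = len(points)
    if n < 2:
        raise SegmentationFailureError("cannot orient a single-point centerline")
    spacing = max(np.median(np.hypot(*np.diff(points, axis=0).T)), 1e-6)
    k = max(2, int(round(half_window_px / spacing)))
    tangents = np.empty_like(points, dtype=float)
    for i in range(n):
        a, b = max(0, i - k), min(n - 1, i + k)
        tangents[i] = points[b] - points[a]
    norms = np.hypot(tangents[:, 0], tangents[:, 1])
    norms[norms == 0] = 1.0
    return tangents / norms[:, None]


def transverse_profile(polyline: SkeletonPolyline, contour: Contour) -> DiameterProfile:
    """Perpendicular chord diameter and contour clearance at each centerline point.

    Points whose perpendicular fails to meet the contour on both sides
    (endpoint tangency) are skipped and recorded in ``skipped``.
    """
    pts = polyline.points
    arcs = polyline.arc_positions
    tangents = _tangents(pts)
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    boundary = contour.polygon.exterior
    reach = float(np.hypot(*np.ptp(contour.points, axis=0))) + 2.0

    positions, diameters, chords, min_dists, kept, skipped = [], [], [], [], [], []
    for i, (p, nrm) in enumerate(zip(pts, normals)):
        line = LineString(
            [tuple(p - reach * nrm), tuple(p + reach * nrm)]
        )
        hits = line.intersection(boundary)
        if hits.is_empty:
            skipped.append(i)
            continue
        if hits.geom_type == "Point":
            pts_hit = [hits]
        elif hits.geom_type == "MultiPoint":
            pts_hit = list(hits.geoms)
        else:  # GeometryCollection / LineString overlaps: take representative points
            pts_hit = [g for g in getattr(hits, "geoms", []) if g.geom_type == "Point"]
        side_pos, side_neg = [], []
        for h in pts_hit:
            v = np.array([h.x - p[0], h.y - p[1]])
            s = float(v @ nrm)
            (side_pos if s >= 0 else side_neg).append((abs(s), (h.x, h.y)))
        if not side_pos or not side_neg:
            skipped.append(i)
            continue
        d_pos, c_pos = min(side_pos)
        d_neg, c_neg = min(side_neg)
        if d_pos + d_neg < 2.0:
            # endpoint tangency: the chord at a contour-touching terminal
            # point degenerates and would poison the gradient search
            skipped.append(i)
            continue
        positions.append(arcs[i])
        diameters.append(d_pos + d_neg)
        chords.append([c_pos, c_neg])
        # transverse clearance: the shorter perpendicular half-chord.  The
        # all-points minimum distance is biased near taper shoulders (the
        # thin wall is visible across the corner); the perpendicular
        # clearance tracks the local width without that bias.
        min_dists.append(min(d_pos, d_neg))
        kept.append(i)

    return DiameterProfile(
        positions=np.asarray(positions),
        diameters=np.asarray(diameters),
        chords=np.asarray(chords),
        min_dists=np.asarray(min_dists),
        point_index=np.asarray(kept, dtype=int),
        skipped=skipped,
    )


def otsu_split_threshold(values: np.ndarray) -> float | None:
    """Exhaustive two-class Otsu threshold over the unique values.

    Returns the threshold maximizing between-class variance, as the midpoint
    between the optimal low-class maximum and high-class minimum, or None if
    all values are (numerically) equal.
    """
    values = np.asarray(values, dtype=float)
    uniq = np.unique(values)
    if len(uniq) < 2:
        return None
    best, best_t = -np.inf, None
    for k in range(len(uniq) - 1):
        t = 0.5 * (uniq[k] + uniq[k + 1])
        low, high = values[values <= t], values[values > t]
        if len(low) == 0 or len(high) == 0:  # adjacent uniques within rounding
            continue
        var_between = len(low) * len(high) * (low.mean() - high.mean()) ** 2
        if var_between > best:
            best, best_t = var_between, t
    return best_t


def otsu_boundary(min_dists: np.ndarray) -> int | None:
    """Index of the low-to-high class transition with the largest value gap.

    ``min_dists`` is ordered from the fruit end inward, so the thin (neck or
    tip) region forms the low class and the body the high class.  Returns the
    first index of the high class at the widest adjacent low/high gap, or
    None when the sequence has no class structure (degenerate neck/tip).
    """
    v = np.asarray(min_dists, dtype=float)
    if len(v) < 4:
        return None
    t = otsu_split_threshold(v)
    if t is None:
        return None
    low = v <= t
    best_gap, best_idx = -np.inf, None
    for i in range(len(v) - 1):
        if low[i] != low[i + 1]:
            gap = abs(v[i + 1] - v[i])
            if gap > best_gap:
                best_gap = gap
                best_idx = i + 1 if low[i] else i
    return best_idx


def gradient_boundary(diameters: np.ndarray) -> int | None:
    """First index of the new diameter regime at the maximum first difference.

    Returns None for a constant sequence (degenerate stalk/stem).
    """
    v = np.asarray(diameters, dtype=float)
    if len(v) < 3:
        return None
    diffs = np.abs(np.diff(v))
    if diffs.max() <= 1e-9:
        return None
    return int(np.argmax(diffs)) + 1


def _half_partition(
    diam: np.ndarray,
    dists: np.ndarray,
    positions: np.ndarray,
    config: SegmentationConfig,
) -> tuple[int | None, int | None]:
    """(stalk_boundary, neck_boundary) local indices for one half.

    Input arrays are ordered from the fruit end inward.  The neck (or tip)
    boundary comes first, from the Otsu split of the clearance sequence;
    the stalk (or stem) jump is then searched before that boundary — or,
    when the half has no class structure, within the outer
    ``stalk_search_frac`` of the half's arc — so body bulges can never be
    read as a stalk.
    """
    neck_b = otsu_boundary(dists)
    if neck_b is not None:
        outer = neck_b
    else:
        span = positions[-1] - positions[0]
        outer = int(np.searchsorted(positions,
                                    positions[0] + config.stalk_search_frac * span))
    outer = max(outer, 3)
    stalk_b = gradient_boundary(diam[:outer])
    if stalk_b is not None and neck_b is not None and neck_b <= stalk_b:
        neck_b = None
    return stalk_b, neck_b


def _thin_run_length(dists: np.ndarray) -> int:
    """Length of the initial thin run (below the global Otsu split)."""
    t = otsu_split_threshold(dists)
    if t is None:
        return 0
    run = 0
    for d in dists:
        if d <= t:
            run += 1
        else:
            break
    return run


def segment_fruit(
    profile: DiameterProfile,
    polyline: SkeletonPolyline,
    scale: ScaleCalibration,
    config: SegmentationConfig | None = None,
) -> FruitSegmentation:
    """Partition the fruit into stalk / neck / body / tip / stem.

    The profile is split at the arc midpoint; the neck half (chosen by the
    longer thin-end run under ``auto`` orientation) gets a stalk boundary
    from the diameter gradient and a neck boundary from the Otsu split of
    the clearance sequence; the other half is treated symmetrically for the
    stem and tip.  Degenerate boundaries (uniform rods) are flagged rather
    than invented.
    """
    config = config or SegmentationConfig()
    n = len(profile.positions)
    if n < 8:
        raise SegmentationFailureError("profile too short to segment")
    total = polyline.arc_length_px
    mid = int(np.searchsorted(profile.positions, total / 2.0))
    mid = min(max(mid, 2), n - 2)

    # halves ordered from their fruit end inward
    left = slice(0, mid)
    right_idx = np.arange(n - 1, mid - 1, -1)

    if config.orientation == "auto":
        run_left = _thin_run_length(profile.min_dists[left])
        run_right = _thin_run_length(profile.min_dists[right_idx])
        neck_left = run_left >= run_right
    else:
        neck_left = config.orientation == "neck-left"

    def half_arrays(is_left: bool):
        if is_left:
            return (
                profile.diameters[left],
                profile.min_dists[left],
                profile.positions[left],
                np.arange(mid),
            )
        return (
            profile.diameters[right_idx],
            profile.min_dists[right_idx],
            profile.positions[n - 1] - profile.positions[right_idx],
            right_idx,
        )

    degenerate: set[str] = set()
    bounds_global: dict[str, int | None] = {}
    for side, (stalk_name, neck_name) in (
        (neck_left, ("stalk", "neck")),
        (not neck_left, ("stem", "tip")),
    ):
        diam, dists, pos, idx_map = half_arrays(side)
        stalk_b, neck_b = _half_partition(diam, dists, pos, config)
        if stalk_b is None:
            degenerate.add(stalk_name)
        if neck_b is None:
            degenerate.add(neck_name)
        bounds_global[stalk_name] = None if stalk_b is None else int(idx_map[stalk_b])
        bounds_global[neck_name] = None if neck_b is None else int(idx_map[neck_b])

    if {"neck", "tip", "stalk", "stem"} <= degenerate:
        # uniform rod: everything is body
        labels = np.array(["body"] * n, dtype=object)
        lengths = {k: 0.0 for k in SEGMENT_LABELS}
        lengths["body"] = scale.to_cm(total)
        return FruitSegmentation(
            boundaries=np.array([0.0, 0.0, total, total]),
            lengths_cm=lengths,
            labels=labels,
            degenerate={"stalk", "neck", "tip", "stem"},
            neck_side_left=neck_left,
        )

    # resolve index boundaries in profile order (low arc -> high arc)
    def _or(v, fallback):
        return fallback if v is None else v

    if neck_left:
        i_stalk = _or(bounds_global["stalk"], 0)
        i_neck = _or(bounds_global["neck"], i_stalk)
        i_tip = _or(bounds_global["tip"], n)          # first index of tip (from left)
        i_stem = _or(bounds_global["stem"], n)        # first index of stem
        if bounds_global["tip"] is not None:
            i_tip += 1  # boundary index was last-of-tip from the right ordering
        if bounds_global["stem"] is not None:
            i_stem += 1
        order = [("stalk", 0, i_stalk), ("neck", i_stalk, i_neck),
                 ("body", i_neck, i_tip), ("tip", i_tip, i_stem), ("stem", i_stem, n)]
    else:
        i_stem = _or(bounds_global["stem"], 0)
        i_tip = _or(bounds_global["tip"], i_stem)
        i_neck = _or(bounds_global["neck"], n)
        i_stalk = _or(bounds_global["stalk"], n)
        if bounds_global["neck"] is not None:
            i_neck += 1
        if bounds_global["stalk"] is not None:
            i_stalk += 1
        order = [("stem", 0, i_stem), ("tip", i_stem, i_tip),
                 ("body", i_tip, i_neck), ("neck", i_neck, i_stalk),
                 ("stalk", i_stalk, n)]

    # clamp to a monotone partition
    prev = 0
    cleaned = []
    for name, a, b in order:
        a = max(a, prev)
        b = max(b, a)
        cleaned.append((name, a, b))
        prev = b
    # last segment absorbs the remainder
    name, a, _ = cleaned[-1]
    cleaned[-1] = (name, a, n)

    labels = np.empty(n, dtype=object)
    for name, a, b in cleaned:
        labels[a:b] = name
    if (labels == "body").sum() == 0:
        raise SegmentationFailureError("empty body segment")

    pos = profile.positions
    ends = {0: 0.0, n: total}

    def boundary_pos(i: int) -> float:
        if i in ends:
            return ends[i]
        return float(pos[i])

    seg_bounds = [boundary_pos(b) for _, _, b in cleaned[:-1]]  # 4 positions
    lengths = {}
    edges = [0.0] + seg_bounds + [total]
    for (name, _, _), lo, hi in zip(cleaned, edges[:-1], edges[1:]):
        lengths[name] = scale.to_cm(max(0.0, hi - lo))
    return FruitSegmentation(
        boundaries=np.asarray(seg_bounds),
        lengths_cm={k: lengths.get(k, 0.0) for k in SEGMENT_LABELS},
        labels=labels,
        degenerate=degenerate,
        neck_side_left=neck_left,
    )
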