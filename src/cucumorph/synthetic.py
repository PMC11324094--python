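"""Synthetic fruit scenes with exact ground truth.

Renders frontal scenes (green fruit silhouette + 3-cm reference card on a
dark curtain) and cross-section scenes (lobed sarcocarp disk with a
star-shaped endocarp + card), all fully determined by a seeded spec.  The
generator is the test oracle: every rendered scene carries its masks,
centerline, segment boundaries, tumor centers and calibrated areas.

The frontal silhouette is swept along a circular-arc centerline whose
arc/chord ratio is the requested curvature; the half-width profile along the
arc encodes the silhouette family:

``segmented``
    thin stalk, tapered neck, constant body, tapered tip, thin stem — the
    canonical cucumber used for partition/recovery tests.  Neck/tip-to-body
    transitions are C1-smooth and centered on the labeled boundary (the
    half-rise convention); stalk/stem junctions are near-steps;
``capsule``
    constant width with rounded caps (rod/cylinder classes);
``ellipse`` / ``spindle`` / ``egg`` / ``bumpy``
    elliptical, doubly-tapered, asymmetric-egg and irregular profiles for
    the remaining shape classes.

Default rendering resolution is 30 px/cm, giving desk-scale images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.spatial import cKDTree
from skimage.draw import disk as draw_disk, polygon as draw_polygon

from .errors import SpecificationError

__all__ = [
    "FrontalSpec",
    "CrossSpec",
    "FrontalGroundTruth",
    "CrossGroundTruth",
    "generate_frontal",
    "generate_cross",
    "frontal_spec_for_class",
    "write_fixture_set",
    "SILHOUETTES",
    "STRIPE_PATTERNS",
]

SILHOUETTES = ("segmented", "capsule", "ellipse", "spindle", "egg", "bumpy")
STRIPE_PATTERNS = ("none", "linear", "fragmented", "connected", "tip-only")

# scene palette: chosen so excess-green separates background/card/fruit and
# stripes/tumors are the lighter within-fruit class
BACKGROUND = (18, 18, 22)
CARD_COLOR = (60, 170, 70)       # supergreen 210
FRUIT_COLOR = (40, 140, 50)      # supergreen 190
STRIPE_COLOR = (70, 225, 70)     # supergreen saturates (255)
TUMOR_COLOR = (100, 255, 100)    # supergreen saturates (255)
MESOCARP_COLOR = (150, 200, 140)  # supergreen 110, mid brightness
ENDOCARP_COLOR = (205, 235, 175)  # supergreen 90, high brightness


@dataclass
class FrontalSpec:
    """Parameters of one frontal fruit scene (lengths in cm)."""

    length_cm: float = 20.0
    body_diameter_cm: float = 4.0
    neck_length_cm: float = 3.0
    tip_length_cm: float = 2.0
    stalk_length_cm: float = 1.0
    stem_length_cm: float = 0.8
    curvature_arc: float = 1.02
    tumor_count: int = 0
    stripe_pattern: str = "none"
    stripe_coverage: float = 0.0
    silhouette: str = "segmented"
    px_per_cm: float = 30.0
    card_length_cm: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.silhouette not in SILHOUETTES:
            raise SpecificationError(f"unknown silhouette {self.silhouette!r}")
        if self.stripe_pattern not in STRIPE_PATTERNS:
            raise SpecificationError(f"unknown stripe pattern {self.stripe_pattern!r}")
        if min(self.length_cm, self.body_diameter_cm, self.px_per_cm,
               self.card_length_cm) <= 0:
            raise SpecificationError("lengths and scales must be positive")
        if self.curvature_arc < 1.0:
            raise SpecificationError("curvature_arc must be >= 1")
        if self.silhouette == "segmented":
            interior = (self.neck_length_cm + self.tip_length_cm
                        + self.stalk_length_cm + self.stem_length_cm)
            if interior >= self.length_cm:
                raise SpecificationError("segments exceed total fruit length")
        if not 0.0 <= self.stripe_coverage <= 1.0:
            raise SpecificationError("stripe_coverage must be in [0, 1]")
        if self.stripe_pattern != "none" and self.stripe_coverage == 0.0:
            raise SpecificationError("striped pattern needs stripe_coverage > 0")


@dataclass
class CrossSpec:
    """Parameters of one cross-section scene."""

    outer_radius_cm: float = 2.5
    lobe_count: int = 10
    lobe_amplitude: float = 0.04
    carpel_count: int = 3
    carpel_amplitude: float = 0.25
    endocarp_radius_frac: float = 0.55
    px_per_cm: float = 30.0
    card_length_cm: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.endocarp_radius_frac < 1.0:
            raise SpecificationError("endocarp_radius_frac must be in (0, 1)")
        if self.lobe_amplitude >= 1.0 or self.lobe_amplitude < 0.0:
            raise SpecificationError("lobe_amplitude must be in [0, 1)")
        if self.carpel_count not in (2, 3, 4, 5):
            raise SpecificationError("carpel_count must be 2..5")
        if self.outer_radius_cm <= 0 or self.px_per_cm <= 0:
            raise SpecificationError("radius and scale must be positive")


@dataclass
class FrontalGroundTruth:
    spec: FrontalSpec
    fruit_mask: np.ndarray
    stripe_mask: np.ndarray
    tumor_centers: np.ndarray       # (N, 2) row, col
    tumor_radius_px: float
    centerline: np.ndarray          # (M, 2) row, col along arc
    arc_length_px: float
    segment_boundaries_px: np.ndarray | None  # 4 arc positions (segmented only)
    card_bbox: tuple[int, int, int, int]      # top, left, bottom, right

    @property
    def length_cm(self) -> float:
        return self.arc_length_px / self.spec.px_per_cm

    @property
    def stripe_fraction(self) -> float:
        return float(self.stripe_mask.sum()) / float(self.fruit_mask.sum())


@dataclass
class CrossGroundTruth:
    spec: CrossSpec
    sarcocarp_mask: np.ndarray
    endocarp_mask: np.ndarray
    card_bbox: tuple[int, int, int, int]

    @property
    def Ss_cm2(self) -> float:
        """Mesocarp (sarcocarp minus endocarp) area in cm²."""
        meso = self.sarcocarp_mask & ~self.endocarp_mask
        return float(meso.sum()) / self.spec.px_per_cm**2

    @property
    def Se_cm2(self) -> float:
        return float(self.endocarp_mask.sum()) / self.spec.px_per_cm**2


def _arc_centerline(length_px: float, curvature: float, n: int) -> np.ndarray:
    """Circular-arc centerline of given arc length and arc/chord ratio.

    Returned as (n, 2) (row, col) with the chord horizontal; row bulges up.
    """
    s = np.linspace(0.0, length_px, n)
    if curvature <= 1.0 + 1e-9:
        return np.column_stack([np.zeros(n), s])
    # solve phi / sin(phi) = curvature for the half-angle phi
    lo, hi = 1e-6, math.pi - 1e-6
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mid / math.sin(mid) < curvature:
            lo = mid
        else:
            hi = mid
    phi = 0.5 * (lo + hi)
    R = length_px / (2.0 * phi)
    alpha = -phi + 2.0 * phi * s / length_px
    col = R * np.sin(alpha) + R * math.sin(phi)
    row = -(R * np.cos(alpha) - R * math.cos(phi))
    return np.column_stack([row, col])


def _half_width_profile(spec: FrontalSpec, s: np.ndarray, L: float,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray | None]:
    """Half-width h(s) in px and, for ``segmented``, the 4 boundary arcs."""
    ppcm = spec.px_per_cm
    hb = spec.body_diameter_cm * ppcm / 2.0
    if spec.silhouette == "segmented":
        b0 = spec.stalk_length_cm * ppcm
        b1 = b0 + spec.neck_length_cm * ppcm
        b3 = L - spec.stem_length_cm * ppcm
        b2 = b3 - spec.tip_length_cm * ppcm
        h_stalk = max(2.0, 0.12 * hb)
        h_stem = max(2.0, 0.10 * hb)
        h_neck = 0.55 * hb
        h_tip = 0.50 * hb
        # The neck/tip-to-body transitions are C1-smooth (real cucumber
        # shoulders, and concave corners spawn spurious medial-axis jogs)
        # and CENTERED on the labeled boundary: the ground-truth segment
        # boundary is the half-rise point of the width transition, the
        # standard edge-localization convention.  The stalk/stem junctions
        # are near-steps (softened over ~0.15 cm) so the diameter jump the
        # partition relies on is preserved.
        taper_n = 0.40 * (b1 - b0)
        taper_t = 0.45 * (b3 - b2)
        step_w = max(3.0, 0.15 * ppcm)

        def smoothstep(u: float) -> float:
            u = min(1.0, max(0.0, u))
            return u * u * (3 - 2 * u)

        h = np.empty_like(s)
        for i, si in enumerate(s):
            if si < b0:                       # stalk
                h[i] = h_stalk
            elif si < (b1 + b2) / 2:          # neck: taper centered on b1
                w = smoothstep((si - (b1 - taper_n / 2)) / taper_n)
                h[i] = h_neck + (hb - h_neck) * w
            elif si < b3:                     # tip: taper centered on b2
                w = smoothstep(((b2 + taper_t / 2) - si) / taper_t)
                h[i] = h_tip + (hb - h_tip) * w
            else:                             # stem
                h[i] = h_stem
        for a, lo_h in ((b0, h_stalk), (b3, h_stem)):
            near = np.nonzero(np.abs(s - a) <= step_w)[0]
            for i in near:
                w = smoothstep(abs(s[i] - a) / step_w)
                h[i] = lo_h + (h[i] - lo_h) * w
        return h, np.array([b0, b1, b2, b3])
    u = s / L
    if spec.silhouette == "capsule":
        cap = min(hb, L / 2)
        d_end = np.minimum(s, L - s)
        h = np.where(
            d_end >= cap, hb, np.sqrt(np.maximum(0.0, hb**2 - (cap - d_end) ** 2))
        )
        return np.maximum(h, 1.0), None
    if spec.silhouette == "ellipse":
        return np.maximum(hb * np.sqrt(np.maximum(0.0, 1 - (2 * u - 1) ** 2)), 1.0), None
    if spec.silhouette == "spindle":
        return np.maximum(hb * np.sin(math.pi * u) ** 1.5, 1.0), None
    if spec.silhouette == "egg":
        prof = u**0.35 * (1 - u) ** 0.75
        return np.maximum(hb * prof / prof.max(), 1.0), None
    if spec.silhouette == "bumpy":
        phase = rng.uniform(0, 2 * math.pi)
        wob = 1.0 + 0.16 * np.sin(2 * math.pi * 3.5 * u + phase)
        cap = min(0.8 * hb, L / 2)
        d_end = np.minimum(s, L - s)
        base = np.where(
            d_end >= cap, hb, np.sqrt(np.maximum(0.0, hb**2 - (cap - d_end) ** 2))
        )
        return np.maximum(base * wob, 1.0), None
    raise SpecificationError(spec.silhouette)


def _render_scene(height: int, width: int, rng: np.random.Generator) -> np.ndarray:
    img = np.empty((height, width, 3), dtype=np.uint8)
    img[:] = BACKGROUND
    noise = rng.integers(-4, 5, size=(height, width, 1))
    img = np.clip(img.astype(int) + noise, 0, 255).astype(np.uint8)
    return img


def _place_card(img: np.ndarray, card_px: int, margin: int) -> tuple[int, int, int, int]:
    h, w = img.shape[:2]
    top = h - margin - card_px
    left = w - margin - card_px
    img[top:top + card_px, left:left + card_px] = CARD_COLOR
    return (top, left, top + card_px, left + card_px)


def generate_frontal(spec: FrontalSpec) -> tuple[np.ndarray, FrontalGroundTruth]:
    """Render a frontal scene; deterministic for a fixed spec (incl. seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ppcm = spec.px_per_cm
    L = spec.length_cm * ppcm
    n = max(64, int(round(2 * L)))
    center = _arc_centerline(L, spec.curvature_arc, n)
    s = np.linspace(0.0, L, n)
    h, bounds = _half_width_profile(spec, s, L, rng)

    tangents = np.gradient(center, axis=0)
    tangents /= np.hypot(tangents[:, 0], tangents[:, 1])[:, None]
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    left_side = center + h[:, None] * normals
    right_side = center - h[:, None] * normals
    outline = np.vstack([left_side, right_side[::-1]])

    margin = int(0.7 * ppcm) + 10
    card_px = int(round(spec.card_length_cm * ppcm))
    min_r, min_c = outline.min(axis=0)
    offset = np.array([margin - min_r, margin - min_c])
    outline += offset
    center = center + offset
    max_r, max_c = outline.max(axis=0)
    height = int(math.ceil(max_r)) + 2 * margin + card_px + margin
    width = max(int(math.ceil(max_c)) + margin, card_px + 2 * margin)

    fruit_mask = np.zeros((height, width), dtype=bool)
    rr, cc = draw_polygon(outline[:, 0], outline[:, 1], shape=fruit_mask.shape)
    fruit_mask[rr, cc] = True

    img = _render_scene(height, width, rng)
    img[fruit_mask] = FRUIT_COLOR
    card_bbox = _place_card(img, card_px, margin)

    stripe_mask = _render_stripes(spec, fruit_mask, center, s, h, rng)
    img[stripe_mask] = STRIPE_COLOR

    tumor_centers, tumor_r = _render_tumors(spec, img, fruit_mask, center, s, h, rng)

    truth = FrontalGroundTruth(
        spec=spec,
        fruit_mask=fruit_mask,
        stripe_mask=stripe_mask,
        tumor_centers=tumor_centers,
        tumor_radius_px=tumor_r,
        centerline=center,
        arc_length_px=L,
        segment_boundaries_px=bounds,
        card_bbox=card_bbox,
    )
    return img, truth


def _fruit_arc_lateral(fruit_mask: np.ndarray, center: np.ndarray):
    """Per-fruit-pixel (arc position, lateral distance, local half width)."""
    pix = np.argwhere(fruit_mask)
    tree = cKDTree(center)
    dist, idx = tree.query(pix)
    return pix, idx, dist


def _render_stripes(spec, fruit_mask, center, s, h, rng) -> np.ndarray:
    stripe = np.zeros_like(fruit_mask)
    if spec.stripe_pattern == "none" or spec.stripe_coverage <= 0:
        return stripe
    pix, idx, dist = _fruit_arc_lateral(fruit_mask, center)
    arc = s[idx]
    local_h = np.maximum(h[idx], 1e-6)
    rel_lat = np.clip(dist / local_h, 0, 1)       # 0 center .. 1 edge
    rel_arc = arc / s[-1]
    cov = spec.stripe_coverage

    if spec.stripe_pattern == "linear":
        # bands at fixed relative lateral offsets, running the fruit's length
        # (each relative band appears on both flanks: 2*n_bands stripes)
        n_bands = 2
        centers = np.linspace(0.2, 0.65, n_bands)
        half_w = cov / (2 * n_bands)
        sel = np.zeros(len(pix), dtype=bool)
        for c0 in centers:
            sel |= np.abs(rel_lat - c0) < half_w
        sel &= (rel_arc > 0.08) & (rel_arc < 0.92)
    elif spec.stripe_pattern == "connected":
        # one contiguous arc window covering the requested share
        start = 0.5 - cov / 2
        sel = (rel_arc >= start) & (rel_arc <= start + cov)
    elif spec.stripe_pattern == "fragmented":
        sel = np.zeros(len(pix), dtype=bool)
        n_blobs = 20
        blob_r_arc = cov * s[-1] / (2.0 * n_blobs) * 2.2
        for _ in range(n_blobs):
            a0 = rng.uniform(0.08, 0.92) * s[-1]
            l0 = rng.uniform(-0.6, 0.6)
            sel |= (np.abs(arc - a0) < blob_r_arc) & (
                np.abs(rel_lat * np.sign(1) - abs(l0)) < 0.3
            )
    elif spec.stripe_pattern == "tip-only":
        # speckle confined to the stem-end (high-arc) eighth of the fruit,
        # with density chosen to hit the requested overall coverage
        in_tip = rel_arc > 0.88
        tip_px = pix[in_tip]
        sel = np.zeros(len(pix), dtype=bool)
        target = cov * len(pix)
        blob_r = 2.0
        done = np.zeros(len(tip_px), dtype=bool)
        tree_pts = tip_px.astype(float)
        placed = 0.0
        for _ in range(4000):
            if placed >= target or len(tip_px) == 0:
                break
            c0 = tip_px[rng.integers(len(tip_px))]
            close = np.hypot(tree_pts[:, 0] - c0[0], tree_pts[:, 1] - c0[1]) <= blob_r
            newly = close & ~done
            done |= close
            placed += newly.sum()
        tip_sel = done
        sel[np.nonzero(in_tip)[0][tip_sel]] = True
    else:
        raise SpecificationError(spec.stripe_pattern)
    stripe[tuple(pix[sel].T)] = True
    return stripe


def _render_tumors(spec, img, fruit_mask, center, s, h, rng):
    """Place well-separated tumor disks inside the midpoint ROI."""
    k_mid = int(np.argmin(np.abs(s - s[-1] / 2)))
    roi_c = center[k_mid]
    roi_half = h[k_mid]  # ROI side = local diameter -> half-side = half width * 2 / 2
    r_t = max(2.0, 0.035 * 2 * h.max())
    centers: list[np.ndarray] = []
    if spec.tumor_count > 0:
        inner = 0.8 * roi_half
        tries = 0
        while len(centers) < spec.tumor_count:
            tries += 1
            if tries > 20000:
                raise SpecificationError("cannot place that many separated tumors in the ROI")
            cand = roi_c + rng.uniform(-inner, inner, size=2)
            rr, cc = int(round(cand[0])), int(round(cand[1]))
            pad = int(math.ceil(r_t)) + 2
            sub = fruit_mask[rr - pad:rr + pad + 1, cc - pad:cc + pad + 1]
            if sub.shape != (2 * pad + 1, 2 * pad + 1) or not sub.all():
                continue
            if any(np.hypot(*(cand - c)) < 3.5 * r_t for c in centers):
                continue
            centers.append(cand)
        for c in centers:
            rr, cc = draw_disk((c[0], c[1]), r_t, shape=fruit_mask.shape)
            img[rr, cc] = TUMOR_COLOR
    return (np.asarray(centers) if centers else np.empty((0, 2))), r_t


def generate_cross(spec: CrossSpec) -> tuple[np.ndarray, CrossGroundTruth]:
    """Render a cross-section scene; deterministic for a fixed spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ppcm = spec.px_per_cm
    R = spec.outer_radius_cm * ppcm
    margin = int(0.7 * ppcm) + 10
    card_px = int(round(spec.card_length_cm * ppcm))
    extent = R * (1 + spec.lobe_amplitude)
    size = int(math.ceil(2 * extent)) + 2 * margin
    height = size + card_px + margin
    width = max(size, card_px + 2 * margin)
    cr, cc = margin + extent, width / 2.0

    theta = np.linspace(0, 2 * math.pi, 1440, endpoint=False)
    r_outer = R * (1 + spec.lobe_amplitude * np.sin(spec.lobe_count * theta))
    outer = np.column_stack([cr + r_outer * np.sin(theta), cc + r_outer * np.cos(theta)])
    sarcocarp = np.zeros((height, width), dtype=bool)
    rr, ccx = draw_polygon(outer[:, 0], outer[:, 1], shape=sarcocarp.shape)
    sarcocarp[rr, ccx] = True

    Re = spec.endocarp_radius_frac * R / (1 + spec.carpel_amplitude)
    phase = rng.uniform(0, 2 * math.pi)
    r_endo = Re * (1 + spec.carpel_amplitude * np.sin(spec.carpel_count * theta + phase))
    endo_poly = np.column_stack([cr + r_endo * np.sin(theta), cc + r_endo * np.cos(theta)])
    endocarp = np.zeros_like(sarcocarp)
    rr, ccx = draw_polygon(endo_poly[:, 0], endo_poly[:, 1], shape=endocarp.shape)
    endocarp[rr, ccx] = True
    endocarp &= sarcocarp

    img = _render_scene(height, width, rng)
    img[sarcocarp] = MESOCARP_COLOR
    img[endocarp] = ENDOCARP_COLOR
    card_bbox = _place_card(img, card_px, margin)

    truth = CrossGroundTruth(
        spec=spec, sarcocarp_mask=sarcocarp, endocarp_mask=endocarp, card_bbox=card_bbox
    )
    return img, truth


# --- labeled corpus -------------------------------------------------------

_CLASS_RANGES = {
    # silhouette, length range, diameter range, curvature range
    "rod": ("capsule", (18.0, 30.0), (2.6, 3.2), (1.03, 1.12)),
    "cylinder": ("capsule", (14.0, 22.0), (4.2, 5.2), (1.0, 1.02)),
    "ellipse": ("ellipse", (10.5, 14.0), (4.5, 6.0), (1.0, 1.0)),
    "inverted-egg": ("egg", (10.5, 13.0), (5.0, 6.5), (1.0, 1.0)),
    "spindle": ("spindle", (12.0, 18.0), (3.5, 4.5), (1.0, 1.02)),
    "heterotype": ("bumpy", (16.0, 26.0), (3.0, 4.5), (1.15, 1.3)),
}


def frontal_spec_for_class(shape_class: str, seed: int) -> FrontalSpec:
    """A seeded spec drawn from the parameter ranges of one shape class."""
    if shape_class not in _CLASS_RANGES:
        raise SpecificationError(f"unknown shape class {shape_class!r}")
    silhouette, lr, dr, cvr = _CLASS_RANGES[shape_class]
    rng = np.random.default_rng([seed, list(_CLASS_RANGES).index(shape_class)])
    return FrontalSpec(
        length_cm=float(rng.uniform(*lr)),
        body_diameter_cm=float(rng.uniform(*dr)),
        curvature_arc=float(rng.uniform(*cvr)),
        silhouette=silhouette,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def write_fixture_set(out_dir: str | Path, n_per_class: int, seed: int,
                      overwrite: bool = False) -> "pd.DataFrame":
    """Emit a labeled PNG corpus spanning shape classes, stripes and carpels.

    Writes ``manifest.csv`` plus one frontal image per (class, replicate),
    one striped fruit per stripe pattern, and one cross-section per carpel
    count; refuses to clobber an existing manifest unless ``overwrite``.
    """
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True")
    rows = []
    for cls in _CLASS_RANGES:
        for i in range(n_per_class):
            spec = frontal_spec_for_class(cls, seed * 1000 + i)
            img, truth = generate_frontal(spec)
            name = f"frontal_{cls}_{i:02d}.png"
            Image.fromarray(img).save(out / name)
            rows.append({
                "file": name, "kind": "frontal", "label": cls,
                "length_cm": spec.length_cm, "diameter_cm": spec.body_diameter_cm,
                "curvature": spec.curvature_arc, "area_cm2":
                    float(truth.fruit_mask.sum()) / spec.px_per_cm**2,
                "seed": spec.seed,
            })
    for j, pattern in enumerate(p for p in STRIPE_PATTERNS if p != "none"):
        spec = FrontalSpec(stripe_pattern=pattern, stripe_coverage=0.25,
                           seed=seed * 131 + j)
        img, truth = generate_frontal(spec)
        name = f"stripe_{pattern.replace(' ', '_')}.png"
        Image.fromarray(img).save(out / name)
        rows.append({"file": name, "kind": "frontal", "label": pattern,
                     "length_cm": spec.length_cm, "diameter_cm": spec.body_diameter_cm,
                     "curvature": spec.curvature_arc,
                     "area_cm2": float(truth.fruit_mask.sum()) / spec.px_per_cm**2,
                     "seed": spec.seed})
    for k in (2, 3, 4, 5):
        spec = CrossSpec(carpel_count=k, seed=seed * 17 + k)
        img, truth = generate_cross(spec)
        name = f"cross_{k}carpel.png"
        Image.fromarray(img).save(out / name)
        rows.append({"file": name, "kind": "cross", "label": f"{k}-carpel",
                     "length_cm": np.nan, "diameter_cm": 2 * spec.outer_radius_cm,
                     "curvature": np.nan, "area_cm2": truth.Ss_cm2 + truth.Se_cm2,
                     "seed": spec.seed})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(manifest_path, index=False)
    return manifest
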