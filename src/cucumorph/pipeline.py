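"""End-to-end run modes and trait-table export.

``run_fruit_mode`` takes frontal photographs through preprocessing,
skeletonization, partition, traits, shape classification and surface
analysis; ``run_flesh_mode`` takes cross-section photographs through
sarcocarp selection, smoothness, endocarp segmentation, flesh traits and
carpel counting.  Each image yields one row of the 51-column trait table
(plus stalk/stem lengths and provenance columns); per-image failures become
error rows and never abort a batch.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .config import PipelineConfig
from .errors import CucumorphError, NoObjectError
from .preprocessing import (
    Contour,
    ScaleCalibration,
    _component_contour,
    preprocess_frontal,
    segment_foreground,
    supergreen_transform,
    two_largest_contours,
    assign_card_and_fruit,
    calibrate_scale,
)
from .profiles import segment_fruit, transverse_profile
from .skeleton import optimized_centerline
from .traits import FrontalTraits, contour_traits, diameter_traits, end_descriptors
from .cross_section import (
    count_carpels,
    flesh_traits,
    pick_sarcocarp_contour,
    segment_endocarp_baseline,
    smoothness_traits,
)
from .surface import (
    classify_stripe_baseline,
    detect_tumors_baseline,
    midpoint_roi,
    stripe_proportion,
    stripe_segment_baseline,
    tumor_density,
)

logger = logging.getLogger("cucumorph")

__all__ = [
    "TRAIT_COLUMNS",
    "AUX_COLUMNS",
    "PROVENANCE_COLUMNS",
    "FrontalAnalysis",
    "analyze_frontal",
    "analyze_cross",
    "run_fruit_mode",
    "run_flesh_mode",
    "export_table",
    "traits_from_mask",
    "load_image",
]

# the 51 trait parameters, in export order: fruit shape (34), fruit surface
# (5), smoothness (5), fruit flesh (7); Gn/Gt/Gfr/Gtu are manual-grade
# pass-through columns
TRAIT_COLUMNS = (
    "Fd", "Fl", "Ln", "Lb", "Lt", "Cf", "Gn", "Gt",
    "S", "Lc", "V", "Ll", "Ls", "Lout", "Wout", "Dr", "Hr_f", "Cr_f",
    "Er_f", "Cf_f", "Rl_f", "Cv", "Nr", "Tr", "Ar", "Dr_f", "Dr_n", "Dr_t",
    "Na", "Ni", "Np", "Ta", "Ti", "Tp",
    "Gfr", "Gtu", "Td", "Sr", "St",
    "Hr_s", "Cr_s", "Rl_s", "Cf_s", "Cdv",
    "Tm", "Re", "Ptr", "Ss", "Se", "Pe", "Nc",
)
AUX_COLUMNS = ("Lstalk", "Lstem")
PROVENANCE_COLUMNS = ("image", "mode", "px_per_cm", "software_version",
                      "config_hash", "error")
ALL_COLUMNS = TRAIT_COLUMNS + AUX_COLUMNS + PROVENANCE_COLUMNS


def _config_hash(config: PipelineConfig) -> str:
    text = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha1(text.encode()).hexdigest()[:10]


def load_image(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def _empty_row() -> dict:
    row = {c: math.nan for c in TRAIT_COLUMNS + AUX_COLUMNS}
    for c in ("Cf", "St", "Gn", "Gt", "Gfr", "Gtu", "Nc"):
        row[c] = None
    return row


@dataclass
class FrontalAnalysis:
    """Full frontal result: the trait row plus reusable intermediates."""

    row: dict
    traits: FrontalTraits
    contour: Contour
    scale: ScaleCalibration
    polyline: object
    profile: object
    segmentation: object
    stripe_mask: np.ndarray | None = None
    roi: object = None
    shape_reason: str | None = None


def analyze_frontal(
    image: np.ndarray,
    config: PipelineConfig | None = None,
    model=None,
    stripe_mask: np.ndarray | None = None,
) -> FrontalAnalysis:
    """Frontal pipeline for one image; raises CucumorphError on failure.

    ``stripe_mask`` (a boolean array) bypasses the stripe baseline, matching
    the external-mask interface.
    """
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    fruit, scale = preprocess_frontal(image, config.preprocess)
    polyline = optimized_centerline(fruit.mask, fruit, config.skeleton)
    profile = transverse_profile(polyline, fruit)
    seg = segment_fruit(profile, polyline, scale, config.segmentation)

    traits = FrontalTraits()
    contour_traits(fruit, scale, traits)
    diameter_traits(profile, seg, polyline, scale, traits)
    end_descriptors(seg, profile, polyline, "neck", scale, traits)
    end_descriptors(seg, profile, polyline, "tip", scale, traits)

    from .shape import classify_shape  # deferred: shape imports pipeline helpers

    result = classify_shape(traits, model=model, config=config.shape_rules,
                            mask=fruit.mask)
    traits.Cf = result.label

    row = _empty_row()
    row.update({k: v for k, v in traits.as_dict().items() if k in row})
    row["Lstalk"] = seg.lengths_cm["stalk"]
    row["Lstem"] = seg.lengths_cm["stem"]

    # surface traits
    roi = midpoint_roi(polyline, profile, image.shape[:2])
    detections = detect_tumors_baseline(image, roi, fruit.mask)
    row["Td"] = tumor_density(detections, roi, scale)
    if stripe_mask is None:
        stripe_mask = stripe_segment_baseline(image, fruit.mask)
    sr = stripe_proportion(stripe_mask, fruit.mask)
    row["Sr"] = sr
    row["St"] = classify_stripe_baseline(stripe_mask, seg, polyline, sr,
                                         config.stripe_rules)
    logger.info("frontal analysis done in %.2fs (Fl=%.2f cm, Cf=%s)",
                time.perf_counter() - t0, traits.Fl, traits.Cf)
    return FrontalAnalysis(
        row=row, traits=traits, contour=fruit, scale=scale, polyline=polyline,
        profile=profile, segmentation=seg, stripe_mask=stripe_mask, roi=roi,
        shape_reason=result.reason,
    )


def analyze_cross(
    image: np.ndarray,
    config: PipelineConfig | None = None,
    endocarp_mask: np.ndarray | None = None,
    carpel_model=None,
) -> dict:
    """Cross-section pipeline for one image -> trait row (flesh columns)."""
    config = config or PipelineConfig()
    gray = supergreen_transform(image)
    mask = segment_foreground(gray, config.preprocess)
    c1, c2 = two_largest_contours(mask, allow_single=True)
    if c2 is not None:
        card, _ = assign_card_and_fruit((c1, c2))
        scale = calibrate_scale(card, config.preprocess.card_length_cm)
    else:
        raise NoObjectError("cross-section scene lacks a reference card")
    # choose the sarcocarp among the two objects by circularity
    sarco = pick_sarcocarp_contour(mask)
    if sarco.area_px < 0.5 * max(c1.area_px, c2.area_px if c2 else 0):
        logger.warning("low-circularity sarcocarp candidate; check the input")
    sarco_mask = sarco.mask

    row = _empty_row()
    sm = smoothness_traits(sarco, scale)
    row.update(Hr_s=sm.Hr_s, Cr_s=sm.Cr_s, Rl_s=sm.Rl_s, Cf_s=sm.Cf_s, Cdv=sm.Cdv)

    if endocarp_mask is not None:
        meso, endo = sarco_mask & ~endocarp_mask, endocarp_mask
    else:
        meso, endo = segment_endocarp_baseline(image, sarco_mask)
    ft = flesh_traits(meso, endo, scale)
    row.update(Ss=ft.Ss, Se=ft.Se, Re=ft.Re, Tm=ft.Tm, Ptr=ft.Ptr, Pe=ft.Pe)
    if endo is not None and endo.any():
        row["Nc"] = count_carpels(endo, model=carpel_model)
    return row


def _finish_row(row: dict, image: str, mode: str, px_per_cm: float | None,
                config: PipelineConfig, error: str | None = None) -> dict:
    row["image"] = image
    row["mode"] = mode
    row["px_per_cm"] = px_per_cm
    row["software_version"] = __version__
    row["config_hash"] = _config_hash(config)
    row["error"] = error
    return row


def run_fruit_mode(
    image_paths: list,
    config: PipelineConfig | None = None,
    model=None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Batch frontal analysis; failures become error rows, never aborts."""
    config = config or PipelineConfig()
    rows = []
    for path in image_paths:
        name = str(path)
        try:
            image = path if isinstance(path, np.ndarray) else load_image(path)
            analysis = analyze_frontal(image, config, model=model)
            row = _finish_row(dict(analysis.row), name, "fruit",
                              analysis.scale.px_per_cm, config)
            if out_dir is not None and config.overlays:
                _write_frontal_overlays(Path(out_dir), Path(name).stem, image, analysis)
        except (CucumorphError, OSError) as exc:
            logger.error("fruit mode failed on %s: %s", name, exc)
            row = _finish_row(_empty_row(), name, "fruit", None, config, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows, columns=list(ALL_COLUMNS))


def run_flesh_mode(
    image_paths: list,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Batch cross-section analysis; failures become error rows."""
    config = config or PipelineConfig()
    rows = []
    for path in image_paths:
        name = str(path)
        try:
            image = path if isinstance(path, np.ndarray) else load_image(path)
            row = analyze_cross(image, config)
            row = _finish_row(row, name, "flesh", None, config)
        except (CucumorphError, OSError) as exc:
            logger.error("flesh mode failed on %s: %s", name, exc)
            row = _finish_row(_empty_row(), name, "flesh", None, config, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows, columns=list(ALL_COLUMNS))


def export_table(table: pd.DataFrame, path: str | Path, format: str = "csv") -> Path:
    """Write the trait table as CSV (canonical) or XLSX; empty cells for NaN."""
    if len(table) == 0:
        raise CucumorphError("refusing to export an empty trait table")
    path = Path(path)
    if format == "csv":
        table.to_csv(path, index=False, na_rep="")
    elif format == "xlsx":
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            for mode, part in table.groupby("mode", sort=True):
                part.to_excel(writer, sheet_name=str(mode), index=False, na_rep="")
    else:
        raise CucumorphError(f"unknown export format {format!r}")
    return path


# --- helpers used by the shape baseline and overlays ----------------------

def traits_from_mask(mask: np.ndarray, config: PipelineConfig | None = None) -> FrontalTraits:
    """Dimensionless frontal traits of a bare mask under a unit scale.

    Used by the descriptor-based shape baseline; skeleton- or
    partition-dependent traits that cannot be computed (near-round masks)
    stay NaN.
    """
    config = config or PipelineConfig()
    unit = ScaleCalibration(px_per_cm=1.0, card_length_cm=1.0)
    contour = _component_contour(np.asarray(mask, dtype=bool))
    traits = FrontalTraits()
    contour_traits(contour, unit, traits)
    try:
        polyline = optimized_centerline(contour.mask, contour, config.skeleton)
        profile = transverse_profile(polyline, contour)
        seg = segment_fruit(profile, polyline, unit, config.segmentation)
        diameter_traits(profile, seg, polyline, unit, traits)
    except CucumorphError:
        pass
    return traits


_SEGMENT_COLORS = {
    "stalk": (200, 120, 40),
    "neck": (230, 220, 60),
    "body": (70, 180, 90),
    "tip": (90, 140, 230),
    "stem": (200, 80, 160),
}


def _write_frontal_overlays(out: Path, stem: str, image: np.ndarray,
                            analysis: FrontalAnalysis) -> None:
    """Segmentation + skeleton overlay PNG next to the trait row."""
    out.mkdir(parents=True, exist_ok=True)
    overlay = image.copy()
    seg = analysis.segmentation
    profile = analysis.profile
    pts = analysis.polyline.points
    h, w = overlay.shape[:2]
    for label in _SEGMENT_COLORS:
        for i in seg.indices(label):
            chord = profile.chords[i]
            for t in np.linspace(0, 1, 64):
                p = (1 - t) * np.asarray(chord[0]) + t * np.asarray(chord[1])
                r, c = int(round(p[0])), int(round(p[1]))
                if 0 <= r < h and 0 <= c < w:
                    overlay[r, c] = _SEGMENT_COLORS[label]
    for p in pts:
        r, c = int(round(p[0])), int(round(p[1]))
        if 0 <= r < h and 0 <= c < w:
            overlay[r, c] = (255, 255, 255)
    Image.fromarray(overlay).save(out / f"{stem}_segments.png")
    if analysis.stripe_mask is not None and analysis.stripe_mask.any():
        stripe = image.copy()
        stripe[analysis.stripe_mask] = (230, 40, 40)
        Image.fromarray(stripe).save(out / f"{stem}_stripes.png")
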