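"""Empirical localization of decision boundaries and recovery studies.

These routines drive the real pipeline over synthetic sweeps to measure,
rather than restate, the behavior of the shape decision tree and the
accuracy of parameter recovery.  They are shared by the test suite and the
acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .config import PipelineConfig
from .errors import CucumorphError
from .pipeline import analyze_frontal, analyze_cross
from .preprocessing import ScaleCalibration, _component_contour
from .shape import FixedShapeModel, classify_shape
from .synthetic import CrossSpec, FrontalSpec, generate_cross, generate_frontal
from .traits import contour_traits, FrontalTraits

__all__ = [
    "ellipse_mask",
    "ball_label_for_aspect",
    "localize_ball_threshold",
    "localize_oval_finger_threshold",
    "localize_short_cutoff",
    "localize_long_short_cutoff",
    "frontal_recovery_study",
    "cross_recovery_study",
]


def ellipse_mask(aspect: float, minor_px: int = 120) -> np.ndarray:
    """Filled ellipse raster with semi-axes (aspect * minor, minor)."""
    a = aspect * minor_px
    shape = (int(2 * minor_px) + 8, int(2 * a) + 8)
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_ellipse(shape[0] / 2, shape[1] / 2, minor_px, a, shape=shape)
    mask[rr, cc] = True
    return mask


def _ellipse_traits(aspect: float, length_cm: float) -> FrontalTraits:
    """Contour traits of an ellipse mask, scaled so the major axis is length_cm."""
    mask = ellipse_mask(aspect)
    contour = _component_contour(mask)
    major_px = 2 * aspect * 120
    scale = ScaleCalibration(px_per_cm=major_px / length_cm, card_length_cm=3.0)
    traits = contour_traits(contour, scale)
    traits.Fl = traits.Ll  # stand-in centerline length of a plain ellipse
    return traits


def _label_for_aspect(aspect: float, length_cm: float, config) -> tuple[str | None, float]:
    traits = _ellipse_traits(aspect, length_cm)
    result = classify_shape(traits, model=None, config=config)
    return result.label, traits.Cf_f


def ball_label_for_aspect(aspect: float, config=None) -> tuple[str | None, float]:
    """(label, measured circle-filling rate) for a short ellipse mask."""
    return _label_for_aspect(aspect, length_cm=8.0, config=config)


def _bisect_rate(lo: float, hi: float, is_upper: callable, rate_of: callable,
                 tol: float) -> float:
    """Bisect an aspect interval until the measured rates bracket within tol."""
    r_lo, r_hi = rate_of(lo), rate_of(hi)
    for _ in range(60):
        if abs(r_lo - r_hi) < tol:
            break
        mid = 0.5 * (lo + hi)
        if is_upper(mid):
            lo = mid
            r_lo = rate_of(mid)
        else:
            hi = mid
            r_hi = rate_of(mid)
    return 0.5 * (r_lo + r_hi)


def localize_ball_threshold(config=None, tol: float = 0.005) -> float:
    """Circle-filling rate at which the ball/non-ball decision flips.

    Sweeps ellipse masks of varying aspect ratio (rates densely spanning
    roughly 0.5-1.0) through the real contour pipeline and decision tree.
    """
    def label(a):
        return ball_label_for_aspect(a, config)[0]

    def rate(a):
        return ball_label_for_aspect(a, config)[1]

    assert label(1.05) == "ball" and label(1.9) != "ball"
    return _bisect_rate(1.05, 1.9, lambda a: label(a) == "ball", rate, tol)


def localize_oval_finger_threshold(config=None, tol: float = 0.005) -> float:
    """Circle-filling rate at which short non-ball fruits flip oval/finger."""
    def label(a):
        return _label_for_aspect(a, 8.0, config)[0]

    def rate(a):
        return _label_for_aspect(a, 8.0, config)[1]

    assert label(1.6) == "oval" and label(6.0) == "finger"
    return _bisect_rate(1.6, 6.0, lambda a: label(a) == "oval", rate, tol)


def _classified_length(length_cm: float, config: PipelineConfig, model,
                       spec_kwargs: dict, seed: int) -> tuple[str | None, float]:
    """(label, measured Fl) for a generated fruit of the given spec length."""
    spec = FrontalSpec(length_cm=length_cm, seed=seed, **spec_kwargs)
    image, _ = generate_frontal(spec)
    analysis = analyze_frontal(image, config, model=model)
    return analysis.traits.Cf, analysis.traits.Fl


def _bisect_length(lo: float, hi: float, is_lower: callable, fl_of: callable,
                   tol: float) -> float:
    fl_lo, fl_hi = fl_of(lo), fl_of(hi)
    for _ in range(40):
        if abs(fl_hi - fl_lo) < tol:
            break
        mid = 0.5 * (lo + hi)
        if is_lower(mid):
            lo = mid
            fl_lo = fl_of(mid)
        else:
            hi = mid
            fl_hi = fl_of(mid)
    return 0.5 * (fl_lo + fl_hi)


def localize_short_cutoff(seed: int = 0, config: PipelineConfig | None = None,
                          tol: float = 0.05) -> float:
    """Calibrated length at which classification leaves the oval/finger branch.

    Sweeps moderately-filled elliptical fruits (lengths spanning 6-14 cm)
    through the full pipeline with the model branch forced to 'ellipse'.
    """
    config = config or PipelineConfig()
    config.preprocess.card_length_cm = 3.0
    model = FixedShapeModel("ellipse")
    kwargs = dict(silhouette="ellipse", curvature_arc=1.0)

    cache: dict[float, tuple[str | None, float]] = {}

    def run(length):
        if length not in cache:
            cache[length] = _classified_length(
                length, config, model,
                {**kwargs, "body_diameter_cm": 0.55 * length}, seed)
        return cache[length]

    assert run(6.0)[0] == "oval" and run(14.0)[0] == "ellipse"
    return _bisect_length(6.0, 14.0, lambda x: run(x)[0] == "oval",
                          lambda x: run(x)[1], tol)


def localize_long_short_cutoff(seed: int = 0, config: PipelineConfig | None = None,
                               tol: float = 0.05) -> float:
    """Calibrated length at which rod fruits flip between short- and long-rod."""
    config = config or PipelineConfig()
    config.preprocess.card_length_cm = 3.0
    model = FixedShapeModel("rod")
    kwargs = dict(silhouette="capsule", curvature_arc=1.0, body_diameter_cm=3.0)

    cache: dict[float, tuple[str | None, float]] = {}

    def run(length):
        if length not in cache:
            cache[length] = _classified_length(length, config, model, kwargs, seed)
        return cache[length]

    assert run(15.0)[0] == "short-rod" and run(25.0)[0] == "long-rod"
    return _bisect_length(15.0, 25.0, lambda x: run(x)[0] == "short-rod",
                          lambda x: run(x)[1], tol)


def frontal_recovery_study(n: int, seed: int, px_per_cm: float = 30.0,
                           config: PipelineConfig | None = None) -> pd.DataFrame:
    """Recover length/diameter/curvature/boundaries on n random fruits.

    Fruits are canonical segmented cucumbers with randomized dimensions and
    curvature; returns one row per fruit with truth and measured values.
    """
    config = config or PipelineConfig()
    config.preprocess.card_length_cm = 3.0
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        length = float(rng.uniform(16.0, 28.0))
        spec = FrontalSpec(
            length_cm=length,
            body_diameter_cm=float(rng.uniform(3.2, 5.0)),
            neck_length_cm=float(rng.uniform(2.2, 3.5)),
            tip_length_cm=float(rng.uniform(1.5, 2.5)),
            stalk_length_cm=float(rng.uniform(0.8, 1.4)),
            stem_length_cm=float(rng.uniform(0.6, 1.0)),
            curvature_arc=float(rng.uniform(1.0, 1.25)),
            px_per_cm=px_per_cm,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        image, truth = generate_frontal(spec)
        row = {
            "true_Fl": truth.length_cm,
            "true_Fd": spec.body_diameter_cm,
            "true_Cv": spec.curvature_arc,
        }
        bounds_cm = truth.segment_boundaries_px / spec.px_per_cm
        for j, name in enumerate(["b_stalk", "b_neck", "b_tip", "b_stem"]):
            row[f"true_{name}"] = bounds_cm[j]
        try:
            analysis = analyze_frontal(image, config)
            t = analysis.traits
            seg = analysis.segmentation
            measured = np.asarray(seg.boundaries) / analysis.scale.px_per_cm
            if not seg.neck_side_left:
                total = t.Fl
                measured = np.sort(total - measured)
            row.update(
                meas_Fl=t.Fl, meas_Fd=t.Fd, meas_Cv=t.Cv,
                meas_b_stalk=measured[0], meas_b_neck=measured[1],
                meas_b_tip=measured[2], meas_b_stem=measured[3],
                error=None,
            )
        except CucumorphError as exc:
            row.update(error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


def cross_recovery_study(seeds_per_class: int, seed: int,
                         config: PipelineConfig | None = None) -> pd.DataFrame:
    """Carpel-count and area-conservation recovery on star cross-sections."""
    config = config or PipelineConfig()
    config.preprocess.card_length_cm = 3.0
    rng = np.random.default_rng(seed)
    rows = []
    for k in (2, 3, 4, 5):
        for _ in range(seeds_per_class):
            spec = CrossSpec(
                outer_radius_cm=float(rng.uniform(2.0, 3.0)),
                carpel_count=k,
                carpel_amplitude=float(rng.uniform(0.15, 0.3)),
                endocarp_radius_frac=float(rng.uniform(0.45, 0.65)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            image, truth = generate_cross(spec)
            row = {"true_Nc": k, "true_Ss": truth.Ss_cm2, "true_Se": truth.Se_cm2}
            try:
                out = analyze_cross(image, config)
                row.update(meas_Nc=out["Nc"], meas_Ss=out["Ss"], meas_Se=out["Se"],
                           error=None)
            except CucumorphError as exc:
                row.update(error=str(exc))
            rows.append(row)
    return pd.DataFrame(rows)
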