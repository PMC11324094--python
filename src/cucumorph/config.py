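"""Configuration dataclasses and YAML loading.

Defaults follow the tool's reference parameterization: skeleton sampling
``step=5`` with a Savitzky-Golay window ``w=3`` of order ``k=1``, end
extension fitting ``e=5`` points and extrapolating ``n=3`` at a time, and
shape-rule thresholds ``theta1=0.75``, ``theta2=0.4``, ``L=10`` cm,
``T=20`` cm.  The physical size of the reference color card is scene
dependent and therefore has no default: it must be configured.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class PreprocessConfig:
    """Foreground extraction settings.

    ``card_length_cm`` is the physical length of the reference card's long
    side; it is mandatory for any calibrated run (synthetic fixtures embed a
    3-cm square card).
    """

    opening_radius_px: int = 3
    erosion_rounds: int = 3
    min_component_frac: float = 0.001  # components below this image fraction are noise
    card_length_cm: float | None = None
    single_object_fallback: bool = False

    def __post_init__(self) -> None:
        if self.opening_radius_px < 1:
            raise ConfigError("opening_radius_px must be >= 1")
        if self.erosion_rounds < 0:
            raise ConfigError("erosion_rounds must be >= 0")
        if self.card_length_cm is not None and self.card_length_cm <= 0:
            raise ConfigError("card_length_cm must be positive")


@dataclass
class SkeletonConfig:
    """Centerline sampling/smoothing/extension parameters."""

    step: int = 5
    window: int = 3
    edge_points: int = 5   # e: terminal points used for the extension fit
    poly_degree: int = 1   # k: polynomial order for smoothing and extension
    extend_step: int = 3   # n: points appended per extrapolation round
    spline_smooth: float = 1.0  # px² residual budget per point for the final spline
    resample_px: float = 2.5    # arc spacing of the resampled centerline

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ConfigError("window must be odd and >= 3")
        if self.poly_degree >= self.edge_points:
            raise ConfigError("poly_degree must be < edge_points")
        if self.step < 1 or self.extend_step < 1:
            raise ConfigError("step and extend_step must be >= 1")


@dataclass
class SegmentationConfig:
    """Five-segment partition settings.

    ``orientation`` controls which image side carries the neck: ``auto``
    compares the two halves' thin-end runs, the explicit values pin it.
    ``stalk_search_frac`` restricts the stalk/stem diameter-gradient search
    to the outer fraction of each half so body bulges cannot masquerade as a
    stalk boundary.
    """

    orientation: str = "auto"  # auto | neck-left | neck-right
    stalk_search_frac: float = 0.15

    def __post_init__(self) -> None:
        if self.orientation not in ("auto", "neck-left", "neck-right"):
            raise ConfigError("orientation must be auto, neck-left or neck-right")
        if not 0.0 < self.stalk_search_frac <= 0.5:
            raise ConfigError("stalk_search_frac must be in (0, 0.5]")


@dataclass
class ShapeRuleConfig:
    """Decision-tree thresholds for the 11-type shape classification."""

    theta1: float = 0.75  # circle-filling rate above which a fruit is a ball
    theta2: float = 0.4   # oval/finger split for short non-ball fruits
    L_cm: float = 10.0    # short-fruit cutoff
    T_cm: float = 20.0    # long/short subtype split for rod and cylinder

    def __post_init__(self) -> None:
        if not 0.0 < self.theta2 < self.theta1 < 1.0:
            raise ConfigError("need 0 < theta2 < theta1 < 1")
        if not 0.0 < self.L_cm < self.T_cm:
            raise ConfigError("need 0 < L_cm < T_cm")


@dataclass
class StripeRuleConfig:
    """Thresholds of the deterministic stripe-type baseline."""

    min_proportion: float = 0.01     # below this the fruit counts as unstriped
    tip_arc_frac: float = 0.25       # tip-side arc fraction for "small stripe at tip"
    tip_mass_frac: float = 0.90      # stripe mass required inside that region
    elongation: float = 4.0          # component aspect above which a stripe is linear
    fragment_count: int = 8          # at least this many components -> fragmented
    min_component_px: int = 12       # components below this size are specks, ignored


@dataclass
class PipelineConfig:
    """Top-level configuration for the fruit/flesh run modes."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    skeleton: SkeletonConfig = field(default_factory=SkeletonConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    shape_rules: ShapeRuleConfig = field(default_factory=ShapeRuleConfig)
    stripe_rules: StripeRuleConfig = field(default_factory=StripeRuleConfig)
    shape_model_path: str | None = None
    overlays: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        try:
            return cls(
                preprocess=PreprocessConfig(**raw.get("preprocessing", {})),
                skeleton=SkeletonConfig(**raw.get("skeleton", {})),
                segmentation=SegmentationConfig(**raw.get("segmentation", {})),
                shape_rules=ShapeRuleConfig(**raw.get("shape_rules", {})),
                stripe_rules=StripeRuleConfig(**raw.get("stripe_rules", {})),
                shape_model_path=raw.get("shape_model_path"),
                overlays=raw.get("overlays", True),
            )
        except TypeError as exc:  # unknown key
            raise ConfigError(str(exc)) from exc
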