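"""Shared fixtures: one analyzed frontal scene and one cross scene per session."""

from __future__ import annotations

import numpy as np
import pytest

from cucumorph.config import PipelineConfig
from cucumorph.pipeline import analyze_frontal, analyze_cross
from cucumorph.synthetic import CrossSpec, FrontalSpec, generate_cross, generate_frontal


def make_config(**kwargs) -> PipelineConfig:
    cfg = PipelineConfig(**kwargs)
    cfg.preprocess.card_length_cm = 3.0
    return cfg


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return make_config()


@pytest.fixture(scope="session")
def frontal_scene(cfg):
    """Canonical segmented cucumber scene: (image, ground truth, analysis)."""
    spec = FrontalSpec(seed=1)
    image, truth = generate_frontal(spec)
    analysis = analyze_frontal(image, cfg)
    return image, truth, analysis


@pytest.fixture(scope="session")
def cross_scene(cfg):
    """Canonical 3-carpel cross-section scene: (image, truth, trait row)."""
    spec = CrossSpec(seed=2)
    image, truth = generate_cross(spec)
    row = analyze_cross(image, cfg)
    return image, truth, row


def disk_mask(radius: int, pad: int = 8) -> np.ndarray:
    """Rasterized disk (the analytic oracle for circle geometry)."""
    size = 2 * (radius + pad)
    rr, cc = np.mgrid[:size, :size]
    return (rr - size / 2) ** 2 + (cc - size / 2) ** 2 <= radius**2
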