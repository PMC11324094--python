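"""Three-stage fruit-shape classification.

Stage 1: a fruit whose circle-filling rate ``Cf_f`` exceeds ``theta1`` is a
ball.  Stage 2: a non-ball fruit shorter than ``L_cm`` is an oval when
``Cf_f`` exceeds ``theta2`` and a finger otherwise.  Stage 3: all remaining
fruits go to a six-class model (rod, cylinder, ellipse, inverted-egg,
spindle, heterotype); rods and cylinders are then split into long/short
subtypes at ``T_cm``.  All comparisons are strict as stated: equality falls
to the negative branch (e.g. ``Cf_f == theta1`` is not a ball, ``Fl ==
T_cm`` is short).

The six-class model is a pluggable contract (``predict(mask) -> label``).
The bundled baseline is a z-scored nearest-centroid classifier over nine
dimensionless shape descriptors, exposed as a scikit-learn style estimator
and serializable to JSON, so an externally trained model can be swapped in
without code changes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .config import PipelineConfig, ShapeRuleConfig
from .errors import CucumorphError, ModelUnavailableError
from .traits import FrontalTraits

__all__ = [
    "SHAPE_LABELS",
    "SIX_CLASS_LABELS",
    "DESCRIPTOR_NAMES",
    "classify_shape",
    "ShapeCentroidClassifier",
    "MaskDescriptorModel",
    "FixedShapeModel",
    "descriptor_vector",
]

SHAPE_LABELS = (
    "long-rod",
    "short-rod",
    "long-cylinder",
    "short-cylinder",
    "ellipse",
    "spindle",
    "inverted-egg",
    "oval",
    "finger",
    "ball",
    "heterotype",
)

SIX_CLASS_LABELS = ("rod", "cylinder", "ellipse", "inverted-egg", "spindle", "heterotype")

DESCRIPTOR_NAMES = ("Dr", "Hr_f", "Cr_f", "Cf_f", "Rl_f", "Ar", "Dr_f", "Cv", "Er_f")


@runtime_checkable
class SixClassModel(Protocol):
    """Contract for the stage-3 classifier: binary mask in, one of six labels out."""

    def predict_mask(self, mask: np.ndarray) -> str: ...


@dataclass(frozen=True)
class ShapeResult:
    """Classification outcome; ``label`` is None when unclassified."""

    label: str | None
    stage: int
    reason: str | None = None

    @property
    def classified(self) -> bool:
        return self.label is not None


def classify_shape(
    traits: FrontalTraits,
    model: SixClassModel | None = None,
    config: ShapeRuleConfig | None = None,
    mask: np.ndarray | None = None,
) -> ShapeResult:
    """Assign one of the 11 shape labels (or an explicit unclassified result)."""
    config = config or ShapeRuleConfig()
    cf = traits.Cf_f
    fl = traits.Fl
    if cf is None or math.isnan(cf):
        return ShapeResult(None, 0, "circle-filling rate unavailable")
    if cf > config.theta1:
        return ShapeResult("ball", 1)
    if fl is None or math.isnan(fl):
        return ShapeResult(None, 0, "fruit length unavailable")
    if fl < config.L_cm:
        return ShapeResult("oval" if cf > config.theta2 else "finger", 2)
    if model is None:
        return ShapeResult(None, 3, "no six-class model configured")
    if mask is None:
        return ShapeResult(None, 3, "mask required for the six-class model")
    base = model.predict_mask(mask)
    if base not in SIX_CLASS_LABELS:
        raise CucumorphError(f"six-class model returned unknown label {base!r}")
    if base in ("rod", "cylinder"):
        prefix = "long" if fl > config.T_cm else "short"
        return ShapeResult(f"{prefix}-{base}", 3)
    return ShapeResult(base, 3)


def descriptor_vector(mask: np.ndarray, config: PipelineConfig | None = None) -> np.ndarray:
    """Nine dimensionless shape descriptors of a bare fruit mask.

    Runs the contour/skeleton/profile pipeline on the mask alone under a
    unit scale (all nine descriptors are scale free).  Degenerate stages
    (e.g. the near-point skeleton of a round mask) contribute neutral
    values: ``Dr_f = 0`` and ``Cv = 1``.
    """
    from .pipeline import traits_from_mask  # local import to avoid a cycle

    t = traits_from_mask(mask, config=config)
    vec = []
    for name in DESCRIPTOR_NAMES:
        v = getattr(t, name)
        if v is None or math.isnan(v):
            v = {"Dr_f": 0.0, "Cv": 1.0}.get(name, 0.0)
        vec.append(float(v))
    return np.asarray(vec)


class ShapeCentroidClassifier(BaseEstimator, ClassifierMixin):
    """Nearest-centroid classifier over z-scored shape descriptors.

    Deterministic and order independent: centroids are per-class means of
    the standardized training descriptors.  Serializable to JSON (centroids
    plus normalization constants), so a trained instance can ship as a flat
    text file.

    Parameters
    ----------
    eps : float
        Floor on the per-feature standard deviation to keep constant
        features harmless.
    """

    def __init__(self, eps: float = 1e-9):
        self.eps = eps

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per label")
        self.classes_ = np.unique(y)
        self.mean_ = X.mean(axis=0)
        self.scale_ = np.maximum(X.std(axis=0), self.eps)
        Z = (X - self.mean_) / self.scale_
        self.centroids_ = np.vstack([Z[y == c].mean(axis=0) for c in self.classes_])
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        Z = (X - self.mean_) / self.scale_
        d = np.linalg.norm(Z[:, None, :] - self.centroids_[None, :, :], axis=2)
        return self.classes_[np.argmin(d, axis=1)]

    # --- JSON round trip -------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        state = {
            "classes": self.classes_.tolist(),
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "centroids": self.centroids_.tolist(),
            "descriptors": list(DESCRIPTOR_NAMES),
        }
        text = json.dumps(state, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ShapeCentroidClassifier":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        state = json.loads(text)
        model = cls()
        model.classes_ = np.asarray(state["classes"])
        model.mean_ = np.asarray(state["mean"], dtype=float)
        model.scale_ = np.asarray(state["scale"], dtype=float)
        model.centroids_ = np.asarray(state["centroids"], dtype=float)
        return model


class MaskDescriptorModel:
    """Adapter giving a :class:`ShapeCentroidClassifier` the mask-in contract."""

    def __init__(self, classifier: ShapeCentroidClassifier, config: PipelineConfig | None = None):
        self.classifier = classifier
        self.config = config

    def predict_mask(self, mask: np.ndarray) -> str:
        vec = descriptor_vector(mask, config=self.config)
        return str(self.classifier.predict(vec[None, :])[0])


class FixedShapeModel:
    """Trivial six-class model returning a fixed label (testing/forcing)."""

    def __init__(self, label: str):
        if label not in SIX_CLASS_LABELS:
            raise ModelUnavailableError(f"{label!r} is not a six-class label")
        self.label = label

    def predict_mask(self, mask: np.ndarray) -> str:
        return self.label


def baseline_six_class(masks: list[np.ndarray], labels: list[str],
                       config: PipelineConfig | None = None) -> MaskDescriptorModel:
    """Train the descriptor-based baseline from labeled masks.

    Requires at least 3 examples for each of the six classes.
    """
    labels_arr = np.asarray(labels)
    for cls in SIX_CLASS_LABELS:
        if (labels_arr == cls).sum() < 3:
            raise CucumorphError(f"need >= 3 training masks for class {cls!r}")
    X = np.vstack([descriptor_vector(m, config=config) for m in masks])
    clf = ShapeCentroidClassifier().fit(X, labels_arr)
    return MaskDescriptorModel(clf, config=config)
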