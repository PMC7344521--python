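"""Composite 0-10 spinal metrology indices.

Two families are provided, sharing one scoring engine:

* the kinematic composite index (computed from optical motion capture, or
  from IMU-derived ranges — the "I" variant): a weighted average of five
  component scores (cervical flexion, cervical rotation, lumbar flexion,
  lateral flexion, lumbar rotation), each mapped from its raw range of
  motion onto 0 (best mobility) … 10 (worst mobility);
* the linearized conventional metrology index, the mean of five clinical
  measures (lateral spinal flexion, tragus-to-wall, modified Schober,
  intermalleolar distance, cervical rotation) each scored 0-10 by a linear
  transform.

Every component transform is an anchor pair ``(best_ref, worst_ref)``: the
raw value at ``best_ref`` scores 0, at ``worst_ref`` scores 10, linear in
between, clipped outside.  The kinematic index's published weights and
anchors are not reproduced here; the shipped defaults (equal weights,
healthy/ankylosed reference anchors) are editable configuration.  The
conventional index's default anchors encode the published linear scoring
functions, e.g. lateral flexion (21.1 - cm)/2.1 becomes the anchor pair
(21.1, 0.1).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ConfigurationError, InvalidInputError, InvalidParameterError

__all__ = [
    "ComponentTransform",
    "IndexConfig",
    "ConventionalMetrology",
    "CompositeScore",
    "KINEMATIC_COMPONENTS",
    "score_component",
    "compute_composite_index",
    "compute_basmi_lin",
    "default_kinematic_index_config",
    "default_basmi_config",
]

#: the five kinematic components of the composite mobility index
KINEMATIC_COMPONENTS = (
    "cervical_flexion",
    "cervical_rotation",
    "lumbar_flexion",
    "lateral_flexion",
    "lumbar_rotation",
)

#: the five conventional metrology items
CONVENTIONAL_COMPONENTS = (
    "lateral_flexion_cm",
    "tragus_to_wall_cm",
    "schober_cm",
    "intermalleolar_cm",
    "cervical_rotation_deg",
)


@dataclass(frozen=True)
class ComponentTransform:
    """Monotone linear map raw value → 0-10 score, clipped.

    ``best_ref`` scores 0 (best mobility) and ``worst_ref`` scores 10; the
    direction of the raw scale is free (``best_ref`` may exceed
    ``worst_ref``, as for distances where larger is better).
    """

    best_ref: float
    worst_ref: float

    def __post_init__(self) -> None:
        if self.best_ref == self.worst_ref:
            raise ConfigurationError("best_ref and worst_ref must differ")

    def __call__(self, value: float) -> float:
        raw = 10.0 * (value - self.best_ref) / (self.worst_ref - self.best_ref)
        return float(np.clip(raw, 0.0, 10.0))


@dataclass
class IndexConfig:
    """Transforms plus weights for one composite index."""

    transforms: Mapping[str, ComponentTransform]
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.transforms) != set(self.weights):
            raise ConfigurationError("transforms and weights must cover the same components")
        if any(w < 0 for w in self.weights.values()):
            raise ConfigurationError("weights must be nonnegative")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"weights must sum to 1 (got {total})")


def default_kinematic_index_config() -> IndexConfig:
    """Editable placeholder configuration for the kinematic composite index.

    Equal weights; anchors are indicative healthy (best) and ankylosed
    (worst) reference ranges in degrees.  The index's published weights and
    anchors come from its own derivation study and should be substituted
    here when exact scores are required.
    """
    anchors = {
        "cervical_flexion": (120.0, 5.0),
        "cervical_rotation": (160.0, 10.0),
        "lumbar_flexion": (70.0, 2.0),
        "lateral_flexion": (80.0, 5.0),
        "lumbar_rotation": (40.0, 2.0),
    }
    return IndexConfig(
        transforms={k: ComponentTransform(*v) for k, v in anchors.items()},
        weights={k: 1.0 / 5.0 for k in anchors},
    )


def default_basmi_config() -> IndexConfig:
    """Anchor form of the published linear conventional-metrology scoring.

    Each anchor pair (best_ref, worst_ref) reproduces the linear component
    functions: lateral flexion (21.1-x)/2.1, tragus-to-wall (x-10)/3,
    modified Schober (7.4-x)/0.7, intermalleolar (124.5-x)/10, cervical
    rotation (89.3-x)/8.5; scores clipped to [0, 10].
    """
    anchors = {
        "lateral_flexion_cm": (21.1, 0.1),
        "tragus_to_wall_cm": (10.0, 40.0),
        "schober_cm": (7.4, 0.4),
        "intermalleolar_cm": (124.5, 24.5),
        "cervical_rotation_deg": (89.3, 4.3),
    }
    return IndexConfig(
        transforms={k: ComponentTransform(*v) for k, v in anchors.items()},
        weights={k: 1.0 / 5.0 for k in anchors},
    )


@dataclass(frozen=True)
class ConventionalMetrology:
    """Raw conventional mobility measures for one subject."""

    lateral_flexion_cm: float
    tragus_to_wall_cm: float
    modified_schober_cm: float
    intermalleolar_cm: float
    cervical_rotation_deg: float

    def __post_init__(self) -> None:
        for name in (
            "lateral_flexion_cm",
            "tragus_to_wall_cm",
            "modified_schober_cm",
            "intermalleolar_cm",
            "cervical_rotation_deg",
        ):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")

    def as_components(self) -> dict[str, float]:
        return {
            "lateral_flexion_cm": self.lateral_flexion_cm,
            "tragus_to_wall_cm": self.tragus_to_wall_cm,
            "schober_cm": self.modified_schober_cm,
            "intermalleolar_cm": self.intermalleolar_cm,
            "cervical_rotation_deg": self.cervical_rotation_deg,
        }


@dataclass
class CompositeScore:
    """A 0-10 composite mobility score with its component breakdown."""

    index_name: str
    score: float
    components: dict[str, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 10.0:
            raise InvalidInputError("composite score must lie in [0, 10]")


def score_component(name: str, value: float, config: IndexConfig) -> float:
    """Score one raw component value on the 0-10 (better-to-worse) scale."""
    if name not in config.transforms:
        raise ConfigurationError(f"component {name!r} not present in the index configuration")
    if not np.isfinite(value):
        raise InvalidInputError(f"component {name!r} value is not finite")
    return config.transforms[name](value)


def compute_composite_index(
    components: Mapping[str, float],
    config: IndexConfig | None = None,
    name: str = "IUCOASMI",
) -> CompositeScore:
    """Weighted-average composite index from raw component values.

    The same operation serves the optical variant (components measured by
    motion capture) and the IMU variant; only the provenance of the raw
    values differs.
    """
    config = config if config is not None else default_kinematic_index_config()
    missing = sorted(set(config.transforms) - set(components))
    if missing:
        raise InvalidInputError("missing components: " + ", ".join(missing))
    scores = {k: score_component(k, components[k], config) for k in config.transforms}
    total = sum(config.weights[k] * scores[k] for k in config.transforms)
    return CompositeScore(name, float(total), scores)


def compute_basmi_lin(
    metrology: ConventionalMetrology, config: IndexConfig | None = None
) -> CompositeScore:
    """Linearized conventional-metrology index (mean of five 0-10 scores)."""
    config = config if config is not None else default_basmi_config()
    return compute_composite_index(metrology.as_components(), config, name="BASMI_LIN")
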