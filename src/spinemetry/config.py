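"""YAML configuration loading for the simulator and indices.

A config file is a single YAML document; every key is optional and falls
back to the shipped defaults::

    seed: 7
    cohort:
      n_per_group: 20
      rom_means:            # group -> region -> plane -> [mean_deg, sd_deg]
        axSpA:
          cervical: {sagittal: [82.1, 24.8]}
    noise:
      orientation_noise_sd: 1.0
      mounting_offset_sd: 2.0
      skin_artifact_amp: 1.0
      marker_noise_sd: 1.0
    outcomes:               # replaces the whole default outcome set if given
      - name: BASDAI
        groups: {axSpA: [3.9, 2.7]}
        bounds: [0, 10]
        target_r: -0.40
        integer: false
    index:                  # kinematic composite index anchors/weights
      weights: {cervical_flexion: 0.2, ...}
      anchors: {cervical_flexion: [120, 5], ...}
"""
from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .metrology import ComponentTransform, IndexConfig, default_kinematic_index_config
from .motion_sim import (
    CohortSpec,
    NoiseSpec,
    OutcomeDef,
    OutcomeSpec,
    default_cohort_spec,
    default_outcome_spec,
)
from .series import Plane, Region

__all__ = ["RunConfig", "load_config"]


class RunConfig:
    """Bundled simulation configuration."""

    def __init__(self, cohort: CohortSpec, outcomes: OutcomeSpec,
                 noise: NoiseSpec, index: IndexConfig, seed: int):
        self.cohort = cohort
        self.outcomes = outcomes
        self.noise = noise
        self.index = index
        self.seed = seed


def _parse_cohort(raw: dict) -> CohortSpec:
    kwargs = {
        k: raw[k]
        for k in (
            "n_per_group", "cycle_duration", "rest_duration",
            "n_reps", "lead_in", "peak_hold", "segment_length_mm",
        )
        if k in raw
    }
    spec = default_cohort_spec(**kwargs)
    if "rom_means" in raw:
        params = {g: dict(v) for g, v in spec.rom_params.items()}
        for group, regions in raw["rom_means"].items():
            if group not in params:
                raise ConfigurationError(f"unknown group {group!r} in rom_means")
            for region, planes in regions.items():
                for plane, pair in planes.items():
                    mean, sd = float(pair[0]), float(pair[1])
                    params[group][(Region(region), Plane(plane))] = (mean, sd)
        spec = replace(spec, rom_params=params)
    return spec


def _parse_outcomes(raw: list) -> OutcomeSpec:
    defs = []
    for item in raw:
        try:
            defs.append(
                OutcomeDef(
                    name=item["name"],
                    params={g: (float(v[0]), float(v[1])) for g, v in item["groups"].items()},
                    lo=float(item["bounds"][0]),
                    hi=float(item["bounds"][1]),
                    target_r=float(item["target_r"]),
                    integer=bool(item.get("integer", False)),
                )
            )
        except KeyError as exc:
            raise ConfigurationError(f"outcome entry missing key {exc}") from exc
    return OutcomeSpec(defs)


def _parse_index(raw: dict) -> IndexConfig:
    base = default_kinematic_index_config()
    transforms = dict(base.transforms)
    weights = dict(base.weights)
    for name, pair in raw.get("anchors", {}).items():
        transforms[name] = ComponentTransform(float(pair[0]), float(pair[1]))
    weights.update({k: float(v) for k, v in raw.get("weights", {}).items()})
    return IndexConfig(transforms, weights)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config (or return all defaults when ``path`` is None)."""
    raw: dict = {}
    if path is not None:
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    cohort = _parse_cohort(raw.get("cohort", {}))
    outcomes = (
        _parse_outcomes(raw["outcomes"]) if "outcomes" in raw else default_outcome_spec()
    )
    noise_kwargs = {k: v for k, v in raw.get("noise", {}).items()}
    try:
        noise = NoiseSpec(**noise_kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"bad noise block: {exc}") from exc
    index = _parse_index(raw.get("index", {}))
    seed = int(raw.get("seed", 0))
    return RunConfig(cohort, outcomes, noise, index, seed)
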