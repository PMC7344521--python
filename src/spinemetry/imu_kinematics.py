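"""Dual-sensor orientation processing: zeroing, per-plane relative angles,
absolute trunk angle, and peak-to-peak range of motion.

The device reports each sensor's absolute orientation (roll, pitch, yaw).
Regional angles are obtained by per-plane subtraction of the lower sensor
from the upper sensor (sagittal = pitch, frontal = roll, axial = yaw); the
trunk (L1-absolute) angle is the upper lumbar sensor's own axis angle.  Both
sensors are first re-referenced to the standing posture recorded at the
start of each trial, which exactly removes any constant mounting offset.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AlignmentError, InvalidInputError, InvalidParameterError
from .series import AXIS_FOR_PLANE, AngleSeries, OrientationSeries, Plane, Region

__all__ = [
    "ROMResult",
    "zero_to_reference",
    "relative_angle_series",
    "absolute_sagittal_angle",
    "peak_to_peak_rom",
    "repetition_windows",
    "rom_by_repetition",
    "aggregate_repetitions",
]


@dataclass
class ROMResult:
    """Aggregated peak-to-peak ROM for one region/plane (degrees)."""

    region: Region | None
    plane: Plane | None
    rom: float
    per_rep: list[float]
    aggregation_rule: str

    def __post_init__(self) -> None:
        if self.rom < 0:
            raise InvalidInputError("rom must be >= 0")


def zero_to_reference(series: OrientationSeries, reference_window: float = 1.0) -> OrientationSeries:
    """Subtract the mean orientation over the initial standing window.

    ``reference_window`` is the duration (s) from the first sample over which
    the per-axis mean is taken; a constant mounting offset is removed exactly.
    """
    if reference_window <= 0:
        raise InvalidParameterError("reference_window must be positive")
    mask = series.t <= series.t[0] + reference_window
    if not np.any(mask):
        raise InvalidParameterError("reference window contains no samples")
    return series.with_axes(
        roll=series.roll - series.roll[mask].mean(),
        pitch=series.pitch - series.pitch[mask].mean(),
        yaw=series.yaw - series.yaw[mask].mean(),
    )


def _unwrap_deg(x: np.ndarray) -> np.ndarray:
    """Remove 360-degree wrap-around jumps (> 180 deg between samples)."""
    return np.unwrap(x, period=360.0)


def relative_angle_series(
    upper: OrientationSeries,
    lower: OrientationSeries,
    plane: Plane,
    region: Region = Region.CERVICAL,
) -> AngleSeries:
    """Per-plane regional angle: upper-axis minus lower-axis.

    Evaluated on the upper sensor's grid restricted to the overlap of both
    supports; the lower series is linearly interpolated (no extrapolation).
    """
    plane = Plane(plane)
    axis = AXIS_FOR_PLANE[plane]
    t0 = max(upper.t[0], lower.t[0])
    t1 = min(upper.t[-1], lower.t[-1])
    if t1 <= t0:
        raise AlignmentError(
            f"sensor supports do not overlap ([{upper.t[0]}, {upper.t[-1]}] vs "
            f"[{lower.t[0]}, {lower.t[-1]}])"
        )
    mask = (upper.t >= t0) & (upper.t <= t1)
    t = upper.t[mask]
    if t.size < 2:
        raise AlignmentError("overlap contains fewer than 2 samples")
    upper_angle = _unwrap_deg(upper.axis(axis))[mask]
    lower_angle = np.interp(t, lower.t, _unwrap_deg(lower.axis(axis)))
    return AngleSeries(region, plane, upper.nominal_rate, t, upper_angle - lower_angle)


def absolute_sagittal_angle(
    upper: OrientationSeries, plane: Plane = Plane.SAGITTAL
) -> AngleSeries:
    """Absolute orientation of the upper sensor with respect to the ground.

    Equivalent to :func:`relative_angle_series` against a virtual static
    ground sensor; used for the trunk (L1) measure, classically in the
    sagittal plane but available for any plane.
    """
    plane = Plane(plane)
    axis = AXIS_FOR_PLANE[plane]
    value = _unwrap_deg(upper.axis(axis))
    return AngleSeries(Region.L1_ABSOLUTE, plane, upper.nominal_rate, upper.t, value)


def peak_to_peak_rom(series: AngleSeries) -> float:
    """Total peak-to-peak range of the angle signal, max(value) - min(value)."""
    if len(series) < 2:
        raise InvalidInputError("ROM requires at least 2 samples")
    return float(np.max(series.value) - np.min(series.value))


def repetition_windows(
    lead_in: float, cycle_duration: float, rest_duration: float, n_reps: int
) -> list[tuple[float, float]]:
    """Scripted time windows of each repetition under the recording protocol."""
    if n_reps < 1:
        raise InvalidParameterError("n_reps must be >= 1")
    return [
        (
            lead_in + r * (cycle_duration + rest_duration),
            lead_in + r * (cycle_duration + rest_duration) + cycle_duration,
        )
        for r in range(n_reps)
    ]


def rom_by_repetition(
    series: AngleSeries, windows: Sequence[tuple[float, float]] | None = None
) -> list[float]:
    """Peak-to-peak ROM inside each repetition window.

    With ``windows=None`` the whole recording is treated as a single
    repetition (the protocol timing is unknown).
    """
    if windows is None:
        return [peak_to_peak_rom(series)]
    t0 = series.t[0]
    out = []
    for start, stop in windows:
        mask = (series.t >= t0 + start) & (series.t <= t0 + stop)
        if mask.sum() < 2:
            raise InvalidInputError(
                f"repetition window [{start}, {stop}] s holds fewer than 2 samples"
            )
        seg = series.value[mask]
        out.append(float(seg.max() - seg.min()))
    return out


def aggregate_repetitions(
    per_rep: Sequence[float],
    rule: str = "max",
    region: Region | None = None,
    plane: Plane | None = None,
) -> ROMResult:
    """Collapse per-repetition ROM values into one result.

    ``rule="max"`` (default) keeps the maximal mobility over repetitions,
    matching the clinical intent of metrology indices; ``rule="mean"``
    averages them.
    """
    if len(per_rep) == 0:
        raise InvalidInputError("per_rep must contain at least one value")
    if rule == "max":
        rom = float(np.max(per_rep))
    elif rule == "mean":
        rom = float(np.mean(per_rep))
    else:
        raise InvalidParameterError(f"unknown aggregation rule {rule!r}")
    return ROMResult(region, plane, rom, [float(v) for v in per_rep], rule)
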