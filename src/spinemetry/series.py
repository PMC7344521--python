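"""Time-series containers shared by the simulator and both kinematic chains.

Angles are kept in degrees end to end.  Anatomical planes map onto the Euler
axes reported by the wearable sensors as sagittal→pitch (flexion/extension),
frontal→roll (lateral flexion), axial→yaw (rotation).
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "Plane",
    "Region",
    "AXIS_FOR_PLANE",
    "OrientationSeries",
    "AngleSeries",
    "MarkerTrajectory",
]


class Plane(str, Enum):
    """Anatomical plane of a spinal movement."""

    SAGITTAL = "sagittal"  # flexion / extension
    FRONTAL = "frontal"    # lateral flexion
    AXIAL = "axial"        # rotation


class Region(str, Enum):
    """Instrumented spinal region.

    ``CERVICAL``: angle between the occiput and T3 sensors.
    ``LUMBAR``: angle between the upper-lumbar (L1/T12) and sacral sensors.
    ``L1_ABSOLUTE``: orientation of the upper lumbar sensor with respect to
    the ground, i.e. lumbar plus pelvic contribution (trunk angle).
    """

    CERVICAL = "cervical"
    LUMBAR = "lumbar"
    L1_ABSOLUTE = "L1_absolute"


#: Euler axis of the sensor output that carries each anatomical plane.
AXIS_FOR_PLANE: dict[Plane, str] = {
    Plane.SAGITTAL: "pitch",
    Plane.FRONTAL: "roll",
    Plane.AXIAL: "yaw",
}

#: Fixed iteration order for planes (keeps random draws reproducible).
PLANES: tuple[Plane, ...] = (Plane.SAGITTAL, Plane.FRONTAL, Plane.AXIAL)


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


def _check_time(t: np.ndarray) -> None:
    if t.size and not np.all(np.isfinite(t)):
        raise InvalidInputError("time vector contains non-finite values")
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise InvalidInputError("time vector must be strictly increasing")


@dataclass
class OrientationSeries:
    """Timestamped roll/pitch/yaw stream for one wearable sensor (degrees)."""

    sensor_id: str
    nominal_rate: float
    t: np.ndarray
    roll: np.ndarray
    pitch: np.ndarray
    yaw: np.ndarray

    def __post_init__(self) -> None:
        if self.nominal_rate <= 0:
            raise InvalidParameterError("nominal_rate must be positive")
        self.t = _as_1d_float(self.t, "t")
        _check_time(self.t)
        for name in ("roll", "pitch", "yaw"):
            arr = _as_1d_float(getattr(self, name), name)
            if arr.shape != self.t.shape:
                raise InvalidInputError(f"{name} length {arr.size} != time length {self.t.size}")
            if not np.all(np.isfinite(arr)):
                raise InvalidInputError(f"{name} contains non-finite values")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return self.t.size

    def axis(self, name: str) -> np.ndarray:
        """Return the angle array for one Euler axis (``roll``/``pitch``/``yaw``)."""
        if name not in ("roll", "pitch", "yaw"):
            raise InvalidParameterError(f"unknown axis {name!r}")
        return getattr(self, name)

    def with_axes(self, roll=None, pitch=None, yaw=None) -> "OrientationSeries":
        """Copy with one or more axis arrays replaced."""
        return replace(
            self,
            roll=self.roll if roll is None else roll,
            pitch=self.pitch if pitch is None else pitch,
            yaw=self.yaw if yaw is None else yaw,
        )


@dataclass
class AngleSeries:
    """A region+plane angle signal (degrees) on a uniform time grid."""

    region: Region
    plane: Plane
    rate: float
    t: np.ndarray
    value: np.ndarray

    #: absolute tolerance (s) on grid uniformity
    _GRID_ATOL = 1e-9

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise InvalidParameterError("rate must be positive")
        self.region = Region(self.region)
        self.plane = Plane(self.plane)
        self.t = _as_1d_float(self.t, "t")
        _check_time(self.t)
        self.value = _as_1d_float(self.value, "value")
        if self.value.shape != self.t.shape:
            raise InvalidInputError("value and t lengths differ")
        if not np.all(np.isfinite(self.value)):
            raise InvalidInputError("value contains non-finite samples")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.max(np.abs(dt - 1.0 / self.rate)) > self._GRID_ATOL:
                raise InvalidInputError(
                    "time grid is not uniform at the declared rate "
                    f"({self.rate} Hz)"
                )

    def __len__(self) -> int:
        return self.t.size


@dataclass
class MarkerTrajectory:
    """3-D point trajectory of one reflective marker (millimetres)."""

    marker_id: str
    t: np.ndarray
    xyz: np.ndarray  # shape (n, 3)

    def __post_init__(self) -> None:
        self.t = _as_1d_float(self.t, "t")
        _check_time(self.t)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape != (self.t.size, 3):
            raise InvalidInputError(
                f"xyz must have shape (n, 3) matching t, got {self.xyz.shape}"
            )
        if not np.all(np.isfinite(self.xyz)):
            raise InvalidInputError("marker coordinates contain non-finite values")

    def __len__(self) -> int:
        return self.t.size
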