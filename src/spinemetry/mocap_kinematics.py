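"""Optical-chain kinematics: plane-projected angles of marker-pair segments.

The optical reference method measures the angle of a segment defined by two
reflective markers, projected onto an anatomical plane.  Lab frame:
right-handed, z up, y anterior, x lateral (to the subject's right); sagittal
is the y-z plane, frontal the x-z plane, axial (transverse) the x-y plane.
The signed angle is measured against the plane's reference axis (vertical z
for sagittal and frontal, anterior y for axial) and then re-referenced to
the initial standing window, exactly as the IMU chain is.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .series import AngleSeries, MarkerTrajectory, Plane, Region

__all__ = ["SegmentDef", "projected_segment_angle_series"]

#: fraction of degenerate (near-perpendicular) samples tolerated per trial
MAX_DEGENERATE_FRACTION = 0.05

#: projected segment length below which the angle is considered undefined (mm)
MIN_PROJECTED_LENGTH_MM = 1e-6

#: (component index for "sine", component index for "cosine") per plane,
#: indexing (x, y, z)
_PLANE_COMPONENTS = {
    Plane.SAGITTAL: (1, 2),  # atan2(y, z)
    Plane.FRONTAL: (0, 2),   # atan2(x, z)
    Plane.AXIAL: (0, 1),     # atan2(x, y)
}


@dataclass(frozen=True)
class SegmentDef:
    """A marker-pair segment and the plane/region it measures."""

    marker_a: str
    marker_b: str
    plane: Plane
    region: Region

    def __post_init__(self) -> None:
        if self.marker_a == self.marker_b:
            raise InvalidParameterError("segment endpoints must be distinct markers")
        object.__setattr__(self, "plane", Plane(self.plane))
        object.__setattr__(self, "region", Region(self.region))


def projected_segment_angle_series(
    a: MarkerTrajectory,
    b: MarkerTrajectory,
    seg: SegmentDef,
    reference_window: float | None = 1.0,
) -> AngleSeries:
    """Signed plane-projected angle of the segment a→b over time.

    Both trajectories must share timestamps (marker *b* is otherwise linearly
    interpolated onto *a*'s grid over the overlap).  Samples whose projected
    segment length falls below ``MIN_PROJECTED_LENGTH_MM`` are flagged and
    filled by interpolation; the trial errors out if more than
    ``MAX_DEGENERATE_FRACTION`` of samples are degenerate.  With
    ``reference_window=None`` the raw lab-frame angle is returned; otherwise
    the series is re-referenced to the initial standing window like the IMU
    chain.
    """
    if reference_window is not None and reference_window <= 0:
        raise InvalidParameterError("reference_window must be positive")
    if a.t.size == b.t.size and np.allclose(a.t, b.t, atol=1e-9):
        t = a.t
        d = b.xyz - a.xyz
    else:
        t0, t1 = max(a.t[0], b.t[0]), min(a.t[-1], b.t[-1])
        if t1 <= t0:
            raise InvalidInputError("marker trajectories do not overlap in time")
        mask = (a.t >= t0) & (a.t <= t1)
        t = a.t[mask]
        b_interp = np.column_stack([np.interp(t, b.t, b.xyz[:, k]) for k in range(3)])
        d = b_interp - a.xyz[mask]
    if t.size < 2:
        raise InvalidInputError("angle series requires at least 2 samples")

    i_sin, i_cos = _PLANE_COMPONENTS[seg.plane]
    u, v = d[:, i_sin], d[:, i_cos]
    proj_len = np.hypot(u, v)
    degenerate = proj_len < MIN_PROJECTED_LENGTH_MM
    frac = degenerate.mean()
    if frac > MAX_DEGENERATE_FRACTION:
        raise InvalidInputError(
            f"{frac:.1%} of samples have the segment perpendicular to the "
            f"{seg.plane.value} plane (limit {MAX_DEGENERATE_FRACTION:.0%})"
        )
    angle = np.degrees(np.arctan2(u, v))
    if degenerate.any():
        good = ~degenerate
        if not good.any():
            raise InvalidInputError("all samples degenerate")
        angle[degenerate] = np.interp(t[degenerate], t[good], angle[good])
    angle = np.unwrap(angle, period=360.0)

    if reference_window is not None:
        ref_mask = t <= t[0] + reference_window
        angle = angle - angle[ref_mask].mean()
    rate = 1.0 / np.median(np.diff(t))
    return AngleSeries(seg.region, seg.plane, rate, t, angle)
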