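"""Common-grid resampling and pointwise curve agreement.

The two acquisition systems run at different rates (IMU 12 Hz, optical
50 Hz); both angle signals are brought onto a common 100 Hz grid by linear
interpolation before mobility curves are compared.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, InvalidInputError, InvalidParameterError
from .series import AngleSeries

__all__ = ["ResampleSpec", "upsample_linear", "curve_rmse"]


@dataclass(frozen=True)
class ResampleSpec:
    """Target grid description; the method is fixed to linear interpolation."""

    target_rate: float = 100.0
    method: str = "linear"

    def __post_init__(self) -> None:
        if self.target_rate <= 0:
            raise InvalidParameterError("target_rate must be positive")
        if self.method != "linear":
            raise InvalidParameterError("only linear resampling is supported")


def upsample_linear(series: AngleSeries, spec: ResampleSpec = ResampleSpec()) -> AngleSeries:
    """Linearly interpolate onto a uniform grid at ``spec.target_rate``.

    The new grid starts at the series' first sample and never extends beyond
    its support; original sample values are reproduced exactly wherever grid
    points coincide.
    """
    if len(series) < 2:
        raise InvalidInputError("upsampling requires at least 2 samples")
    if spec.target_rate < series.rate:
        raise InvalidParameterError(
            f"target rate {spec.target_rate} Hz is below the source rate {series.rate} Hz"
        )
    span = series.t[-1] - series.t[0]
    n = int(np.floor(span * spec.target_rate + 1e-9)) + 1
    t = series.t[0] + np.arange(n) / spec.target_rate
    value = np.interp(t, series.t, series.value)
    return AngleSeries(series.region, series.plane, spec.target_rate, t, value)


def curve_rmse(a: AngleSeries, b: AngleSeries) -> float:
    """Root-mean-square pointwise difference of two same-grid angle curves."""
    if len(a) != len(b) or not np.allclose(a.t, b.t, atol=1e-9):
        raise AlignmentError("curves are not on the same time grid")
    d = a.value - b.value
    return float(np.sqrt(np.mean(d * d)))
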