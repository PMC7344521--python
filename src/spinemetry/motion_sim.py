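"""Synthetic paired-recording generator for spinal-mobility validation studies.

Generates ground-truth spinal motion for virtual subjects (axial
spondyloarthritis patients vs. healthy controls), renders it both as a
dual-sensor IMU orientation recording (12 Hz) and as an optical marker-pair
recording (50 Hz) driven by one shared truth, and draws clinical outcome
variables with a configurable correlation to a latent mobility factor.

The movement waveform is a raised-cosine excursion with a short hold at each
peak: the subject stands still (lead-in), then performs ``n_reps``
repetitions, each consisting of one excursion to the positive peak and one to
the negative peak, separated by rests.  The hold guarantees that the
programmed peak-to-peak range is attained exactly on any sampling grid whose
step is shorter than the hold.

Group-level defaults for every regional range of motion reproduce the
published descriptive statistics of an axSpA cohort and matched healthy
controls; outcome-variable defaults likewise follow the published cohort
descriptives.  All randomness flows through a single
:class:`numpy.random.Generator`, so a seed fully determines the dataset.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, InvalidInputError, InvalidParameterError
from .series import AXIS_FOR_PLANE, PLANES, AngleSeries, MarkerTrajectory, OrientationSeries, Plane, Region

logger = logging.getLogger(__name__)

__all__ = [
    "MovementProfile",
    "NoiseSpec",
    "CohortSpec",
    "OutcomeDef",
    "OutcomeSpec",
    "SubjectSpec",
    "Dataset",
    "simulate_angle_trajectory",
    "render_imu_pair",
    "render_marker_set",
    "generate_cohort",
    "default_cohort_spec",
    "default_outcome_spec",
    "TABLE_ROM_DEFAULTS",
    "GROUP_AXSPA",
    "GROUP_CONTROL",
]

GROUP_AXSPA = "axSpA"
GROUP_CONTROL = "control"

#: internal sampling rate (Hz) of ground-truth trajectories before rendering
TRUTH_RATE = 100.0


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class MovementProfile:
    """One region x plane movement task.

    ``rom_true`` is the total peak-to-peak excursion in degrees;
    ``asymmetry`` is the fraction of it assigned to the positive direction
    (0.5 = symmetric flexion/extension).
    """

    region: Region
    plane: Plane
    rom_true: float
    n_reps: int = 3
    cycle_duration: float = 4.0
    rest_duration: float = 1.0
    asymmetry: float = 0.5
    lead_in: float = 1.0
    peak_hold: float = 0.4

    def __post_init__(self) -> None:
        object.__setattr__(self, "region", Region(self.region))
        object.__setattr__(self, "plane", Plane(self.plane))
        if self.rom_true < 0:
            raise InvalidParameterError("rom_true must be >= 0")
        if self.n_reps < 1:
            raise InvalidParameterError("n_reps must be >= 1")
        if self.cycle_duration <= 0:
            raise InvalidParameterError("cycle_duration must be positive")
        if self.rest_duration < 0:
            raise InvalidParameterError("rest_duration must be >= 0")
        if not 0.0 <= self.asymmetry <= 1.0:
            raise InvalidParameterError("asymmetry must lie in [0, 1]")
        if self.lead_in < 0:
            raise InvalidParameterError("lead_in must be >= 0")
        if self.peak_hold < 0:
            raise InvalidParameterError("peak_hold must be >= 0")

    @property
    def total_duration(self) -> float:
        """Recording length in seconds (lead-in + reps + rests + tail rest)."""
        return self.lead_in + self.n_reps * (self.cycle_duration + self.rest_duration)


@dataclass(frozen=True)
class NoiseSpec:
    """Sensor imperfection model.

    * ``orientation_noise_sd`` — white noise per IMU axis sample (deg).
    * ``mounting_offset_sd`` — constant per-sensor, per-axis bias drawn once
      per recording (deg); removed downstream by reference zeroing.
    * ``skin_artifact_amp`` — amplitude (deg) of a motion-proportional
      soft-tissue artifact (scaled copy of the normalized true motion with a
      random per-sensor gain), mimicking skin movement that worsens with the
      amplitude of the movement itself.
    * ``marker_noise_sd`` — isotropic optical marker jitter (mm).
    """

    orientation_noise_sd: float = 1.0
    mounting_offset_sd: float = 2.0
    skin_artifact_amp: float = 1.0
    marker_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("orientation_noise_sd", "mounting_offset_sd",
                     "skin_artifact_amp", "marker_noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")

    @classmethod
    def noiseless(cls, seed: int = 0) -> "NoiseSpec":
        return cls(0.0, 0.0, 0.0, 0.0, seed)


#: Published group mean (SD) of true peak-to-peak ROM, degrees, per measure.
TABLE_ROM_DEFAULTS: dict[str, dict[tuple[Region, Plane], tuple[float, float]]] = {
    GROUP_AXSPA: {
        (Region.CERVICAL, Plane.SAGITTAL): (82.1, 24.8),
        (Region.CERVICAL, Plane.FRONTAL): (56.2, 26.2),
        (Region.CERVICAL, Plane.AXIAL): (111.9, 39.1),
        (Region.L1_ABSOLUTE, Plane.SAGITTAL): (119.5, 23.6),
        (Region.L1_ABSOLUTE, Plane.FRONTAL): (50.5, 20.2),
        (Region.L1_ABSOLUTE, Plane.AXIAL): (126.3, 29.6),
        (Region.LUMBAR, Plane.SAGITTAL): (49.7, 21.4),
        (Region.LUMBAR, Plane.FRONTAL): (41.8, 17.8),
        (Region.LUMBAR, Plane.AXIAL): (21.2, 8.7),
    },
    GROUP_CONTROL: {
        (Region.CERVICAL, Plane.SAGITTAL): (99.3, 15.6),
        (Region.CERVICAL, Plane.FRONTAL): (67.7, 12.7),
        (Region.CERVICAL, Plane.AXIAL): (138.6, 17.2),
        (Region.L1_ABSOLUTE, Plane.SAGITTAL): (139.6, 19.9),
        (Region.L1_ABSOLUTE, Plane.FRONTAL): (69.5, 12.8),
        (Region.L1_ABSOLUTE, Plane.AXIAL): (128.2, 24.5),
        (Region.LUMBAR, Plane.SAGITTAL): (61.4, 12.5),
        (Region.LUMBAR, Plane.FRONTAL): (53.6, 11.6),
        (Region.LUMBAR, Plane.AXIAL): (26.6, 7.1),
    },
}


@dataclass
class CohortSpec:
    """Two-group cohort description.

    ``rom_params[group][(region, plane)] = (mean, sd)`` in degrees; each
    measure is drawn independently per subject from a truncated normal on
    ``bounds``.  A subject's latent mobility factor — the quantity outcome
    variables are conditioned on — is their standardized mobility composite
    (mean of the measures' group z-scores, rescaled to unit variance).
    """

    n_per_group: int = 20
    rom_params: Mapping[str, Mapping[tuple[Region, Plane], tuple[float, float]]] = field(
        default_factory=lambda: {g: dict(v) for g, v in TABLE_ROM_DEFAULTS.items()}
    )
    bounds: tuple[float, float] = (0.0, 200.0)
    cycle_duration: float = 4.0
    rest_duration: float = 1.0
    n_reps: int = 3
    lead_in: float = 1.0
    peak_hold: float = 0.4
    segment_length_mm: float = 150.0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise InvalidParameterError("n_per_group must be >= 2")
        lo, hi = self.bounds
        if not lo < hi:
            raise InvalidParameterError("bounds must satisfy lo < hi")
        for group, params in self.rom_params.items():
            for key, (mean, sd) in params.items():
                if sd < 0:
                    raise InvalidParameterError(f"{group}/{key}: sd must be >= 0")
                if not 0.0 <= mean <= 200.0:
                    raise InvalidParameterError(
                        f"{group}/{key}: mean {mean} outside physiologic bounds (0-200 deg)"
                    )


@dataclass(frozen=True)
class OutcomeDef:
    """Marginal distribution and latent-mobility correlation of one outcome.

    ``params[group] = (mean, sd)``; groups absent from ``params`` get a
    missing value.  ``target_r`` is the correlation with the latent mobility
    factor (coded higher = more mobile), so disease-burden scores carry
    negative targets.
    """

    name: str
    params: Mapping[str, tuple[float, float]]
    lo: float
    hi: float
    target_r: float
    integer: bool = False

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise InvalidParameterError(f"{self.name}: lo must be < hi")
        for group, (mean, sd) in self.params.items():
            if sd < 0:
                raise InvalidParameterError(f"{self.name}/{group}: sd must be >= 0")


@dataclass
class OutcomeSpec:
    """The set of outcome variables to generate."""

    outcomes: Sequence[OutcomeDef]

    def __post_init__(self) -> None:
        bad = [o.name for o in self.outcomes if abs(o.target_r) > 1.0]
        if bad:
            raise ConfigurationError(
                "infeasible latent-factor correlation (|target_r| > 1) for: "
                + ", ".join(bad)
            )
        names = [o.name for o in self.outcomes]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate outcome names")

    def __iter__(self):
        return iter(self.outcomes)


#: conventional metrology items (generated for both groups)
_METROLOGY_DEFAULTS = [
    # name, axSpA (mean, sd), control (mean, sd), lo, hi, target_r
    ("lateral_flexion_cm", (11.7, 5.7), (21.6, 16.7), 0.0, 120.0, 0.60),
    ("tragus_to_wall_cm", (13.5, 4.7), (11.1, 1.2), 8.0, 45.0, -0.71),
    ("schober_cm", (4.8, 1.9), (5.3, 1.0), 0.0, 12.0, 0.68),
    ("intermalleolar_cm", (95.5, 16.3), (117.0, 15.4), 20.0, 180.0, 0.77),
    ("cervical_rotation_deg", (56.1, 18.1), (75.0, 7.2), 0.0, 180.0, 0.83),
]

#: disease outcomes (axSpA only)
_DISEASE_DEFAULTS = [
    # name, (mean, sd), lo, hi, target_r, integer
    ("BASDAI", (3.9, 2.7), 0.0, 10.0, -0.40, False),
    ("BASFI", (3.2, 2.7), 0.0, 10.0, -0.62, False),
    ("ASAS_HI", (4.1, 3.7), 0.0, 17.0, -0.55, False),
    ("BAS_G", (4.0, 2.9), 0.0, 10.0, -0.45, False),
    ("ASDAS", (2.4, 0.9), 0.3, 7.0, -0.36, False),
    ("mSASSS", (11.8, 13.7), 0.0, 72.0, -0.76, True),
]


def default_outcome_spec() -> OutcomeSpec:
    """Outcome set with published cohort descriptives as marginals."""
    defs: list[OutcomeDef] = []
    for name, axspa, control, lo, hi, r in _METROLOGY_DEFAULTS:
        defs.append(OutcomeDef(name, {GROUP_AXSPA: axspa, GROUP_CONTROL: control}, lo, hi, r))
    for name, axspa, lo, hi, r, integer in _DISEASE_DEFAULTS:
        defs.append(OutcomeDef(name, {GROUP_AXSPA: axspa}, lo, hi, r, integer))
    return OutcomeSpec(defs)


def default_cohort_spec(**overrides) -> CohortSpec:
    """CohortSpec with published axSpA/control group means and SDs."""
    return CohortSpec(**overrides)


@dataclass
class SubjectSpec:
    """Per-subject ground truth: movement profiles plus pelvic contributions.

    ``profiles`` holds one :class:`MovementProfile` per region x plane for the
    two directly instrumented regions (cervical, lumbar).  ``pelvic_rom``
    gives the pelvic share of trunk motion per plane in degrees, so the
    absolute L1 range is lumbar ROM + pelvic ROM.
    """

    subject_id: str
    group: str
    profiles: dict[tuple[Region, Plane], MovementProfile]
    pelvic_rom: dict[Plane, float]
    latent: float
    segment_length_mm: float = 150.0

    def __post_init__(self) -> None:
        expected = {(r, p) for r in (Region.CERVICAL, Region.LUMBAR) for p in PLANES}
        if set(self.profiles) != expected:
            raise InvalidInputError("profiles must cover cervical & lumbar x 3 planes")
        if any(v < 0 for v in self.pelvic_rom.values()):
            raise InvalidParameterError("pelvic contributions must be >= 0")

    def truth_rom(self, region: Region, plane: Plane) -> float:
        if region is Region.L1_ABSOLUTE:
            return self.profiles[(Region.LUMBAR, plane)].rom_true + self.pelvic_rom[plane]
        return self.profiles[(region, plane)].rom_true


@dataclass
class Dataset:
    """A simulated (or loaded) study dataset.

    ``imu[(subject_id, region, plane)] = (upper, lower)`` orientation series
    for the two directly instrumented regions; ``mocap[(subject_id, region,
    plane)] = (marker_a, marker_b)`` for cervical, lumbar and trunk (L1)
    segments.  ``truth`` is present for synthetic data only.
    """

    subjects: "object"  # pandas.DataFrame: subject_id, group
    imu: dict
    mocap: dict
    truth: "object | None" = None   # DataFrame: subject_id, region, plane, rom_true_deg
    outcomes: "object | None" = None  # DataFrame: subject_id, group, <outcome columns>
    protocol: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


# --------------------------------------------------------------------------- #
# trajectory synthesis
# --------------------------------------------------------------------------- #

def simulate_angle_trajectory(profile: MovementProfile, rate: float) -> AngleSeries:
    """Sample the noise-free movement waveform of one profile at ``rate`` Hz.

    The signal starts and ends at 0 deg and contains ``n_reps`` repetitions;
    each repetition is a raised-cosine excursion to ``+asymmetry*rom_true``
    followed by one to ``-(1-asymmetry)*rom_true``, with a ``peak_hold``
    plateau at each peak so the global max - min equals ``rom_true`` exactly
    whenever the sampling step does not exceed the hold.
    """
    if rate <= 0:
        raise InvalidParameterError("rate must be positive")
    n = int(round(profile.total_duration * rate)) + 1
    t = np.arange(n) / rate
    v = np.zeros(n)
    pos_peak = profile.asymmetry * profile.rom_true
    neg_peak = -(1.0 - profile.asymmetry) * profile.rom_true
    half = profile.cycle_duration / 2.0
    hold = min(profile.peak_hold, 0.5 * half)
    ramp = (half - hold) / 2.0
    for rep in range(profile.n_reps):
        start = profile.lead_in + rep * (profile.cycle_duration + profile.rest_duration)
        for peak, offset in ((pos_peak, 0.0), (neg_peak, half)):
            if peak == 0.0:
                continue
            s = t - (start + offset)
            rise = (s >= 0) & (s < ramp)
            v[rise] = peak * 0.5 * (1.0 - np.cos(np.pi * s[rise] / ramp))
            plateau = (s >= ramp) & (s < ramp + hold)
            v[plateau] = peak
            fall = (s >= ramp + hold) & (s < 2 * ramp + hold)
            v[fall] = peak * 0.5 * (1.0 + np.cos(np.pi * (s[fall] - ramp - hold) / ramp))
    return AngleSeries(profile.region, profile.plane, rate, t, v)


def _resample_to(t_new: np.ndarray, series: AngleSeries) -> np.ndarray:
    return np.interp(t_new, series.t, series.value)


def _common_grid(truth: Mapping[Plane, AngleSeries], rate: float) -> np.ndarray:
    ref = next(iter(truth.values()))
    for s in truth.values():
        if s.t.size != ref.t.size or not np.allclose(s.t, ref.t, atol=1e-9):
            raise InvalidInputError("truth signals must share one time grid")
    span = ref.t[-1] - ref.t[0]
    n = int(np.floor(span * rate)) + 1
    return ref.t[0] + np.arange(n) / rate


def render_imu_pair(
    truth: Mapping[Plane, AngleSeries],
    noise: NoiseSpec,
    region: Region,
    distal: Mapping[Plane, AngleSeries] | None = None,
    rate: float = 12.0,
    rng: np.random.Generator | None = None,
    sensor_prefix: str = "",
) -> tuple[OrientationSeries, OrientationSeries]:
    """Render a dual-sensor IMU recording of one region.

    The upper sensor carries the regional truth plus any distal share (e.g.
    pelvic motion under the lumbar region); the lower sensor carries only the
    distal share, so their per-plane difference reproduces the regional truth.
    Each axis is perturbed by a constant mounting offset, a motion-proportional
    skin artifact and white noise, then sampled at ``rate`` Hz.
    """
    if rate <= 0:
        raise InvalidParameterError("rate must be positive")
    if not truth:
        raise InvalidInputError("truth must contain at least one plane")
    region = Region(region)
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    all_series = dict(truth)
    if distal:
        all_series.update({p: s for p, s in distal.items() if p not in all_series})
    t_out = _common_grid(all_series, rate)

    def render_sensor(role: str, include_regional: bool) -> OrientationSeries:
        axes: dict[str, np.ndarray] = {}
        for plane in PLANES:
            clean = np.zeros_like(t_out)
            parts: list[AngleSeries] = []
            if include_regional and plane in truth:
                parts.append(truth[plane])
            if distal and plane in distal:
                parts.append(distal[plane])
            for part in parts:
                clean = clean + _resample_to(t_out, part)
            offset = rng.normal(0.0, noise.mounting_offset_sd) if noise.mounting_offset_sd else 0.0
            gain = rng.uniform(-1.0, 1.0) if noise.skin_artifact_amp else 0.0
            scale = np.max(np.abs(clean))
            artifact = (
                gain * noise.skin_artifact_amp * clean / scale if scale > 0 else 0.0
            )
            white = (
                rng.normal(0.0, noise.orientation_noise_sd, t_out.size)
                if noise.orientation_noise_sd
                else 0.0
            )
            axes[AXIS_FOR_PLANE[plane]] = clean + offset + artifact + white
        sensor_id = f"{sensor_prefix}{region.value}:{role}"
        return OrientationSeries(sensor_id, rate, t_out, axes["roll"], axes["pitch"], axes["yaw"])

    upper = render_sensor("upper", include_regional=True)
    lower = render_sensor("lower", include_regional=False)
    return upper, lower


#: rest direction and in-plane rotation used to embed a plane angle in 3-D.
#: Lab frame: right-handed, z up, y anterior, x lateral (to the right).
def _plane_direction(plane: Plane, theta_rad: np.ndarray) -> np.ndarray:
    s, c = np.sin(theta_rad), np.cos(theta_rad)
    zero = np.zeros_like(theta_rad)
    if plane is Plane.SAGITTAL:     # rotate from vertical, within y-z
        return np.stack([zero, s, c], axis=1)
    if plane is Plane.FRONTAL:      # rotate from vertical, within x-z
        return np.stack([s, zero, c], axis=1)
    # axial: rotate from anterior, within x-y
    return np.stack([s, c, zero], axis=1)


def render_marker_set(
    truth: Mapping[Plane, AngleSeries],
    noise: NoiseSpec,
    segment_length_mm: float = 150.0,
    base_position_mm: tuple[float, float, float] = (0.0, 0.0, 1000.0),
    rate: float = 50.0,
    rng: np.random.Generator | None = None,
    marker_prefix: str = "",
) -> dict[tuple[Plane, str], MarkerTrajectory]:
    """Render optical marker pairs whose segment reproduces each truth angle.

    For every plane present in ``truth`` a pair of point trajectories is
    produced such that the segment from marker *a* to marker *b*, projected on
    that anatomical plane, equals the truth angle; isotropic Gaussian jitter of
    ``noise.marker_noise_sd`` mm is added to every coordinate.
    """
    if segment_length_mm <= 0:
        raise InvalidParameterError("segment_length_mm must be positive")
    if rate <= 0:
        raise InvalidParameterError("rate must be positive")
    if not truth:
        raise InvalidInputError("truth must contain at least one plane")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    t_out = _common_grid(truth, rate)
    base = np.asarray(base_position_mm, dtype=float)
    out: dict[tuple[Plane, str], MarkerTrajectory] = {}
    for plane in PLANES:
        if plane not in truth:
            continue
        theta = np.deg2rad(_resample_to(t_out, truth[plane]))
        a = np.tile(base, (t_out.size, 1))
        b = a + segment_length_mm * _plane_direction(plane, theta)
        if noise.marker_noise_sd:
            a = a + rng.normal(0.0, noise.marker_noise_sd, a.shape)
            b = b + rng.normal(0.0, noise.marker_noise_sd, b.shape)
        out[(plane, "a")] = MarkerTrajectory(f"{marker_prefix}{plane.value}:a", t_out, a)
        out[(plane, "b")] = MarkerTrajectory(f"{marker_prefix}{plane.value}:b", t_out, b)
    return out


# --------------------------------------------------------------------------- #
# cohort generation
# --------------------------------------------------------------------------- #

def _truncated_draw(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    shared: float,
    loading: float,
    bounds: tuple[float, float],
    max_tries: int = 200,
) -> float:
    """One factor-structured normal draw, rejected into ``bounds``.

    value = mean + sd * (loading * shared + sqrt(1 - loading^2) * e); the
    idiosyncratic term is redrawn until the value is inside the bounds (the
    shared factor is kept so the correlation structure survives truncation up
    to the small rejection distortion), falling back to clipping.
    """
    resid = np.sqrt(max(0.0, 1.0 - loading**2))
    lo, hi = bounds
    val = mean + sd * (loading * shared + resid * rng.standard_normal())
    tries = 0
    while not (lo <= val <= hi) and tries < max_tries:
        val = mean + sd * (loading * shared + resid * rng.standard_normal())
        tries += 1
    return float(min(max(val, lo), hi))


def _draw_subject(
    rng: np.random.Generator,
    subject_id: str,
    group: str,
    cohort: CohortSpec,
) -> SubjectSpec:
    params = cohort.rom_params[group]
    rom: dict[tuple[Region, Plane], float] = {}
    zscores: list[float] = []
    for region in (Region.CERVICAL, Region.LUMBAR, Region.L1_ABSOLUTE):
        for plane in PLANES:
            mean, sd = params[(region, plane)]
            val = _truncated_draw(rng, mean, sd, 0.0, 0.0, cohort.bounds)
            rom[(region, plane)] = val
            if sd > 0:
                zscores.append((val - mean) / sd)
    # latent mobility factor: standardized mobility composite of the draws
    z = float(np.mean(zscores) * np.sqrt(len(zscores))) if zscores else 0.0
    profiles = {
        (region, plane): MovementProfile(
            region,
            plane,
            rom[(region, plane)],
            n_reps=cohort.n_reps,
            cycle_duration=cohort.cycle_duration,
            rest_duration=cohort.rest_duration,
            lead_in=cohort.lead_in,
            peak_hold=cohort.peak_hold,
        )
        for region in (Region.CERVICAL, Region.LUMBAR)
        for plane in PLANES
    }
    # pelvic share: whatever of the drawn absolute-L1 range exceeds the lumbar range
    pelvic = {
        plane: max(0.0, rom[(Region.L1_ABSOLUTE, plane)] - rom[(Region.LUMBAR, plane)])
        for plane in PLANES
    }
    return SubjectSpec(subject_id, group, profiles, pelvic, z, cohort.segment_length_mm)


def _draw_outcomes(
    rng: np.random.Generator, spec: OutcomeSpec, group: str, z: float
) -> dict[str, float]:
    row: dict[str, float] = {}
    for o in spec:
        if group not in o.params:
            row[o.name] = np.nan
            continue
        mean, sd = o.params[group]
        val = _truncated_draw(rng, mean, sd, z, o.target_r, (o.lo, o.hi))
        if o.integer:
            val = float(np.clip(round(val), o.lo, o.hi))
        row[o.name] = val
    return row


def generate_cohort(
    cohort: CohortSpec | None = None,
    outcomes: OutcomeSpec | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    render: str = "full",
    imu_rate: float = 12.0,
    mocap_rate: float = 50.0,
) -> Dataset:
    """Simulate a full two-group study dataset.

    ``render`` selects how much signal-level data to produce: ``"full"``
    (IMU + optical), ``"imu"`` (IMU only, as for the control group in a
    concurrent-validity design) or ``"none"`` (ground-truth ROM and outcome
    tables only, for fast statistical Monte-Carlo work).
    """
    import pandas as pd

    cohort = cohort if cohort is not None else default_cohort_spec()
    outcomes = outcomes if outcomes is not None else default_outcome_spec()
    noise = noise if noise is not None else NoiseSpec()
    if render not in ("full", "imu", "none"):
        raise InvalidParameterError("render must be one of 'full', 'imu', 'none'")
    rng = np.random.default_rng(seed)

    subj_rows, truth_rows, outcome_rows = [], [], []
    imu: dict = {}
    mocap: dict = {}
    for group in (GROUP_AXSPA, GROUP_CONTROL):
        for i in range(cohort.n_per_group):
            sid = f"{group}-{i + 1:03d}"
            spec = _draw_subject(rng, sid, group, cohort)
            subj_rows.append({"subject_id": sid, "group": group})
            for region in (Region.CERVICAL, Region.LUMBAR, Region.L1_ABSOLUTE):
                for plane in PLANES:
                    truth_rows.append(
                        {
                            "subject_id": sid,
                            "region": region.value,
                            "plane": plane.value,
                            "rom_true_deg": spec.truth_rom(region, plane),
                        }
                    )
            outcome_rows.append(
                {"subject_id": sid, "group": group, **_draw_outcomes(rng, outcomes, group, spec.latent)}
            )
            if render == "none":
                continue
            for region in (Region.CERVICAL, Region.LUMBAR):
                for plane in PLANES:
                    profile = spec.profiles[(region, plane)]
                    truth_series = simulate_angle_trajectory(profile, TRUTH_RATE)
                    distal = None
                    l1_series = None
                    if region is Region.LUMBAR:
                        pelvic_profile = replace(
                            profile, region=Region.L1_ABSOLUTE, rom_true=spec.pelvic_rom[plane]
                        )
                        pelvic_series = simulate_angle_trajectory(pelvic_profile, TRUTH_RATE)
                        distal = {plane: pelvic_series}
                        l1_series = AngleSeries(
                            Region.L1_ABSOLUTE,
                            plane,
                            TRUTH_RATE,
                            truth_series.t,
                            truth_series.value + pelvic_series.value,
                        )
                    upper, lower = render_imu_pair(
                        {plane: truth_series},
                        noise,
                        region,
                        distal=distal,
                        rate=imu_rate,
                        rng=rng,
                        sensor_prefix=f"{sid}:{plane.value}:",
                    )
                    imu[(sid, region, plane)] = (upper, lower)
                    if render == "full":
                        pair = render_marker_set(
                            {plane: truth_series},
                            noise,
                            segment_length_mm=spec.segment_length_mm,
                            rate=mocap_rate,
                            rng=rng,
                            marker_prefix=f"{sid}:{region.value}:",
                        )
                        mocap[(sid, region, plane)] = (pair[(plane, "a")], pair[(plane, "b")])
                        if l1_series is not None:
                            pair = render_marker_set(
                                {plane: l1_series},
                                noise,
                                segment_length_mm=spec.segment_length_mm,
                                rate=mocap_rate,
                                rng=rng,
                                marker_prefix=f"{sid}:{Region.L1_ABSOLUTE.value}:",
                            )
                            mocap[(sid, Region.L1_ABSOLUTE, plane)] = (
                                pair[(plane, "a")],
                                pair[(plane, "b")],
                            )

    protocol = {
        "lead_in": cohort.lead_in,
        "cycle_duration": cohort.cycle_duration,
        "rest_duration": cohort.rest_duration,
        "n_reps": cohort.n_reps,
    }
    ds = Dataset(
        subjects=pd.DataFrame(subj_rows),
        imu=imu,
        mocap=mocap,
        truth=pd.DataFrame(truth_rows),
        outcomes=pd.DataFrame(outcome_rows),
        protocol=protocol,
        provenance={"seed": seed, "render": render, "noise": noise.__dict__.copy()},
    )
    logger.info(
        "generated cohort: %d subjects/group, render=%s, seed=%d",
        cohort.n_per_group, render, seed,
    )
    return ds
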