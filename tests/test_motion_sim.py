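"""Simulator: waveform shape, paired rendering, cohort and outcome draws."""
import numpy as np
import pytest

from spinemetry.errors import ConfigurationError, InvalidParameterError
from spinemetry.motion_sim import (
    GROUP_CONTROL,
    MovementProfile,
    NoiseSpec,
    OutcomeDef,
    OutcomeSpec,
    default_cohort_spec,
    default_outcome_spec,
    generate_cohort,
    render_imu_pair,
    render_marker_set,
    simulate_angle_trajectory,
)
from spinemetry.series import Plane, Region


def profile(rom, **kw):
    kw.setdefault("region", Region.CERVICAL)
    kw.setdefault("plane", Plane.SAGITTAL)
    return MovementProfile(rom_true=rom, **kw)


class TestTrajectory:
    def test_zero_rom_gives_constant_zero_signal(self):
        s = simulate_angle_trajectory(profile(0.0), rate=100.0)
        assert np.all(s.value == 0.0)

    def test_symmetric_excursion_peaks(self):
        s = simulate_angle_trajectory(profile(60.0, asymmetry=0.5), rate=100.0)
        assert s.value.max() == pytest.approx(30.0, abs=1e-12)
        assert s.value.min() == pytest.approx(-30.0, abs=1e-12)

    def test_asymmetric_split_of_range(self):
        s = simulate_angle_trajectory(profile(60.0, asymmetry=0.3), rate=100.0)
        assert s.value.max() == pytest.approx(18.0, abs=1e-12)
        assert s.value.min() == pytest.approx(-42.0, abs=1e-12)

    @pytest.mark.parametrize("rate", [12.0, 50.0, 100.0])
    def test_peak_to_peak_recovers_programmed_range(self, rate):
        # oracle: exhaustive max - min over the generated samples
        s = simulate_angle_trajectory(profile(82.1), rate=rate)
        ptp = max(s.value) - min(s.value)
        assert ptp == pytest.approx(82.1, abs=1e-9)

    def test_signal_starts_and_ends_at_zero(self):
        s = simulate_angle_trajectory(profile(45.0), rate=100.0)
        assert s.value[0] == 0.0 and abs(s.value[-1]) < 1e-9

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_angle_trajectory(profile(60.0), rate=0.0)
        with pytest.raises(InvalidParameterError):
            profile(-5.0)
        with pytest.raises(InvalidParameterError):
            profile(60.0, cycle_duration=0.0)
        with pytest.raises(InvalidParameterError):
            profile(60.0, asymmetry=1.5)


class TestImuRender:
    def test_noiseless_difference_reproduces_truth(self):
        truth = simulate_angle_trajectory(profile(70.0), rate=100.0)
        upper, lower = render_imu_pair(
            {Plane.SAGITTAL: truth}, NoiseSpec.noiseless(), Region.CERVICAL
        )
        expected = np.interp(upper.t, truth.t, truth.value)
        np.testing.assert_allclose(upper.pitch - lower.pitch, expected, atol=1e-9)
        assert np.all(lower.pitch == 0.0)

    def test_distal_share_moves_both_sensors(self):
        lum = simulate_angle_trajectory(profile(50.0, region=Region.LUMBAR), rate=100.0)
        pelv = simulate_angle_trajectory(profile(20.0, region=Region.L1_ABSOLUTE), rate=100.0)
        upper, lower = render_imu_pair(
            {Plane.SAGITTAL: lum}, NoiseSpec.noiseless(), Region.LUMBAR,
            distal={Plane.SAGITTAL: pelv},
        )
        # lower sensor carries only the pelvic share; difference is the lumbar truth
        np.testing.assert_allclose(
            lower.pitch, np.interp(upper.t, pelv.t, pelv.value), atol=1e-9
        )
        np.testing.assert_allclose(
            upper.pitch - lower.pitch, np.interp(upper.t, lum.t, lum.value), atol=1e-9
        )
        assert max(upper.pitch) - min(upper.pitch) == pytest.approx(70.0, abs=1e-9)

    def test_mounting_offset_is_constant_and_removable(self):
        from spinemetry.imu_kinematics import zero_to_reference

        truth = simulate_angle_trajectory(profile(40.0), rate=100.0)
        noise = NoiseSpec(0.0, mounting_offset_sd=5.0, skin_artifact_amp=0.0,
                          marker_noise_sd=0.0, seed=3)
        upper, lower = render_imu_pair({Plane.SAGITTAL: truth}, noise, Region.CERVICAL)
        clean_u, _ = render_imu_pair(
            {Plane.SAGITTAL: truth}, NoiseSpec.noiseless(), Region.CERVICAL
        )
        # offset is constant per axis ...
        assert np.ptp(upper.pitch - clean_u.pitch) < 1e-9
        # ... and zeroing recovers the clean zeroed signal exactly
        np.testing.assert_allclose(
            zero_to_reference(upper).pitch, zero_to_reference(clean_u).pitch, atol=1e-9
        )

    def test_same_seed_identical_different_seed_differs(self):
        truth = simulate_angle_trajectory(profile(40.0), rate=100.0)
        noise = NoiseSpec(orientation_noise_sd=2.0, seed=9)
        u1, l1 = render_imu_pair({Plane.SAGITTAL: truth}, noise, Region.CERVICAL)
        u2, l2 = render_imu_pair({Plane.SAGITTAL: truth}, noise, Region.CERVICAL)
        np.testing.assert_array_equal(u1.pitch, u2.pitch)
        np.testing.assert_array_equal(l1.yaw, l2.yaw)
        u3, _ = render_imu_pair(
            {Plane.SAGITTAL: truth}, NoiseSpec(orientation_noise_sd=2.0, seed=10),
            Region.CERVICAL,
        )
        assert not np.array_equal(u1.pitch, u3.pitch)


class TestMarkerRender:
    def test_constant_zero_truth_keeps_markers_aligned(self):
        truth = simulate_angle_trajectory(profile(0.0), rate=100.0)
        pair = render_marker_set({Plane.SAGITTAL: truth}, NoiseSpec.noiseless(),
                                 segment_length_mm=100.0)
        a, b = pair[(Plane.SAGITTAL, "a")], pair[(Plane.SAGITTAL, "b")]
        d = b.xyz - a.xyz
        np.testing.assert_allclose(d[:, 0], 0.0, atol=1e-12)
        np.testing.assert_allclose(d[:, 1], 0.0, atol=1e-12)
        np.testing.assert_allclose(d[:, 2], 100.0, atol=1e-12)

    def test_marker_noise_induced_angle_jitter_matches_theory(self, rng):
        # Monte-Carlo oracle: sd of atan2 of a noisy near-vertical segment.
        # Both endpoints jittered by sd=1 mm -> in-plane transverse error
        # sd sqrt(2) mm over a 300 mm lever -> ~ sqrt(2)/300 rad.
        from spinemetry.mocap_kinematics import SegmentDef, projected_segment_angle_series

        n = 10_000
        t = np.arange(n) / 50.0
        from spinemetry.series import MarkerTrajectory

        base = np.zeros((n, 3))
        seg_vec = np.array([0.0, 0.0, 300.0])
        a_xyz = base + rng.normal(0, 1.0, (n, 3))
        b_xyz = base + seg_vec + rng.normal(0, 1.0, (n, 3))
        a = MarkerTrajectory("a", t, a_xyz)
        b = MarkerTrajectory("b", t, b_xyz)
        seg = SegmentDef("a", "b", Plane.SAGITTAL, Region.CERVICAL)
        series = projected_segment_angle_series(a, b, seg, reference_window=None)
        theory = np.degrees(np.sqrt(2.0) / 300.0)
        assert np.std(series.value) == pytest.approx(theory, rel=0.15)

    def test_degenerate_segment_length_rejected(self):
        truth = simulate_angle_trajectory(profile(30.0), rate=100.0)
        with pytest.raises(InvalidParameterError):
            render_marker_set({Plane.SAGITTAL: truth}, NoiseSpec.noiseless(),
                              segment_length_mm=0.0)


class TestCohort:
    def test_same_seed_reproduces_dataset_exactly(self):
        spec = default_cohort_spec(n_per_group=3)
        a = generate_cohort(spec, seed=5, render="none")
        b = generate_cohort(spec, seed=5, render="none")
        assert a.truth.equals(b.truth)
        assert a.outcomes.equals(b.outcomes)
        c = generate_cohort(spec, seed=6, render="none")
        assert not a.truth.equals(c.truth)

    def test_truth_respects_truncation_and_additivity(self):
        ds = generate_cohort(default_cohort_spec(n_per_group=10), seed=2, render="none")
        t = ds.truth
        assert (t["rom_true_deg"] >= 0).all() and (t["rom_true_deg"] <= 200).all()
        wide = t.pivot_table(index="subject_id", columns=["region", "plane"],
                             values="rom_true_deg")
        # absolute trunk range is never below the lumbar regional range
        for plane in ("sagittal", "frontal", "axial"):
            assert (
                wide[("L1_absolute", plane)] >= wide[("lumbar", plane)] - 1e-9
            ).all()

    def test_group_mean_coverage_of_declared_parameters(self):
        # sampling-theory oracle: the mean of n independent truncated-normal
        # draws should fall inside mean +- 1.96 sd/sqrt(n) in ~95% of seeds
        spec = default_cohort_spec(n_per_group=20)
        half = 1.96 * 15.6 / np.sqrt(20)
        hits = 0
        n_seeds = 300
        for seed in range(n_seeds):
            ds = generate_cohort(spec, seed=seed, render="none")
            tr = ds.truth
            sel = tr[
                (tr["region"] == "cervical")
                & (tr["plane"] == "sagittal")
                & tr["subject_id"].str.startswith(GROUP_CONTROL)
            ]
            if abs(sel["rom_true_deg"].mean() - 99.3) < half:
                hits += 1
        assert hits / n_seeds >= 0.93

    def test_zero_target_correlation_outcome_is_uncorrelated(self):
        flat = OutcomeSpec([
            OutcomeDef("flat", {"axSpA": (5.0, 2.0)}, -1e6, 1e6, target_r=0.0)
        ])
        spec = default_cohort_spec(n_per_group=200)
        ds = generate_cohort(spec, outcomes=flat, seed=4, render="none")
        wide = ds.truth.pivot_table(index="subject_id", values="rom_true_deg",
                                    columns=["region", "plane"])
        merged = ds.outcomes.dropna(subset=["flat"]).merge(
            wide.mean(axis=1).rename("mobility"), left_on="subject_id", right_index=True
        )
        r = np.corrcoef(merged["flat"], merged["mobility"])[0, 1]
        assert abs(r) < 0.2

    def test_high_target_correlation_is_recovered(self):
        strong = OutcomeSpec([
            OutcomeDef("strong", {"axSpA": (0.0, 1.0)}, -1e6, 1e6, target_r=0.9)
        ])
        spec = default_cohort_spec(n_per_group=200)
        ds = generate_cohort(spec, outcomes=strong, seed=4, render="none")
        wide = ds.truth.pivot_table(index="subject_id", values="rom_true_deg",
                                    columns=["region", "plane"])
        # reconstruct the latent factor: standardized mobility composite
        from spinemetry.motion_sim import TABLE_ROM_DEFAULTS

        z = None
        cols = []
        for (region, plane), (mean, sd) in TABLE_ROM_DEFAULTS["axSpA"].items():
            cols.append((wide[(region.value, plane.value)] - mean) / sd)
        latent = sum(cols) / len(cols) * np.sqrt(len(cols))
        merged = ds.outcomes.dropna(subset=["strong"]).merge(
            latent.rename("z"), left_on="subject_id", right_index=True
        )
        r = np.corrcoef(merged["strong"], merged["z"])[0, 1]
        assert r == pytest.approx(0.9, abs=0.1)

    def test_infeasible_correlation_names_offender(self):
        with pytest.raises(ConfigurationError, match="bad_outcome"):
            OutcomeSpec([
                OutcomeDef("bad_outcome", {"axSpA": (1.0, 1.0)}, 0.0, 10.0, target_r=1.2)
            ])

    def test_msasss_is_integer_within_bounds(self):
        ds = generate_cohort(default_cohort_spec(n_per_group=30), seed=8, render="none")
        vals = ds.outcomes["mSASSS"].dropna()
        assert len(vals) == 30  # patients only
        assert (vals == vals.round()).all()
        assert vals.between(0, 72).all()
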