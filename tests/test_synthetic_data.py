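"""Generator-level checks: determinism, truth bookkeeping, and agreement of
sampled populations with their analytic distributions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nmquant import synthetic_data as sd


class TestMusclePhantom:
    def test_deterministic_given_seed(self):
        spec = sd.MusclePhantomSpec(n_fibers=4, seed=42)
        vol1, truth1 = sd.generate_muscle_phantom(spec)
        vol2, truth2 = sd.generate_muscle_phantom(sd.MusclePhantomSpec(n_fibers=4, seed=42))
        np.testing.assert_array_equal(vol1.data, vol2.data)
        pd.testing.assert_frame_equal(truth1.fibers, truth2.fibers)
        np.testing.assert_array_equal(truth1.label_volume, truth2.label_volume)

    def test_truth_conservation(self, clean_muscle_phantom):
        """Every fibre record corresponds to exactly one label in the volume."""
        spec, vol, truth = clean_muscle_phantom
        labels = set(np.unique(truth.label_volume)) - {0}
        assert labels == set(truth.fibers.fiber_id)

    def test_circular_fiber_csa_is_pi_r_squared(self):
        """Eccentricity 0 and zero CSA spread give an exact circular cylinder."""
        mean = 400.0
        spec = sd.MusclePhantomSpec(
            n_fibers=1,
            csa_mean_um2={c: mean for c in sd.CLASS_NAMES},
            csa_cv=0.0,
            fiber_eccentricity_range=(0.0, 0.0),
            axis_tilt_deg=0.0,
            psf_sigma_um=0.0,
            poisson_scale=0.0,
            gaussian_sd=0.0,
            seed=1,
        )
        vol, truth = sd.generate_muscle_phantom(spec)
        r = np.sqrt(mean / np.pi)
        assert truth.fibers.csa_um2.iloc[0] == pytest.approx(np.pi * r**2, rel=1e-12)
        assert truth.fibers.a_um.iloc[0] == pytest.approx(r, rel=1e-12)
        assert truth.fibers.b_um.iloc[0] == pytest.approx(r, rel=1e-12)

    def test_voxel_count_matches_analytic_ellipse(self, clean_muscle_phantom):
        """Label voxel counts on a constant-x slab equal the analytic CSA
        (corrected for tilt) to within one voxel-area per boundary voxel."""
        spec, vol, truth = clean_muscle_phantom
        vx, vy, vz = vol.voxel_size_um
        labels = truth.label_volume
        slab = labels[:, :, labels.shape[2] // 2]
        for row in truth.fibers.itertuples():
            if row.clipped:
                continue
            count = int((slab == row.fiber_id).sum())
            # a constant-x cut of a tilted elliptic cylinder has area
            # (pi a b) / cos(tilt); the voxel count discretises that
            expected_px = row.csa_um2 / row.axis_x / (vy * vz)
            perimeter_px = np.pi * (row.a_um + row.b_um) / min(vy, vz)
            assert abs(count - expected_px) <= perimeter_px

    def test_class_counts_match_reference_proportions(self):
        """Class draws at n=220 stay within the multinomial 95% band around
        the reference proportions (117/62/28/13 of 220)."""
        spec = sd.MusclePhantomSpec(n_fibers=220, seed=20)
        pop = sd.sample_fiber_population(spec)
        counts = pop.innervation_class.value_counts()
        n = spec.n_fibers
        for cls, frac in sd.DEFAULT_CLASS_FRACTIONS.items():
            se = np.sqrt(n * frac * (1 - frac))
            assert abs(counts.get(cls, 0) - n * frac) <= 1.96 * se

    def test_class_conditional_csa_converges(self):
        """Per-class mean CSA at n=500/class is within 3 SE of the spec mean."""
        spec = sd.MusclePhantomSpec(
            n_fibers=2000,
            class_fractions={c: 0.25 for c in sd.CLASS_NAMES},
            seed=31,
        )
        pop = sd.sample_fiber_population(spec)
        for cls in sd.CLASS_NAMES:
            vals = pop.loc[pop.innervation_class == cls, "csa_um2"]
            target = spec.csa_mean_um2[cls]
            se = target * spec.csa_cv / np.sqrt(len(vals))
            assert abs(vals.mean() - target) <= 3 * se

    def test_endplates_only_for_confirmed_classes(self, clean_muscle_phantom):
        """Unconfirmed fibres have no endplate inside the volume; all other
        classes have exactly one, with the matching truth category."""
        spec, vol, truth = clean_muscle_phantom
        eps = truth.endplates.set_index("fiber_id")
        for row in truth.fibers.itertuples():
            if row.innervation_class == "unconfirmed":
                assert row.endplate_ids == ""
            else:
                assert row.fiber_id in eps.index
        cat_by_class = {"graft": "graft_full", "endogenous": "endogenous", "denervated": "denervated"}
        merged = truth.endplates.merge(truth.fibers, on="fiber_id")
        for r in merged.itertuples():
            assert r.category == cat_by_class[r.innervation_class]

    def test_packing_failure_reports_achievable_count(self):
        spec = sd.MusclePhantomSpec(n_fibers=30, lateral_extent_um=120.0, seed=0)
        with pytest.raises(sd.PackingError) as err:
            sd.generate_muscle_phantom(spec)
        assert err.value.achieved < 30

    def test_invalid_fractions_rejected(self):
        frac = dict(sd.DEFAULT_CLASS_FRACTIONS)
        frac["graft"] += 0.1
        with pytest.raises(ValueError, match="sum to 1"):
            sd.MusclePhantomSpec(class_fractions=frac).validate()


class TestNervePhantom:
    def test_empty_spec_gives_blank_image(self):
        vol, table = sd.generate_nerve_phantom(sd.NervePhantomSpec(n_axons=0, seed=0))
        assert len(table) == 0
        assert not vol.data.any()

    def test_sample_mean_matches_lognormal_moments(self):
        """Single-component mixture: sample mean CSA within 3 SE of the
        analytic lognormal mean (SE = mean*cv/sqrt(n))."""
        spec = sd.NervePhantomSpec(
            n_axons=1000,
            calibre_means_um2=(8.0,),
            calibre_cvs=(0.5,),
            calibre_weights=(1.0,),
            seed=3,
        )
        rng = np.random.default_rng(np.random.SeedSequence(3).spawn(3)[0])
        csa = sd.sample_axon_calibres(spec, rng)
        se = 8.0 * 0.5 / np.sqrt(1000)
        assert abs(csa.mean() - 8.0) <= 3 * se

    def test_all_motor_means_identical_channels(self):
        spec = sd.NervePhantomSpec(
            n_axons=40, motor_fraction=1.0, psf_sigma_um=0, poisson_scale=0, gaussian_sd=0, seed=4
        )
        vol, table = sd.generate_nerve_phantom(spec)
        assert table.is_motor.all()
        np.testing.assert_array_equal(vol.channel("bIII"), vol.channel("chat"))

    def test_discs_do_not_overlap(self, clean_nerve_phantom):
        spec, vol, table = clean_nerve_phantom
        xy = table[["x_um", "y_um"]].to_numpy()
        r = np.sqrt(table.csa_um2.to_numpy() / np.pi)
        d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
        sep = r[:, None] + r[None, :]
        off_diag = ~np.eye(len(xy), dtype=bool)
        assert (d[off_diag] > sep[off_diag]).all()

    def test_packing_failure_reports_achievable(self):
        spec = sd.NervePhantomSpec(n_axons=2000, image_size_px=(64, 64), seed=0)
        with pytest.raises(sd.PackingError):
            sd.generate_nerve_phantom(spec)


class TestForceTrace:
    def test_single_unit_single_pulse_peak(self):
        """One supra-threshold pulse: peak equals the unit twitch force
        (kernel is peak-normalised), within the noise floor."""
        spec = sd.TracePhantomSpec(
            n_motor_units=1,
            unit_twitch_forces_g=(0.5,),
            recruitment_thresholds=(0.2,),
            noise_sd_g=0.0,
            seed=0,
        )
        trace = sd.generate_force_trace(spec, sd.ramp_program([1.0])[:1])
        assert trace.force_g.max() == pytest.approx(0.5, rel=1e-6)

    def test_subthreshold_pulse_recruits_nothing(self):
        spec = sd.TracePhantomSpec(
            n_motor_units=1,
            unit_twitch_forces_g=(0.5,),
            recruitment_thresholds=(0.8,),
            noise_sd_g=0.0,
            seed=0,
        )
        trace = sd.generate_force_trace(spec, sd.ramp_program([0.5])[:1])
        assert trace.force_g.max() == 0.0

    def test_ramp_gives_staircase_with_one_step_per_unit(self, trace_spec):
        """Six units, ramped intensity: exactly 6 distinct amplitude
        increments before noise."""
        spec = sd.TracePhantomSpec(seed=0, noise_sd_g=0.0)
        intensities = [0.05, 0.15, 0.3, 0.45, 0.6, 0.75, 0.9, 1.0]
        trace = sd.generate_force_trace(spec, sd.ramp_program(intensities))
        amps = []
        for ev in trace.stim_events:
            i0 = int(ev.t_start_s * spec.sampling_hz)
            i1 = i0 + int(0.3 * spec.sampling_hz)
            amps.append(trace.force_g[i0:i1].max())
        increments = sum(1 for a, b in zip(amps, amps[1:]) if b > a + 1e-9)
        assert increments == 6
        assert amps[0] == 0.0  # below first threshold

    def test_no_fatigue_means_constant_burst_peaks(self):
        spec = sd.TracePhantomSpec(seed=0, noise_sd_g=0.0, fatigue_tau_s=np.inf)
        trace = sd.generate_force_trace(spec, sd.fatigue_program(n_bursts=30, t_first_s=0.5))
        peaks = []
        for ev in trace.stim_events[1:]:  # first burst starts from rest
            i0 = int(ev.t_start_s * spec.sampling_hz)
            i1 = int((ev.t_end_s + 0.05) * spec.sampling_hz)
            peaks.append(trace.force_g[i0:i1].max())
        assert np.ptp(peaks) / np.mean(peaks) < 1e-6

    def test_trace_determinism(self, trace_spec):
        t1 = sd.generate_force_trace(trace_spec, sd.tetanus_program())
        t2 = sd.generate_force_trace(trace_spec, sd.tetanus_program())
        np.testing.assert_array_equal(t1.force_g, t2.force_g)

    def test_event_outside_duration_rejected(self, trace_spec):
        with pytest.raises(ValueError, match="duration"):
            sd.generate_force_trace(trace_spec, sd.tetanus_program(t_start_s=5.0), duration_s=2.0)

    def test_nonmonotone_thresholds_rejected(self):
        spec = sd.TracePhantomSpec(
            n_motor_units=2,
            unit_twitch_forces_g=(0.1, 0.2),
            recruitment_thresholds=(0.5, 0.3),
        )
        with pytest.raises(ValueError, match="strictly increasing"):
            spec.validate()
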