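"""Force-trace metrics: tetanic force, fold change, ONS/ENS efficiency,
MUNE increment counting and the fatigue index."""

import numpy as np
import pytest

from nmquant import physiology as ph
from nmquant import synthetic_data as sd
from nmquant.synthetic_data import ForceTrace, StimEvent


def flat_trace_with_plateau(level=7.5, baseline=1.0, hz=1000.0):
    """A constructed trace: baseline then a 7.5 g plateau during a 20 Hz event."""
    t = np.arange(0, 3.0, 1 / hz)
    f = np.full_like(t, baseline)
    f[(t >= 1.0) & (t < 2.0)] += level
    ev = StimEvent(1.0, 2.0, "ONS", 20.0, 1.0)
    return ForceTrace(t, f, hz, [ev])


class TestTetanicForce:
    def test_plateau_height_recovered_above_baseline(self):
        trace = flat_trace_with_plateau(level=7.5, baseline=1.0)
        assert ph.max_tetanic_force(trace) == pytest.approx(7.5, abs=1e-9)

    def test_offset_invariance(self):
        """Adding a constant to the whole trace leaves the result unchanged."""
        trace = flat_trace_with_plateau()
        shifted = ForceTrace(
            trace.time_s, trace.force_g + 3.3, trace.sampling_hz, trace.stim_events
        )
        assert ph.max_tetanic_force(shifted) == pytest.approx(ph.max_tetanic_force(trace))

    def test_no_tetanic_events_is_error(self):
        t = np.arange(0, 1.0, 0.001)
        trace = ForceTrace(t, np.zeros_like(t), 1000.0, [])
        with pytest.raises(ValueError, match="tetanic"):
            ph.max_tetanic_force(trace)

    def test_phantom_tetanus_recovered_within_noise(self, trace_spec):
        """Generator truth: fused plateau of the 6-unit pool at gain 3."""
        clean = sd.TracePhantomSpec(seed=0, noise_sd_g=0.0)
        ref = ph.max_tetanic_force(sd.generate_force_trace(clean, sd.tetanus_program()))
        noisy = sd.generate_force_trace(trace_spec, sd.tetanus_program())
        assert ph.max_tetanic_force(noisy) == pytest.approx(ref, abs=5 * trace_spec.noise_sd_g)


class TestRatios:
    def test_reference_fold_change_displays_9_4(self):
        fc = ph.fold_change(7.5, 0.8)
        assert fc == pytest.approx(9.375)
        assert round(fc, 1) == 9.4

    def test_identity_and_zero(self):
        assert ph.fold_change(4.2, 4.2) == 1.0
        assert ph.fold_change(0.0, 5.0) == 0.0

    def test_nonpositive_reference_is_error(self):
        with pytest.raises(ValueError):
            ph.fold_change(1.0, 0.0)

    def test_percent_of_ens(self):
        assert ph.percent_of_ens(22.7, 100.0) == pytest.approx(22.7)
        assert ph.percent_of_ens(0.0, 10.0) == 0.0
        with pytest.raises(ValueError):
            ph.percent_of_ens(1.0, 0.0)

    def test_trained_vs_untrained_efficiency_exceeds_13_fold(self):
        """Group means 22.7% vs 1.46% of ENS: an over-13-fold improvement."""
        assert ph.fold_change(22.7, 1.46) > 13


def ramp_trace(n_units=6, noise_frac=0.2, seed=0, k_units=None):
    """Staircase ramp crossing each unit threshold once; noise_frac scales
    the noise SD relative to the smallest unit step."""
    forces = (0.12, 0.18, 0.22, 0.28, 0.32, 0.38)[:n_units]
    thresholds = tuple(np.linspace(0.1, 0.85, n_units))
    spec = sd.TracePhantomSpec(
        n_motor_units=n_units,
        unit_twitch_forces_g=forces,
        recruitment_thresholds=thresholds,
        noise_sd_g=noise_frac * min(forces),
        seed=seed,
    )
    intensities = list(np.concatenate([[t + 0.02 for t in thresholds], [1.0]]))
    return sd.generate_force_trace(spec, sd.ramp_program(intensities, t_first_s=1.0))


class TestMune:
    def test_six_unit_staircase_counted_exactly(self):
        assert ph.mune_estimate(ramp_trace(noise_frac=0.2, seed=3)) == 6

    def test_flat_zero_response_gives_zero(self):
        t = np.arange(0, 5.0, 0.001)
        rng = np.random.default_rng(0)
        events = sd.ramp_program([0.1, 0.2, 0.3, 0.4, 0.5, 0.6], t_first_s=1.0)
        trace = ForceTrace(t, rng.normal(0, 0.01, t.size), 1000.0, events)
        assert ph.mune_estimate(trace) == 0

    def test_fewer_than_five_stimuli_rejected(self):
        t = np.arange(0, 3.0, 0.001)
        events = sd.ramp_program([0.2, 0.4, 0.6], t_first_s=1.0)
        trace = ForceTrace(t, np.zeros_like(t), 1000.0, events)
        with pytest.raises(ValueError, match=">= 5"):
            ph.mune_estimate(trace)

    def test_recovery_rate_at_step_noise_5(self):
        """At step/noise = 5 the estimator recovers 6 units in >= 95% of
        seeds (over 40 seeds here; the acceptance suite runs 100)."""
        hits = sum(ph.mune_estimate(ramp_trace(noise_frac=0.2, seed=s)) == 6 for s in range(40))
        assert hits >= 38

    def test_underestimates_monotonically_with_noise(self):
        """Median MUNE is monotone non-increasing as noise grows to the
        step size."""
        medians = []
        for frac in (0.2, 1.0, 3.0):
            vals = [ph.mune_estimate(ramp_trace(noise_frac=frac, seed=s)) for s in range(15)]
            medians.append(np.median(vals))
        assert medians[0] == 6
        assert medians[0] >= medians[1] >= medians[2]


def synthetic_burst_trace(peak_fn, n_bursts=180, hz=500.0):
    """Square bursts of analytically prescribed amplitude every second."""
    duration = n_bursts + 1.0
    t = np.arange(0, duration, 1 / hz)
    f = np.zeros_like(t)
    events = []
    for i in range(n_bursts):
        t0 = 0.5 + i
        f[(t >= t0) & (t < t0 + 0.25)] = peak_fn(i)
        events.append(StimEvent(t0, t0 + 0.25, "ONS", 20.0, 1.0))
    return ForceTrace(t, f, hz, events)


class TestFatigue:
    def test_constant_amplitude_gives_zero_index(self):
        trace = synthetic_burst_trace(lambda i: 5.0)
        assert ph.fatigue_index(trace) == 0.0

    def test_exponential_decay_to_quarter_gives_0_75(self):
        """Burst peaks decaying so the last-10 mean is 25% of the first-10
        mean give an index of exactly 0.75."""
        tau = 170.0 / np.log(4.0)
        trace = synthetic_burst_trace(lambda i: 5.0 * np.exp(-i / tau))
        assert ph.fatigue_index(trace) == pytest.approx(0.75, abs=1e-3)

    def test_generator_without_fatigue_has_negligible_index(self, trace_spec):
        trace = sd.generate_force_trace(trace_spec, sd.fatigue_program())
        noise_bound = 2 * trace_spec.noise_sd_g / ph.max_tetanic_force(trace)
        assert ph.fatigue_index(trace) <= max(noise_bound, 0.02)

    def test_index_monotone_in_fatigue_rate(self):
        """Faster fatigue (smaller tau) never lowers the index."""
        taus = [np.inf, 500.0, 120.0, 60.0]
        idx = []
        for tau in taus:
            spec = sd.TracePhantomSpec(seed=1, fatigue_tau_s=tau)
            trace = sd.generate_force_trace(spec, sd.fatigue_program())
            idx.append(ph.fatigue_index(trace))
        assert all(b >= a - 1e-6 for a, b in zip(idx, idx[1:]))

    def test_too_few_bursts_rejected(self):
        trace = synthetic_burst_trace(lambda i: 5.0, n_bursts=10)
        with pytest.raises(ValueError, match="bursts"):
            ph.fatigue_index(trace)

    def test_short_protocol_rejected(self):
        trace = synthetic_burst_trace(lambda i: 5.0, n_bursts=30)
        with pytest.raises(ValueError, match="spans"):
            ph.fatigue_index(trace)


class TestSummary:
    def test_summary_assembles_available_metrics(self, trace_spec):
        tet = sd.generate_force_trace(trace_spec, sd.tetanus_program())
        ramp = ramp_trace(seed=2)
        out = ph.summarize_physiology(
            tetanic_trace=tet, ramp_trace=ramp, reference_tetanic_g=0.8, ens_max_g=33.0
        )
        assert out.max_tetanic_force_g > 0
        assert out.fold_change == pytest.approx(out.max_tetanic_force_g / 0.8)
        assert out.percent_of_ens == pytest.approx(100 * out.max_tetanic_force_g / 33.0)
        assert out.mune == 6
        assert out.fatigue_index is None
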