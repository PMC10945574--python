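"""Isometric force-trace analytics: tetanic/twitch force, fold change,
optical-vs-electrical efficiency, motor unit number estimation and the
fatigue index.

Conventions shared by all metrics:

* Baseline is the median force over the 200 ms preceding a stimulus (or
  preceding the first stimulus, for protocol-level metrics), so every
  metric is invariant to a constant offset on the whole trace.
* A stimulus train at >= 20 Hz counts as tetanic (fused); anything slower,
  or a single pulse, is a twitch. 20 Hz is the stimulation frequency used
  for tetanic contractions in the optogenetic re-innervation setting this
  toolkit targets.
* Peaks are searched inside the stimulus window plus a 50 ms decay
  allowance for the twitch tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .synthetic_data import ForceTrace, StimEvent

#: default tetanic fusion threshold, Hz
FUSION_HZ = 20.0
#: baseline window before a stimulus, s
BASELINE_S = 0.2
#: post-stimulus decay allowance when searching for the peak, s
DECAY_S = 0.05


@dataclass
class PhysiologySummary:
    """Derived contractile metrics for one preparation."""

    max_tetanic_force_g: float | None = None
    max_twitch_force_g: float | None = None
    fold_change: float | None = None
    percent_of_ens: float | None = None
    mune: int | None = None
    fatigue_index: float | None = None


def _slice_for(trace: ForceTrace, t0: float, t1: float) -> slice:
    i0 = max(0, int(np.floor(t0 * trace.sampling_hz)))
    i1 = min(len(trace.force_g), int(np.ceil(t1 * trace.sampling_hz)) + 1)
    return slice(i0, i1)


def _baseline(trace: ForceTrace, t_stim: float) -> float:
    win = _slice_for(trace, t_stim - BASELINE_S, t_stim)
    seg = trace.force_g[win.start : max(win.start + 1, win.stop - 1)]
    if seg.size == 0:
        seg = trace.force_g[:1]
    return float(np.median(seg))


def _event_peak(trace: ForceTrace, ev: StimEvent, smooth_s: float = 0.0) -> float:
    """Baseline-subtracted peak force of one stimulus event."""
    force = trace.force_g
    if smooth_s > 0:
        force = uniform_filter1d(force, max(1, int(round(smooth_s * trace.sampling_hz))))
    win = _slice_for(trace, ev.t_start_s, ev.t_end_s + DECAY_S)
    return float(force[win].max()) - _baseline(trace, ev.t_start_s)


def max_tetanic_force(trace: ForceTrace, fusion_hz: float = FUSION_HZ) -> float:
    """Maximal baseline-subtracted force within tetanic stimulus windows (g).

    Raises ``ValueError`` when the trace has no tetanic (>= ``fusion_hz``)
    stimulation events.
    """
    tetanic = [ev for ev in trace.stim_events if ev.frequency_hz >= fusion_hz]
    if not tetanic:
        raise ValueError("trace has no tetanic stimulation events")
    return max(_event_peak(trace, ev) for ev in tetanic)


def max_twitch_force(trace: ForceTrace, fusion_hz: float = FUSION_HZ) -> float:
    """Maximal baseline-subtracted single-twitch force (g)."""
    twitches = [ev for ev in trace.stim_events if ev.frequency_hz < fusion_hz]
    if not twitches:
        raise ValueError("trace has no sub-tetanic stimulation events")
    return max(_event_peak(trace, ev) for ev in twitches)


def fold_change(test_g: float, reference_g: float) -> float:
    """Force ratio test/reference; full precision (display rounds to 1 dp)."""
    if reference_g <= 0:
        raise ValueError("reference force must be > 0")
    return float(test_g) / float(reference_g)


def percent_of_ens(ons_max_g: float, ens_max_g: float) -> float:
    """Optically elicited force as a percentage of the electrical maximum.

    ENS (supra-maximal electrical nerve stimulation) recruits every motor
    axon and so measures total residual muscle capacity; ONS recruits only
    the optogenetically excitable subset.
    """
    if ens_max_g <= 0:
        raise ValueError("ENS reference force must be > 0")
    return 100.0 * float(ons_max_g) / float(ens_max_g)


def _noise_sd(trace: ForceTrace) -> float:
    """Noise SD from the pre-stimulus baseline segment."""
    t_first = min(ev.t_start_s for ev in trace.stim_events)
    seg = trace.force_g[_slice_for(trace, 0.0, max(0.0, t_first - 0.05))]
    if seg.size < 10:
        raise ValueError("insufficient pre-stimulus baseline to estimate noise")
    return float(seg.std(ddof=1))


def mune_estimate(
    trace: ForceTrace,
    k: float = 3.0,
    fusion_hz: float = FUSION_HZ,
    smooth_s: float = 0.005,
) -> int:
    """Motor unit number estimate by twitch-increment counting.

    Twitch responses to a ramp of stimulus intensities are sorted by
    intensity; an increment is counted whenever the response amplitude
    rises more than ``k`` x noise SD above the previous plateau, each
    increment corresponding to one newly recruited motor unit. The noise SD
    comes from the pre-stimulus baseline; responses are lightly smoothed
    (``smooth_s``) before peak extraction so single-sample noise does not
    masquerade as recruitment.

    Underestimates when the noise approaches the single-unit step size
    (monotone non-increasing in noise); requires >= 5 twitch stimuli.
    """
    twitches = sorted(
        (ev for ev in trace.stim_events if ev.frequency_hz < fusion_hz),
        key=lambda ev: ev.intensity,
    )
    if len(twitches) < 5:
        raise ValueError(f"MUNE needs >= 5 twitch stimuli, got {len(twitches)}")
    noise = _noise_sd(trace)
    amplitudes = [_event_peak(trace, ev, smooth_s=smooth_s) for ev in twitches]
    count = 0
    plateau = 0.0
    for amp in amplitudes:
        if amp > plateau + k * noise:
            count += 1
            plateau = amp
    return count


def fatigue_index(
    trace: ForceTrace,
    n_reference: int = 10,
    min_bursts: int = 20,
    min_span_s: float = 170.0,
) -> float:
    """Fractional decline of burst peak force over a repeated-burst protocol.

    ``1 - mean(peak of final n) / mean(peak of first n)`` clipped to
    [0, 1]: 0 means no fatigue, 1 complete loss of force. The protocol must
    contain >= ``min_bursts`` bursts spanning >= ``min_span_s`` seconds
    (the reference protocol is 250 ms 20 Hz bursts every 1 s for 180 s).
    """
    bursts = sorted(trace.stim_events, key=lambda ev: ev.t_start_s)
    if len(bursts) < min_bursts:
        raise ValueError(f"fatigue protocol needs >= {min_bursts} bursts, got {len(bursts)}")
    span = bursts[-1].t_end_s - bursts[0].t_start_s
    if span < min_span_s:
        raise ValueError(f"fatigue protocol spans {span:.1f} s < required {min_span_s} s")
    base = _baseline(trace, bursts[0].t_start_s)
    force = trace.force_g
    peaks = []
    for ev in bursts:
        win = _slice_for(trace, ev.t_start_s, ev.t_end_s + DECAY_S)
        peaks.append(float(force[win].max()) - base)
    first = float(np.mean(peaks[:n_reference]))
    last = float(np.mean(peaks[-n_reference:]))
    if first <= 0:
        raise ValueError("no contractile response in the first bursts")
    return float(np.clip(1.0 - last / first, 0.0, 1.0))


def summarize_physiology(
    tetanic_trace: ForceTrace | None = None,
    ramp_trace: ForceTrace | None = None,
    fatigue_trace: ForceTrace | None = None,
    reference_tetanic_g: float | None = None,
    ens_max_g: float | None = None,
) -> PhysiologySummary:
    """Assemble a :class:`PhysiologySummary` from whichever traces exist."""
    out = PhysiologySummary()
    if tetanic_trace is not None:
        out.max_tetanic_force_g = max_tetanic_force(tetanic_trace)
        if reference_tetanic_g is not None:
            out.fold_change = fold_change(out.max_tetanic_force_g, reference_tetanic_g)
        if ens_max_g is not None:
            out.percent_of_ens = percent_of_ens(out.max_tetanic_force_g, ens_max_g)
    if ramp_trace is not None:
        out.max_twitch_force_g = max_twitch_force(ramp_trace)
        out.mune = mune_estimate(ramp_trace)
    if fatigue_trace is not None:
        out.fatigue_index = fatigue_index(fatigue_trace)
    return out
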