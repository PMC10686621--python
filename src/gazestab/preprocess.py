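"""Slow-phase extraction: differentiation, quick-phase removal, cycle sweeps.

Nystagmus alternates compensatory slow phases with fast resetting quick
phases.  Reflex fits must only see the slow phases, so the pipeline is:

1. differentiate eye position (optionally low-pass filtered, zero phase);
2. flag quick phases with an absolute velocity threshold, dilated by a
   safety margin;
3. rebuild a cumulative slow-phase position ``EHp`` by integrating the
   valid velocity only — quick-phase displacements vanish and the trace is
   continuous across the gaps;
4. cut the trace into per-cycle sweeps anchored at the rising
   zero-crossings of the reference velocity and resampled to a fixed
   number of phase bins.

Invalid samples stay missing throughout: sweep bins inside a saccade gap
are never interpolated, and downstream statistics use pairwise-complete
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from gazestab.trace import RawTrace

DEFAULT_MARGIN_S = 0.02
DEFAULT_LOWPASS_HZ = 30.0
THRESHOLD_FLOOR = 50.0       # deg/s
THRESHOLD_PEAK_FACTOR = 2.5  # × stimulus peak velocity
MIN_VALID_FRACTION = 0.5


class TrialRejected(ValueError):
    """Trial unusable for slow-phase analysis (too few valid samples/cycles)."""


@dataclass
class SegmentMask:
    """Per-sample validity plus the merged excluded intervals (seconds)."""

    valid: np.ndarray
    intervals: list = field(default_factory=list)
    margin_s: float = DEFAULT_MARGIN_S

    def __post_init__(self):
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_excluded(self) -> int:
        return int((~self.valid).sum())


@dataclass
class SlowPhaseSeries:
    """Desaccaded eye velocity/position with the stimulus reference.

    ``EHv`` is NaN on invalid samples.  ``EHp`` is the cumulative
    slow-phase position (quick-phase displacements removed, mean over valid
    samples fixed to 0); it is defined everywhere — held constant across
    gaps — but only ``valid`` samples should enter statistics.
    """

    t: np.ndarray
    EHv: np.ndarray
    EHp: np.ndarray
    ref_vel: np.ndarray
    valid: np.ndarray
    modality: str
    frequency_Hz: float
    peak_vel: float

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass
class Sweep:
    """One cycle's phase-aligned slow-phase position trajectory."""

    cycle_index: int
    pos: np.ndarray    # K phase bins, NaN where invalid
    valid: np.ndarray  # K booleans

    @property
    def K(self) -> int:
        return self.pos.size


def _check_uniform(t: np.ndarray) -> float:
    dt = np.diff(t)
    step = np.median(dt)
    if np.max(np.abs(dt - step)) > 1e-3 * step:
        raise ValueError("non-uniform time grid: resample the trace first")
    return float(step)


def differentiate_position(
    trace: RawTrace | np.ndarray,
    fs: float | None = None,
    lowpass_hz: float | None = DEFAULT_LOWPASS_HZ,
    channel: str = "eye_h",
) -> np.ndarray:
    """Differentiate eye position into velocity (deg/s).

    Central differences in the interior, one-sided at the edges.  A
    zero-phase Butterworth low-pass (default 30 Hz cutoff) is applied to
    the position before differencing; pass ``lowpass_hz=None`` to disable.
    """
    if isinstance(trace, RawTrace):
        pos = getattr(trace, channel)
        dt = _check_uniform(trace.t)
    else:
        pos = np.asarray(trace, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a bare array")
        dt = 1.0 / fs
    if pos.size < 3:
        raise ValueError("need at least 3 samples to differentiate")

    if lowpass_hz is not None and lowpass_hz < 0.5 / dt:
        sos = sps.butter(4, lowpass_hz, fs=1.0 / dt, output="sos")
        pos = sps.sosfiltfilt(sos, pos)

    vel = np.empty_like(pos)
    vel[1:-1] = (pos[2:] - pos[:-2]) / (2.0 * dt)
    vel[0] = (pos[1] - pos[0]) / dt
    vel[-1] = (pos[-1] - pos[-2]) / dt
    return vel


def default_threshold(peak_vel: float) -> float:
    """Quick-phase velocity threshold: 2.5× stimulus peak, floored at 50 deg/s."""
    return max(THRESHOLD_FLOOR, THRESHOLD_PEAK_FACTOR * float(peak_vel))


def detect_quick_phases(
    velocity: np.ndarray,
    fs: float,
    threshold: float | None = None,
    margin_s: float = DEFAULT_MARGIN_S,
    peak_vel: float = 0.0,
) -> SegmentMask:
    """Flag quick-phase (saccadic) samples by absolute velocity threshold.

    Samples with ``|v| > threshold`` are invalid, dilated by ``±margin_s``
    to absorb filter smear; overlapping exclusions are merged into
    intervals.
    """
    if threshold is None:
        threshold = default_threshold(peak_vel)
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    velocity = np.asarray(velocity, dtype=float)
    hot = np.abs(velocity) > threshold
    if hot.any():
        pad = max(0, int(np.ceil(margin_s * fs)))
        kernel = np.ones(2 * pad + 1, dtype=bool)
        hot = np.convolve(hot, kernel, mode="same") > 0
    valid = ~hot
    intervals = _runs_to_intervals(hot, fs)
    return SegmentMask(valid=valid, intervals=intervals, margin_s=margin_s)


def _runs_to_intervals(flag: np.ndarray, fs: float) -> list:
    starts, stops = [], []
    in_run = False
    for i, f in enumerate(flag):
        if f and not in_run:
            starts.append(i)
            in_run = True
        elif not f and in_run:
            stops.append(i)
            in_run = False
    if in_run:
        stops.append(flag.size)
    return [(s / fs, e / fs) for s, e in zip(starts, stops)]


def extract_slow_phases(
    trace: RawTrace,
    mask: SegmentMask | None = None,
    lowpass_hz: float | None = DEFAULT_LOWPASS_HZ,
    threshold: float | None = None,
    margin_s: float = DEFAULT_MARGIN_S,
) -> SlowPhaseSeries:
    """Build the desaccaded slow-phase series for one trial.

    If no mask is given, quick phases are detected here with the default
    threshold for the trial's stimulus peak velocity.  The cumulative
    slow-phase position sums valid velocity only, so each quick-phase
    displacement is removed and the trajectory is continuous across gaps;
    its gauge is fixed to mean 0 over valid samples.

    Raises
    ------
    TrialRejected
        If fewer than 50% of samples survive the mask.
    """
    # detection and position reconstruction use the raw derivative so a
    # quick-phase step stays localized in two samples instead of being
    # smeared by the zero-phase filter; the filter only serves the fitted
    # velocity series
    vel_raw = differentiate_position(trace, lowpass_hz=None)
    vel = (differentiate_position(trace, lowpass_hz=lowpass_hz)
           if lowpass_hz is not None else vel_raw)
    fs = 1.0 / _check_uniform(trace.t)
    if mask is None:
        mask = detect_quick_phases(
            vel_raw, fs, threshold=threshold, margin_s=margin_s,
            peak_vel=trace.peak_vel,
        )
    if mask.valid.shape != trace.t.shape:
        raise ValueError("mask not aligned to trace")
    valid = mask.valid
    frac = valid.mean()
    if frac < MIN_VALID_FRACTION:
        raise TrialRejected(
            f"only {frac:.0%} of samples valid (< {MIN_VALID_FRACTION:.0%}) "
            f"for trial {trace.meta.get('animal_id', '?')}"
        )

    EHv = np.where(valid, vel, np.nan)
    # trapezoidal cumulative slow-phase position; segments touching an
    # invalid sample contribute nothing, removing quick-phase displacements
    v0 = np.where(valid, vel_raw, 0.0)
    seg_ok = valid[1:] & valid[:-1]
    step = np.where(seg_ok, (v0[1:] + v0[:-1]) / 2.0, 0.0) / fs
    EHp = np.concatenate([[0.0], np.cumsum(step)])
    EHp -= EHp[valid].mean()
    return SlowPhaseSeries(
        t=trace.t, EHv=EHv, EHp=EHp,
        ref_vel=trace.reference_velocity(),
        valid=valid,
        modality=trace.modality,
        frequency_Hz=trace.frequency_Hz,
        peak_vel=trace.peak_vel,
    )


def _reference_phase(t, ref, freq):
    """Phase offset psi (rad) of the reference, ref(t) ~ sin(2*pi*f*t + psi)."""
    w = 2.0 * np.pi * freq
    a = 2.0 * np.mean(ref * np.sin(w * t))
    b = 2.0 * np.mean(ref * np.cos(w * t))
    return float(np.arctan2(b, a))


def segment_cycles(
    series: SlowPhaseSeries,
    frequency_Hz: float | None = None,
    K: int = 128,
    min_cycles: int = 2,
) -> list[Sweep]:
    """Cut the slow-phase position into per-cycle sweeps of K phase bins.

    Cycle boundaries sit at the rising zero-crossings of the reference
    velocity (phase 0 of the analysis).  Each sweep is linearly resampled
    to ``K`` bins; a bin is valid only if the samples it interpolates from
    are valid; each sweep is centred to zero mean over its valid bins.
    """
    freq = frequency_Hz if frequency_Hz is not None else series.frequency_Hz
    if freq <= 0:
        raise ValueError("positive stimulation frequency required")
    t = series.t
    period = 1.0 / freq
    dt = float(np.median(np.diff(t)))

    # analytic boundary times from the reference's projected phase:
    # sin(w t + psi) has rising zero-crossings at t = (2 pi k - psi) / w
    psi = _reference_phase(t, series.ref_vel, freq)
    k0 = int(np.ceil((t[0] - dt / 2 + psi / (2 * np.pi) * period) / period))
    boundaries = []
    k = k0
    while True:
        tb = k * period - psi / (2 * np.pi) * period
        if tb > t[-1] + dt:
            break
        boundaries.append(tb)
        k += 1

    valid_f = series.valid.astype(float)
    # extend by one sample at each end (linear continuation) so a final
    # boundary landing within one sample of the trace end interpolates
    # instead of clamping flat
    t_ext = np.concatenate([[t[0] - dt], t, [t[-1] + dt]])
    p = series.EHp
    p_ext = np.concatenate([[2 * p[0] - p[1]], p, [2 * p[-1] - p[-2]]])
    v_ext = np.concatenate([[valid_f[0]], valid_f, [valid_f[-1]]])
    sweeps: list[Sweep] = []
    for ci, (t0, t1) in enumerate(zip(boundaries[:-1], boundaries[1:])):
        tb = t0 + (np.arange(K) + 0.5) / K * (t1 - t0)
        pos = np.interp(tb, t_ext, p_ext)
        ok = np.interp(tb, t_ext, v_ext) > 0.999
        if ok.sum() < 2:
            continue
        pos = pos - pos[ok].mean()
        pos[~ok] = np.nan
        sweeps.append(Sweep(cycle_index=ci, pos=pos, valid=ok))
    if len(sweeps) < min_cycles:
        raise TrialRejected(
            f"only {len(sweeps)} usable cycles (need >= {min_cycles})")
    return sweeps
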