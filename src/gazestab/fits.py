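"""Reflex parameter estimation.

Sinusoidal reflexes (aVOR, OKR, CGR) are fit with the velocity model

    EHv(t) = g · r(t − td) + Cte

where ``r`` is the signed compensatory reference (−head velocity for
vestibular rotations, +drum velocity for OKR), ``g`` the dimensionless
gain, ``td`` the dynamic lag (ms) and ``Cte`` a velocity offset.  Because
``r`` is a sinusoid of known frequency, the least-squares problem is
solved in closed form by quadrature regression (sin/cos basis plus a
constant); ``td`` and the phase follow from the angle between the eye and
reference phasors.  Phase is reported lead-positive in (−180, 180] with
``phase_deg = −360·f·td/1000``.

Fit quality is the variance-accounted-for,

    VAF = 1 − var(est − EHv) / var(EHv),

computed on valid (desaccaded) samples; 1 is a perfect fit.  Gains below
0.10 with VAF below 0.5 are QC-flagged: the gain remains usable but the
phase is meaningless and is excluded downstream.

The static ocular counter-roll (OCR) gain is the OLS slope of the vertical
eye angle against the head tilt plateaus, and the off-vertical-axis
rotation (OVAR) response is fit as a bias-plus-modulation sinusoid at the
table rotation frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from gazestab.preprocess import (
    SlowPhaseSeries,
    default_threshold,
    differentiate_position,
)
from gazestab.trace import RawTrace

QC_GAIN_MAX = 0.10
QC_VAF_MAX = 0.5
MIN_CYCLES = 10


class FitError(ValueError):
    """Insufficient or degenerate data for a reflex fit."""


@dataclass
class SinusoidFit:
    g: float
    td_ms: float
    Cte: float
    phase_deg: float
    VAF: float
    n_cycles: int
    qc_flag: bool = False
    modality: str = "VOR_DARK"
    frequency_Hz: float = 1.0


@dataclass
class OCRFit:
    slope: float
    intercept: float
    r2: float
    n_plateaus: int


@dataclass
class OVARFit:
    beta: float        # bias, sign-normalized: compensatory positive
    beta_raw: float    # bias as fitted (signed slow-phase velocity)
    mu: float          # modulation amplitude, >= 0
    phase0_deg: float
    f0_Hz: float
    direction: str
    VAF: float


def wrap_phase(deg: float) -> float:
    """Map a phase to (−180, 180]."""
    out = (float(deg) + 180.0) % 360.0 - 180.0
    return 180.0 if out == -180.0 else out


def _quadrature(t, y, freq):
    """Project y on [sin, cos, 1] at freq; returns (amplitude, phase_rad, offset)."""
    w = 2.0 * np.pi * freq
    X = np.column_stack([np.sin(w * t), np.cos(w * t), np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, b, c = coef
    return float(np.hypot(a, b)), float(np.arctan2(b, a)), float(c)


def fit_sinusoid(
    series: SlowPhaseSeries,
    frequency_Hz: float | None = None,
    peak_vel: float | None = None,
    min_cycles: int = MIN_CYCLES,
) -> SinusoidFit:
    """Closed-form least-squares sinusoid fit of the slow-phase velocity.

    Both the eye velocity and the reference are projected on the sin/cos
    basis at the stimulation frequency; the gain is the amplitude ratio
    and the phase the lead of the eye phasor over the reference phasor.
    The returned gain is non-negative by construction — an
    anti-compensatory response shows up as a phase near ±180°.
    """
    freq = frequency_Hz if frequency_Hz is not None else series.frequency_Hz
    if freq <= 0:
        raise FitError("positive stimulation frequency required")
    valid = series.valid & np.isfinite(series.EHv)
    n_cycles = int(np.floor(valid.sum() / series.fs * freq))
    if n_cycles < min_cycles:
        raise FitError(
            f"{n_cycles} whole cycles of valid data (need >= {min_cycles})")
    t, y = series.t[valid], series.EHv[valid]
    if np.var(y) == 0:
        raise FitError("zero-variance eye velocity")

    amp_e, psi_e, c_e = _quadrature(t, y, freq)
    amp_r, psi_r, _ = _quadrature(series.t, series.ref_vel, freq)
    if amp_r == 0:
        raise FitError("reference velocity has no component at the fit frequency")

    g = amp_e / amp_r
    phase = wrap_phase(np.rad2deg(psi_e - psi_r))
    td_ms = -phase / (360.0 * freq) * 1000.0

    w = 2.0 * np.pi * freq
    est = amp_e * np.sin(w * t + psi_e) + c_e
    vaf = 1.0 - np.var(est - y) / np.var(y)
    return SinusoidFit(
        g=g, td_ms=td_ms, Cte=c_e, phase_deg=phase, VAF=float(vaf),
        n_cycles=n_cycles, modality=series.modality, frequency_Hz=freq,
    )


def qc_flag(fit: SinusoidFit) -> SinusoidFit:
    """Apply the low-gain/low-VAF quality rule.

    A fit with gain < 0.10 *and* VAF < 0.5 keeps its gain for gain-based
    statistics, but its phase is unusable and must not enter phase-based
    analyses or the combined-response model.
    """
    return replace(fit, qc_flag=bool(fit.g < QC_GAIN_MAX and fit.VAF < QC_VAF_MAX))


def fit_ocr(
    trace: RawTrace,
    tilt_schedule=None,
    plateau_fraction: float = 0.5,
    threshold: float | None = None,
) -> OCRFit:
    """OCR gain: OLS slope of vertical eye angle vs head tilt plateaus.

    Each plateau's eye value is the mean of the last ``plateau_fraction``
    of the hold, after dropping samples flagged by the velocity-threshold
    detector on the vertical channel.
    """
    schedule = tilt_schedule or trace.meta.get("tilt_schedule")
    if not schedule:
        raise FitError("tilt schedule unresolved")
    if len({round(float(a), 6) for *_ss, a in schedule}) < 3:
        raise FitError("need >= 3 distinct tilt plateaus")

    fs = 1.0 / float(np.median(np.diff(trace.t)))
    vel_v = differentiate_position(trace, channel="eye_v")
    thr = threshold if threshold is not None else default_threshold(0.0)
    ok = np.abs(vel_v) <= thr

    tilts, eyes = [], []
    for start_s, end_s, angle in schedule:
        if end_s - start_s < 10.0 - 1.0 / fs:
            raise FitError("plateau shorter than 10 s")
        lo = start_s + (1.0 - plateau_fraction) * (end_s - start_s)
        sel = (trace.t >= lo) & (trace.t < end_s) & ok
        if not sel.any():
            continue
        tilts.append(float(angle))
        eyes.append(float(trace.eye_v[sel].mean()))
    if len(tilts) < 3:
        raise FitError("fewer than 3 usable plateaus")
    res = stats.linregress(tilts, eyes)
    return OCRFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r2=float(res.rvalue ** 2), n_plateaus=len(tilts),
    )


def fit_ovar(
    series: SlowPhaseSeries,
    rotation_speed: float,
    direction: str,
) -> OVARFit:
    """Fit SP(t) = β + μ·sin(2π f0 t + φ0) at f0 = rotation speed / 360.

    ``beta_raw`` is the fitted bias of the slow-phase velocity; ``beta``
    is sign-normalized so a compensatory nystagmus (slow phases opposing
    the table rotation) is positive for either direction.
    """
    if rotation_speed <= 0:
        raise FitError("rotation speed must be > 0")
    if direction not in ("CW", "CCW"):
        raise FitError("direction must be CW or CCW")
    f0 = rotation_speed / 360.0
    valid = series.valid & np.isfinite(series.EHv)
    if valid.sum() / series.fs * f0 < 5:
        raise FitError("need >= 5 table rotations of valid slow-phase data")
    t, y = series.t[valid], series.EHv[valid]

    mu, phase0, beta_raw = _quadrature(t, y, f0)
    w = 2.0 * np.pi * f0
    est = mu * np.sin(w * t + phase0) + beta_raw
    vaf = 1.0 - np.var(est - y) / np.var(y) if np.var(y) > 0 else 1.0
    dir_sign = 1.0 if direction == "CCW" else -1.0
    return OVARFit(
        beta=-dir_sign * beta_raw, beta_raw=float(beta_raw),
        mu=float(mu), phase0_deg=wrap_phase(np.rad2deg(phase0)),
        f0_Hz=f0, direction=direction, VAF=float(vaf),
    )
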