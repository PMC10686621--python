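"""Synthetic oculography cohort generator.

Emulates a longitudinal ototoxic-lesion study in mice: two groups (SHAM and
IDPN-treated) are tested every two weeks from week 0 to week 12 with
sinusoidal vestibular rotations in the dark (aVOR), optokinetic drum
stimulation (OKR), combined rotation in light (CGR), static lateral tilts
(OCR) and off-vertical-axis rotation (OVAR).  The treated group's vestibular
gains dip to a trough at week 6 (about two thirds of the angular VOR lost)
and partially recover by week 12, while OKR gains at frequencies above
0.2 Hz rise after the lesion — the visual-substitution signature.

Each animal carries a full generative ground truth: per-condition gains and
phases, cycle-to-cycle gain jitter (which controls downstream sweep
reproducibility), additive velocity noise, and a Poisson quick-phase
process that resets eye position toward a centering set-point.  Trials are
rendered as dual-rate recordings (eye near 120 Hz, stimulus near 1 kHz,
stimulus interpolated onto the eye timebase) with the ground-truth
quick-phase mask stored alongside so detectors can be validated without
hand labels.

Integration subtypes
--------------------
Treated animals are split into three phenotypes:

``DELTA_PLUS``
    reliable (low-jitter) VOR; combined responses equal the optimally
    shifted sum of the unimodal reflexes.
``DELTA_PLUS_LOWVOR``
    reliable but extra-attenuated VOR; combination still near-optimal.
``DELTA_MINUS``
    unreliable VOR: large cycle-to-cycle gain jitter, VOR amplitude matched
    to the low-VOR subtype (the base gain is deflated by
    ``1/sqrt(1 + jitter^2)`` so the expected raw sweep amplitude is equal),
    and combined gain well below the model prediction — these animals do
    worse with vestibular input than with vision alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from gazestab.trace import RawTrace, align_to_eye_timebase

GROUPS = ("SHAM", "IDPN")
SUBTYPES = ("DELTA_PLUS", "DELTA_PLUS_LOWVOR", "DELTA_MINUS", "NA")

WEEKS = (0, 2, 4, 6, 8, 10, 12)
VOR_FREQS = (0.2, 0.5, 0.8, 1.0, 2.0)
OKR_FREQS = (0.1, 0.2, 0.33, 0.5, 1.0)
CGR_FREQS = (0.2, 0.5, 1.0)
VOR_PEAK_VEL = 30.0   # deg/s, vestibular sinusoidal rotations
OKR_PEAK_VEL = 10.0   # deg/s, optokinetic drum
OVAR_SPEED = 50.0     # deg/s constant off-vertical-axis rotation


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass
class CohortConfig:
    """Parameters of the synthetic study.

    Gain schedules are built as ``baseline × weekly multiplier``; baselines
    are drawn per animal around the configured means with fractional spread
    ``gain_spread``.  Weekly multipliers encode the lesion trajectory
    (trough at week 6, partial recovery by week 12) and the frequency-
    specific OKR increase after week 6.
    """

    n_sham: int = 4
    n_idpn: int = 6
    weeks: tuple = WEEKS
    vor_freqs: tuple = VOR_FREQS
    okr_freqs: tuple = OKR_FREQS
    cgr_freqs: tuple = CGR_FREQS

    # Baseline (week 0) population means.  aVOR gain grows with frequency,
    # OKR gain falls with frequency, so the vestibular weight
    # g_vor/(g_vor+g_okr) crosses 50% between 0.2 and 0.5 Hz.
    vor_baseline: dict = field(default_factory=lambda: {
        0.2: 0.35, 0.5: 0.55, 0.8: 0.68, 1.0: 0.75, 2.0: 0.85})
    okr_baseline: dict = field(default_factory=lambda: {
        0.1: 0.75, 0.2: 0.65, 0.33: 0.50, 0.5: 0.40, 1.0: 0.25})
    ocr_baseline: float = 0.55        # vertical-eye vs tilt slope, SHAM 0.5-0.6
    ovar_bias_baseline: float = 6.0   # deg/s maculo-ocular reflex bias
    ovar_modulation: float = 2.5      # deg/s velocity modulation
    gain_spread: float = 0.08         # between-animal fractional SD

    # IDPN weekly multipliers: trough at W6 (aVOR keeps ~1/3 of its gain,
    # i.e. ~2/3 lost), recovery by W12 back to the W4 level.
    vor_lesion_mult: dict = field(default_factory=lambda: {
        0: 1.0, 2: 0.95, 4: 0.55, 6: 1.0 / 3.0, 8: 0.45, 10: 0.5, 12: 0.55})
    ocr_lesion_mult: dict = field(default_factory=lambda: {
        0: 1.0, 2: 0.95, 4: 0.75, 6: 0.60, 8: 0.75, 10: 0.9, 12: 1.0})
    ovar_lesion_mult: dict = field(default_factory=lambda: {
        0: 1.0, 2: 0.8, 4: 0.6, 6: 0.45, 8: 0.7, 10: 0.9, 12: 1.0})
    # OKR multiplier applied only at frequencies > okr_boost_min_freq.
    okr_boost_mult: dict = field(default_factory=lambda: {
        0: 1.0, 2: 1.0, 4: 1.0, 6: 1.15, 8: 1.30, 10: 1.25, 12: 1.20})
    okr_boost_min_freq: float = 0.2

    # Phases (deg, lead positive).  The lesioned aVOR develops a phase lead
    # proportional to the gain loss; OKR keeps a fixed small processing lag.
    vor_lead_at_trough_deg: float = 15.0
    okr_lag_ms: float = 20.0

    # Integration subtypes among treated animals.  Proportions follow the
    # observed 12/7 split of well- vs mal-integrating phenotypes, with a
    # low-VOR minority inside the well-integrating cluster.
    subtype_proportions: dict = field(default_factory=lambda: {
        "DELTA_PLUS": 0.47, "DELTA_PLUS_LOWVOR": 0.16, "DELTA_MINUS": 0.37})
    lowvor_extra_atten: float = 0.5     # extra VOR attenuation of the low-VOR subtypes
    base_cycle_jitter_sd: float = 0.05  # fractional per-cycle gain SD, reliable VOR
    delta_minus_jitter_sd: float = 0.5  # unreliable VOR
    delta_minus_cgr_atten: float = 0.4  # observed CGR / model-predicted CGR

    # True combined-response time shifts used to build CGR ground truth.
    cgr_delta_vor_ms: float = 10.0
    cgr_delta_okr_ms: float = -5.0

    # Trial rendering.
    noise_sd: float = 3.0          # deg/s additive velocity noise
    qp_rate_hz: float = 1.2        # Poisson quick-phase rate
    qp_amp_mean: float = 8.0       # deg
    qp_amp_sd: float = 2.0
    qp_refractory_s: float = 0.1
    eye_rate_Hz: float = 120.0
    stim_rate_Hz: float = 1000.0

    def validate(self) -> None:
        if self.n_sham < 1 or self.n_idpn < 1:
            raise ConfigError("group sizes must be >= 1")
        props = self.subtype_proportions
        if any(p < 0 or p > 1 for p in props.values()):
            raise ConfigError("subtype proportions must lie in [0, 1]")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ConfigError("subtype proportions must sum to 1")
        if self.gain_spread < 0 or self.noise_sd < 0:
            raise ConfigError("spreads and noise SDs must be >= 0")
        if self.base_cycle_jitter_sd < 0 or self.delta_minus_jitter_sd < 0:
            raise ConfigError("jitter SDs must be >= 0")


@dataclass
class AnimalSpec:
    """Generative ground truth for one animal.

    ``gain_schedule`` / ``phase_schedule`` map ``(week, modality,
    frequency_Hz)`` to the true gain (dimensionless) and phase (deg, lead
    positive).  OCR entries use frequency 0 and store the tilt slope; OVAR
    entries use frequency 0 and store the bias magnitude (deg/s).
    """

    animal_id: str
    group: str
    subtype: str = "NA"
    gain_schedule: dict = field(default_factory=dict)
    phase_schedule: dict = field(default_factory=dict)
    cycle_jitter_sd: dict = field(default_factory=dict)
    noise_sd: float = 3.0
    ovar_modulation: float = 2.5
    qp_rate_hz: float = 1.2
    qp_amp_mean: float = 8.0
    qp_amp_sd: float = 2.0
    qp_refractory_s: float = 0.1
    eye_rate_Hz: float = 120.0
    stim_rate_Hz: float = 1000.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigError(f"unknown group {self.group!r}")
        if self.subtype not in SUBTYPES:
            raise ConfigError(f"unknown subtype {self.subtype!r}")
        bad = [k for k, g in self.gain_schedule.items() if g < 0]
        if bad:
            raise ConfigError(f"negative gains at {bad[:3]}")

    def gain(self, week: int, modality: str, frequency_Hz: float = 0.0) -> float:
        return self.gain_schedule[(week, modality, round(float(frequency_Hz), 6))]

    def phase(self, week: int, modality: str, frequency_Hz: float = 0.0) -> float:
        return self.phase_schedule.get(
            (week, modality, round(float(frequency_Hz), 6)), 0.0)

    def jitter(self, modality: str) -> float:
        return self.cycle_jitter_sd.get(modality, 0.0)

    @classmethod
    def constant(
        cls,
        gain: float,
        phase_deg: float = 0.0,
        modality: str = "VOR_DARK",
        frequencies=VOR_FREQS,
        weeks=WEEKS,
        jitter_sd: float = 0.0,
        noise_sd: float = 0.0,
        qp_rate_hz: float = 0.0,
        animal_id: str = "test",
        group: str = "SHAM",
        **kw,
    ) -> "AnimalSpec":
        """Single-modality spec with one gain/phase at every week — the
        minimal ground truth needed to render standalone test trials."""
        gains = {(w, modality, round(float(f), 6)): gain
                 for w in weeks for f in frequencies}
        phases = {(w, modality, round(float(f), 6)): phase_deg
                  for w in weeks for f in frequencies}
        return cls(
            animal_id=animal_id, group=group,
            gain_schedule=gains, phase_schedule=phases,
            cycle_jitter_sd={modality: jitter_sd},
            noise_sd=noise_sd, qp_rate_hz=qp_rate_hz, **kw,
        )


def _key(week, modality, freq):
    return (int(week), modality, round(float(freq), 6))


def _allocate_subtypes(n: int, proportions: dict) -> list[str]:
    """Largest-remainder allocation so small cohorts hit the proportions."""
    names = ["DELTA_PLUS", "DELTA_PLUS_LOWVOR", "DELTA_MINUS"]
    quotas = [proportions.get(k, 0.0) * n for k in names]
    counts = [int(math.floor(q)) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    for i in sorted(range(len(names)), key=lambda i: -remainders[i]):
        if sum(counts) >= n:
            break
        counts[i] += 1
    while sum(counts) < n:  # degenerate proportions
        counts[0] += 1
    out: list[str] = []
    for name, c in zip(names, counts):
        out.extend([name] * c)
    return out[:n]


def _phasor_sum_truth(g_v, ph_v, g_o, ph_o, dv_ms, do_ms, freq):
    """Closed-form gain/phase of the shifted two-sinusoid sum (ground truth
    used to build CGR schedules; the analysis-side model lives in
    :mod:`gazestab.cgr`)."""
    pv = g_v * np.exp(1j * np.deg2rad(ph_v - 360.0 * freq * dv_ms / 1000.0))
    po = g_o * np.exp(1j * np.deg2rad(ph_o - 360.0 * freq * do_ms / 1000.0))
    s = pv + po
    return float(abs(s)), float(np.rad2deg(np.angle(s)))


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> list[AnimalSpec]:
    """Draw a cohort of :class:`AnimalSpec` ground truths.

    Deterministic for a fixed ``(config, seed)``.  SHAM animals keep their
    baseline gains at every week; treated animals follow the lesion and
    recovery multipliers with subtype-specific VOR attenuation, jitter and
    combined-response construction.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0407]))

    subtypes = _allocate_subtypes(config.n_idpn, config.subtype_proportions)
    animals: list[AnimalSpec] = []
    order = (
        [("SHAM", "NA", i) for i in range(config.n_sham)]
        + [("IDPN", subtypes[i], i) for i in range(config.n_idpn)]
    )
    for group, subtype, idx in order:
        animals.append(_draw_animal(config, group, subtype, idx, rng))
    return animals


def _draw_baseline(rng, mean, spread):
    return max(0.05 * mean, mean * (1.0 + spread * rng.standard_normal()))


def _draw_animal(config: CohortConfig, group: str, subtype: str, idx: int, rng) -> AnimalSpec:
    aid = f"{group.lower()}{idx + 1:02d}"
    lesioned = group == "IDPN"

    vor_base = {f: _draw_baseline(rng, m, config.gain_spread)
                for f, m in config.vor_baseline.items()}
    okr_base = {f: _draw_baseline(rng, m, config.gain_spread)
                for f, m in config.okr_baseline.items()}
    ocr_base = _draw_baseline(rng, config.ocr_baseline, config.gain_spread)
    ovar_base = _draw_baseline(rng, config.ovar_bias_baseline, config.gain_spread)

    vor_jit = config.base_cycle_jitter_sd
    vor_atten = 1.0
    if subtype in ("DELTA_PLUS_LOWVOR", "DELTA_MINUS"):
        vor_atten = config.lowvor_extra_atten
    if subtype == "DELTA_MINUS":
        vor_jit = config.delta_minus_jitter_sd
        # amplitude matching: per-cycle gain g(1+e) has E[g^2(1+e)^2] =
        # g^2(1+sd^2); deflate g so the expected sweep amplitude equals the
        # low-VOR subtype's.
        vor_atten /= math.sqrt(1.0 + vor_jit ** 2)

    gains: dict = {}
    phases: dict = {}
    for w in config.weeks:
        vm = config.vor_lesion_mult[w] if lesioned else 1.0
        om = config.ocr_lesion_mult[w] if lesioned else 1.0
        ovm = config.ovar_lesion_mult[w] if lesioned else 1.0
        lead = config.vor_lead_at_trough_deg * (1.0 - vm) if lesioned else 0.0
        for f in config.vor_freqs:
            gains[_key(w, "VOR_DARK", f)] = vor_base[f] * vm * vor_atten
            phases[_key(w, "VOR_DARK", f)] = lead
        for f in config.okr_freqs:
            bm = (config.okr_boost_mult[w]
                  if lesioned and f > config.okr_boost_min_freq else 1.0)
            gains[_key(w, "OKR", f)] = okr_base[f] * bm
            phases[_key(w, "OKR", f)] = -360.0 * f * config.okr_lag_ms / 1000.0
        gains[_key(w, "OCR", 0.0)] = ocr_base * om
        phases[_key(w, "OCR", 0.0)] = 0.0
        gains[_key(w, "OVAR", 0.0)] = ovar_base * ovm
        phases[_key(w, "OVAR", 0.0)] = 0.0
        for f in config.cgr_freqs:
            g_cgr, ph_cgr = _phasor_sum_truth(
                gains[_key(w, "VOR_DARK", f)], phases[_key(w, "VOR_DARK", f)],
                gains[_key(w, "OKR", f)], phases[_key(w, "OKR", f)],
                config.cgr_delta_vor_ms, config.cgr_delta_okr_ms, f,
            )
            if subtype == "DELTA_MINUS":
                g_cgr *= config.delta_minus_cgr_atten
            gains[_key(w, "CGR", f)] = g_cgr
            phases[_key(w, "CGR", f)] = ph_cgr

    return AnimalSpec(
        animal_id=aid,
        group=group,
        subtype=subtype,
        gain_schedule=gains,
        phase_schedule=phases,
        cycle_jitter_sd={
            "VOR_DARK": vor_jit,
            "CGR": vor_jit,
            "OKR": config.base_cycle_jitter_sd,
        },
        noise_sd=config.noise_sd,
        ovar_modulation=config.ovar_modulation,
        qp_rate_hz=config.qp_rate_hz,
        qp_amp_mean=config.qp_amp_mean,
        qp_amp_sd=config.qp_amp_sd,
        qp_refractory_s=config.qp_refractory_s,
        eye_rate_Hz=config.eye_rate_Hz,
        stim_rate_Hz=config.stim_rate_Hz,
    )


# ---------------------------------------------------------------------------
# trial rendering


def _quick_phase_times(rng, duration_s, rate_hz, refractory_s):
    """Poisson arrival times with a hard refractory period."""
    if rate_hz <= 0:
        return np.empty(0)
    times = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rate_hz)
        if times:
            t = max(t, times[-1] + refractory_s)
        if t >= duration_s:
            break
        times.append(t)
    return np.asarray(times)


def _integrate_with_quick_phases(v_slow, fs, rng, spec: AnimalSpec):
    """Integrate slow-phase velocity into position, inserting instantaneous
    quick-phase steps toward the centering set-point (0 deg).

    Returns (position, qp_truth_mask, qp_free_position)."""
    n = v_slow.size
    # trapezoidal cumulative integral: phase-consistent with the central
    # differences used on the analysis side
    pos_slow = np.concatenate(
        [[0.0], np.cumsum((v_slow[1:] + v_slow[:-1]) / 2.0) / fs])
    pos = pos_slow.copy()
    mask = np.zeros(n, dtype=bool)
    times = _quick_phase_times(rng, n / fs, spec.qp_rate_hz, spec.qp_refractory_s)
    for ts in times:
        k = int(round(ts * fs))
        if k <= 0 or k >= n:
            continue
        amp = abs(rng.normal(spec.qp_amp_mean, spec.qp_amp_sd))
        step = -np.sign(pos[k - 1]) * amp if pos[k - 1] != 0 else amp
        pos[k:] += step
        mask[k] = True
    return pos, mask, pos_slow


def _sinusoid_stim(duration_s, freq, peak_vel, fs_stim):
    n = max(2, int(round(duration_s * fs_stim)))
    t = np.arange(n) / fs_stim
    w = 2.0 * np.pi * freq
    vel = peak_vel * np.sin(w * t)
    pos = peak_vel / w * (1.0 - np.cos(w * t))
    return t, pos, vel


def synthesize_sinusoid_trial(
    spec: AnimalSpec,
    modality: str,
    frequency_Hz: float,
    peak_vel: float | None = None,
    n_cycles: int = 20,
    seed: int = 0,
    week: int = 0,
) -> RawTrace:
    """Render one sinusoidal trial (aVOR in dark, OKR, or combined CGR).

    The slow-phase eye velocity is ``g_c · r(t; phase)`` plus white velocity
    noise, where ``r`` is the signed compensatory reference (−head velocity
    for vestibular rotations, +drum velocity for OKR), ``g_c`` is the true
    gain jittered independently per stimulus cycle, and the phase is the
    animal's scheduled lead.  Position integrates this velocity and is
    punctuated by Poisson quick phases recorded in ``qp_truth``.
    """
    if modality not in ("VOR_DARK", "OKR", "CGR"):
        raise ConfigError(f"not a sinusoidal modality: {modality!r}")
    if n_cycles < 1:
        raise ConfigError("n_cycles must be >= 1")
    if peak_vel is None:
        peak_vel = OKR_PEAK_VEL if modality == "OKR" else VOR_PEAK_VEL

    g = spec.gain(week, modality, frequency_Hz)
    phase_deg = spec.phase(week, modality, frequency_Hz)
    jitter = spec.jitter(modality)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x51]))

    fs = spec.eye_rate_Hz
    duration = n_cycles / frequency_Hz
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    t_stim, stim_pos_hi, stim_vel_hi = _sinusoid_stim(
        duration, frequency_Hz, peak_vel, spec.stim_rate_Hz)
    stim_pos, stim_vel = align_to_eye_timebase(t, t_stim, stim_pos_hi, stim_vel_hi)

    # reference sign: compensatory convention
    s = 1.0 if modality == "OKR" else -1.0
    w = 2.0 * np.pi * frequency_Hz
    ref_shifted = s * peak_vel * np.sin(w * t + np.deg2rad(phase_deg))

    cycle = np.minimum((t * frequency_Hz).astype(int), n_cycles - 1)
    g_cycle = g * (1.0 + jitter * rng.standard_normal(n_cycles))
    v_slow = g_cycle[cycle] * ref_shifted
    if spec.noise_sd > 0:
        v_slow = v_slow + spec.noise_sd * rng.standard_normal(n)

    pos, qp_mask, _ = _integrate_with_quick_phases(v_slow, fs, rng, spec)

    return RawTrace(
        t=t, eye_h=pos, eye_v=np.zeros(n),
        stim_pos=stim_pos, stim_vel=stim_vel,
        modality=modality, frequency_Hz=frequency_Hz, peak_vel=peak_vel,
        eye_rate_Hz=fs, stim_rate_Hz=spec.stim_rate_Hz,
        qp_truth=qp_mask,
        meta={"animal_id": spec.animal_id, "week": week, "seed": int(seed),
              "true_gain": g, "true_phase_deg": phase_deg,
              "n_cycles": int(n_cycles)},
    )


def synthesize_ocr_trial(
    spec: AnimalSpec,
    tilt_angles=(-40, -30, -20, -10, 0, 10, 20, 30, 40),
    hold_s: float = 10.0,
    seed: int = 0,
    week: int = 0,
) -> RawTrace:
    """Render a static ocular counter-roll trial.

    The table steps through ``tilt_angles`` (deg), holding each for
    ``hold_s`` seconds; the vertical eye angle settles at
    ``slope × tilt`` plus measurement noise.
    """
    tilt_angles = [float(a) for a in tilt_angles]
    if not tilt_angles:
        raise ConfigError("tilt_angles must be non-empty")
    if hold_s < 10.0:
        raise ConfigError("plateaus must be held for at least 10 s")
    if any(abs(a) > 40 for a in tilt_angles):
        raise ConfigError("tilt angles limited to +/-40 deg")

    slope = spec.gain(week, "OCR", 0.0)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x0C4]))
    fs = spec.eye_rate_Hz
    n_hold = int(round(hold_s * fs))
    n = n_hold * len(tilt_angles)
    t = np.arange(n) / fs

    tilt = np.repeat(tilt_angles, n_hold)
    # position noise on the eye channel: velocity noise integrated over one
    # frame gives noise_sd/fs deg per sample; keep a modest static jitter.
    pos_noise_sd = spec.noise_sd / fs * 5.0
    eye_v = slope * tilt + pos_noise_sd * rng.standard_normal(n)
    eye_h = pos_noise_sd * rng.standard_normal(n)

    schedule = [
        (i * n_hold / fs, (i + 1) * n_hold / fs, a)
        for i, a in enumerate(tilt_angles)
    ]
    return RawTrace(
        t=t, eye_h=eye_h, eye_v=eye_v,
        stim_pos=tilt, stim_vel=np.zeros(n),
        modality="OCR", frequency_Hz=0.0, peak_vel=0.0,
        eye_rate_Hz=fs, stim_rate_Hz=spec.stim_rate_Hz,
        meta={"animal_id": spec.animal_id, "week": week, "seed": int(seed),
              "tilt_schedule": schedule, "true_slope": slope},
    )


def synthesize_ovar_trial(
    spec: AnimalSpec,
    speed: float = OVAR_SPEED,
    direction: str = "CCW",
    duration_s: float = 60.0,
    seed: int = 0,
    week: int = 0,
    phase0_deg: float = 0.0,
) -> RawTrace:
    """Render an off-vertical-axis rotation trial.

    Slow-phase horizontal velocity is ``β + μ·sin(2π f0 t + φ0)`` with
    ``f0 = speed/360``.  The raw bias opposes the table rotation
    (compensatory nystagmus): for CCW rotation the generated bias is
    ``−bias_magnitude``, for CW it is ``+bias_magnitude``.
    """
    if speed <= 0:
        raise ConfigError("rotation speed must be > 0")
    if direction not in ("CW", "CCW"):
        raise ConfigError("direction must be CW or CCW")
    f0 = speed / 360.0
    if duration_s * f0 < 5:
        raise ConfigError("trial must cover at least 5 table rotations")

    bias_mag = spec.gain(week, "OVAR", 0.0)
    mu = spec.ovar_modulation
    dir_sign = 1.0 if direction == "CCW" else -1.0
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x0A7]))

    fs = spec.eye_rate_Hz
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    stim_vel = np.full(n, dir_sign * speed)
    stim_pos = dir_sign * speed * t

    v_slow = (-dir_sign * bias_mag
              + mu * np.sin(2 * np.pi * f0 * t + np.deg2rad(phase0_deg)))
    if spec.noise_sd > 0:
        v_slow = v_slow + spec.noise_sd * rng.standard_normal(n)

    pos, qp_mask, _ = _integrate_with_quick_phases(v_slow, fs, rng, spec)

    return RawTrace(
        t=t, eye_h=pos, eye_v=np.zeros(n),
        stim_pos=stim_pos, stim_vel=stim_vel,
        modality="OVAR", frequency_Hz=f0, peak_vel=speed,
        eye_rate_Hz=fs, stim_rate_Hz=spec.stim_rate_Hz,
        direction=direction, qp_truth=qp_mask,
        meta={"animal_id": spec.animal_id, "week": week, "seed": int(seed),
              "true_bias": -dir_sign * bias_mag, "true_modulation": mu,
              "true_phase0_deg": phase0_deg},
    )


# ---------------------------------------------------------------------------
# hair-cell count tables

DEFAULT_HC_LINK = {
    # marker: (slope per unit gain, intercept, noise SD, gain-linked?)
    "Spp1":   (40.0, 5.0, 8.0, True),
    "CASPR1": (45.0, 4.0, 8.0, True),
    "Calre":  (0.0, 18.0, 2.0, False),
    "Myo7a":  (0.0, 40.0, 3.0, False),
}


def synthesize_hc_counts(
    cohort: list[AnimalSpec],
    link: dict | None = None,
    seed: int = 0,
    week: int = 6,
):
    """Synthesize hair-cell marker count tables linked to reflex gains.

    Type-I markers (Spp1, CASPR1) are linear in the animal's angular VOR
    gain (canal) or OCR slope (utricule) at the sampling week, plus noise;
    type-II (Calre) and pan-HC (Myo7a) counts are gain-independent.  Counts
    are rounded and clipped at zero.  Returns a long-format DataFrame with
    columns ``animal_id, organ, zone, marker, count``.
    """
    import pandas as pd

    link = link or DEFAULT_HC_LINK
    for marker, (slope, *_rest) in link.items():
        if not np.isfinite(slope):
            raise ConfigError(f"non-finite slope for marker {marker}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x4C]))
    rows = []
    for spec in cohort:
        drivers = {
            "canal": spec.gain(week, "VOR_DARK", 1.0),
            "utricule": spec.gain(week, "OCR", 0.0),
        }
        for organ, gain in drivers.items():
            for zone in ("central", "peripheral"):
                zscale = 1.0 if zone == "central" else 0.8
                for marker, (slope, intercept, noise_sd, linked) in link.items():
                    mean = (slope * gain + intercept) if linked else intercept
                    count = zscale * mean + noise_sd * rng.standard_normal()
                    rows.append({
                        "animal_id": spec.animal_id,
                        "organ": organ,
                        "zone": zone,
                        "marker": marker,
                        "count": int(max(0, round(count))),
                        "gain": gain,
                        "week": week,
                    })
    return pd.DataFrame(rows)
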