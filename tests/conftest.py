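"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pandas as pd
import pytest

from gazestab import AnimalSpec
from gazestab.preprocess import SlowPhaseSeries


def make_series(
    g=0.8,
    phase_deg=0.0,
    Cte=0.0,
    freq=1.0,
    peak_vel=30.0,
    n_cycles=20,
    fs=120.0,
    noise_sd=0.0,
    modality="VOR_DARK",
    seed=0,
):
    """Build an analytic slow-phase series: EHv = g·A·sin(wt+φ) + Cte against
    the reference A·sin(wt).  Bypasses trace rendering for fit-level tests."""
    n = int(round(n_cycles / freq * fs))
    t = np.arange(n) / fs
    w = 2 * np.pi * freq
    ref = peak_vel * np.sin(w * t)
    rng = np.random.default_rng(seed)
    EHv = g * peak_vel * np.sin(w * t + np.deg2rad(phase_deg)) + Cte
    if noise_sd > 0:
        EHv = EHv + noise_sd * rng.standard_normal(n)
    EHp = -g * peak_vel / w * np.cos(w * t + np.deg2rad(phase_deg))
    EHp -= EHp.mean()
    return SlowPhaseSeries(
        t=t, EHv=EHv, EHp=EHp, ref_vel=ref,
        valid=np.ones(n, dtype=bool),
        modality=modality, frequency_Hz=freq, peak_vel=peak_vel,
    )


def nonlinear_sinusoid_oracle(series, freq=None):
    """Independent oracle: iterative nonlinear least squares over (g, td, Cte)
    of EHv(t) = g·r(t − td) + Cte with the reference handled analytically."""
    from scipy.optimize import least_squares

    freq = freq if freq is not None else series.frequency_Hz
    w = 2 * np.pi * freq
    valid = series.valid & np.isfinite(series.EHv)
    t, y = series.t[valid], series.EHv[valid]
    # reference amplitude/phase from projection (exact for clean sinusoids)
    a = 2 * np.mean(series.ref_vel * np.sin(w * series.t))
    b = 2 * np.mean(series.ref_vel * np.cos(w * series.t))
    A, psi = np.hypot(a, b), np.arctan2(b, a)

    def residual(p):
        g, td, cte = p
        return g * A * np.sin(w * (t - td) + psi) + cte - y

    amp0 = np.sqrt(2) * np.std(y)
    best = None
    for td0 in np.linspace(-0.4 / freq, 0.4 / freq, 9):
        sol = least_squares(residual, x0=[amp0 / A, td0, np.mean(y)],
                            method="lm", xtol=1e-14, ftol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    g, td, cte = best.x
    if g < 0:  # fold the sign ambiguity into a half-period shift
        g = -g
        td += 0.5 / freq
    phase = -(360.0 * freq * td) % 360.0
    phase = (phase + 180.0) % 360.0 - 180.0
    phase = 180.0 if phase == -180.0 else phase
    return g, phase, cte


def naive_upgma(X):
    """Brute-force UPGMA on Euclidean distances; returns a linkage-style
    array [[i, j, height, size], ...] merging lowest-index pairs on ties."""
    X = np.asarray(X, float)
    n = len(X)
    clusters = {i: [i] for i in range(n)}
    ids = {i: i for i in range(n)}
    active = list(range(n))
    Z = []
    next_id = n
    point_d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))

    def cdist(a, b):
        return np.mean([point_d[i, j] for i in clusters[a] for j in clusters[b]])

    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                d = cdist(a, b)
                key = (d, min(ids[a], ids[b]), max(ids[a], ids[b]))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, *_), a, b = best
        clusters[next_id] = clusters[a] + clusters[b]
        ids[next_id] = next_id
        Z.append([min(ids[a], ids[b]), max(ids[a], ids[b]), d,
                  len(clusters[next_id])])
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return np.array(Z)


@pytest.fixture
def clean_spec():
    """Noiseless, saccade-free single-modality animal."""
    return AnimalSpec.constant(gain=0.8)


@pytest.fixture
def fits_table():
    """Small long-format fit table for cohort metrics tests."""
    rows = []
    for aid, gv, go, gc in (("a1", 0.6, 0.2, 0.7), ("a2", 0.4, 0.4, 0.8)):
        for week in (0, 6):
            for f in (0.2, 0.5, 1.0):
                for modality, g in (("VOR_DARK", gv), ("OKR", go), ("CGR", gc)):
                    rows.append({
                        "animal_id": aid, "group": "IDPN", "week": week,
                        "modality": modality, "frequency_Hz": f,
                        "gain": g, "phase_deg": 0.0, "VAF": 0.95,
                        "qc_flag": False,
                    })
    return pd.DataFrame(rows)
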