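"""Combined-response model: phasor algebra, waveform path, shift search."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import gazestab as gs
from gazestab.cgr import CGRError, _wide_unimodal
from gazestab.fits import wrap_phase


def _phase_diff(a, b):
    return abs(wrap_phase(a - b))


class TestPhasorSum:
    def test_in_phase_sum(self):
        assert gs.phasor_sum(0.5, 0, 0.5, 0, 0, 0, 1.0) == (1.0, 0.0)

    def test_cancellation(self):
        gain, phase = gs.phasor_sum(0.5, 0, 0.5, 180.0, 0, 0, 1.0)
        assert gain == 0.0
        assert np.isnan(phase)

    def test_complex_addition_example(self):
        # independent complex oracle: 0.6∠10° + 0.3∠−5°
        z = 0.6 * np.exp(1j * np.deg2rad(10)) + 0.3 * np.exp(1j * np.deg2rad(-5))
        gain, phase = gs.phasor_sum(0.6, 10.0, 0.3, -5.0, 0, 0, 0.5)
        assert gain == pytest.approx(abs(z), abs=1e-12)
        assert gain == pytest.approx(0.893, abs=2e-3)
        assert phase == pytest.approx(np.rad2deg(np.angle(z)), abs=1e-9)
        assert phase == pytest.approx(5.0, abs=0.05)

    def test_negative_gain_rejected(self):
        with pytest.raises(CGRError):
            gs.phasor_sum(-0.1, 0, 0.5, 0, 0, 0, 1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(gv=st.floats(0, 1.2), go=st.floats(0, 1.2),
           pv=st.floats(-180, 180), po=st.floats(-180, 180))
    def test_triangle_inequality(self, gv, go, pv, po):
        gain, _ = gs.phasor_sum(gv, pv, go, po, 0, 0, 1.0)
        assert abs(gv - go) - 1e-9 <= gain <= gv + go + 1e-9


class TestWaveformPrediction:
    def test_agrees_with_phasor_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            gv, go = rng.uniform(0.05, 1.2, 2)
            pv, po = rng.uniform(-90, 90, 2)
            dv, do = rng.uniform(-200, 200, 2)
            f = rng.choice([0.2, 0.5, 1.0])
            g1, p1 = gs.phasor_sum(gv, pv, go, po, dv, do, f)
            g2, p2 = gs.predict_cgr_waveform(gv, pv, go, po, dv, do, f)
            assert g2 == pytest.approx(g1, abs=1e-3)
            assert _phase_diff(p1, p2) < 0.5

    def test_zero_okr_reduces_to_shifted_vor(self):
        gain, phase = gs.predict_cgr_waveform(0.7, 12.0, 0.0, 0.0, 30.0, 0.0,
                                              frequency_Hz=0.5)
        assert gain == pytest.approx(0.7, abs=1e-6)
        assert _phase_diff(phase, 12.0 - 360 * 0.5 * 0.03) < 0.5

    def test_both_zero_gains(self):
        gain, phase = gs.predict_cgr_waveform(0.0, 0.0, 0.0, 0.0)
        assert gain == 0.0
        assert np.isnan(phase)

    def test_shift_covariance(self):
        # adding Δ to both shifts rotates the phase by −360·f·Δ, gain fixed
        g0, p0 = gs.phasor_sum(0.5, 20.0, 0.4, -10.0, 15.0, -5.0, 0.5)
        delta = 40.0
        g1, p1 = gs.phasor_sum(0.5, 20.0, 0.4, -10.0, 15.0 + delta,
                               -5.0 + delta, 0.5)
        assert g1 == pytest.approx(g0, abs=1e-12)
        assert _phase_diff(p1, p0 - 360 * 0.5 * delta / 1000) < 1e-9

    def test_coarse_sampling_rejected(self):
        with pytest.raises(CGRError):
            gs.predict_cgr_waveform(0.5, 0, 0.5, 0, samples_per_cycle=64)


def _sham_fit_table(true_shifts, n_animals=5, seed=0,
                    frequencies=(0.2, 0.5, 1.0), group="SHAM"):
    """Fit table whose observed CGR is the exact shifted sum of the
    unimodal responses at the given per-frequency shifts."""
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_animals):
        aid = f"{group.lower()}{a:02d}"
        for f in frequencies:
            gv, go = rng.uniform(0.3, 0.9, 2)
            pv, po = rng.uniform(-60, 60, 2)
            dv, do = true_shifts[f]
            gc, pc = gs.phasor_sum(gv, pv, go, po, dv, do, f)
            for modality, g, p in (("VOR_DARK", gv, pv), ("OKR", go, po),
                                   ("CGR", gc, pc)):
                rows.append({"animal_id": aid, "group": group, "week": 6,
                             "modality": modality, "frequency_Hz": f,
                             "gain": g, "phase_deg": p, "VAF": 0.99,
                             "qc_flag": False})
    return pd.DataFrame(rows)


class TestOptimizeShifts:
    def test_recovers_constructed_shifts(self):
        # grid step is period/200: 25, 10 and 5 ms at the three frequencies
        true = {0.2: (25.0, -50.0), 0.5: (20.0, -10.0), 1.0: (15.0, -10.0)}
        table = _sham_fit_table(true, seed=1)
        params = gs.optimize_shifts(table)
        for f, (dv, do) in true.items():
            got = params.for_frequency(f)
            step = got["grid_step_ms"]
            assert abs(got["delta_vor_ms"] - dv) <= step
            assert abs(got["delta_okr_ms"] - do) <= step

    def test_plain_sum_gives_zero_shifts(self):
        true = {f: (0.0, 0.0) for f in (0.2, 0.5, 1.0)}
        params = gs.optimize_shifts(_sham_fit_table(true, seed=2))
        for f in true:
            got = params.for_frequency(f)
            assert got["delta_vor_ms"] == 0.0
            assert got["delta_okr_ms"] == 0.0
            assert got["loss_at_optimum"] == pytest.approx(0.0, abs=1e-12)

    def test_loss_at_optimum_bounded_by_unshifted_loss(self):
        true = {f: (30.0, 20.0) for f in (0.2, 0.5, 1.0)}
        table = _sham_fit_table(true, seed=3)
        params = gs.optimize_shifts(table)
        for f in true:
            wide = _wide_unimodal(table[table.frequency_Hz == f], f)
            pv = wide.g_vor * np.exp(1j * np.deg2rad(wide.phase_vor))
            po = wide.g_okr * np.exp(1j * np.deg2rad(wide.phase_okr))
            pobs = wide.g_cgr * np.exp(1j * np.deg2rad(wide.phase_cgr))
            loss00 = float(np.mean(np.abs(pv + po - pobs) ** 2)) * 30 ** 2 / 2
            assert params.for_frequency(f)["loss_at_optimum"] <= loss00 + 1e-12

    def test_phasor_loss_equals_waveform_mse(self):
        # the closed-form grid loss is the literal waveform mean-squared
        # difference over one sampled cycle
        rng = np.random.default_rng(5)
        A = 30.0
        for _ in range(10):
            gv, go, gc = rng.uniform(0.1, 1.0, 3)
            pv, po, pc = rng.uniform(-60, 60, 3)
            dv, do = rng.uniform(-100, 100, 2)
            f = 0.5
            n = 2048
            t = np.arange(n) / n / f
            w = 2 * np.pi * f
            pred = (gv * A * np.sin(w * (t - dv / 1000) + np.deg2rad(pv))
                    + go * A * np.sin(w * (t - do / 1000) + np.deg2rad(po)))
            obs = gc * A * np.sin(w * t + np.deg2rad(pc))
            mse = float(np.mean((pred - obs) ** 2))
            zp = (gv * np.exp(1j * np.deg2rad(pv - 360 * f * dv / 1000))
                  + go * np.exp(1j * np.deg2rad(po - 360 * f * do / 1000)))
            zo = gc * np.exp(1j * np.deg2rad(pc))
            assert mse == pytest.approx(abs(zp - zo) ** 2 * A ** 2 / 2, rel=1e-9)

    def test_too_few_controls_rejected(self):
        true = {f: (0.0, 0.0) for f in (0.2, 0.5, 1.0)}
        with pytest.raises(CGRError):
            gs.optimize_shifts(_sham_fit_table(true, n_animals=2))


class TestApplyModel:
    def test_missing_okr_row_skipped(self):
        true = {f: (0.0, 0.0) for f in (0.2, 0.5, 1.0)}
        table = _sham_fit_table(true, seed=4)
        params = gs.optimize_shifts(table)
        dropped = table[~((table.animal_id == "sham00")
                          & (table.modality == "OKR"))]
        preds = gs.apply_model(dropped, params)
        assert "sham00" not in set(preds.animal_id)
        assert len(set(preds.animal_id)) == 4

    def test_qc_flagged_phase_excluded(self):
        true = {f: (0.0, 0.0) for f in (0.2, 0.5, 1.0)}
        table = _sham_fit_table(true, seed=4)
        params = gs.optimize_shifts(table)
        table.loc[(table.animal_id == "sham01") & (table.modality == "VOR_DARK"),
                  "qc_flag"] = True
        preds = gs.apply_model(table, params)
        assert "sham01" not in set(preds.animal_id)

    def test_delta_minus_construction_underperforms_prediction(self):
        # animals built with combined gain below the shifted sum show
        # observed < predicted
        true = {f: (0.0, 0.0) for f in (0.2, 0.5, 1.0)}
        sham = _sham_fit_table(true, seed=6)
        weak = _sham_fit_table(true, seed=7, group="IDPN")
        weak.loc[weak.modality == "CGR", "gain"] *= 0.4
        params = gs.optimize_shifts(sham)
        preds = gs.apply_model(pd.concat([sham, weak]), params)
        idpn = preds[preds.animal_id.str.startswith("idpn")]
        assert (idpn.gain_obs < idpn.gain_pred).all()

    def test_unknown_frequency_rejected(self):
        params = gs.CGRShiftParams(shifts={})
        with pytest.raises(CGRError):
            params.for_frequency(0.8)
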