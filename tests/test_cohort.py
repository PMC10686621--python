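"""Cohort metrics, phenotype clustering and structure-function regressions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gazestab as gs
from gazestab.cohort import CohortError
from conftest import naive_upgma


class TestVestibularWeight:
    def test_basic_ratio(self, fits_table):
        w = gs.vestibular_weight(fits_table, baseline_week=0)
        a1 = w[w.animal_id == "a1"]["weight_pct"]
        assert np.allclose(a1, 75.0)  # 0.6 / (0.6 + 0.2)
        a2 = w[w.animal_id == "a2"]["weight_pct"]
        assert np.allclose(a2, 50.0)

    def test_zero_vor_gives_zero(self, fits_table):
        t = fits_table.copy()
        t.loc[t.modality == "VOR_DARK", "gain"] = 0.0
        w = gs.vestibular_weight(t)
        assert np.allclose(w.weight_pct, 0.0)

    def test_scale_invariance(self, fits_table):
        w0 = gs.vestibular_weight(fits_table)
        scaled = fits_table.copy()
        scaled["gain"] *= 3.7
        w1 = gs.vestibular_weight(scaled)
        np.testing.assert_allclose(w1.weight_pct, w0.weight_pct)


class TestDeltaGain:
    def test_constant_gain_zero_delta(self, fits_table):
        d = gs.delta_gain(fits_table, reference_week=0)
        assert np.allclose(d.delta, 0.0)

    def test_recovers_constructed_change(self, fits_table):
        t = fits_table.copy()
        t.loc[(t.week == 6) & (t.modality == "VOR_DARK"), "gain"] -= 0.25
        d = gs.delta_gain(t, reference_week=0)
        vor6 = d[(d.week == 6) & (d.modality == "VOR_DARK")]
        assert np.allclose(vor6.delta, -0.25)

    def test_missing_reference_rejected(self, fits_table):
        with pytest.raises(CohortError):
            gs.delta_gain(fits_table, reference_week=99)


class TestIntegrationDelta:
    def test_equal_cgr_okr_gives_zero(self, fits_table):
        t = fits_table.copy()
        t.loc[t.modality == "CGR", "gain"] = \
            t.loc[t.modality == "OKR", "gain"].to_numpy()
        m = gs.integration_delta(t, week=0)
        assert np.allclose(m.delta, 0.0)

    def test_delta_is_mean_of_per_frequency_differences(self, fits_table):
        m = gs.integration_delta(fits_table, week=0)
        a1 = m[m.animal_id == "a1"].iloc[0]
        assert a1.delta == pytest.approx(0.7 - 0.2)
        assert a1.mean_aVOR == pytest.approx(0.6)

    def test_negative_delta_means_cgr_below_okr(self, fits_table):
        t = fits_table.copy()
        t.loc[t.modality == "CGR", "gain"] = 0.1
        m = gs.integration_delta(t, week=0)
        assert (m.delta < 0).all()


class TestClustering:
    def test_separated_clouds_recovered(self):
        rng = np.random.default_rng(0)
        f1 = rng.normal([0.2, 0.2], 0.01, size=(6, 2))
        f2 = rng.normal([0.1, -0.3], 0.01, size=(4, 2))
        df = pd.DataFrame(np.vstack([f1, f2]), columns=["mean_aVOR", "delta"])
        df["animal_id"] = [f"m{i}" for i in range(10)]
        res = gs.cluster_animals(df)
        labels = [res.labels[f"m{i}"] for i in range(10)]
        assert labels[:6] == ["DELTA_PLUS"] * 6
        assert labels[6:] == ["DELTA_MINUS"] * 4

    def test_linkage_matches_naive_upgma(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(size=(6, 2))
        df = pd.DataFrame(X, columns=["mean_aVOR", "delta"])
        df["animal_id"] = list("abcdef")
        res = gs.cluster_animals(df)
        Z_naive = naive_upgma(X)
        np.testing.assert_allclose(
            np.sort(res.linkage[:, 2]), np.sort(Z_naive[:, 2]), atol=1e-12)
        np.testing.assert_allclose(res.linkage[:, 2], Z_naive[:, 2], atol=1e-12)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(size=(8, 2))
        df = pd.DataFrame(X, columns=["mean_aVOR", "delta"])
        df["animal_id"] = [f"m{i}" for i in range(8)]
        res1 = gs.cluster_animals(df)
        shuffled = df.sample(frac=1, random_state=1).reset_index(drop=True)
        res2 = gs.cluster_animals(shuffled)
        assert res1.labels == res2.labels

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(7, 2))
        df = pd.DataFrame(X, columns=["mean_aVOR", "delta"])
        df["animal_id"] = [f"m{i}" for i in range(7)]
        res1 = gs.cluster_animals(df)
        df2 = df.copy()
        df2[["mean_aVOR", "delta"]] += 5.0
        res2 = gs.cluster_animals(df2)
        np.testing.assert_allclose(res1.linkage[:, 2], res2.linkage[:, 2],
                                   atol=1e-9)

    def test_sublabels_mark_low_vor_subgroup(self):
        rows = []
        for i, (vor, delta) in enumerate(
                [(0.6, 0.2), (0.62, 0.22), (0.58, 0.21),   # Δ+ high VOR
                 (0.15, 0.18), (0.17, 0.19),               # Δ+ low VOR
                 (0.12, -0.3), (0.14, -0.28)]):            # Δ−
            rows.append({"animal_id": f"m{i}", "mean_aVOR": vor, "delta": delta})
        res = gs.cluster_animals(pd.DataFrame(rows))
        assert res.labels["m5"] == res.labels["m6"] == "DELTA_MINUS"
        assert res.sublabels["m3"] == res.sublabels["m4"] == "DELTA_PLUS_LOWVOR"
        assert res.sublabels["m0"] == "DELTA_PLUS"

    def test_invalid_inputs_rejected(self):
        df = pd.DataFrame({"animal_id": ["a", "a", "b", "c"],
                           "mean_aVOR": [1, 2, 3, 4.0],
                           "delta": [0, 0, 0, 0.0]})
        with pytest.raises(CohortError, match="duplicate"):
            gs.cluster_animals(df)
        df2 = pd.DataFrame({"animal_id": list("abcd"),
                            "mean_aVOR": [1, 2, np.nan, 4.0],
                            "delta": [0, 0, 0, 0.0]})
        with pytest.raises(CohortError, match="finite"):
            gs.cluster_animals(df2)


class TestStructureFunction:
    def _gain_table(self, gains):
        rows = []
        for aid, g in gains.items():
            rows.append({"animal_id": aid, "week": 6, "modality": "VOR_DARK",
                         "frequency_Hz": 1.0, "gain": g, "phase_deg": 0.0,
                         "VAF": 0.9, "qc_flag": False})
        return pd.DataFrame(rows)

    def test_perfect_linear_counts(self):
        gains = {f"m{i}": 0.1 * i for i in range(8)}
        counts = pd.DataFrame([
            {"animal_id": aid, "organ": "canal", "zone": "central",
             "marker": "Spp1", "count": 40 * g + 5, "week": 6}
            for aid, g in gains.items()])
        res = gs.structure_function_regression(counts, self._gain_table(gains))
        assert res.iloc[0].slope == pytest.approx(40.0)
        assert res.iloc[0].r2 == pytest.approx(1.0)

    def test_unlinked_marker_rarely_significant(self):
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            gains = {f"m{i}": rng.uniform(0.1, 0.8) for i in range(23)}
            counts = pd.DataFrame([
                {"animal_id": aid, "organ": "canal", "zone": "central",
                 "marker": "Calre", "count": rng.poisson(18), "week": 6}
                for aid in gains])
            res = gs.structure_function_regression(
                counts, self._gain_table(gains))
            ok += res.iloc[0].p > 0.05
        assert ok >= 17  # ~90% of seeds


class TestDissociationStructure:
    def test_rep_separates_subtypes_amp_does_not(self):
        # the unreliable-VOR subtype is amplitude-matched to the low-VOR
        # subtype but has high cycle jitter: Rep dissociates, Amp does not
        cc = gs.CohortConfig(
            n_sham=1, n_idpn=10,
            subtype_proportions={"DELTA_PLUS": 0.0, "DELTA_PLUS_LOWVOR": 0.5,
                                 "DELTA_MINUS": 0.5})
        cohort = gs.generate_cohort(cc, seed=21)
        rep, amp = {}, {}
        for i, spec in enumerate(cohort):
            if spec.group != "IDPN":
                continue
            tr = gs.synthesize_sinusoid_trial(spec, "VOR_DARK", 1.0,
                                              n_cycles=15, week=6,
                                              seed=500 + i)
            st_ = gs.sweep_stats(tr)
            rep.setdefault(spec.subtype, []).append(st_.Rep)
            amp.setdefault(spec.subtype, []).append(st_.Amp)
        assert np.mean(rep["DELTA_PLUS_LOWVOR"]) > np.mean(rep["DELTA_MINUS"])
        ratio = np.mean(amp["DELTA_MINUS"]) / np.mean(amp["DELTA_PLUS_LOWVOR"])
        assert 0.8 < ratio < 1.25
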