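"""Cohort-level derived metrics and phenotype clustering.

Works on the long-format fit table (one row per animal × week × modality ×
frequency with gain, phase, VAF and QC flag).  Provides:

* the *vestibular weight* w = g_aVOR / (g_aVOR + g_OKR) at baseline — the
  frequency-resolved share of gaze stabilization carried by the vestibular
  input;
* longitudinal gain deltas relative to a reference week;
* the integration metrics: per-animal mean aVOR, OKR and CGR gains over
  the common frequencies and Δ = mean CGR − mean OKR (negative Δ means
  vestibular input degrades gaze stabilization in light);
* agglomerative phenotype clustering (UPGMA, unweighted average Euclidean
  linkage) on the (mean aVOR, Δ) plane: the 2-cluster cut separates Δ+
  from Δ− animals and the next split inside Δ+ isolates the low-VOR
  subgroup;
* structure-function regressions of hair-cell marker counts on reflex
  gains.

QC-flagged gains remain usable in gain-based metrics; flagged phases never
enter any metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

COMMON_FREQS = (0.2, 0.5, 1.0)


class CohortError(ValueError):
    """Invalid cohort table or features."""


@dataclass
class IntegrationMetrics:
    animal_id: str
    mean_aVOR: float
    mean_OKR: float
    mean_CGR: float
    delta: float


@dataclass
class ClusterResult:
    linkage: np.ndarray          # scipy linkage matrix
    animal_ids: list
    labels: dict                 # animal_id -> DELTA_PLUS / DELTA_MINUS
    sublabels: dict = field(default_factory=dict)  # refined labels incl. low-VOR
    features: pd.DataFrame | None = None


def _gain_lookup(table: pd.DataFrame, modality: str, week=None) -> pd.DataFrame:
    df = table[table["modality"] == modality].copy()
    if week is not None:
        df = df[df["week"] == week]
    df["frequency_Hz"] = df["frequency_Hz"].astype(float).round(6)
    return df


def vestibular_weight(
    table: pd.DataFrame,
    baseline_week: int = 0,
    frequencies=COMMON_FREQS,
) -> pd.DataFrame:
    """Per-animal, per-frequency vestibular weight at baseline, in percent.

    w = g_aVOR / (g_aVOR + g_OKR); both gains must be present at the
    baseline week.  Scale-invariant in the two gains; 0 when the aVOR gain
    is 0 (and both are not 0).
    """
    vor = _gain_lookup(table, "VOR_DARK", baseline_week)
    okr = _gain_lookup(table, "OKR", baseline_week)
    freqs = [round(float(f), 6) for f in frequencies]
    merged = vor.merge(
        okr, on=["animal_id", "frequency_Hz"], suffixes=("_vor", "_okr"))
    merged = merged[merged["frequency_Hz"].isin(freqs)]
    denom = merged["gain_vor"] + merged["gain_okr"]
    w = np.where(denom > 0, merged["gain_vor"] / denom, np.nan)
    return pd.DataFrame({
        "animal_id": merged["animal_id"],
        "frequency_Hz": merged["frequency_Hz"],
        "weight_pct": 100.0 * w,
    })


def delta_gain(
    table: pd.DataFrame,
    reference_week: int = 0,
    percent: bool = False,
) -> pd.DataFrame:
    """Gain change per animal/modality/frequency relative to a reference week.

    Adds ``delta`` = gain(week) − gain(reference); with ``percent=True``
    also ``delta_pct`` = 100·delta/gain(reference).
    """
    df = table.copy()
    df["frequency_Hz"] = df["frequency_Hz"].astype(float).round(6)
    ref = df[df["week"] == reference_week]
    if ref.empty:
        raise CohortError(f"reference week {reference_week} absent")
    ref = ref.set_index(["animal_id", "modality", "frequency_Hz"])["gain"]
    keys = list(zip(df["animal_id"], df["modality"], df["frequency_Hz"]))
    base = np.array([ref.get(k, np.nan) for k in keys])
    out = df[["animal_id", "modality", "frequency_Hz", "week", "gain"]].copy()
    out["delta"] = df["gain"].to_numpy() - base
    if percent:
        with np.errstate(divide="ignore", invalid="ignore"):
            out["delta_pct"] = 100.0 * out["delta"].to_numpy() / base
    return out


def integration_delta(
    table: pd.DataFrame,
    week=None,
    frequencies=COMMON_FREQS,
) -> pd.DataFrame:
    """Per-animal integration metrics over the common frequencies.

    Gains are averaged across ``frequencies`` (optionally restricted to
    one or more weeks); Δ = mean CGR − mean OKR.  By linearity Δ equals
    the mean of the per-frequency differences when both are complete.
    """
    freqs = [round(float(f), 6) for f in frequencies]
    weeks = None if week is None else ([week] if np.isscalar(week) else list(week))
    rows = []
    for aid, sub in table.groupby("animal_id"):
        if weeks is not None:
            sub = sub[sub["week"].isin(weeks)]
        means = {}
        for modality, name in (("VOR_DARK", "mean_aVOR"), ("OKR", "mean_OKR"),
                               ("CGR", "mean_CGR")):
            sel = sub[(sub["modality"] == modality)
                      & (sub["frequency_Hz"].astype(float).round(6).isin(freqs))]
            means[name] = float(sel["gain"].mean()) if len(sel) else np.nan
        rows.append({
            "animal_id": aid, **means,
            "delta": means["mean_CGR"] - means["mean_OKR"],
        })
    return pd.DataFrame(rows)


def cluster_animals(
    features: pd.DataFrame,
    feature_cols=("mean_aVOR", "delta"),
    standardize: bool = False,
) -> ClusterResult:
    """UPGMA phenotype clustering on the (mean aVOR, Δ) plane.

    Unweighted average Euclidean linkage, no feature scaling by default.
    The 2-cluster cut labels the lower-Δ cluster ``DELTA_MINUS``; the next
    split inside the Δ+ cluster marks its lower-aVOR child
    ``DELTA_PLUS_LOWVOR`` in ``sublabels``.
    """
    ids = list(features["animal_id"])
    if len(ids) != len(set(ids)):
        raise CohortError("duplicate animal ids")
    if len(ids) < 4:
        raise CohortError("need at least 4 animals to cluster")
    X = features[list(feature_cols)].to_numpy(float)
    if not np.all(np.isfinite(X)):
        raise CohortError("non-finite features")
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0)

    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    two = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    delta_col = list(feature_cols).index("delta")
    means = {c: X[two == c, delta_col].mean() for c in np.unique(two)}
    minus_c = min(means, key=means.get)
    labels = {aid: ("DELTA_MINUS" if c == minus_c else "DELTA_PLUS")
              for aid, c in zip(ids, two)}

    sublabels = dict(labels)
    plus_ids = [aid for aid in ids if labels[aid] == "DELTA_PLUS"]
    if len(plus_ids) >= 2:
        left, right = _children_of_cluster(
            Z, [i for i, aid in enumerate(ids) if aid in set(plus_ids)])
        if left and right:
            vor_col = list(feature_cols).index("mean_aVOR")
            low = left if X[left, vor_col].mean() < X[right, vor_col].mean() else right
            for i in low:
                sublabels[ids[i]] = "DELTA_PLUS_LOWVOR"
    return ClusterResult(
        linkage=Z, animal_ids=ids, labels=labels, sublabels=sublabels,
        features=features.copy(),
    )


def _children_of_cluster(Z: np.ndarray, members: list):
    """Leaf sets of the two children of the smallest tree node containing
    exactly ``members``."""
    n = Z.shape[0] + 1
    leaves = {i: [i] for i in range(n)}
    target = set(members)
    for k in range(Z.shape[0]):
        a, b = int(Z[k, 0]), int(Z[k, 1])
        merged = leaves[a] + leaves[b]
        leaves[n + k] = merged
        if set(merged) == target:
            return leaves[a], leaves[b]
    return [], []


def structure_function_regression(
    counts: pd.DataFrame,
    gains: pd.DataFrame,
    organ_map: dict | None = None,
    week=None,
) -> pd.DataFrame:
    """OLS of hair-cell marker counts on the matching reflex gain.

    ``organ_map`` maps organ → (modality, frequency); by default the canal
    counts regress on the 1 Hz angular VOR gain and the utricule counts on
    the OCR slope.  Returns one row per (organ, zone, marker) with slope,
    intercept, r², two-sided p and n.
    """
    organ_map = organ_map or {
        "canal": ("VOR_DARK", 1.0), "utricule": ("OCR", 0.0)}
    gains = gains.copy()
    gains["frequency_Hz"] = gains["frequency_Hz"].astype(float).round(6)
    rows = []
    for (organ, zone, marker), sub in counts.groupby(["organ", "zone", "marker"]):
        modality, freq = organ_map[organ]
        gsel = gains[(gains["modality"] == modality)
                     & (gains["frequency_Hz"] == round(float(freq), 6))]
        if week is not None:
            gsel = gsel[gsel["week"] == week]
        elif "week" in sub.columns:
            gsel = gsel.merge(sub[["animal_id", "week"]].drop_duplicates(),
                              on=["animal_id", "week"])
        merged = sub.drop(columns=["gain"], errors="ignore").merge(
            gsel.groupby("animal_id", as_index=False)["gain"].mean(),
            on="animal_id")
        if len(merged) < 3:
            continue
        res = stats.linregress(merged["gain"], merged["count"])
        rows.append({
            "organ": organ, "zone": zone, "marker": marker,
            "slope": float(res.slope), "intercept": float(res.intercept),
            "r2": float(res.rvalue ** 2), "p": float(res.pvalue),
            "n": int(len(merged)),
        })
    return pd.DataFrame(rows)
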