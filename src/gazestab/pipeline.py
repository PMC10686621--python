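"""End-to-end pipeline: simulate → fit → model → sweep stats → cohort tables.

Every artifact is delimited text (or JSON) under a single output directory,
stamped with the configuration hash and seed so a rerun with the same
configuration reproduces all outputs byte-identically.

Stages
------
1. ``simulate``   — synthetic cohort + raw trace files + manifest.csv
2. ``fit``        — slow-phase extraction and reflex fits → fits.csv
3. ``cgr``        — shift optimization on controls + predictions.csv
4. ``sweeps``     — per-trial Rep/Amp → sweeps.csv
5. ``metrics``    — integration metrics, weights, clustering, hair-cell
                    count regressions → metrics.csv, clusters.json, ...
6. ``report``     — plain-text summary report.md
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gazestab import cgr as cgr_mod
from gazestab import cohort as cohort_mod
from gazestab import sweeps as sweeps_mod
from gazestab.fits import FitError, fit_ocr, fit_ovar, fit_sinusoid, qc_flag
from gazestab.preprocess import TrialRejected, extract_slow_phases, segment_cycles
from gazestab.synthetic import (
    AnimalSpec,
    CohortConfig,
    generate_cohort,
    synthesize_hc_counts,
    synthesize_ocr_trial,
    synthesize_ovar_trial,
    synthesize_sinusoid_trial,
    OKR_PEAK_VEL,
    OVAR_SPEED,
    VOR_PEAK_VEL,
)
from gazestab.trace import read_trace, write_trace

log = logging.getLogger("gazestab")

_FLOAT_FMT = "%.10g"
_MOD_CODE = {"VOR_DARK": 1, "OKR": 2, "CGR": 3, "OCR": 4, "OVAR": 5}


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage and trial."""


@dataclass
class PipelineConfig:
    """Validated configuration of a full run; unknown keys are rejected."""

    out_dir: str = "gazestab_run"
    n_sham: int = 4
    n_idpn: int = 6
    weeks: tuple = (0, 6, 12)
    frequencies: tuple = (0.2, 0.5, 1.0)
    n_cycles: int = 15
    include_ocr: bool = True
    include_ovar: bool = True
    detector_threshold: float | None = None
    detector_margin_s: float = 0.02
    min_cycles: int = 10
    sweep_bins: int = 128
    baseline_week: int = 0
    cluster_week: int = 6
    standardize_clustering: bool = False
    seed: int = 0
    log_level: str = "INFO"
    cohort_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        for key in ("weeks", "frequencies"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def cohort_config(self) -> CohortConfig:
        cc = CohortConfig(n_sham=self.n_sham, n_idpn=self.n_idpn,
                          weeks=tuple(self.weeks))
        known = {f.name for f in dataclasses.fields(CohortConfig)}
        unknown = set(self.cohort_overrides) - known
        if unknown:
            raise PipelineError(f"unknown cohort_overrides keys: {sorted(unknown)}")
        for k, v in self.cohort_overrides.items():
            setattr(cc, k, v)
        cc.validate()
        return cc

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _trial_seed(base_seed: int, animal_idx: int, week: int, modality: str,
                freq: float, extra: int = 0) -> int:
    ss = np.random.SeedSequence(
        [int(base_seed), animal_idx, week, _MOD_CODE[modality],
         int(round(freq * 1000)), extra])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _write_df(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def simulate_stage(config: PipelineConfig, out: Path) -> pd.DataFrame:
    """Generate the cohort and write one trace file per trial + manifest."""
    cc = config.cohort_config()
    cohort = generate_cohort(cc, seed=config.seed)
    tdir = out / "traces"
    tdir.mkdir(parents=True, exist_ok=True)
    rows = []

    def add(spec: AnimalSpec, week, modality, freq, trace, suffix=""):
        name = (f"{spec.animal_id}_w{week:02d}_{modality.lower()}"
                f"_{freq:g}hz{suffix}.tsv")
        write_trace(trace, tdir / name)
        rows.append({
            "animal_id": spec.animal_id, "group": spec.group,
            "subtype": spec.subtype, "week": week, "modality": modality,
            "frequency_Hz": freq, "trace_path": f"traces/{name}",
        })

    for idx, spec in enumerate(cohort):
        for week in config.weeks:
            for modality in ("VOR_DARK", "OKR", "CGR"):
                peak = OKR_PEAK_VEL if modality == "OKR" else VOR_PEAK_VEL
                for freq in config.frequencies:
                    tr = synthesize_sinusoid_trial(
                        spec, modality, freq, peak_vel=peak,
                        n_cycles=config.n_cycles, week=week,
                        seed=_trial_seed(config.seed, idx, week, modality, freq))
                    add(spec, week, modality, freq, tr)
            if config.include_ocr:
                tr = synthesize_ocr_trial(
                    spec, week=week,
                    seed=_trial_seed(config.seed, idx, week, "OCR", 0.0))
                add(spec, week, "OCR", 0.0, tr)
            if config.include_ovar:
                for d_i, direction in enumerate(("CCW", "CW")):
                    tr = synthesize_ovar_trial(
                        spec, direction=direction, week=week,
                        seed=_trial_seed(config.seed, idx, week, "OVAR", 0.0, d_i))
                    add(spec, week, "OVAR", round(OVAR_SPEED / 360.0, 6), tr,
                        suffix=f"_{direction.lower()}")
    manifest = pd.DataFrame(rows)
    _write_df(manifest, out / "manifest.csv")
    log.info("simulate: %d animals, %d trials", len(cohort), len(manifest))
    return manifest


def fit_stage(config: PipelineConfig, out: Path, manifest: pd.DataFrame) -> pd.DataFrame:
    """Fit every trial in the manifest; returns the long fit table."""
    rows = []
    n_rejected = 0
    for rec in manifest.itertuples(index=False):
        path = out / rec.trace_path
        if not path.exists():
            raise PipelineError(f"fit: missing trace file for trial "
                                f"{rec.animal_id} {rec.modality} ({path})")
        trace = read_trace(path)
        base = {
            "animal_id": rec.animal_id, "group": rec.group,
            "subtype": rec.subtype, "week": rec.week,
            "modality": rec.modality, "frequency_Hz": rec.frequency_Hz,
        }
        try:
            if rec.modality == "OCR":
                f = fit_ocr(trace)
                rows.append({**base, "gain": f.slope, "td_ms": np.nan,
                             "phase_deg": np.nan, "offset": f.intercept,
                             "VAF": f.r2, "n_cycles": f.n_plateaus,
                             "qc_flag": False, "direction": "NA"})
            elif rec.modality == "OVAR":
                series = extract_slow_phases(
                    trace, threshold=config.detector_threshold,
                    margin_s=config.detector_margin_s)
                f = fit_ovar(series, trace.peak_vel, trace.direction)
                rows.append({**base, "gain": f.beta, "td_ms": np.nan,
                             "phase_deg": f.phase0_deg, "offset": f.beta_raw,
                             "VAF": f.VAF, "n_cycles": np.nan,
                             "qc_flag": False, "direction": trace.direction})
            else:
                series = extract_slow_phases(
                    trace, threshold=config.detector_threshold,
                    margin_s=config.detector_margin_s)
                f = qc_flag(fit_sinusoid(series, min_cycles=config.min_cycles))
                rows.append({**base, "gain": f.g, "td_ms": f.td_ms,
                             "phase_deg": f.phase_deg, "offset": f.Cte,
                             "VAF": f.VAF, "n_cycles": f.n_cycles,
                             "qc_flag": f.qc_flag, "direction": "NA"})
        except (TrialRejected, FitError) as exc:
            n_rejected += 1
            log.warning("fit: rejected %s %s w%s %sHz: %s", rec.animal_id,
                        rec.modality, rec.week, rec.frequency_Hz, exc)
    fits = pd.DataFrame(rows)
    # OVAR: mean of the two direction-normalized biases per session
    ovar = fits[fits["modality"] == "OVAR"]
    extra = []
    for (aid, week), sub in ovar.groupby(["animal_id", "week"]):
        if len(sub) < 2:
            continue
        row = sub.iloc[0].to_dict()
        row.update({"gain": float(sub["gain"].mean()), "direction": "MEAN",
                    "offset": np.nan, "phase_deg": np.nan,
                    "VAF": float(sub["VAF"].mean())})
        extra.append(row)
    if extra:
        fits = pd.concat([fits, pd.DataFrame(extra)], ignore_index=True)
    _write_df(fits, out / "fits.csv")
    log.info("fit: %d fits, %d trials rejected", len(fits), n_rejected)
    return fits


def cgr_stage(config: PipelineConfig, out: Path, fits: pd.DataFrame):
    sham = fits[fits["group"] == "SHAM"]
    shifts = cgr_mod.optimize_shifts(sham, frequencies=config.frequencies)
    shifts.to_json(out / "shifts.json")
    predictions = cgr_mod.apply_model(fits, shifts)
    predictions = predictions.merge(
        fits[["animal_id", "group", "subtype"]].drop_duplicates(),
        on="animal_id", how="left")
    _write_df(predictions, out / "predictions.csv")
    log.info("cgr: %d predictions", len(predictions))
    return shifts, predictions


def sweeps_stage(config: PipelineConfig, out: Path, manifest: pd.DataFrame) -> pd.DataFrame:
    """Rep/Amp for every angular VOR trial."""
    rows = []
    vor = manifest[manifest["modality"] == "VOR_DARK"]
    for rec in vor.itertuples(index=False):
        trace = read_trace(out / rec.trace_path)
        try:
            series = extract_slow_phases(
                trace, threshold=config.detector_threshold,
                margin_s=config.detector_margin_s)
            sw = segment_cycles(series, K=config.sweep_bins)
            st = sweeps_mod.sweep_stats(sw)
        except (TrialRejected, sweeps_mod.SweepError) as exc:
            log.warning("sweeps: skipped %s w%s %sHz: %s", rec.animal_id,
                        rec.week, rec.frequency_Hz, exc)
            continue
        rows.append({
            "animal_id": rec.animal_id, "group": rec.group,
            "subtype": rec.subtype, "week": rec.week,
            "frequency_Hz": rec.frequency_Hz,
            "N": st.N, "Rep": st.Rep, "Amp": st.Amp,
        })
    df = pd.DataFrame(rows)
    _write_df(df, out / "sweeps.csv")
    return df


def metrics_stage(config: PipelineConfig, out: Path, fits: pd.DataFrame,
                  sweeps: pd.DataFrame, cohort_cc: CohortConfig):
    metrics = cohort_mod.integration_delta(
        fits, week=config.cluster_week, frequencies=config.frequencies)
    if not sweeps.empty:
        sw = (sweeps[sweeps["week"] == config.cluster_week]
              .groupby("animal_id", as_index=False)[["Rep", "Amp"]].mean())
        metrics = metrics.merge(sw, on="animal_id", how="left")
    meta = fits[["animal_id", "group", "subtype"]].drop_duplicates()
    metrics = metrics.merge(meta, on="animal_id", how="left")
    _write_df(metrics, out / "metrics.csv")

    weights = cohort_mod.vestibular_weight(
        fits, baseline_week=config.baseline_week,
        frequencies=config.frequencies)
    _write_df(weights, out / "weights.csv")

    clusters = None
    idpn = metrics[metrics["group"] == "IDPN"].dropna(subset=["mean_aVOR", "delta"])
    if len(idpn) >= 4:
        clusters = cohort_mod.cluster_animals(
            idpn, standardize=config.standardize_clustering)
        sizes = pd.Series(clusters.labels).value_counts().to_dict()
        (out / "clusters.json").write_text(json.dumps({
            "labels": clusters.labels,
            "sublabels": clusters.sublabels,
            "cluster_sizes": sizes,
            "linkage": clusters.linkage.tolist(),
        }, indent=1, sort_keys=True))
        log.info("metrics: cluster sizes %s", sizes)
    return metrics, weights, clusters


def counts_stage(config: PipelineConfig, out: Path, fits: pd.DataFrame):
    cohort = generate_cohort(config.cohort_config(), seed=config.seed)
    week = config.cluster_week if config.cluster_week in config.weeks else config.weeks[-1]
    counts = synthesize_hc_counts(cohort, seed=config.seed, week=week)
    _write_df(counts, out / "counts.csv")
    regressions = cohort_mod.structure_function_regression(counts, fits, week=week)
    _write_df(regressions, out / "regressions.csv")
    return counts, regressions


def report_stage(config: PipelineConfig, out: Path, fits, metrics, clusters):
    lines = ["# gazestab run report", ""]
    lines.append(f"- config hash: `{config.hash()}`  seed: {config.seed}")
    lines.append(f"- fits: {len(fits)} rows")
    for modality in ("VOR_DARK", "OKR", "CGR"):
        sub = fits[(fits["modality"] == modality) & (fits["week"] == config.cluster_week)]
        if len(sub):
            by_group = sub.groupby("group")["gain"].mean()
            desc = ", ".join(f"{g}: {v:.3f}" for g, v in by_group.items())
            lines.append(f"- mean {modality} gain at W{config.cluster_week}: {desc}")
    if clusters is not None:
        sizes = pd.Series(clusters.labels).value_counts().to_dict()
        lines.append(f"- phenotype clusters (IDPN): {sizes}")
    (out / "report.md").write_text("\n".join(lines) + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the artifact directory."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": dataclasses.asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
    }
    stage = "simulate"
    try:
        manifest = simulate_stage(config, out)
        stage = "fit"
        fits = fit_stage(config, out, manifest)
        stage = "cgr"
        cgr_result = cgr_stage(config, out, fits)
        stage = "sweeps"
        sweeps = sweeps_stage(config, out, manifest)
        stage = "metrics"
        metrics, weights, clusters = metrics_stage(
            config, out, fits, sweeps, config.cohort_config())
        stage = "counts"
        counts_stage(config, out, fits)
        stage = "report"
        report_stage(config, out, fits, metrics, clusters)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    (out / "run_meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True, default=str))
    return out
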