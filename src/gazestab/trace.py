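"""Raw oculography trial container and its on-disk format.

A trial is one continuous recording of eye position together with the
stimulus (turntable or optokinetic drum) position and velocity.  Eye video
tracking runs near 120 Hz while the stimulus channels are digitised near
1 kHz; after loading, all series live on the eye timebase (the stimulus is
linearly interpolated), so a :class:`RawTrace` always holds equal-length
arrays on a uniform time grid.

On disk a trial is a tab-separated table (one row per eye sample, columns
``t, eye_h, eye_v, stim_pos, stim_vel`` and optionally the generator's
ground-truth quick-phase flag ``qp_truth``) plus a JSON sidecar with the
acquisition metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MODALITIES = ("VOR_DARK", "OKR", "CGR", "OCR", "OVAR")
DIRECTIONS = ("CW", "CCW", "NA")

_COLUMNS = ("t", "eye_h", "eye_v", "stim_pos", "stim_vel")


class TraceError(ValueError):
    """Malformed trace file or inconsistent trial data."""


@dataclass
class RawTrace:
    """One trial's synchronized eye and stimulus series.

    Attributes
    ----------
    t : ndarray
        Sample times in seconds, strictly increasing, uniform grid.
    eye_h, eye_v : ndarray
        Horizontal / vertical eye position in degrees.
    stim_pos, stim_vel : ndarray
        Stimulus position (deg) and velocity (deg/s), resampled onto the
        eye timebase.
    modality : str
        One of ``VOR_DARK, OKR, CGR, OCR, OVAR``.
    frequency_Hz : float
        Stimulation frequency for sinusoidal modalities; for OVAR the table
        rotation frequency (speed/360); 0 for OCR.
    peak_vel : float
        Stimulus peak velocity in deg/s (or rotation speed for OVAR).
    eye_rate_Hz, stim_rate_Hz : float
        Native acquisition rates before resampling.
    direction : str
        Rotation direction for OVAR, else ``NA``.
    qp_truth : ndarray or None
        Generator ground-truth boolean mask of quick-phase samples
        (synthetic trials only).
    meta : dict
        Free-form extra metadata (animal id, week, seed, tilt schedule...).
    """

    t: np.ndarray
    eye_h: np.ndarray
    eye_v: np.ndarray
    stim_pos: np.ndarray
    stim_vel: np.ndarray
    modality: str
    frequency_Hz: float
    peak_vel: float
    eye_rate_Hz: float = 120.0
    stim_rate_Hz: float = 1000.0
    direction: str = "NA"
    qp_truth: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("eye_h", "eye_v", "stim_pos", "stim_vel"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.t.shape:
                raise TraceError(
                    f"column {name!r} has length {arr.size}, expected {self.t.size}"
                )
            setattr(self, name, arr)
        if self.t.size < 2:
            raise TraceError("trace needs at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise TraceError("time column must be strictly increasing")
        if self.modality not in MODALITIES:
            raise TraceError(f"unknown modality {self.modality!r}")
        if self.direction not in DIRECTIONS:
            raise TraceError(f"unknown direction {self.direction!r}")
        if self.qp_truth is not None:
            self.qp_truth = np.asarray(self.qp_truth, dtype=bool)
            if self.qp_truth.shape != self.t.shape:
                raise TraceError("qp_truth length mismatch")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    def reference_velocity(self) -> np.ndarray:
        """Signed compensatory reference in deg/s.

        An ideal compensatory response tracks ``−stimulus velocity`` for
        vestibular rotations (VOR in dark or in light) and ``+drum
        velocity`` for the optokinetic reflex, so under this convention a
        perfect reflex has gain 1 and phase 0 for every modality.
        """
        if self.modality in ("VOR_DARK", "CGR", "OVAR"):
            return -self.stim_vel
        if self.modality == "OKR":
            return self.stim_vel
        raise TraceError(f"no velocity reference for modality {self.modality!r}")

    def copy(self) -> "RawTrace":
        out = replace(self)
        for name in ("t", "eye_h", "eye_v", "stim_pos", "stim_vel"):
            setattr(out, name, getattr(self, name).copy())
        if self.qp_truth is not None:
            out.qp_truth = self.qp_truth.copy()
        out.meta = dict(self.meta)
        return out


def align_to_eye_timebase(
    t_eye: np.ndarray, t_stim: np.ndarray, stim_pos: np.ndarray, stim_vel: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate stimulus channels onto the eye sample times."""
    t_eye = np.asarray(t_eye, float)
    t_stim = np.asarray(t_stim, float)
    pos = np.interp(t_eye, t_stim, np.asarray(stim_pos, float))
    vel = np.interp(t_eye, t_stim, np.asarray(stim_vel, float))
    return pos, vel


def write_trace(trace: RawTrace, path: str | Path) -> Path:
    """Write a trial as TSV plus JSON sidecar; returns the TSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = {name: getattr(trace, name) for name in _COLUMNS}
    if trace.qp_truth is not None:
        cols["qp_truth"] = trace.qp_truth.astype(int)
    df = pd.DataFrame(cols)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    sidecar = {
        "modality": trace.modality,
        "frequency_Hz": trace.frequency_Hz,
        "peak_vel": trace.peak_vel,
        "eye_rate_Hz": trace.eye_rate_Hz,
        "stim_rate_Hz": trace.stim_rate_Hz,
        "direction": trace.direction,
        "meta": _jsonable(trace.meta),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True)
    )
    return path


def read_trace(path: str | Path) -> RawTrace:
    """Read a trial written by :func:`write_trace`.

    Raises
    ------
    TraceError
        On missing columns, non-monotonic time, or a missing sidecar.
    """
    path = Path(path)
    if not path.exists():
        raise TraceError(f"trace file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise TraceError(f"{path}: missing columns {missing}")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise TraceError(f"sidecar not found: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    qp = df["qp_truth"].to_numpy(bool) if "qp_truth" in df.columns else None
    return RawTrace(
        t=df["t"].to_numpy(),
        eye_h=df["eye_h"].to_numpy(),
        eye_v=df["eye_v"].to_numpy(),
        stim_pos=df["stim_pos"].to_numpy(),
        stim_vel=df["stim_vel"].to_numpy(),
        modality=sidecar["modality"],
        frequency_Hz=float(sidecar["frequency_Hz"]),
        peak_vel=float(sidecar["peak_vel"]),
        eye_rate_Hz=float(sidecar.get("eye_rate_Hz", 120.0)),
        stim_rate_Hz=float(sidecar.get("stim_rate_Hz", 1000.0)),
        direction=sidecar.get("direction", "NA"),
        qp_truth=qp,
        meta=sidecar.get("meta", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
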