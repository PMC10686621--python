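"""Sweep reproducibility and amplitude statistics.

These two statistics describe the vestibular response without assuming it
is sinusoidal.  Working on the per-cycle slow-phase position trajectories
(sweeps):

* ``Rep`` — the mean of the above-diagonal entries of the N×N matrix of
  pairwise Pearson correlations between sweeps.  Identical sweeps give 1;
  uncorrelated noise gives ~0; cycle-to-cycle gain jitter drives it down.
* ``Amp`` — for each sweep the dispersion σ of the position about the
  sweep mean; Amp is the root of the mean of σ² across sweeps (degrees).

Sweeps may have missing bins (saccade gaps): correlations use the
pairwise-overlapping valid bins, and entries with too little overlap or a
constant sweep are treated as missing with the averaging denominator
adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gazestab.preprocess import Sweep, extract_slow_phases, segment_cycles
from gazestab.trace import RawTrace

MIN_OVERLAP_FRAC = 0.5


class SweepError(ValueError):
    """Not enough sweep data for the requested statistic."""


@dataclass
class SweepCorrelationMatrix:
    N: int
    R: np.ndarray             # N×N, NaN where missing
    valid_overlap: np.ndarray  # N×N counts of bins used


@dataclass
class SweepStats:
    Rep: float
    Amp: float
    N: int
    sigma_EHp: np.ndarray  # per-sweep position dispersion (deg)


def sweep_correlation_matrix(
    sweeps: list[Sweep],
    min_overlap_frac: float = MIN_OVERLAP_FRAC,
) -> SweepCorrelationMatrix:
    """Pairwise Pearson correlations of mean-centred sweep trajectories.

    Pairs sharing fewer than ``min_overlap_frac`` of their bins, or
    involving a constant trajectory on the overlap, are marked missing
    (NaN).
    """
    n = len(sweeps)
    if n < 2:
        raise SweepError("need at least 2 sweeps")
    K = sweeps[0].K
    if any(s.K != K for s in sweeps):
        raise SweepError("sweeps must share the same bin count")
    P = np.stack([s.pos for s in sweeps])
    V = np.stack([s.valid for s in sweeps])

    R = np.full((n, n), np.nan)
    overlap = np.zeros((n, n), dtype=int)
    np.fill_diagonal(R, 1.0)
    np.fill_diagonal(overlap, V.sum(axis=1))
    min_bins = int(np.ceil(min_overlap_frac * K))
    for i in range(n):
        for j in range(i + 1, n):
            both = V[i] & V[j]
            m = int(both.sum())
            overlap[i, j] = overlap[j, i] = m
            if m < max(min_bins, 2):
                continue
            x, y = P[i, both], P[j, both]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
            R[i, j] = R[j, i] = r
    return SweepCorrelationMatrix(N=n, R=R, valid_overlap=overlap)


def reproducibility(matrix: SweepCorrelationMatrix) -> float:
    """Rep: mean of the non-missing above-diagonal correlation entries."""
    iu = np.triu_indices(matrix.N, k=1)
    vals = matrix.R[iu]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise SweepError("all sweep pairs missing")
    return float(vals.mean())


def sweep_amplitude(sweeps: list[Sweep]) -> float:
    """Amp: root mean square across sweeps of the per-sweep position SD.

    σ uses the population convention (divide by n) since σ² enters a
    plain mean.
    """
    if not sweeps:
        raise SweepError("empty sweep set")
    sig2 = []
    for s in sweeps:
        x = s.pos[s.valid]
        if x.size == 0:
            continue
        sig2.append(float(np.mean((x - x.mean()) ** 2)))
    if not sig2:
        raise SweepError("no valid bins in any sweep")
    return float(np.sqrt(np.mean(sig2)))


def per_sweep_sigma(sweeps: list[Sweep]) -> np.ndarray:
    return np.array([
        float(np.std(s.pos[s.valid])) if s.valid.any() else np.nan
        for s in sweeps
    ])


def sweep_stats(
    trace_or_sweeps: RawTrace | list,
    K: int = 128,
    min_overlap_frac: float = MIN_OVERLAP_FRAC,
) -> SweepStats:
    """Convenience chain: trace (or pre-cut sweeps) → Rep and Amp."""
    if isinstance(trace_or_sweeps, RawTrace):
        series = extract_slow_phases(trace_or_sweeps)
        sweeps = segment_cycles(series, K=K)
    else:
        sweeps = trace_or_sweeps
    mat = sweep_correlation_matrix(sweeps, min_overlap_frac=min_overlap_frac)
    return SweepStats(
        Rep=reproducibility(mat),
        Amp=sweep_amplitude(sweeps),
        N=len(sweeps),
        sigma_EHp=per_sweep_sigma(sweeps),
    )
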