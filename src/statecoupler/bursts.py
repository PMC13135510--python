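"""Beta-burst detection on an LFP channel and burst/state overlap.

A burst is a maximal run of samples where the band-limited amplitude
envelope strictly exceeds the scan's percentile threshold for at least the
minimum duration.  Overlap with a network state is the percentage of that
state's occurrence time during which a burst was ongoing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal


@dataclass
class BurstSet:
    """Sorted, disjoint half-open burst intervals in samples."""

    intervals: list[tuple[int, int]]
    threshold_value: float
    fs: float
    band: tuple[float, float] = (13.0, 30.0)
    min_duration_s: float = 0.1
    peak_envelope: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -1
        n_min = int(round(self.min_duration_s * self.fs))
        for start, end in self.intervals:
            if end - start < max(n_min, 1):
                raise ValueError("interval shorter than minimum duration")
            if start <= prev_end:
                raise ValueError("intervals must be sorted and disjoint")
            prev_end = end

    @property
    def n_bursts(self) -> int:
        return len(self.intervals)

    def indicator(self, n_samples: int) -> np.ndarray:
        out = np.zeros(n_samples, dtype=bool)
        for start, end in self.intervals:
            out[start:end] = True
        return out

    def total_burst_samples(self) -> int:
        return sum(end - start for start, end in self.intervals)


@dataclass
class OverlapResult:
    """Burst overlap of one state vs. all remaining states pooled."""

    state: int
    overlap_pct: float
    other_pct: float
    contrast_pct: float


def amplitude_envelope(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = (13.0, 30.0),
    good_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Z-score, band-pass, and take the analytic-signal magnitude."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single-channel series")
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError("band must lie below Nyquist")
    # require a few cycles of the low edge for filter warm-up
    if x.size < int(3 * fs / lo):
        raise ValueError("series too short for the band-pass warm-up")
    good = (
        np.ones(x.size, dtype=bool)
        if good_mask is None
        else np.asarray(good_mask, dtype=bool)
    )
    sd = x[good].std()
    if sd == 0:
        raise ValueError("zero-variance input cannot be z-scored")
    z = (x - x[good].mean()) / sd
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, z)
    return np.abs(signal.hilbert(filtered))


def detect_bursts(
    envelope: np.ndarray,
    fs: float,
    percentile: float = 75.0,
    min_duration_s: float = 0.1,
    band: tuple[float, float] = (13.0, 30.0),
    good_mask: np.ndarray | None = None,
) -> BurstSet:
    """Maximal strictly-supra-threshold runs of at least the minimum length.

    The threshold is the given percentile of the scan's envelope computed
    over good samples; samples exactly at the threshold do not count.
    """
    env = np.asarray(envelope, dtype=float)
    if not np.all(np.isfinite(env)):
        raise ValueError("envelope must be finite")
    good = (
        np.ones(env.size, dtype=bool)
        if good_mask is None
        else np.asarray(good_mask, dtype=bool)
    )
    threshold = float(np.percentile(env[good], percentile))
    above = (env > threshold) & good
    n_min = max(1, int(round(min_duration_s * fs)))

    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    intervals = []
    peaks = []
    for start, end in zip(edges[::2], edges[1::2]):
        if end - start >= n_min:
            intervals.append((int(start), int(end)))
            peaks.append(float(env[start:end].max()))
    return BurstSet(
        intervals=intervals,
        threshold_value=threshold,
        fs=fs,
        band=band,
        min_duration_s=min_duration_s,
        peak_envelope=peaks,
    )


def burst_state_overlap(
    bursts: BurstSet,
    gamma: np.ndarray,
    state: int,
    weighted: bool = False,
) -> OverlapResult:
    """Overlap of bursts with one 1-based state vs. all other states.

    States are binarized per sample as the argmax over posterior
    probabilities (ties break to the lowest state index); rows with NaN
    posteriors are excluded.  With ``weighted`` the posterior probability
    itself replaces the hard indicator.
    """
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    T, K = gamma.shape
    if not 1 <= state <= K:
        raise ValueError("state out of range")
    valid = np.all(np.isfinite(gamma), axis=1)
    burst = bursts.indicator(T)

    if weighted:
        w_state = np.where(valid, gamma[:, state - 1], 0.0)
        w_other = np.where(valid, 1.0 - gamma[:, state - 1], 0.0)
    else:
        hard = np.argmax(gamma, axis=1) + 1
        w_state = (valid & (hard == state)).astype(float)
        w_other = (valid & (hard != state)).astype(float)

    denom_state = w_state.sum()
    if denom_state == 0:
        return OverlapResult(
            state=state, overlap_pct=np.nan, other_pct=np.nan, contrast_pct=np.nan
        )
    overlap = 100.0 * float(burst @ w_state) / denom_state
    denom_other = w_other.sum()
    other = (
        100.0 * float(burst @ w_other) / denom_other if denom_other > 0 else np.nan
    )
    contrast = overlap - other if np.isfinite(other) else np.nan
    return OverlapResult(
        state=state, overlap_pct=overlap, other_pct=other, contrast_pct=contrast
    )


def overlap_table(bursts: BurstSet, gamma: np.ndarray) -> list[OverlapResult]:
    """Overlap results for every state."""
    K = np.atleast_2d(gamma).shape[1]
    return [burst_state_overlap(bursts, gamma, k) for k in range(1, K + 1)]


def bursts_to_records(bursts: BurstSet) -> list[dict]:
    """Rows of (start_s, end_s, duration_s, peak_envelope) for CSV export."""
    rows = []
    for i, (start, end) in enumerate(bursts.intervals):
        rows.append(
            {
                "start_s": start / bursts.fs,
                "end_s": end / bursts.fs,
                "duration_s": (end - start) / bursts.fs,
                "peak_envelope": bursts.peak_envelope[i]
                if i < len(bursts.peak_envelope)
                else float("nan"),
            }
        )
    return rows
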