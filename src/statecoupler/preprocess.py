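"""Recording conditioning: filtering, resampling, standardization, bad segments.

Filtering is zero-phase (forward-backward IIR) so burst timing and state
alignment are not phase-shifted.  Bad segments are detected per 2-s window
from the window standard deviation via the GESD outlier test, applied to
both raw and first-difference signals within each channel role, with the
final mask being the union across signal groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .permstats import gesd
from .recording import Recording


@dataclass
class FilterSpec:
    """Band-pass + notch + resample specification.

    ``band`` is (low_hz, high_hz); set ``low_hz`` to 0 for a pure low-pass
    and ``high_hz`` to None for a pure high-pass.  ``fs_out`` of None keeps
    the input rate.
    """

    band: tuple[float, float | None] = (0.5, 125.0)
    order: int = 5
    notches: tuple[float, ...] = ()
    fs_out: float | None = None

    def validate(self, fs: float) -> None:
        low, high = self.band
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if low < 0:
            raise ValueError("band low edge must be >= 0")
        if high is not None:
            if high > fs / 2:
                raise ValueError("band high edge must not exceed Nyquist")
            if low >= high:
                raise ValueError("band low edge must be below high edge")
        if self.fs_out is not None and self.fs_out > fs:
            raise ValueError("fs_out must not exceed the input rate")
        for f0 in self.notches:
            if not 0 < f0 < fs / 2:
                raise ValueError("notch frequency must lie in (0, Nyquist)")


def _bandpass_sos(spec: FilterSpec, fs: float) -> np.ndarray | None:
    low, high = spec.band
    at_nyquist = high is not None and high >= fs / 2 - 1e-9
    if high is None or at_nyquist:
        if low <= 0:
            return None  # full band: identity
        return signal.butter(spec.order, low, btype="highpass", fs=fs, output="sos")
    if low <= 0:
        return signal.butter(spec.order, high, btype="lowpass", fs=fs, output="sos")
    return signal.butter(
        spec.order, [low, high], btype="bandpass", fs=fs, output="sos"
    )


def filter_resample(rec: Recording, spec: FilterSpec) -> Recording:
    """Zero-phase band-pass, then notches, then anti-aliased resampling."""
    spec.validate(rec.fs)
    data = rec.data
    sos = _bandpass_sos(spec, rec.fs)
    if sos is not None:
        data = signal.sosfiltfilt(sos, data, axis=1)
    for f0 in spec.notches:
        b, a = signal.iirnotch(f0, Q=30.0, fs=rec.fs)
        data = signal.filtfilt(b, a, data, axis=1)

    fs_out = spec.fs_out if spec.fs_out is not None else rec.fs
    bad = rec.bad_mask
    if fs_out != rec.fs:
        frac = Fraction(fs_out / rec.fs).limit_denominator(1000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=1)
        # carry the mask: an output sample is bad if its source window was
        idx = np.minimum(
            (np.arange(data.shape[1]) * rec.fs / fs_out).astype(int),
            rec.n_samples - 1,
        )
        bad = rec.bad_mask[idx]
    return rec.copy_with(data=data, fs=float(fs_out), bad_mask=bad)


def standardize(rec: Recording) -> Recording:
    """Zero-mean, unit-variance per channel over good samples."""
    good = rec.good_mask()
    if not np.any(good):
        raise ValueError("no good samples to standardize over")
    mean = rec.data[:, good].mean(axis=1, keepdims=True)
    sd = rec.data[:, good].std(axis=1, keepdims=True)
    zero = np.flatnonzero(sd[:, 0] == 0)
    if zero.size:
        names = ", ".join(rec.channel_labels[i] for i in zero)
        raise ValueError(f"constant channel(s) cannot be standardized: {names}")
    return rec.copy_with(data=(rec.data - mean) / sd)


def detect_bad_segments(
    rec: Recording,
    window_s: float = 2.0,
    alpha: float = 0.05,
    max_outlier_frac: float = 0.20,
) -> np.ndarray:
    """GESD bad-window mask from windowed standard deviations.

    The recording is tiled into non-overlapping windows; a trailing partial
    window is not tested and stays good.  Per channel-role group, the mean
    window std (over channels in the group) of the raw and first-difference
    signals is screened with GESD; flagged windows from every group are
    unioned into the returned per-sample mask.
    """
    win = int(round(window_s * rec.fs))
    if win > rec.n_samples:
        raise ValueError("window longer than recording")
    n_win = rec.n_samples // win
    if n_win < 2:
        raise ValueError("need at least 2 windows")

    mask = np.zeros(rec.n_samples, dtype=bool)
    roles = sorted(set(rec.channel_roles))
    for role in roles:
        rows = [i for i, r in enumerate(rec.channel_roles) if r == role]
        for differenced in (False, True):
            sig = rec.data[rows]
            if differenced:
                sig = np.diff(sig, axis=1, prepend=sig[:, :1])
            trimmed = sig[:, : n_win * win].reshape(len(rows), n_win, win)
            window_std = trimmed.std(axis=2).mean(axis=0)  # mean over channels
            if n_win < 3:
                continue  # GESD degenerate: too few windows to test
            max_out = max(1, int(np.ceil(max_outlier_frac * n_win)))
            max_out = min(max_out, (n_win - 1) // 2)
            if max_out < 1:
                continue
            result = gesd(window_std, alpha=alpha, max_outliers=max_out)
            for w in result.outlier_indices:
                mask[w * win : (w + 1) * win] = True
    return mask
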