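"""State-weighted multitaper cross-spectra, coherence and band summaries.

The recording is tiled into windows; each window gets a multitaper
cross-spectral matrix and a per-state weight equal to the mean posterior
state probability over the window.  The state-k cross-spectral density is
the weight-normalized average of window CSDs, so states pool every period
in which they occur.  Because per-window state weights sum to one, the
occupancy-weighted average of state CSDs equals the plain all-window CSD
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal


@dataclass
class TaperSet:
    """Orthonormal DPSS (Slepian) tapers for one analysis window."""

    window_s: float
    n_tapers: int
    fs: float
    half_bandwidth_hz: float
    tapers: np.ndarray  # (n_tapers, window_samples)

    @property
    def window_samples(self) -> int:
        return self.tapers.shape[1]


def make_tapers(
    window_s: float = 2.0,
    n_tapers: int = 7,
    fs: float = 250.0,
    half_bandwidth_hz: float | None = None,
) -> TaperSet:
    """Build a DPSS taper set.

    When ``half_bandwidth_hz`` is omitted it follows from the taper-count
    relation K = 2TW - 1, i.e. W = (K + 1) / (2T); a 2-s window with seven
    tapers therefore gives 2 Hz.  An explicit half-bandwidth must satisfy
    the stability bound K <= 2TW - 1.
    """
    if n_tapers < 1:
        raise ValueError("n_tapers must be >= 1")
    if window_s <= 0 or fs <= 0:
        raise ValueError("window_s and fs must be positive")
    if half_bandwidth_hz is None:
        half_bandwidth_hz = (n_tapers + 1) / (2.0 * window_s)
    else:
        if n_tapers > 2 * window_s * half_bandwidth_hz - 1:
            raise ValueError(
                "n_tapers exceeds the 2TW - 1 stability bound for this bandwidth"
            )
    n = int(round(window_s * fs))
    nw = window_s * half_bandwidth_hz
    tapers = signal.windows.dpss(n, NW=nw, Kmax=n_tapers)
    return TaperSet(
        window_s=window_s,
        n_tapers=n_tapers,
        fs=fs,
        half_bandwidth_hz=float(half_bandwidth_hz),
        tapers=np.atleast_2d(tapers),
    )


@dataclass
class StateSpectra:
    """Per-state Hermitian cross-spectral matrices over a frequency axis."""

    freqs: np.ndarray  # (F,)
    csd: np.ndarray  # (K, C, C, F), NaN for zero-weight states
    weights: np.ndarray  # (K,) total gamma mass per state
    fo: np.ndarray  # (K,) normalized weights
    channel_labels: list[str]
    n_windows: int

    @property
    def n_states(self) -> int:
        return self.csd.shape[0]

    def defined_states(self) -> np.ndarray:
        return self.weights > 0

    def power(self, channel: str, state: int) -> np.ndarray:
        """Real power spectrum of one channel in one 1-based state."""
        i = self.channel_labels.index(channel)
        return np.real(self.csd[state - 1, i, i])


@dataclass
class CoherenceSpectrum:
    freqs: np.ndarray
    values: np.ndarray
    kind: str  # "magnitude" | "imaginary"
    pair: tuple[str, str]


def _window_starts(
    n_samples: int, win: int, overlap: float, usable: np.ndarray
) -> list[int]:
    step = max(1, int(round(win * (1.0 - overlap))))
    starts = []
    for s in range(0, n_samples - win + 1, step):
        if np.all(usable[s : s + win]):
            starts.append(s)
    return starts


def state_weighted_csd(
    data: np.ndarray,
    fs: float,
    gamma: np.ndarray,
    tapers: TaperSet,
    channel_labels: list[str] | None = None,
    bad_mask: np.ndarray | None = None,
    overlap: float = 0.0,
) -> StateSpectra:
    """State-weighted multitaper CSD from channels x samples data.

    ``gamma`` is (n_samples, K) posterior state probabilities on the same
    sample axis as ``data``; rows of NaN (e.g. embedding margins) and bad
    samples exclude any window that touches them.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    C, T = data.shape
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    if gamma.shape[0] != T:
        raise ValueError("gamma must be aligned to the sample axis")
    K = gamma.shape[1]
    if channel_labels is None:
        channel_labels = [f"ch{i}" for i in range(C)]
    if tapers.fs != fs:
        raise ValueError("taper set built for a different sampling rate")
    win = tapers.window_samples
    if win > T:
        raise ValueError("window longer than recording")

    usable = np.all(np.isfinite(gamma), axis=1)
    if bad_mask is not None:
        usable &= ~np.asarray(bad_mask, dtype=bool)
    starts = _window_starts(T, win, overlap, usable)
    if not starts:
        raise ValueError("no usable windows")

    freqs = np.fft.rfftfreq(win, d=1.0 / fs)
    F = freqs.size
    csd_acc = np.zeros((K, C, C, F), dtype=complex)
    weight_acc = np.zeros(K)
    one_sided = np.full(F, 2.0)
    one_sided[0] = 1.0
    if win % 2 == 0:
        one_sided[-1] = 1.0

    for s in starts:
        seg = data[:, s : s + win]
        w_k = gamma[s : s + win].mean(axis=0)
        # (n_tapers, C, F) tapered spectra
        Z = np.fft.rfft(tapers.tapers[:, None, :] * seg[None, :, :], axis=2)
        P = np.einsum("mif,mjf->ijf", Z, np.conj(Z)) / tapers.n_tapers
        P *= one_sided / fs
        csd_acc += w_k[:, None, None, None] * P[None]
        weight_acc += w_k

    csd = np.full((K, C, C, F), np.nan, dtype=complex)
    defined = weight_acc > 0
    csd[defined] = csd_acc[defined] / weight_acc[defined, None, None, None]
    fo = weight_acc / weight_acc.sum()
    return StateSpectra(
        freqs=freqs,
        csd=csd,
        weights=weight_acc,
        fo=fo,
        channel_labels=list(channel_labels),
        n_windows=len(starts),
    )


def coherence_from_csd(
    csd: np.ndarray, i: int, j: int, kind: str = "magnitude"
) -> np.ndarray:
    """Coherence of channels i, j from a (C, C, F) cross-spectral matrix."""
    sxx = np.real(csd[i, i])
    syy = np.real(csd[j, j])
    sxy = csd[i, j]
    denom = np.sqrt(sxx * syy)
    with np.errstate(divide="ignore", invalid="ignore"):
        coherency = np.where(denom > 0, sxy / denom, np.nan)
    if kind == "magnitude":
        return np.abs(coherency)
    if kind == "imaginary":
        return np.abs(np.imag(coherency))
    raise ValueError(f"unknown coherence kind {kind!r}")


def coherence(
    spectra: StateSpectra,
    pair: tuple[str, str],
    kind: str = "magnitude",
    state: int = 1,
) -> CoherenceSpectrum:
    """Coherence spectrum for a channel pair in one 1-based state."""
    i = spectra.channel_labels.index(pair[0])
    j = spectra.channel_labels.index(pair[1])
    values = coherence_from_csd(spectra.csd[state - 1], i, j, kind)
    return CoherenceSpectrum(
        freqs=spectra.freqs, values=values, kind=kind, pair=tuple(pair)
    )


def time_average_csd(spectra: StateSpectra) -> np.ndarray:
    """Occupancy-weighted average of state CSDs = the all-window CSD."""
    defined = spectra.defined_states()
    fo = spectra.fo[defined] / spectra.fo[defined].sum()
    return np.einsum("k,kijf->ijf", fo, spectra.csd[defined])


def time_average_spectrum(
    spectra: StateSpectra, channel: str
) -> np.ndarray:
    """Time-averaged (across states) power spectrum of one channel."""
    i = spectra.channel_labels.index(channel)
    return np.real(time_average_csd(spectra)[i, i])


def band_power(
    values: np.ndarray, freqs: np.ndarray, band: tuple[float, float] = (13.0, 30.0)
) -> float:
    """Mean power over frequencies inside [low, high] inclusive."""
    lo, hi = band
    sel = (freqs >= lo) & (freqs <= hi)
    if not np.any(sel):
        raise ValueError("no frequencies inside the requested band")
    return float(np.mean(values[sel]))


def threshold_network(values: np.ndarray, percentile: float = 98.0) -> np.ndarray:
    """Boolean mask of values strictly above the given percentile."""
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size < 1:
        raise ValueError("need at least one finite value")
    cut = np.percentile(finite, percentile)
    return values > cut


def align_gamma(
    gamma: np.ndarray, n_lags_each_side: int, n_samples: int
) -> np.ndarray:
    """Pad embedded-row posteriors back onto the recording sample axis.

    Embedded row t corresponds to recording sample t + L; the L margin
    samples at each end get NaN rows.
    """
    L = n_lags_each_side
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    if gamma.shape[0] + 2 * L != n_samples:
        raise ValueError("gamma rows + 2L must equal n_samples")
    pad = np.full((L, gamma.shape[1]), np.nan)
    return np.vstack([pad, gamma, pad])
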