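"""Ground-truth-labelled synthetic recordings with Markov state switching.

Each channel is a sum of state-gated, band-limited stochastic oscillations
(band-pass-filtered Gaussian noise) plus white noise.  Couplings inject a
shared band-limited component into a source and a target channel while
designated states are active, creating coherence confined to that band and
those states.  Paired "off"/"on" cohorts scale the LFP beta amplitude in
designated states to emulate a medication effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .recording import Recording

BETA_BAND = (13.0, 30.0)


# ------------------------------------------------------------------ types


@dataclass
class MarkovSpec:
    """Discrete-time Markov chain over ``n_states`` states (1-based labels)."""

    n_states: int
    transition: np.ndarray
    initial: np.ndarray

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        K = self.n_states
        if self.transition.shape != (K, K):
            raise ValueError("transition must be K x K")
        if np.any(self.transition < 0) or np.any(self.initial < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        if self.initial.shape != (K,):
            raise ValueError("initial must have length K")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-12):
            raise ValueError("initial must sum to 1")

    @classmethod
    def uniform_sticky(cls, n_states: int, stay_prob: float) -> "MarkovSpec":
        """Chain with common stay probability and uniform off-diagonal mass."""
        K = n_states
        off = (1.0 - stay_prob) / (K - 1) if K > 1 else 0.0
        A = np.full((K, K), off)
        np.fill_diagonal(A, stay_prob if K > 1 else 1.0)
        return cls(K, A, np.full(K, 1.0 / K))


@dataclass
class OscillatorSpec:
    """Band-limited stochastic oscillation: center, full bandwidth, gain.

    ``amplitude`` is the RMS of the generated component, so component power
    scales as ``amplitude ** 2``.
    """

    center_hz: float
    bandwidth_hz: float
    amplitude: float

    def validate(self, fs: float) -> None:
        if not 0 < self.center_hz < fs / 2:
            raise ValueError("center_hz must lie in (0, fs/2)")
        if self.bandwidth_hz <= 0:
            raise ValueError("bandwidth_hz must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    def band_edges(self) -> tuple[float, float]:
        half = self.bandwidth_hz / 2.0
        return (self.center_hz - half, self.center_hz + half)

    def in_beta_band(self) -> bool:
        lo, hi = BETA_BAND
        return lo <= self.center_hz <= hi


@dataclass
class CouplingSpec:
    """Shared band-limited component between two channels in given states."""

    source_channel: str
    target_channel: str
    active_states: frozenset[int]
    band: OscillatorSpec
    mixing: float

    def __post_init__(self) -> None:
        self.active_states = frozenset(int(s) for s in self.active_states)
        if self.source_channel == self.target_channel:
            raise ValueError("source and target channels must differ")
        if self.mixing < 0:
            raise ValueError("mixing must be non-negative")


@dataclass
class GroundTruth:
    """Labels the generator knows: the state path, couplings, gains."""

    state_sequence: np.ndarray
    burst_intervals: list[tuple[int, int]] = field(default_factory=list)
    coupling_specs: list[CouplingSpec] = field(default_factory=list)
    medication_scalers: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.state_sequence = np.asarray(self.state_sequence, dtype=int)
        prev_end = -1
        for start, end in self.burst_intervals:
            if start >= end:
                raise ValueError("intervals must be non-empty half-open")
            if start <= prev_end:
                raise ValueError("intervals must be sorted, non-overlapping")
            prev_end = end

    def to_json(self) -> str:
        payload = {
            "state_sequence": self.state_sequence.tolist(),
            "burst_intervals": [list(iv) for iv in self.burst_intervals],
            "coupling_specs": [
                {
                    "source_channel": c.source_channel,
                    "target_channel": c.target_channel,
                    "active_states": sorted(c.active_states),
                    "band": vars(c.band),
                    "mixing": c.mixing,
                }
                for c in self.coupling_specs
            ],
            "medication_scalers": {
                str(k): v for k, v in self.medication_scalers.items()
            },
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            state_sequence=np.asarray(d["state_sequence"], dtype=int),
            burst_intervals=[tuple(iv) for iv in d["burst_intervals"]],
            coupling_specs=[
                CouplingSpec(
                    source_channel=c["source_channel"],
                    target_channel=c["target_channel"],
                    active_states=frozenset(c["active_states"]),
                    band=OscillatorSpec(**c["band"]),
                    mixing=c["mixing"],
                )
                for c in d["coupling_specs"]
            ],
            medication_scalers={
                int(k): v for k, v in d["medication_scalers"].items()
            },
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        return cls.from_json(Path(path).read_text())


# ------------------------------------------------------------- primitives


def sample_state_sequence(
    spec: MarkovSpec, n_samples: int, seed: int
) -> np.ndarray:
    """Sample a length-``n_samples`` path of 1-based state labels."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    cum_init = np.cumsum(spec.initial)
    cum_trans = np.cumsum(spec.transition, axis=1)
    u = rng.random(n_samples)
    states = np.empty(n_samples, dtype=int)
    states[0] = np.searchsorted(cum_init, u[0], side="right")
    for t in range(1, n_samples):
        states[t] = np.searchsorted(cum_trans[states[t - 1]], u[t], side="right")
    return states + 1


def band_limited_noise(
    osc: OscillatorSpec, n_samples: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise band-passed to the oscillator band, RMS = amplitude."""
    osc.validate(fs)
    lo, hi = osc.band_edges()
    lo = max(lo, 1e-3)
    hi = min(hi, fs / 2 - 1e-3)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
    rms = np.sqrt(np.mean(x**2))
    if rms == 0:
        return np.zeros(n_samples)
    return x * (osc.amplitude / rms)


def state_gate(
    states: np.ndarray,
    active: frozenset[int] | set[int],
    fs: float,
    ramp_s: float = 0.02,
) -> np.ndarray:
    """Smoothed 0/1 gate for the given active states.

    A raised-cosine (Hann) ramp of ``ramp_s`` avoids filter-edge clicks at
    state boundaries.
    """
    indicator = np.isin(states, list(active)).astype(float)
    n_ramp = int(round(ramp_s * fs))
    if n_ramp < 2:
        return indicator
    # interior of a Hann window: endpoints of hann() are exactly zero
    kernel = signal.windows.hann(n_ramp + 2)[1:-1]
    kernel /= kernel.sum()
    return np.convolve(indicator, kernel, mode="same")


def dwell_lengths(states: np.ndarray) -> np.ndarray:
    """Run lengths of consecutive identical states."""
    change = np.flatnonzero(np.diff(states)) + 1
    bounds = np.concatenate(([0], change, [len(states)]))
    return np.diff(bounds)


# ------------------------------------------------------------- synthesis


def synthesize_recording(
    states: np.ndarray,
    per_state_channel_spectra: dict[int, dict[str, list[OscillatorSpec]]],
    couplings: list[CouplingSpec],
    noise_sd: float,
    fs: float,
    seed: int,
    channel_labels: list[str] | None = None,
    channel_roles: list[str] | None = None,
    subject: str = "s0",
    condition: str = "off",
) -> tuple[Recording, GroundTruth]:
    """Render a multichannel recording from a state path and oscillator specs.

    Each oscillator contributes band-limited noise multiplied by a smoothed
    gate of its state; each coupling adds one shared band-limited component
    to its source channel and ``mixing`` times that component to its target,
    gated by the coupling's active states.
    """
    states = np.asarray(states, dtype=int)
    if states.size < 1:
        raise ValueError("states must be non-empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    n_samples = states.size

    if channel_labels is None:
        seen: dict[str, None] = {}
        for chan_map in per_state_channel_spectra.values():
            for label in chan_map:
                seen.setdefault(label)
        for c in couplings:
            seen.setdefault(c.source_channel)
            seen.setdefault(c.target_channel)
        channel_labels = list(seen)
    if channel_roles is None:
        channel_roles = [
            "lfp" if "lfp" in lab.lower() else "cortical"
            for lab in channel_labels
        ]
    index = {lab: i for i, lab in enumerate(channel_labels)}

    for chan_map in per_state_channel_spectra.values():
        for label, oscs in chan_map.items():
            if label not in index:
                raise ValueError(f"unknown channel {label!r} in spectra spec")
            for osc in oscs:
                osc.validate(fs)
    for c in couplings:
        if c.source_channel not in index or c.target_channel not in index:
            raise ValueError("coupling references unknown channel")
        c.band.validate(fs)

    rng = np.random.default_rng(seed)
    data = rng.standard_normal((len(channel_labels), n_samples)) * noise_sd

    for state, chan_map in sorted(per_state_channel_spectra.items()):
        gate = state_gate(states, {state}, fs)
        for label in sorted(chan_map):
            for osc in chan_map[label]:
                comp = band_limited_noise(osc, n_samples, fs, rng)
                data[index[label]] += comp * gate

    for c in couplings:
        gate = state_gate(states, c.active_states, fs)
        shared = band_limited_noise(c.band, n_samples, fs, rng)
        data[index[c.source_channel]] += shared * gate
        data[index[c.target_channel]] += c.mixing * shared * gate

    rec = Recording(
        data=data,
        fs=fs,
        channel_labels=list(channel_labels),
        channel_roles=list(channel_roles),
        subject=subject,
        condition=condition,
    )
    truth = GroundTruth(state_sequence=states, coupling_specs=list(couplings))
    return rec, truth


# ---------------------------------------------------------------- cohorts


@dataclass
class CohortDesign:
    """Design of a paired (off/on) synthetic cohort.

    Defaults give a 4-state chain over two cortical channels plus one LFP
    channel.  Each state carries a distinct cortical oscillator so state
    covariances are separable; LFP-cortex coupling is active in
    ``coupled_states`` (one theta/alpha-band, one beta-band); every state
    carries an LFP beta oscillator whose amplitude the "on" condition
    rescales per ``medication_scalers``.
    """

    n_states: int = 4
    fs: float = 100.0
    duration_s: float = 120.0
    stay_prob: float = 0.999
    noise_sd: float = 1.0
    channel_labels: tuple[str, ...] = ("SMA", "occipital", "lfp")
    channel_roles: tuple[str, ...] = ("cortical", "cortical", "lfp")
    coupled_states: tuple[int, ...] = (1, 3)
    coupling_mixing: float = 0.9
    lfp_beta_amplitude: float = 1.2
    # weak broadband LFP-cortex coupling active in every state: keeps the
    # coherence baseline above the zero-coherence estimator bias floor, as
    # in real recordings
    background_amplitude: float = 0.8
    background_mixing: float = 0.6
    subject_amp_jitter_sd: float = 0.1
    # per-condition (session) multiplicative jitter of LFP oscillator
    # amplitudes, emulating between-session recording-gain differences
    session_amp_jitter_sd: float = 0.15

    def markov_spec(self) -> MarkovSpec:
        return MarkovSpec.uniform_sticky(self.n_states, self.stay_prob)

    def state_spectra(self) -> dict[int, dict[str, list[OscillatorSpec]]]:
        """One distinctive cortical oscillator per state, plus LFP beta."""
        cortical = [
            lab
            for lab, role in zip(self.channel_labels, self.channel_roles)
            if role == "cortical"
        ]
        lfp = [
            lab
            for lab, role in zip(self.channel_labels, self.channel_roles)
            if role == "lfp"
        ][0]
        centers = (10.0, 22.0)
        spectra: dict[int, dict[str, list[OscillatorSpec]]] = {}
        for k in range(1, self.n_states + 1):
            chan = cortical[(k - 1) // len(centers) % len(cortical)]
            center = centers[(k - 1) % len(centers)]
            spectra[k] = {
                chan: [OscillatorSpec(center, 4.0, 1.6)],
                lfp: [OscillatorSpec(21.0, 8.0, self.lfp_beta_amplitude)],
            }
        return spectra

    def coupling_specs(self) -> list[CouplingSpec]:
        cortical_target = self.channel_labels[0]
        lfp = [
            lab
            for lab, role in zip(self.channel_labels, self.channel_roles)
            if role == "lfp"
        ][0]
        bands = [OscillatorSpec(10.0, 4.0, 1.3), OscillatorSpec(21.0, 6.0, 1.3)]
        specs = [
            CouplingSpec(
                source_channel=cortical_target,
                target_channel=lfp,
                active_states=frozenset({state}),
                band=bands[i % len(bands)],
                mixing=self.coupling_mixing,
            )
            for i, state in enumerate(self.coupled_states)
        ]
        if self.background_amplitude > 0:
            lo, hi = 2.0, min(44.0, self.fs / 2 - 4.0)
            specs.append(
                CouplingSpec(
                    source_channel=cortical_target,
                    target_channel=lfp,
                    active_states=frozenset(range(1, self.n_states + 1)),
                    band=OscillatorSpec(
                        (lo + hi) / 2, hi - lo, self.background_amplitude
                    ),
                    mixing=self.background_mixing,
                )
            )
        return specs


@dataclass
class PairedSubject:
    """One subject's paired recordings plus its generating ground truth."""

    off: Recording
    on: Recording
    truth: GroundTruth


def _scaled_spectra(
    spectra: dict[int, dict[str, list[OscillatorSpec]]],
    lfp_labels: set[str],
    scalers: dict[int, float],
    amp_jitter: dict[int, float],
    lfp_session_gain: float = 1.0,
) -> dict[int, dict[str, list[OscillatorSpec]]]:
    out: dict[int, dict[str, list[OscillatorSpec]]] = {}
    for state, chan_map in spectra.items():
        gain = scalers.get(state, 1.0)
        out[state] = {}
        for label, oscs in chan_map.items():
            scaled = []
            for osc in oscs:
                amp = osc.amplitude * amp_jitter.get(state, 1.0)
                if label in lfp_labels:
                    amp *= lfp_session_gain
                    if osc.in_beta_band():
                        amp *= gain
                scaled.append(OscillatorSpec(osc.center_hz, osc.bandwidth_hz, amp))
            out[state][label] = scaled
    return out


def _jittered_couplings(
    couplings: list[CouplingSpec], factor: float
) -> list[CouplingSpec]:
    return [
        CouplingSpec(
            source_channel=c.source_channel,
            target_channel=c.target_channel,
            active_states=c.active_states,
            band=OscillatorSpec(
                c.band.center_hz, c.band.bandwidth_hz, c.band.amplitude * factor
            ),
            mixing=c.mixing,
        )
        for c in couplings
    ]


def make_paired_cohort(
    n_subjects: int,
    med_beta_gain: dict[int, float],
    seed: int,
    design: CohortDesign | None = None,
) -> list[PairedSubject]:
    """Paired off/on cohort; "on" rescales LFP beta amplitude per state.

    ``med_beta_gain`` maps state label -> gain in [0, 1] applied to LFP
    beta-band oscillator amplitudes in the "on" condition (unlisted states
    keep gain 1).  Subject randomness derives deterministically from
    ``seed`` via a spawned seed sequence.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    design = design or CohortDesign()
    for state, gain in med_beta_gain.items():
        if gain < 0:
            raise ValueError("medication gain must be non-negative")
        if not 1 <= state <= design.n_states:
            raise ValueError(f"medication gain for unknown state {state}")

    markov = design.markov_spec()
    base_spectra = design.state_spectra()
    couplings = design.coupling_specs()
    lfp_labels = {
        lab
        for lab, role in zip(design.channel_labels, design.channel_roles)
        if role == "lfp"
    }
    n_samples = int(round(design.duration_s * design.fs))

    master = np.random.SeedSequence(seed)
    cohort: list[PairedSubject] = []
    for subj_idx, subj_ss in enumerate(master.spawn(n_subjects)):
        seq_seed, off_seed, on_seed, jitter_seed = (
            int(s.generate_state(1)[0]) for s in subj_ss.spawn(4)
        )
        states = sample_state_sequence(markov, n_samples, seq_seed)
        jitter_rng = np.random.default_rng(jitter_seed)
        amp_jitter = {
            k: float(
                np.exp(jitter_rng.normal(0.0, design.subject_amp_jitter_sd))
            )
            for k in range(1, design.n_states + 1)
        }
        coupling_factor = float(
            np.exp(jitter_rng.normal(0.0, design.subject_amp_jitter_sd))
        )
        session_gain = {
            cond: float(
                np.exp(jitter_rng.normal(0.0, design.session_amp_jitter_sd))
            )
            for cond in ("off", "on")
        }
        subject = f"sub-{subj_idx:02d}"
        common = dict(
            states=states,
            couplings=_jittered_couplings(couplings, coupling_factor),
            noise_sd=design.noise_sd,
            fs=design.fs,
            channel_labels=list(design.channel_labels),
            channel_roles=list(design.channel_roles),
            subject=subject,
        )
        off_spectra = _scaled_spectra(
            base_spectra, lfp_labels, {}, amp_jitter, session_gain["off"]
        )
        on_spectra = _scaled_spectra(
            base_spectra,
            lfp_labels,
            dict(med_beta_gain),
            amp_jitter,
            session_gain["on"],
        )
        rec_off, truth = synthesize_recording(
            per_state_channel_spectra=off_spectra,
            seed=off_seed,
            condition="off",
            **common,
        )
        rec_on, _ = synthesize_recording(
            per_state_channel_spectra=on_spectra,
            seed=on_seed,
            condition="on",
            **common,
        )
        truth.medication_scalers = dict(med_beta_gain)
        cohort.append(PairedSubject(off=rec_off, on=rec_on, truth=truth))
    return cohort
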