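"""Config-driven end-to-end analysis on synthetic paired cohorts.

Stages: generate -> preprocess -> embed/PCA -> HMM (canonical-subset fit by
default) -> state-weighted spectra -> state vs time-averaged contrasts
(power, coherence, imaginary-coherence control) -> burst overlap -> on/off
medication contrasts (with and without GESD outlier exclusion).  Every
stage draws randomness deterministically from the master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bursts as bursts_mod
from . import permstats, preprocess, specest, synthgen, tdehmm
from .recording import Recording

log = logging.getLogger("statecoupler")


@dataclass
class PipelineConfig:
    """Parameter registry for the full analysis."""

    # cohort generation
    n_subjects: int = 10
    n_states: int = 4
    fs: float = 100.0
    duration_s: float = 120.0
    stay_prob: float = 0.999
    coupled_states: tuple[int, ...] = (1, 3)
    med_states: tuple[int, ...] = (2, 4)
    med_beta_gain: float = 0.5
    coupling_mixing: float = 0.9
    # preprocessing
    detect_bad: bool = False
    bad_window_s: float = 2.0
    # HMM
    hmm_states: int | None = None  # default: n_states
    n_lags: int = 7
    pca_components: int | None = None  # default: min(120, embedded dim)
    canonical_subjects: int = 2
    re_estimate_transition: bool = True
    hmm_restarts: int = 2
    hmm_max_iter: int = 30
    hmm_tol: float = 1e-4
    # spectra
    taper_window_s: float = 2.0
    n_tapers: int = 7
    contrast_band: tuple[float, float] = (1.0, 45.0)
    cortical_pair_channel: str = "SMA"
    # bursts
    beta_band: tuple[float, float] = (13.0, 30.0)
    burst_percentile: float = 75.0
    burst_min_duration_s: float = 0.1
    # statistics
    n_perm: int = 1000
    cluster_alpha: float = 0.05
    alpha: float = 0.05
    gesd_alpha: float = 0.05

    def __post_init__(self) -> None:
        self.coupled_states = tuple(self.coupled_states)
        self.med_states = tuple(self.med_states)
        self.contrast_band = tuple(self.contrast_band)
        self.beta_band = tuple(self.beta_band)

    @property
    def K(self) -> int:
        return self.hmm_states if self.hmm_states is not None else self.n_states

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.K < 2:
            raise ValueError("contrasts need at least 2 states")
        if not 0 <= self.med_beta_gain:
            raise ValueError("med_beta_gain must be non-negative")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.taper_window_s * 2 > self.duration_s:
            raise ValueError("taper window too long for the recording")
        if self.beta_band[1] >= self.fs / 2:
            raise ValueError("beta band must lie below Nyquist")
        for s in self.coupled_states + self.med_states:
            if not 1 <= s <= self.n_states:
                raise ValueError(f"state {s} outside 1..{self.n_states}")

    def design(self) -> synthgen.CohortDesign:
        return synthgen.CohortDesign(
            n_states=self.n_states,
            fs=self.fs,
            duration_s=self.duration_s,
            stay_prob=self.stay_prob,
            coupled_states=self.coupled_states,
            coupling_mixing=self.coupling_mixing,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SubjectSpectra:
    """Per-condition state spectra for one subject."""

    off: specest.StateSpectra
    on: specest.StateSpectra


@dataclass
class AnalysisReport:
    """Everything the full analysis produces, JSON/CSV-serializable."""

    config: dict
    seed: int
    state_map: list[int]  # est state (0-based) matched to each true state
    fractional_occupancy: pd.DataFrame
    coherence_clusters: pd.DataFrame
    imag_coherence_clusters: pd.DataFrame
    power_clusters: pd.DataFrame
    burst_overlap: pd.DataFrame
    burst_stats: pd.DataFrame
    medication_stats: pd.DataFrame
    medication_stats_no_exclusion: pd.DataFrame
    excluded_subjects: list[int]
    time_averaged_med: dict
    notes: list[str] = field(default_factory=list)

    def significant_coherence_states(self, bonferroni_m: int | None = None) -> list[int]:
        """Estimated states (1-based) with a Bonferroni-significant positive cluster."""
        df = self.coherence_clusters
        m = bonferroni_m or len(self.state_map)
        thr = permstats.bonferroni_threshold(0.05, m)
        hits = df[(df.sign > 0) & (df.p_value < thr)]
        return sorted(set(int(s) for s in hits.state))

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "config": self.config,
            "seed": self.seed,
            "state_map": self.state_map,
            "excluded_subjects": self.excluded_subjects,
            "time_averaged_med": self.time_averaged_med,
            "notes": self.notes,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        for name in (
            "fractional_occupancy",
            "coherence_clusters",
            "imag_coherence_clusters",
            "power_clusters",
            "burst_overlap",
            "burst_stats",
            "medication_stats",
            "medication_stats_no_exclusion",
        ):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)


# ------------------------------------------------------------------ stages


def generate_cohort(
    config: PipelineConfig, seed: int
) -> list[synthgen.PairedSubject]:
    gains = {s: config.med_beta_gain for s in config.med_states}
    return synthgen.make_paired_cohort(
        config.n_subjects, gains, seed, design=config.design()
    )


def preprocess_recording(rec: Recording, config: PipelineConfig) -> Recording:
    if config.detect_bad:
        mask = preprocess.detect_bad_segments(rec, window_s=config.bad_window_s)
        rec = rec.copy_with(bad_mask=rec.bad_mask | mask)
    return preprocess.standardize(rec)


def _embed_recording(
    rec: Recording, config: PipelineConfig
) -> tuple[np.ndarray, np.ndarray]:
    cortical = rec.channels_with_role("cortical")
    X = np.vstack([rec.channel(c) for c in cortical])
    cfg = tdehmm.EmbeddingConfig(
        n_lags_each_side=config.n_lags, channels_in=X.shape[0]
    )
    return tdehmm.time_delay_embed(X, cfg, bad_mask=rec.bad_mask)


def infer_state_time_courses(
    cohort: list[synthgen.PairedSubject],
    config: PipelineConfig,
    seed: int,
) -> tuple[tdehmm.HMMModel, list[dict[str, np.ndarray]], list[int]]:
    """Fit a canonical HMM on a subject subset and infer gamma per recording.

    Returns (model, per-subject {"off": gamma, "on": gamma} aligned to the
    recording sample axis, state_map) where ``state_map[k]`` is the
    estimated state (0-based) matched to true state k+1.
    """
    embedded: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}
    for i, subj in enumerate(cohort):
        for cond in ("off", "on"):
            rec = preprocess_recording(getattr(subj, cond), config)
            embedded[(i, cond)] = _embed_recording(rec, config)

    n_canon = min(config.canonical_subjects, len(cohort))
    canon_blocks = []
    canon_bad = []
    sep = None
    for i in range(n_canon):
        for cond in ("off", "on"):
            E, bad = embedded[(i, cond)]
            if sep is None:
                sep = np.zeros((1, E.shape[1]))
            canon_blocks.extend([E, sep])
            canon_bad.extend([bad, np.array([True])])
    E_canon = np.vstack(canon_blocks)
    bad_canon = np.concatenate(canon_bad)

    dim = E_canon.shape[1]
    P = config.pca_components or min(120, dim)
    P = min(P, dim)
    pca = tdehmm.fit_pca(E_canon, n_components=P, bad_rows=bad_canon)
    Y_canon = pca.project(E_canon)
    model, _, _ = tdehmm.fit_hmm(
        Y_canon,
        config.K,
        seed=seed,
        n_restarts=config.hmm_restarts,
        max_iter=config.hmm_max_iter,
        tol=config.hmm_tol,
        bad_rows=bad_canon,
    )

    gammas: list[dict[str, np.ndarray]] = []
    hard_all, true_all = [], []
    L = config.n_lags
    for i, subj in enumerate(cohort):
        per_cond = {}
        for cond in ("off", "on"):
            E, bad = embedded[(i, cond)]
            Y = pca.project(E)
            post = tdehmm.infer_with_canonical_states(
                model,
                Y,
                re_estimate_transition=config.re_estimate_transition,
                bad_rows=bad,
                tol=config.hmm_tol,
                max_iter=15,
            )
            rec = getattr(subj, cond)
            per_cond[cond] = specest.align_gamma(post.gamma, L, rec.n_samples)
            hard_all.append(post.hard_states())
            true_all.append(subj.truth.state_sequence[L:-L] if L else subj.truth.state_sequence)
        gammas.append(per_cond)

    state_map = _match_rectangular(
        np.concatenate(hard_all), np.concatenate(true_all), config.n_states, config.K
    )
    return model, gammas, [int(k) for k in state_map]


def _match_rectangular(
    hard: np.ndarray, true: np.ndarray, n_true: int, n_est: int
) -> np.ndarray:
    """Assign one estimated state to each true state by confusion overlap."""
    from scipy.optimize import linear_sum_assignment

    conf = np.zeros((n_true, n_est))
    valid = (hard > 0) & (true > 0)
    np.add.at(conf, (true[valid] - 1, hard[valid] - 1), 1)
    row, col = linear_sum_assignment(-conf)
    out = np.full(n_true, -1, dtype=int)
    out[row] = col
    return out


def compute_subject_spectra(
    cohort: list[synthgen.PairedSubject],
    gammas: list[dict[str, np.ndarray]],
    config: PipelineConfig,
) -> list[SubjectSpectra]:
    tapers = specest.make_tapers(
        window_s=config.taper_window_s, n_tapers=config.n_tapers, fs=config.fs
    )
    out = []
    for subj, g in zip(cohort, gammas):
        spectra = {}
        for cond in ("off", "on"):
            # spectra use the unstandardized signal: per-condition z-scoring
            # would rescale power by the condition's total variance and leak
            # a planted amplitude change into unaffected states
            rec = getattr(subj, cond)
            if config.detect_bad:
                mask = preprocess.detect_bad_segments(
                    rec, window_s=config.bad_window_s
                )
                rec = rec.copy_with(bad_mask=rec.bad_mask | mask)
            spectra[cond] = specest.state_weighted_csd(
                rec.data,
                rec.fs,
                g[cond],
                tapers,
                channel_labels=rec.channel_labels,
                bad_mask=rec.bad_mask,
            )
        out.append(SubjectSpectra(off=spectra["off"], on=spectra["on"]))
    return out


def _lfp_label(config: PipelineConfig) -> str:
    return "lfp"


def _cluster_table(
    contrasts: np.ndarray,
    freqs: np.ndarray,
    states: list[int],
    config: PipelineConfig,
    seed: int,
    measure: str,
) -> pd.DataFrame:
    """Cluster-permutation tests, one per state, stacked into a table."""
    rows = []
    for idx, state in enumerate(states):
        X = contrasts[:, idx, :]
        keep = ~np.any(np.isnan(X), axis=1)
        if keep.sum() < 2:
            continue
        res = permstats.cluster_permutation_test(
            X[keep],
            freqs,
            n_perm=config.n_perm,
            cluster_alpha=config.cluster_alpha,
            seed=seed + idx,
        )
        for c in res.clusters:
            rows.append(
                dict(
                    measure=measure,
                    state=state,
                    freq_lo=c.freq_lo,
                    freq_hi=c.freq_hi,
                    peak_freq=c.peak_freq,
                    mean_t=c.mean_t,
                    mass=c.mass,
                    sign=c.sign,
                    p_value=c.p_value,
                    n_subjects=int(keep.sum()),
                )
            )
    cols = [
        "measure", "state", "freq_lo", "freq_hi", "peak_freq",
        "mean_t", "mass", "sign", "p_value", "n_subjects",
    ]
    return pd.DataFrame(rows, columns=cols)


def run_full_analysis(
    config: PipelineConfig, seed: int = 0, out_dir: str | Path | None = None
) -> AnalysisReport:
    """Execute the complete synthetic-cohort analysis."""
    config.validate()
    notes: list[str] = []
    log.info("generating cohort (n=%d, seed=%d)", config.n_subjects, seed)
    cohort = generate_cohort(config, seed)

    log.info("inferring state time courses (K=%d)", config.K)
    model, gammas, state_map = infer_state_time_courses(cohort, config, seed)
    subject_spectra = compute_subject_spectra(cohort, gammas, config)

    K = config.K
    lfp = _lfp_label(config)
    pair = (config.cortical_pair_channel, lfp)
    freqs = subject_spectra[0].off.freqs
    band_sel = (freqs >= config.contrast_band[0]) & (freqs <= config.contrast_band[1])
    f_axis = freqs[band_sel]
    states = list(range(1, K + 1))

    # per-subject state-vs-time-averaged contrast spectra (mean of conditions)
    n = len(cohort)
    coh_con = np.full((n, K, f_axis.size), np.nan)
    imcoh_con = np.full((n, K, f_axis.size), np.nan)
    pow_con = np.full((n, K, f_axis.size), np.nan)
    beta_power = np.full((n, 2, K), np.nan)  # (subject, off/on, state)
    fo_rows = []
    i_sma = None
    for s_idx, spec_pair in enumerate(subject_spectra):
        per_cond = {"coh": [], "imcoh": [], "pow": []}
        for c_idx, cond in enumerate(("off", "on")):
            sp: specest.StateSpectra = getattr(spec_pair, cond)
            i_sma = sp.channel_labels.index(pair[0])
            i_lfp = sp.channel_labels.index(pair[1])
            avg_csd = specest.time_average_csd(sp)
            avg_coh = specest.coherence_from_csd(avg_csd, i_sma, i_lfp, "magnitude")
            avg_imcoh = specest.coherence_from_csd(avg_csd, i_sma, i_lfp, "imaginary")
            avg_pow = np.real(avg_csd[i_lfp, i_lfp])
            coh_k = np.full((K, f_axis.size), np.nan)
            imcoh_k = np.full((K, f_axis.size), np.nan)
            pow_k = np.full((K, f_axis.size), np.nan)
            for k in states:
                if not sp.defined_states()[k - 1]:
                    notes.append(
                        f"subject {s_idx} {cond}: state {k} has zero weight; dropped"
                    )
                    continue
                coh = specest.coherence_from_csd(
                    sp.csd[k - 1], i_sma, i_lfp, "magnitude"
                )
                imcoh = specest.coherence_from_csd(
                    sp.csd[k - 1], i_sma, i_lfp, "imaginary"
                )
                pw = sp.power(pair[1], k)
                coh_k[k - 1] = (coh - avg_coh)[band_sel]
                imcoh_k[k - 1] = (imcoh - avg_imcoh)[band_sel]
                pow_k[k - 1] = (pw - avg_pow)[band_sel]
                beta_power[s_idx, c_idx, k - 1] = specest.band_power(
                    pw, freqs, config.beta_band
                )
            per_cond["coh"].append(coh_k)
            per_cond["imcoh"].append(imcoh_k)
            per_cond["pow"].append(pow_k)
            fo_rows.append(
                dict(
                    subject=s_idx,
                    condition=cond,
                    **{f"state_{k}": sp.fo[k - 1] for k in states},
                )
            )
        coh_con[s_idx] = np.mean(per_cond["coh"], axis=0)
        imcoh_con[s_idx] = np.mean(per_cond["imcoh"], axis=0)
        pow_con[s_idx] = np.mean(per_cond["pow"], axis=0)

    log.info("cluster permutation contrasts")
    coh_df = _cluster_table(coh_con, f_axis, states, config, seed + 1000, "coherence")
    imcoh_df = _cluster_table(
        imcoh_con, f_axis, states, config, seed + 2000, "imag_coherence"
    )
    pow_df = _cluster_table(pow_con, f_axis, states, config, seed + 3000, "lfp_power")

    # burst overlap (medication-off scans)
    log.info("burst detection and overlap")
    overlap_rows = []
    overlap_con = np.full((n, K), np.nan)
    for s_idx, subj in enumerate(cohort):
        rec = preprocess_recording(subj.off, config)
        env = bursts_mod.amplitude_envelope(
            rec.channel(lfp), rec.fs, band=config.beta_band,
            good_mask=rec.good_mask(),
        )
        bset = bursts_mod.detect_bursts(
            env,
            rec.fs,
            percentile=config.burst_percentile,
            min_duration_s=config.burst_min_duration_s,
            band=config.beta_band,
            good_mask=rec.good_mask(),
        )
        for res in bursts_mod.overlap_table(bset, gammas[s_idx]["off"]):
            overlap_rows.append(
                dict(
                    subject=s_idx,
                    state=res.state,
                    overlap_pct=res.overlap_pct,
                    other_pct=res.other_pct,
                    contrast_pct=res.contrast_pct,
                )
            )
            overlap_con[s_idx, res.state - 1] = res.contrast_pct
    overlap_df = pd.DataFrame(overlap_rows)

    keep = ~np.any(np.isnan(overlap_con), axis=1)
    t_burst, p_burst = permstats.max_t_permutation(
        overlap_con[keep], n_perm=config.n_perm, seed=seed + 4000
    )
    burst_stats = pd.DataFrame(
        dict(state=states, t=t_burst, p_corrected=p_burst)
    )

    # medication contrast on state-specific beta power
    log.info("medication contrasts")
    diff = beta_power[:, 0, :] - beta_power[:, 1, :]  # off - on
    subj_level = np.nanmean(beta_power, axis=(1, 2))
    gesd_res = permstats.gesd(subj_level, alpha=config.gesd_alpha)
    excluded = gesd_res.outlier_indices
    keep_med = np.array([i not in excluded for i in range(n)])
    keep_med &= ~np.any(np.isnan(diff), axis=1)

    def med_table(rows_keep: np.ndarray, tag_seed: int) -> pd.DataFrame:
        t_med, p_med = permstats.max_t_permutation(
            diff[rows_keep], n_perm=config.n_perm, seed=tag_seed
        )
        return pd.DataFrame(
            dict(
                state=states,
                t=t_med,
                p_corrected=p_med,
                n_subjects=int(rows_keep.sum()),
            )
        )

    med_df = med_table(keep_med, seed + 5000)
    med_all_df = med_table(~np.any(np.isnan(diff), axis=1), seed + 6000)

    # time-averaged medication effect on beta power
    ta_diff = np.nanmean(beta_power[:, 0, :], axis=1) - np.nanmean(
        beta_power[:, 1, :], axis=1
    )
    ta_diff = ta_diff[~np.isnan(ta_diff)]
    t_ta, p_ta = permstats.sign_flip_t_test(
        ta_diff, n_perm=config.n_perm, seed=seed + 7000
    )

    report = AnalysisReport(
        config=config.to_dict(),
        seed=seed,
        state_map=state_map,
        fractional_occupancy=pd.DataFrame(fo_rows),
        coherence_clusters=coh_df,
        imag_coherence_clusters=imcoh_df,
        power_clusters=pow_df,
        burst_overlap=overlap_df,
        burst_stats=burst_stats,
        medication_stats=med_df,
        medication_stats_no_exclusion=med_all_df,
        excluded_subjects=[int(i) for i in excluded],
        time_averaged_med={"t": t_ta, "p": p_ta},
        notes=notes,
    )
    if out_dir is not None:
        report.save(out_dir)
    return report


def robustness_sweep(
    config: PipelineConfig,
    seed: int = 0,
    K_list: tuple[int, ...] = (8, 10, 12),
) -> dict[int, AnalysisReport]:
    """Re-run the full analysis with different HMM state counts."""
    out = {}
    for K in K_list:
        if K < 2:
            raise ValueError("sweep requires K >= 2 (contrasts undefined)")
        cfg = PipelineConfig.from_dict({**config.to_dict(), "hmm_states": K})
        out[K] = run_full_analysis(cfg, seed=seed)
    return out
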