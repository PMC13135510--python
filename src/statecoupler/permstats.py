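"""GLM contrasts, permutation inference and outlier screening.

Implements within-subject OLS contrasts, cluster-based permutation over a
frequency axis (sign-flip null, cluster mass = summed |t|), max-t
permutation pooled across states, Bonferroni adjustment, the generalized
extreme studentized deviate (GESD) outlier test, and group contrasts with
covariates.

Permutation p-values follow the convention p = (1 + #{null >= obs}) /
(1 + n_perm), which includes the observed statistic and never yields 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


# ------------------------------------------------------------------ types


@dataclass
class GLMDesign:
    """Design matrix, contrast vector and observation labels."""

    design: np.ndarray
    contrast: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.design = np.atleast_2d(np.asarray(self.design, dtype=float))
        self.contrast = np.asarray(self.contrast, dtype=float)
        n_obs, n_reg = self.design.shape
        if self.contrast.shape != (n_reg,):
            raise ValueError("contrast length must match design columns")
        if not np.any(self.contrast):
            raise ValueError("contrast must not be all-zero")
        if np.linalg.matrix_rank(self.design) < n_reg:
            raise ValueError("design matrix is rank deficient (collinear regressors)")


@dataclass
class Cluster:
    """A contiguous supra-threshold frequency run."""

    freq_lo: float
    freq_hi: float
    mass: float
    mean_t: float
    peak_freq: float
    p_value: float
    sign: int
    indices: tuple[int, int]  # half-open index interval into the freq axis


@dataclass
class ContrastResult:
    t_spectrum: np.ndarray
    freqs: np.ndarray
    clusters: list[Cluster]
    n_perm: int
    cluster_alpha: float

    def significant_clusters(self, threshold: float) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < threshold]


@dataclass
class GESDResult:
    outlier_indices: list[int]
    test_statistics: list[float] = field(default_factory=list)
    critical_values: list[float] = field(default_factory=list)


# ------------------------------------------------------------------- GLMs


def first_level_contrast(values: np.ndarray, design: GLMDesign) -> np.ndarray:
    """OLS contrast estimate c' beta for one subject.

    ``values`` has shape (n_obs,) or (n_obs, n_freqs); the result is a
    scalar or a length-n_freqs vector.  For a two-condition design with
    contrast (1, -1) this reduces exactly to the condition-mean difference.
    """
    values = np.asarray(values, dtype=float)
    scalar = values.ndim == 1
    Y = values[:, None] if scalar else values
    if Y.shape[0] != design.design.shape[0]:
        raise ValueError("values rows must match design rows")
    beta, *_ = np.linalg.lstsq(design.design, Y, rcond=None)
    est = design.contrast @ beta
    return float(est[0]) if scalar else est


def paired_design(n_conditions: int = 2) -> GLMDesign:
    """Condition-indicator design with contrast first-minus-second."""
    design = np.eye(n_conditions)
    contrast = np.zeros(n_conditions)
    contrast[0], contrast[1] = 1.0, -1.0
    return GLMDesign(design=design, contrast=contrast)


def _one_sample_t(X: np.ndarray) -> np.ndarray:
    """One-sample t per column; columns with zero variance give t=0 or inf."""
    n = X.shape[0]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where(
            sd == 0, np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t
        )
    return t


def _find_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index intervals of True runs."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def cluster_permutation_test(
    subject_contrasts: np.ndarray,
    freqs: np.ndarray,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    seed: int = 0,
) -> ContrastResult:
    """Two-sided cluster-based sign-flip permutation test over frequency.

    The cluster-forming threshold is the two-sided critical t at
    ``cluster_alpha`` with df = n_subjects - 1.  Clusters are contiguous
    supra-threshold runs of same-signed t, scored by summed |t|; the null
    records the maximum cluster mass per sign-flip permutation.
    """
    X = np.atleast_2d(np.asarray(subject_contrasts, dtype=float))
    freqs = np.asarray(freqs, dtype=float)
    n_subj, n_freq = X.shape
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    if freqs.shape != (n_freq,):
        raise ValueError("freqs length must match contrast columns")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    t_crit = stats.t.ppf(1 - cluster_alpha / 2, df=n_subj - 1)
    t_obs = _one_sample_t(X)

    def cluster_masses(t: np.ndarray) -> list[tuple[int, int, float, int]]:
        out = []
        for sign in (1, -1):
            for lo, hi in _find_runs(sign * t > t_crit):
                out.append((lo, hi, float(np.abs(t[lo:hi]).sum()), sign))
        return out

    observed = cluster_masses(t_obs)

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    for p in range(n_perm):
        t_perm = _one_sample_t(signs[p][:, None] * X)
        masses = [m for _, _, m, _ in cluster_masses(t_perm)]
        null_max[p] = max(masses) if masses else 0.0

    clusters = []
    for lo, hi, mass, sign in observed:
        p_val = (1 + np.sum(null_max >= mass)) / (1 + n_perm)
        seg = t_obs[lo:hi]
        peak = freqs[lo + int(np.argmax(np.abs(seg)))]
        clusters.append(
            Cluster(
                freq_lo=float(freqs[lo]),
                freq_hi=float(freqs[hi - 1]),
                mass=mass,
                mean_t=float(seg.mean()),
                peak_freq=float(peak),
                p_value=float(p_val),
                sign=sign,
                indices=(lo, hi),
            )
        )
    clusters.sort(key=lambda c: c.freq_lo)
    return ContrastResult(
        t_spectrum=t_obs,
        freqs=freqs,
        clusters=clusters,
        n_perm=n_perm,
        cluster_alpha=cluster_alpha,
    )


def max_t_permutation(
    values: np.ndarray, n_perm: int = 1000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Max-|t| sign-flip permutation across states (columns).

    ``values`` holds per-subject paired differences, shape
    (n_subjects, n_states).  Returns (t per state, corrected p per state);
    corrected p compares each |t_k| against the permutation distribution of
    the maximum |t| over all states.
    """
    X = np.atleast_2d(np.asarray(values, dtype=float))
    n_subj, n_states = X.shape
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    if np.any(X.std(axis=0, ddof=1) == 0):
        raise ValueError("constant column: t statistic undefined")

    t_obs = _one_sample_t(X)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    # vectorized: mean and sd of sign-flipped data per permutation
    flipped_mean = (signs @ X) / n_subj
    sq_mean = (X**2).mean(axis=0)  # invariant under sign flips
    var = (sq_mean[None, :] - flipped_mean**2) * n_subj / (n_subj - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = flipped_mean / np.sqrt(var / n_subj)
    max_null = np.nanmax(np.abs(t_null), axis=1)
    p = (1 + (max_null[:, None] >= np.abs(t_obs)[None, :]).sum(axis=0)) / (
        1 + n_perm
    )
    return t_obs, p


def sign_flip_t_test(
    values: np.ndarray, n_perm: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Two-sided one-sample sign-flip permutation t-test on a vector."""
    t, p = max_t_permutation(
        np.asarray(values, dtype=float)[:, None], n_perm=n_perm, seed=seed
    )
    return float(t[0]), float(p[0])


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Adjusted per-test threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


# ------------------------------------------------------------------- GESD


def gesd(
    values: np.ndarray, alpha: float = 0.05, max_outliers: int | None = None
) -> GESDResult:
    """Generalized extreme studentized deviate test for up to r outliers.

    Iteratively removes the most extreme studentized value; at step i the
    statistic R_i = max|x - mean| / sd is compared against the
    t-distribution-based critical value lambda_i.  The declared outliers
    are the first i* removals where i* is the largest i with R_i >
    lambda_i.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("GESD requires at least 3 values")
    if max_outliers is None:
        max_outliers = int(np.ceil(0.2 * n))
    if not 1 <= max_outliers < n / 2:
        raise ValueError("max_outliers must be in [1, n/2)")

    remaining = np.arange(n)
    work = x.copy()
    R_list: list[float] = []
    lam_list: list[float] = []
    removed: list[int] = []
    for i in range(1, max_outliers + 1):
        m = work.size
        sd = work.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(work - work.mean())
        j = int(np.argmax(dev))
        R = dev[j] / sd
        p = 1 - alpha / (2 * m)
        t_val = stats.t.ppf(p, df=m - 2)
        lam = (m - 1) * t_val / np.sqrt((m - 2 + t_val**2) * m)
        R_list.append(float(R))
        lam_list.append(float(lam))
        removed.append(int(remaining[j]))
        work = np.delete(work, j)
        remaining = np.delete(remaining, j)

    n_out = 0
    for i, (R, lam) in enumerate(zip(R_list, lam_list), start=1):
        if R > lam:
            n_out = i
    return GESDResult(
        outlier_indices=sorted(removed[:n_out]),
        test_statistics=R_list,
        critical_values=lam_list,
    )


# ----------------------------------------------------- group-level GLMs


def group_contrast_with_covariates(
    values: np.ndarray,
    group: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Group-difference t with covariate adjustment and permutation p.

    Fits OLS of ``values`` on [intercept, group indicator, covariates],
    reports the t statistic on the group coefficient and a permutation
    p-value from shuffling group labels (covariates stay attached to their
    subjects, i.e. the Freedman-Lane-style residual exchangeability holds
    under the null of no group effect).
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(group, dtype=float)
    n = y.size
    groups = np.unique(g)
    if groups.size != 2:
        raise ValueError("exactly two groups required")
    if min(np.sum(g == groups[0]), np.sum(g == groups[1])) < 2:
        raise ValueError("each group needs at least 2 subjects")
    g01 = (g == groups[1]).astype(float)

    cov = None
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        if cov.shape[0] != n:
            raise ValueError("covariates rows must match values")

    def t_for(labels: np.ndarray) -> float:
        cols = [np.ones(n), labels]
        if cov is not None:
            cols.extend(cov.T)
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("confounded design: group collinear with covariate")
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        resid = y - X @ beta
        dof = n - X.shape[1]
        sigma2 = resid @ resid / dof
        se = np.sqrt(sigma2 * XtX_inv[1, 1])
        return 0.0 if se == 0 else float(beta[1] / se)

    t_obs = t_for(g01)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if abs(t_for(rng.permutation(g01))) >= abs(t_obs):
            count += 1
    p = (1 + count) / (1 + n_perm)
    return t_obs, p
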