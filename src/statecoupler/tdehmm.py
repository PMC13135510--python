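"""Time-delay embedding, PCA reduction and Gaussian HMM inference.

States are zero-mean full-covariance Gaussians over the embedded-PCA space,
so each state is defined purely by auto- and cross-covariance structure.
Training is maximum-likelihood EM (Baum-Welch) with scaled forward-backward
inference; canonical-state mode holds the observation covariances fixed and
optionally re-estimates only the transition structure.

Masked (bad) samples split the sequence into contiguous good segments;
forward-backward runs per segment and bad rows carry NaN posteriors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import linear_sum_assignment

# ------------------------------------------------------------------ types


@dataclass
class EmbeddingConfig:
    """Time-delay embedding with ``n_lags_each_side`` lags per side."""

    n_lags_each_side: int = 7
    channels_in: int = 1

    def __post_init__(self) -> None:
        if self.n_lags_each_side < 0:
            raise ValueError("n_lags_each_side must be >= 0")
        if self.channels_in < 1:
            raise ValueError("channels_in must be >= 1")

    @property
    def embedded_dim(self) -> int:
        return self.channels_in * (2 * self.n_lags_each_side + 1)


@dataclass
class PCABasis:
    """Orthonormal principal-component basis of the embedded space."""

    components: np.ndarray  # (embedded_dim, P)
    explained_variance: np.ndarray  # (P,), nonincreasing
    total_variance: float
    mean: np.ndarray  # (embedded_dim,)
    whiten: bool = False

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def explained_variance_ratio(self) -> np.ndarray:
        return self.explained_variance / self.total_variance

    def project(self, embedded: np.ndarray) -> np.ndarray:
        Y = (embedded - self.mean) @ self.components
        if self.whiten:
            Y = Y / np.sqrt(np.maximum(self.explained_variance, 1e-300))
        return Y


@dataclass
class HMMModel:
    """Zero-mean Gaussian HMM over the projected space."""

    n_states: int
    transition: np.ndarray  # (K, K) row-stochastic
    initial: np.ndarray  # (K,)
    covariances: np.ndarray  # (K, P, P) symmetric positive definite

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        K = self.n_states
        if self.transition.shape != (K, K):
            raise ValueError("transition must be K x K")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition rows must sum to 1")
        if self.initial.shape != (K,):
            raise ValueError("initial must have length K")
        if self.covariances.shape[:1] != (K,):
            raise ValueError("need one covariance per state")
        for k in range(K):
            cholesky(self.covariances[k], lower=True)  # PD check

    @property
    def dim(self) -> int:
        return self.covariances.shape[1]

    def permuted(self, perm: np.ndarray) -> "HMMModel":
        """Model with states reordered so new state k = old state perm[k]."""
        perm = np.asarray(perm, dtype=int)
        return HMMModel(
            n_states=self.n_states,
            transition=self.transition[np.ix_(perm, perm)],
            initial=self.initial[perm],
            covariances=self.covariances[perm],
        )

    def save(self, path: str | Path) -> None:
        payload = {
            "n_states": self.n_states,
            "transition": self.transition.tolist(),
            "initial": self.initial.tolist(),
            "covariances": self.covariances.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "HMMModel":
        d = json.loads(Path(path).read_text())
        return cls(
            n_states=d["n_states"],
            transition=np.asarray(d["transition"]),
            initial=np.asarray(d["initial"]),
            covariances=np.asarray(d["covariances"]),
        )


@dataclass
class StatePosterior:
    """Per-sample posterior state probabilities and model evidence."""

    gamma: np.ndarray  # (T, K); NaN rows where samples are bad
    log_evidence: float
    viterbi_path: np.ndarray | None = None
    bad_rows: np.ndarray | None = field(default=None)

    def good_rows(self) -> np.ndarray:
        if self.bad_rows is None:
            return np.ones(self.gamma.shape[0], dtype=bool)
        return ~self.bad_rows

    def hard_states(self) -> np.ndarray:
        """1-based argmax state per sample (0 for bad samples)."""
        out = np.zeros(self.gamma.shape[0], dtype=int)
        good = self.good_rows()
        out[good] = np.argmax(self.gamma[good], axis=1) + 1
        return out


# -------------------------------------------------------------- embedding


def time_delay_embed(
    X: np.ndarray,
    cfg: EmbeddingConfig,
    bad_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Embed channels x samples into (T - 2L) x C(2L+1).

    Row t (for original sample index t + L) holds, channel-major, the
    channel values at offsets -L..+L: column ``c * (2L + 1) + (l + L)`` is
    ``X[c, t + L + l]``.  Returns (embedded, bad_rows) where a row is bad
    if any sample it touches is bad.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    C, T = X.shape
    if C != cfg.channels_in:
        raise ValueError("channel count does not match config")
    L = cfg.n_lags_each_side
    n_rows = T - 2 * L
    if n_rows < 1:
        raise ValueError("series too short for the requested lags")
    cols = []
    for c in range(C):
        for l in range(-L, L + 1):
            cols.append(X[c, L + l : L + l + n_rows])
    embedded = np.column_stack(cols)

    if bad_mask is None:
        bad_rows = np.zeros(n_rows, dtype=bool)
    else:
        bad_mask = np.asarray(bad_mask, dtype=bool)
        if bad_mask.shape != (T,):
            raise ValueError("bad_mask length must equal samples")
        # window max: row t touches samples t .. t + 2L
        kernel = np.ones(2 * L + 1)
        touched = np.convolve(bad_mask.astype(float), kernel, mode="valid")
        bad_rows = touched > 0
    return embedded, bad_rows


def fit_pca(
    embedded: np.ndarray,
    n_components: int = 120,
    bad_rows: np.ndarray | None = None,
    whiten: bool = False,
) -> PCABasis:
    """PCA basis from the eigendecomposition of the good-row covariance."""
    embedded = np.asarray(embedded, dtype=float)
    good = (
        np.ones(embedded.shape[0], dtype=bool)
        if bad_rows is None
        else ~np.asarray(bad_rows, dtype=bool)
    )
    Z = embedded[good]
    n, d = Z.shape
    if n_components > d:
        raise ValueError("n_components exceeds embedded dimension")
    if n < n_components:
        raise ValueError("fewer rows than requested components")
    mean = Z.mean(axis=0)
    cov = np.cov(Z - mean, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_components]
    return PCABasis(
        components=evecs[:, order],
        explained_variance=np.maximum(evals[order], 0.0),
        total_variance=float(np.sum(np.maximum(evals, 0.0))),
        mean=mean,
        whiten=whiten,
    )


# --------------------------------------------------------------- emissions


def _emission_loglik(model: HMMModel, Y: np.ndarray) -> np.ndarray:
    """(T, K) log N(y_t | 0, Sigma_k)."""
    T, P = Y.shape
    K = model.n_states
    out = np.empty((T, K))
    const = -0.5 * P * np.log(2 * np.pi)
    eye = np.eye(P)
    for k in range(K):
        L = cholesky(model.covariances[k], lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        Linv = solve_triangular(L, eye, lower=True)
        sol = Y @ Linv.T
        quad = np.einsum("ij,ij->i", sol, sol)
        out[:, k] = const - 0.5 * logdet - 0.5 * quad
    return out


def _segments(bad_rows: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index intervals of contiguous good rows."""
    good = ~bad_rows
    padded = np.concatenate(([False], good, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def _forward_scan(B: np.ndarray, A: np.ndarray, pi: np.ndarray):
    T, K = B.shape
    alpha = np.empty((T, K))
    scale = np.empty(T)
    a = pi * B[0]
    s = a.sum()
    if s <= 0:
        return alpha, scale, 0
    alpha[0] = a / s
    scale[0] = s
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        s = a.sum()
        if s <= 0:
            return alpha, scale, t
        alpha[t] = a / s
        scale[t] = s
    return alpha, scale, -1


def _backward_scan(B: np.ndarray, A: np.ndarray, scale: np.ndarray):
    T, K = B.shape
    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / scale[t + 1]
    return beta


try:  # optional acceleration; the numpy fallback is the reference path
    from numba import njit as _njit

    _forward_scan = _njit(cache=True, fastmath=False)(_forward_scan)
    _backward_scan = _njit(cache=True, fastmath=False)(_backward_scan)
except ImportError:  # pragma: no cover
    pass


def _forward_backward_segment(
    loglik: np.ndarray, transition: np.ndarray, initial: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward-backward on one contiguous segment.

    Returns (gamma, xi_sum, log_evidence); xi_sum is the summed expected
    transition-count matrix.
    """
    T, K = loglik.shape
    # subtract per-row max for stability before exponentiating
    shift = loglik.max(axis=1, keepdims=True)
    B = np.exp(loglik - shift)
    alpha, scale, fail = _forward_scan(B, transition, initial)
    if fail >= 0:
        raise FloatingPointError(f"zero-probability deadlock at sample {fail}")
    beta = _backward_scan(B, transition, scale)
    if T > 1:
        bb = B[1:] * beta[1:] / scale[1:, None]
        xi_sum = transition * (alpha[:-1].T @ bb)
    else:
        xi_sum = np.zeros((K, K))
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    log_ev = float(np.sum(np.log(scale)) + np.sum(shift))
    return gamma, xi_sum, log_ev


def forward_backward(
    model: HMMModel,
    Y: np.ndarray,
    bad_rows: np.ndarray | None = None,
) -> StatePosterior:
    """Exact posteriors and log-evidence; one run per contiguous good segment."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != model.dim:
        raise ValueError("Y must be T x model.dim")
    T = Y.shape[0]
    bad = (
        np.zeros(T, dtype=bool)
        if bad_rows is None
        else np.asarray(bad_rows, dtype=bool)
    )
    gamma = np.full((T, model.n_states), np.nan)
    log_ev = 0.0
    loglik = _emission_loglik(model, Y)
    for lo, hi in _segments(bad):
        g, _, le = _forward_backward_segment(
            loglik[lo:hi], model.transition, model.initial
        )
        gamma[lo:hi] = g
        log_ev += le
    return StatePosterior(gamma=gamma, log_evidence=log_ev, bad_rows=bad)


# ---------------------------------------------------------------- training


def _m_step_covariances(
    Y: np.ndarray, gamma: np.ndarray, ridge: float
) -> np.ndarray:
    K = gamma.shape[1]
    P = Y.shape[1]
    covs = np.empty((K, P, P))
    for k in range(K):
        w = gamma[:, k]
        total = w.sum()
        S = (Y * w[:, None]).T @ Y / max(total, 1e-300)
        S += ridge * np.mean(np.diag(S)) * np.eye(P) + 1e-12 * np.eye(P)
        covs[k] = 0.5 * (S + S.T)
    return covs


def _init_model(
    Y: np.ndarray, K: int, rng: np.random.Generator, ridge: float
) -> HMMModel:
    T = Y.shape[0]
    gamma0 = rng.dirichlet(np.ones(K), size=T)
    covs = _m_step_covariances(Y, gamma0, ridge=max(ridge, 1e-3))
    A = np.full((K, K), 0.1 / max(K - 1, 1))
    np.fill_diagonal(A, 0.9 if K > 1 else 1.0)
    return HMMModel(
        n_states=K,
        transition=A,
        initial=np.full(K, 1.0 / K),
        covariances=covs,
    )


def _em(
    Y: np.ndarray,
    model: HMMModel,
    bad: np.ndarray,
    tol: float,
    max_iter: int,
    ridge: float,
    update_covariances: bool = True,
) -> tuple[HMMModel, StatePosterior, list[float]]:
    T = Y.shape[0]
    K = model.n_states
    segs = _segments(bad)
    n_good = int((~bad).sum())
    history: list[float] = []
    gamma = np.full((T, K), np.nan)
    prev_ll = -np.inf
    for _ in range(max_iter):
        loglik = _emission_loglik(model, Y)
        xi_total = np.zeros((K, K))
        init_acc = np.zeros(K)
        log_ev = 0.0
        for lo, hi in segs:
            g, xi, le = _forward_backward_segment(
                loglik[lo:hi], model.transition, model.initial
            )
            gamma[lo:hi] = g
            xi_total += xi
            init_acc += g[0]
            log_ev += le
        history.append(log_ev)

        trans = xi_total / np.maximum(xi_total.sum(axis=1, keepdims=True), 1e-300)
        zero_rows = xi_total.sum(axis=1) == 0
        trans[zero_rows] = 1.0 / K
        initial = init_acc / init_acc.sum()
        covs = (
            _m_step_covariances(Y[~bad], gamma[~bad], ridge)
            if update_covariances
            else model.covariances
        )
        try:
            model = HMMModel(
                n_states=K, transition=trans, initial=initial, covariances=covs
            )
        except np.linalg.LinAlgError:
            warnings.warn("singular covariance update; keeping previous model")
            break
        if abs(log_ev - prev_ll) / n_good < tol:
            break
        prev_ll = log_ev
    post = StatePosterior(gamma=gamma, log_evidence=history[-1], bad_rows=bad)
    return model, post, history


def fit_hmm(
    Y: np.ndarray,
    K: int,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 100,
    n_restarts: int = 3,
    ridge: float = 1e-6,
    bad_rows: np.ndarray | None = None,
) -> tuple[HMMModel, StatePosterior, list[float]]:
    """EM training with restarts; best model by final log-likelihood.

    Returns (model, posterior, log-likelihood history of the best restart).
    """
    Y = np.asarray(Y, dtype=float)
    if not np.all(np.isfinite(Y)):
        raise ValueError("Y must be finite")
    if K < 1:
        raise ValueError("K must be >= 1")
    T = Y.shape[0]
    if K > T:
        raise ValueError("more states than samples")
    bad = (
        np.zeros(T, dtype=bool)
        if bad_rows is None
        else np.asarray(bad_rows, dtype=bool)
    )
    seeds = np.random.SeedSequence(seed).spawn(max(n_restarts, 1))
    best: tuple[HMMModel, StatePosterior, list[float]] | None = None
    for ss in seeds:
        rng = np.random.default_rng(ss)
        model0 = _init_model(Y[~bad], K, rng, ridge)
        fitted = _em(Y, model0, bad, tol=tol, max_iter=max_iter, ridge=ridge)
        if best is None or fitted[1].log_evidence > best[1].log_evidence:
            best = fitted
    assert best is not None
    return best


def infer_with_canonical_states(
    canonical: HMMModel,
    Y: np.ndarray,
    re_estimate_transition: bool = True,
    bad_rows: np.ndarray | None = None,
    tol: float = 1e-5,
    max_iter: int = 50,
) -> StatePosterior:
    """Infer state time courses with fixed canonical observation models.

    With ``re_estimate_transition`` the transition matrix and initial
    distribution are re-fit by EM while covariances stay fixed; otherwise a
    single forward-backward pass with the canonical dynamics is returned.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != canonical.dim:
        raise ValueError("data dimension does not match canonical model")
    if not re_estimate_transition:
        return forward_backward(canonical, Y, bad_rows=bad_rows)
    bad = (
        np.zeros(Y.shape[0], dtype=bool)
        if bad_rows is None
        else np.asarray(bad_rows, dtype=bool)
    )
    _, post, _ = _em(
        Y,
        canonical,
        bad,
        tol=tol,
        max_iter=max_iter,
        ridge=0.0,
        update_covariances=False,
    )
    return post


# ---------------------------------------------------------------- summaries


def fractional_occupancy(post: StatePosterior) -> np.ndarray:
    """Mean posterior probability per state over good samples; sums to 1."""
    good = post.good_rows()
    if not np.any(good):
        raise ValueError("no good samples")
    return post.gamma[good].mean(axis=0)


def match_states(estimated: HMMModel, reference: HMMModel) -> np.ndarray:
    """Permutation aligning estimated states to reference states.

    Returns ``perm`` with ``perm[k]`` = index of the estimated state
    assigned to reference state ``k``, maximizing the summed Pearson
    correlation between vectorized state covariance matrices.  Apply as
    ``estimated.permuted(perm)`` or ``gamma[:, perm]``.
    """
    if estimated.n_states != reference.n_states:
        raise ValueError("state counts differ")
    if estimated.dim != reference.dim:
        raise ValueError("dimensions differ")
    K = reference.n_states
    sim = np.empty((K, K))
    for i in range(K):
        a = reference.covariances[i].ravel()
        for j in range(K):
            b = estimated.covariances[j].ravel()
            sim[i, j] = np.corrcoef(a, b)[0, 1]
    row, col = linear_sum_assignment(-sim)
    perm = np.empty(K, dtype=int)
    perm[row] = col
    return perm


def match_states_by_sequence(
    hard_states: np.ndarray, true_states: np.ndarray, n_states: int
) -> np.ndarray:
    """Permutation aligning hard state labels to a ground-truth sequence.

    Maximizes per-sample agreement via the confusion matrix; both inputs
    are 1-based with 0 allowed for masked samples.  ``perm[k]`` is the
    estimated state (0-based) matched to true state k+1.
    """
    conf = np.zeros((n_states, n_states))
    valid = (hard_states > 0) & (true_states > 0)
    for t_true, t_est in zip(true_states[valid], hard_states[valid]):
        conf[t_true - 1, t_est - 1] += 1
    row, col = linear_sum_assignment(-conf)
    perm = np.empty(n_states, dtype=int)
    perm[row] = col
    return perm
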