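"""Variational-Bayes Gaussian-emission HMMs on E* series with evidence-based
selection of the number of states.

The generative model: hidden state z_t follows a first-order Markov chain
(Dirichlet priors on the initial distribution and each transition row); the
observed per-frame E* is Gaussian given the state, with a conjugate
Normal-Gamma prior on each state's mean and precision.  Coordinate-ascent
variational inference yields a lower bound on the marginal likelihood (the
"evidence"); fitting K = 1..3 and keeping the argmax automates the choice of
the number of FRET states, penalizing complexity the Bayesian way.  Decoded
paths come from Viterbi under the posterior point estimates, posterior state
marginals from forward-backward.

Invalid (masked) frames split a series into segments separated by gaps of at
least 3 frames; segments share parameters and each restarts from the initial
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln

from . import _hmm_core
from .types import FretSeries

__all__ = [
    "HmmPriors",
    "HmmModel",
    "StatePath",
    "fit_vb_hmm",
    "select_model",
    "decode_path",
    "categorize_states",
]

_LN2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class HmmPriors:
    """Conjugate hyperparameters (all weakly informative by default).

    ``mean_loc=None`` centres the emission-mean prior on the series mean.
    The Gamma(shape=1, rate=0.01) precision prior puts the prior emission sd
    near 0.1 E* units.
    """

    dirichlet: float = 1.0
    mean_loc: float | None = None
    mean_precision: float = 0.1
    precision_shape: float = 1.0
    precision_rate: float = 0.01


@dataclass
class HmmModel:
    n_states: int
    initial_probs: np.ndarray
    transition_matrix: np.ndarray
    emission_mean: np.ndarray
    emission_sd: np.ndarray
    evidence: float
    converged: bool
    n_iterations: int
    elbo_trace: np.ndarray = field(repr=False, default=None)
    priors: HmmPriors = HmmPriors()
    evidence_by_k: dict[int, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "initial_probs": self.initial_probs.tolist(),
            "transition_matrix": self.transition_matrix.tolist(),
            "emission_mean": self.emission_mean.tolist(),
            "emission_sd": self.emission_sd.tolist(),
            "evidence": self.evidence,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "evidence_by_k": {str(k): v for k, v in self.evidence_by_k.items()},
            "priors": {
                "dirichlet": self.priors.dirichlet,
                "mean_loc": self.priors.mean_loc,
                "mean_precision": self.priors.mean_precision,
                "precision_shape": self.priors.precision_shape,
                "precision_rate": self.priors.precision_rate,
            },
        }


@dataclass
class StatePath:
    states: np.ndarray      # per-frame decoded state; -1 on invalid frames
    posterior: np.ndarray   # (T, K); NaN rows on invalid frames


def segments_from_mask(mask: np.ndarray, min_gap: int = 3) -> list[np.ndarray]:
    """Index arrays of valid frames, split where >= ``min_gap`` invalid
    frames intervene (shorter gaps are simply dropped from a segment)."""
    idx = np.flatnonzero(np.asarray(mask, bool))
    if idx.size == 0:
        return []
    gaps = np.diff(idx)
    cuts = np.flatnonzero(gaps > min_gap)
    return [seg for seg in np.split(idx, cuts + 1) if seg.size]


def _kl_dirichlet(alpha: np.ndarray, alpha0: float) -> float:
    a0 = np.full_like(alpha, alpha0)
    s, s0 = alpha.sum(), a0.sum()
    return float(
        gammaln(s) - gammaln(s0)
        - (gammaln(alpha) - gammaln(a0)).sum()
        + ((alpha - a0) * (digamma(alpha) - digamma(s))).sum()
    )


def _kl_normal_gamma(
    m, beta, a, b, m0: float, beta0: float, a0: float, b0: float
) -> float:
    kl_gamma = (
        (a - a0) * digamma(a) - gammaln(a) + gammaln(a0)
        + a0 * (np.log(b) - np.log(b0)) + a * (b0 - b) / b
    )
    kl_mu = (
        0.5 * np.log(beta / beta0) + 0.5 * beta0 / beta
        + 0.5 * beta0 * (a / b) * (m - m0) ** 2 - 0.5
    )
    return float((kl_gamma + kl_mu).sum())


class _Posterior:
    """Variational posterior factors for one restart."""

    __slots__ = ("alpha_pi", "alpha_A", "m", "beta", "a", "b")

    def __init__(self, alpha_pi, alpha_A, m, beta, a, b):
        self.alpha_pi = alpha_pi
        self.alpha_A = alpha_A
        self.m = m
        self.beta = beta
        self.a = a
        self.b = b


def _e_step(segments: list[np.ndarray], q: _Posterior):
    """Forward-backward with exponentiated expected-log parameters."""
    k = q.m.size
    ln_pi = digamma(q.alpha_pi) - digamma(q.alpha_pi.sum())
    ln_A = digamma(q.alpha_A) - digamma(q.alpha_A.sum(axis=1))[:, None]
    pi_t = np.exp(ln_pi)
    A_t = np.exp(ln_A)
    e_ln_lam = digamma(q.a) - np.log(q.b)
    e_lam = q.a / q.b
    logZ = 0.0
    gamma_first = np.zeros(k)
    xi_sum = np.zeros((k, k))
    nk = np.zeros(k)
    sx = np.zeros(k)
    sxx = np.zeros(k)
    gammas = []
    for x in segments:
        logB = 0.5 * (
            e_ln_lam[None, :] - _LN2PI
            - e_lam[None, :] * (x[:, None] - q.m[None, :]) ** 2
            - 1.0 / q.beta[None, :]
        )
        g, xi, lz = _hmm_core.forward_backward(logB, pi_t, A_t)
        logZ += lz
        gamma_first += g[0]
        xi_sum += xi
        nk += g.sum(axis=0)
        sx += g.T @ x
        sxx += g.T @ (x * x)
        gammas.append(g)
    return logZ, gamma_first, xi_sum, nk, sx, sxx, gammas


def _m_step(
    stats, k: int, m0: float, pri: HmmPriors
) -> _Posterior:
    _, gamma_first, xi_sum, nk, sx, sxx, _ = stats
    alpha_pi = pri.dirichlet + gamma_first
    alpha_A = pri.dirichlet + xi_sum
    xbar = np.where(nk > 0, sx / np.maximum(nk, 1e-300), m0)
    ssq = np.maximum(sxx - nk * xbar**2, 0.0)
    beta = pri.mean_precision + nk
    m = (pri.mean_precision * m0 + nk * xbar) / beta
    a = pri.precision_shape + 0.5 * nk
    b = pri.precision_rate + 0.5 * (
        ssq + pri.mean_precision * nk * (xbar - m0) ** 2 / beta
    )
    return _Posterior(alpha_pi, alpha_A, m, beta, a, b)


def _elbo(logZ: float, q: _Posterior, m0: float, pri: HmmPriors) -> float:
    k = q.m.size
    kl = _kl_dirichlet(q.alpha_pi, pri.dirichlet)
    for row in q.alpha_A:
        kl += _kl_dirichlet(row, pri.dirichlet)
    kl += _kl_normal_gamma(
        q.m, q.beta, q.a, q.b,
        m0, pri.mean_precision, pri.precision_shape, pri.precision_rate,
    )
    return logZ - kl


def _init_posterior(
    x: np.ndarray, k: int, m0: float, pri: HmmPriors,
    rng: np.random.Generator, jitter: bool,
) -> _Posterior:
    n = x.size
    mu = np.quantile(x, (np.arange(k) + 0.5) / k)
    if jitter:
        spread = max(float(x.std()), 1e-3)
        mu = mu + rng.normal(0.0, 0.5 * spread / k, size=k)
    var0 = max(float(x.var()) / max(k, 1), 1e-8)
    beta = np.full(k, pri.mean_precision + n / k)
    a = np.full(k, pri.precision_shape + 0.5 * n / k)
    b = a * var0
    alpha_pi = np.full(k, pri.dirichlet + n / k)
    alpha_A = np.full((k, k), pri.dirichlet) + (n / k) * np.eye(k)
    return _Posterior(alpha_pi, alpha_A, mu, beta, a, b)


def _sort_states(q: _Posterior) -> _Posterior:
    order = np.argsort(q.m)
    return _Posterior(
        q.alpha_pi[order], q.alpha_A[np.ix_(order, order)],
        q.m[order], q.beta[order], q.a[order], q.b[order],
    )


def fit_vb_hmm(
    fret_series: FretSeries | np.ndarray,
    n_states: int,
    priors: HmmPriors = HmmPriors(),
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
    min_frames: int = 50,
) -> HmmModel:
    """Fit one K by coordinate-ascent VB; keep the best of seeded restarts.

    The first restart is deterministic (quantile-placed means); the rest add
    seeded jitter.  Raises on fewer than ``min_frames`` valid frames (such
    molecules stay classifiable as static by mean E*).
    """
    if not 1 <= n_states <= 3:
        raise ValueError("n_states must be 1..3")
    values, mask = _coerce_series(fret_series)
    segs_idx = segments_from_mask(mask)
    segments = [values[idx] for idx in segs_idx]
    n_valid = sum(s.size for s in segments)
    if n_valid < min_frames:
        raise ValueError(f"needs >= {min_frames} valid frames, got {n_valid}")
    x_all = np.concatenate(segments)
    m0 = priors.mean_loc if priors.mean_loc is not None else float(x_all.mean())
    rng = np.random.default_rng(np.random.SeedSequence((seed, n_states)))

    best = None
    for restart in range(max(1, n_restarts)):
        q = _init_posterior(x_all, n_states, m0, priors, rng, jitter=restart > 0)
        trace = []
        converged = False
        prev = -np.inf
        for _ in range(max_iter):
            stats = _e_step(segments, q)
            f = _elbo(stats[0], q, m0, priors)
            trace.append(f)
            if abs(f - prev) < tol:
                converged = True
                break
            prev = f
            q = _m_step(stats, n_states, m0, priors)
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], q, np.array(trace), converged)

    evidence, q, trace, converged = best
    q = _sort_states(q)
    return HmmModel(
        n_states=n_states,
        initial_probs=q.alpha_pi / q.alpha_pi.sum(),
        transition_matrix=q.alpha_A / q.alpha_A.sum(axis=1, keepdims=True),
        emission_mean=q.m.copy(),
        emission_sd=np.sqrt(q.b / q.a),
        evidence=float(evidence),
        converged=converged,
        n_iterations=len(trace),
        elbo_trace=trace,
        priors=priors,
    )


def select_model(
    fret_series: FretSeries | np.ndarray,
    k_max: int = 3,
    priors: HmmPriors = HmmPriors(),
    seed: int = 0,
    **fit_kwargs,
) -> HmmModel:
    """Fit K = 1..k_max and return the maximum-evidence model (ties, within
    1e-9, go to the smaller K)."""
    evidences: dict[int, float] = {}
    models: dict[int, HmmModel] = {}
    for k in range(1, k_max + 1):
        model = fit_vb_hmm(fret_series, k, priors=priors, seed=seed, **fit_kwargs)
        models[k] = model
        evidences[k] = model.evidence
    best_k = 1
    for k in range(2, k_max + 1):
        if evidences[k] > evidences[best_k] + 1e-9:
            best_k = k
    chosen = models[best_k]
    chosen.evidence_by_k = evidences
    return chosen


def decode_path(
    model: HmmModel, fret_series: FretSeries | np.ndarray
) -> StatePath:
    """Viterbi path and forward-backward marginals under point estimates."""
    values, mask = _coerce_series(fret_series)
    k = model.n_states
    t_total = values.size
    states = np.full(t_total, -1, dtype=np.int64)
    posterior = np.full((t_total, k), np.nan)
    var = model.emission_sd**2
    log_pi = np.log(np.maximum(model.initial_probs, 1e-300))
    log_A = np.log(np.maximum(model.transition_matrix, 1e-300))
    for idx in segments_from_mask(mask):
        x = values[idx]
        logB = (
            -0.5 * _LN2PI - 0.5 * np.log(var)[None, :]
            - 0.5 * (x[:, None] - model.emission_mean[None, :]) ** 2 / var[None, :]
        )
        path, _ = _hmm_core.viterbi(logB, log_pi, log_A)
        gamma, _, _ = _hmm_core.forward_backward(
            logB, model.initial_probs, model.transition_matrix
        )
        states[idx] = path
        posterior[idx] = gamma
    return StatePath(states=states, posterior=posterior)


def categorize_states(
    model: HmmModel, boundaries: tuple[float, float] = (0.275, 0.40)
) -> list[str]:
    """Map each state to closed / intermediate / open by its emission mean
    (half-open intervals; a mean exactly at the upper boundary is open)."""
    lo, hi = boundaries
    out = []
    for mu in model.emission_mean:
        if mu < lo:
            out.append("closed")
        elif mu < hi:
            out.append("intermediate")
        else:
            out.append("open")
    return out


def _coerce_series(series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, FretSeries):
        return series.efficiency, series.valid & np.isfinite(series.efficiency)
    values = np.asarray(series, float)
    return values, np.isfinite(values)
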