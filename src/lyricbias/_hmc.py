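"""Minimal Hamiltonian Monte Carlo with dual-averaging step-size
adaptation and (diagonal or dense) mass-matrix estimation from warmup.

Kept deliberately small: a log-density-with-gradient callable in, an
array of draws out.  Used by :mod:`lyricbias.model`; not a general
probabilistic-programming layer.  A dense metric is the default for
moderate dimensionality because the posteriors fitted here have strong
linear correlations (year-level covariates against year intercepts).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ChainResult", "sample_chain", "sample_chains"]

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


class _Metric:
    """Euclidean metric: kinetic energy 0.5 * p' Sigma p with momentum
    p ~ N(0, Sigma^{-1}); Sigma is the estimated posterior covariance."""

    def __init__(self, dim: int):
        self.dim = dim
        self._diag: np.ndarray | None = np.ones(dim)
        self._sigma: np.ndarray | None = None
        self._chol: np.ndarray | None = None  # Cholesky of Sigma

    def set_diag(self, var: np.ndarray) -> None:
        self._diag = var
        self._sigma = self._chol = None

    def set_dense(self, sigma: np.ndarray) -> None:
        self._chol = np.linalg.cholesky(sigma)
        self._sigma = sigma
        self._diag = None

    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        xi = rng.standard_normal(self.dim)
        if self._diag is not None:
            return xi / np.sqrt(self._diag)
        # p = L^{-T} xi has covariance Sigma^{-1}
        return np.linalg.solve(self._chol.T, xi)

    def kinetic(self, p: np.ndarray) -> float:
        if self._diag is not None:
            return 0.5 * float(np.sum(p * p * self._diag))
        return 0.5 * float(np.sum((self._chol.T @ p) ** 2))

    def velocity(self, p: np.ndarray) -> np.ndarray:
        if self._diag is not None:
            return self._diag * p
        return self._sigma @ p


@dataclass
class ChainResult:
    samples: np.ndarray  # (draws, dim)
    accept_rate: float
    step_size: float
    divergences: int


def _leapfrog(
    logp_grad: LogpGrad,
    q: np.ndarray,
    p: np.ndarray,
    grad: np.ndarray,
    eps: float,
    n_steps: int,
    metric: _Metric,
):
    q, p = q.copy(), p.copy()
    logp = -np.inf
    p += 0.5 * eps * grad
    for step in range(n_steps):
        q += eps * metric.velocity(p)
        logp, grad = logp_grad(q)
        if not np.isfinite(logp):
            return q, p, logp, grad
        if step != n_steps - 1:
            p += eps * grad
    p += 0.5 * eps * grad
    return q, p, logp, grad


def _find_initial_step(
    logp_grad: LogpGrad, q: np.ndarray, metric: _Metric, rng: np.random.Generator
) -> float:
    eps = 0.1
    logp0, grad0 = logp_grad(q)
    p0 = metric.sample_momentum(rng)
    h0 = logp0 - metric.kinetic(p0)

    def joint(eps_try: float) -> float:
        q1, p1, logp1, _ = _leapfrog(logp_grad, q, p0, grad0, eps_try, 1, metric)
        return (logp1 - metric.kinetic(p1)) if np.isfinite(logp1) else -np.inf

    direction = 1 if (joint(eps) - h0) > math.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0**direction
        crossed = (joint(eps) - h0) > math.log(0.5)
        if (direction == 1 and not crossed) or (direction == -1 and crossed):
            break
    return float(np.clip(eps, 1e-8, 10.0))


def _shrunk_cov(window: np.ndarray) -> np.ndarray:
    """Covariance estimate regularised toward its own diagonal
    (Stan-style shrinkage)."""
    n = window.shape[0]
    cov = np.cov(window, rowvar=False)
    w = n / (n + 5.0)
    cov = w * cov + (1 - w) * np.diag(np.diag(cov)) + 1e-6 * np.eye(cov.shape[0])
    return cov


def sample_chain(
    logp_grad: LogpGrad,
    init: np.ndarray,
    warmup: int,
    draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.85,
    path_length: float = 1.5,
    max_steps: int = 128,
    dense_mass: bool = True,
    dense_max_dim: int = 600,
    divergence_threshold: float = 1000.0,
) -> ChainResult:
    """Run one HMC chain; returns post-warmup draws."""
    dim = init.size
    q = init.astype(float).copy()
    metric = _Metric(dim)

    logp, grad = logp_grad(q)
    if not np.isfinite(logp):
        raise RuntimeError("non-finite log density at initialisation")

    eps = _find_initial_step(logp_grad, q, metric, rng)
    # dual averaging (Hoffman & Gelman 2014 defaults)
    mu = math.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    mass_window: list[np.ndarray] = []
    win_lo, win_hi = int(warmup * 0.25), int(warmup * 0.75)

    samples = np.empty((draws, dim))
    n_accept = 0
    divergences = 0
    total = warmup + draws

    for it in range(total):
        p0 = metric.sample_momentum(rng)
        h0 = logp - metric.kinetic(p0)
        # short trajectories until the metric is estimated: early warmup
        # only needs to reach the typical set, not explore it
        step_cap = max_steps if it >= win_hi else min(max_steps, 24)
        n_steps = int(
            np.clip(round(path_length * rng.uniform(0.7, 1.3) / eps), 1, step_cap)
        )
        q1, p1, logp1, grad1 = _leapfrog(logp_grad, q, p0, grad, eps, n_steps, metric)
        if np.isfinite(logp1):
            delta = (logp1 - metric.kinetic(p1)) - h0
        else:
            delta = -np.inf
        if delta < -divergence_threshold:
            divergences += 1
        accept_prob = min(1.0, math.exp(min(delta, 0.0)))
        if rng.uniform() < accept_prob:
            q, logp, grad = q1, logp1, grad1
            if it >= warmup:
                n_accept += 1

        if it < warmup:
            frac = 1.0 / (it + 1 + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - accept_prob)
            log_eps = mu - math.sqrt(it + 1) / gamma * h_bar
            w = (it + 1) ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = math.exp(log_eps)
            if win_lo <= it < win_hi:
                mass_window.append(q.copy())
            if it == win_hi - 1 and len(mass_window) >= 10:
                window = np.asarray(mass_window)
                if dense_mass and dim <= dense_max_dim:
                    metric.set_dense(_shrunk_cov(window))
                else:
                    metric.set_diag(np.var(window, axis=0) + 1e-6)
                eps = _find_initial_step(logp_grad, q, metric, rng)
                mu = math.log(10.0 * eps)
                log_eps_bar, h_bar = 0.0, 0.0
            if it == warmup - 1:
                eps = math.exp(log_eps_bar)
        else:
            samples[it - warmup] = q

    return ChainResult(
        samples=samples,
        accept_rate=n_accept / max(draws, 1),
        step_size=eps,
        divergences=divergences,
    )


def sample_chains(
    logp_grad: LogpGrad,
    init_fn: Callable[[np.random.Generator], np.ndarray],
    n_chains: int,
    warmup: int,
    draws: int,
    seed: int,
    **kwargs,
) -> list[ChainResult]:
    """Run ``n_chains`` sequential chains with independent substreams."""
    seqs = np.random.SeedSequence(seed).spawn(n_chains)
    results = []
    for c, seq in enumerate(seqs):
        rng = np.random.default_rng(seq)
        res = sample_chain(logp_grad, init_fn(rng), warmup, draws, rng, **kwargs)
        logger.debug(
            "chain %d: accept=%.2f step=%.3g divergences=%d",
            c, res.accept_rate, res.step_size, res.divergences,
        )
        results.append(res)
    return results
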