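"""Bayesian aggregated-binomial multilevel model.

Per design row (one song), the response is k polarity words out of W,
with

    p = inverse-logit(alpha + a_artist + a_genre + a_year + sum_j beta_j x_j)

and adaptively regularising varying intercepts: a_g ~ Normal(0, sigma_g)
with sigma_g ~ Exponential(rate).  Sampling uses Hamiltonian Monte Carlo
on a non-centred parameterisation with analytic gradients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, gammaln, log_expit

from ._hmc import sample_chains
from .covariates import Design, DesignRow
from .sentiment import Polarity

logger = logging.getLogger(__name__)

__all__ = [
    "PriorConfig",
    "SamplerConfig",
    "ModelSpec",
    "FitResult",
    "CoefSummary",
    "ConvergenceWarning",
    "log_likelihood",
    "log_prior",
    "fit",
    "summarize",
    "odds_interpretation",
]

EFFECT_ORDER = ("success", "prestige", "unbiased", "rank")
GROUP_ORDER = ("artist", "genre", "year")


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class PriorConfig:
    """Weakly regularising defaults; all overridable."""

    alpha_loc: float = 0.0
    alpha_scale: float = 1.5
    beta_scale: float = 1.0
    sigma_rate: float = 1.0


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 4
    draws: int = 1000
    warmup: int = 1000
    target_accept: float = 0.85
    path_length: float = 1.5
    max_steps: int = 128
    dense_mass: bool = True
    rhat_threshold: float = 1.01
    ess_threshold: float = 400.0


@dataclass(frozen=True)
class ModelSpec:
    polarity: Polarity
    effects: tuple[str, ...] = ()
    groups: tuple[str, ...] = ("artist", "genre", "year")
    priors: PriorConfig = PriorConfig()
    sampler: SamplerConfig = SamplerConfig()

    def __post_init__(self) -> None:
        for e in self.effects:
            if e not in EFFECT_ORDER:
                raise ValueError(f"unknown effect {e!r}")
        for g in self.groups:
            if g not in GROUP_ORDER:
                raise ValueError(f"unknown grouping factor {g!r}")


@dataclass
class CoefSummary:
    name: str
    mean: float
    lower: float
    upper: float
    excludes_zero: bool

    def __post_init__(self) -> None:
        if not (self.lower <= self.mean <= self.upper):
            raise ValueError("mean outside interval")


@dataclass
class FitResult:
    """Posterior draws plus pointwise log-likelihood and diagnostics."""

    posterior: dict[str, np.ndarray]  # each (chains, draws) or (chains, draws, levels)
    log_lik: np.ndarray  # (chains, draws, rows)
    diagnostics: dict[str, dict[str, float]]
    spec: ModelSpec
    seed: int
    groups_used: tuple[str, ...]
    sampler_info: dict = field(default_factory=dict)

    def stacked(self, name: str) -> np.ndarray:
        arr = self.posterior[name]
        return arr.reshape(-1, *arr.shape[2:])

    @property
    def loglik_matrix(self) -> np.ndarray:
        """Pointwise log-likelihood, (total draws, rows)."""
        c, d, n = self.log_lik.shape
        return self.log_lik.reshape(c * d, n)

    @property
    def n_draws(self) -> int:
        c, d = self.posterior["alpha"].shape[:2]
        return c * d


# ---------------------------------------------------------------------------
# densities


def _rows_of(design: Design | Sequence[DesignRow]) -> list[DesignRow]:
    return list(design.rows) if isinstance(design, Design) else list(design)


def log_likelihood(
    params: Mapping[str, object], design: Design | Sequence[DesignRow]
) -> np.ndarray:
    """Per-row aggregated-binomial log-likelihood (binomial coefficient
    included).

    ``params`` holds ``alpha`` (float), ``beta`` (mapping effect name ->
    float) and optional ``a_artist``/``a_genre``/``a_year`` arrays
    indexed by the rows' grouping indices.  A p of exactly 0 or 1 with
    incompatible k yields ``-inf``, never an exception.
    """
    rows = _rows_of(design)
    k = np.array([r.k for r in rows], dtype=float)
    W = np.array([r.W for r in rows], dtype=float)
    eta = np.full(len(rows), float(params.get("alpha", 0.0)))
    beta: Mapping[str, float] = params.get("beta", {})  # type: ignore[assignment]
    for name, value in beta.items():
        eta += float(value) * np.array([r.covariate(name) for r in rows])
    for group, attr in (("a_artist", "artist_idx"), ("a_genre", "genre_idx"), ("a_year", "year_idx")):
        if group in params and params[group] is not None:
            a = np.asarray(params[group], dtype=float)
            idx = np.array([getattr(r, attr) for r in rows])
            eta += a[idx]
    with np.errstate(invalid="ignore"):
        ll = (
            k * log_expit(eta)
            + (W - k) * log_expit(-eta)
            + gammaln(W + 1) - gammaln(k + 1) - gammaln(W - k + 1)
        )
    # 0 * -inf -> nan; that means k=0 (or k=W) against p=0 (or 1): consistent, contributes 0
    ll = np.where(np.isnan(ll), _ll_edge(k, W, eta), ll)
    return ll


def _ll_edge(k: np.ndarray, W: np.ndarray, eta: np.ndarray) -> np.ndarray:
    out = np.zeros_like(k, dtype=float)
    p = expit(eta)
    bad = ((p == 0.0) & (k > 0)) | ((p == 1.0) & (k < W))
    out[bad] = -np.inf
    return out


def log_prior(params: Mapping[str, object], spec: ModelSpec) -> float:
    """Joint log prior density of global intercept, slopes, centred group
    intercepts and group standard deviations."""
    pr = spec.priors
    alpha = float(params.get("alpha", 0.0))
    out = _normal_logpdf(alpha, pr.alpha_loc, pr.alpha_scale)
    beta: Mapping[str, float] = params.get("beta", {})  # type: ignore[assignment]
    for value in beta.values():
        out += _normal_logpdf(float(value), 0.0, pr.beta_scale)
    for group in GROUP_ORDER:
        a = params.get(f"a_{group}")
        sigma = params.get(f"sigma_{group}")
        if a is None and sigma is None:
            continue
        sigma = float(sigma)  # type: ignore[arg-type]
        if sigma <= 0:
            return -np.inf
        # Exponential(rate) prior on sigma
        out += np.log(pr.sigma_rate) - pr.sigma_rate * sigma
        if a is not None:
            a = np.asarray(a, dtype=float)
            out += float(np.sum(_normal_logpdf(a, 0.0, sigma)))
    return float(out)


def _normal_logpdf(x, loc, scale):
    z = (np.asarray(x, dtype=float) - loc) / scale
    return -0.5 * z**2 - np.log(scale) - 0.5 * np.log(2 * np.pi)


# ---------------------------------------------------------------------------
# fitting


def _design_arrays(design: Design, spec: ModelSpec):
    rows = design.rows
    if not rows:
        raise ValueError("empty design")
    k = np.array([r.k for r in rows], dtype=float)
    W = np.array([r.W for r in rows], dtype=float)
    effects = tuple(e for e in EFFECT_ORDER if e in spec.effects)
    X = np.empty((len(rows), len(effects)))
    for j, e in enumerate(effects):
        X[:, j] = [r.covariate(e) for r in rows]
        if np.ptp(X[:, j]) == 0.0:
            raise ValueError(f"degenerate design: covariate column {e!r} is constant")
    groups = []
    for g in GROUP_ORDER:
        if g not in spec.groups:
            continue
        if g == "genre" and not design.has_genre:
            logger.info("fit: genre factor dropped (no genre information)")
            continue
        attr = f"{g}_idx"
        idx = np.array([getattr(r, attr) for r in rows])
        n_levels = int(idx.max()) + 1
        if n_levels < 2:
            raise ValueError(f"grouping factor {g!r} has fewer than 2 levels")
        groups.append((g, idx, n_levels))
    log_binom = gammaln(W + 1) - gammaln(k + 1) - gammaln(W - k + 1)
    return k, W, X, effects, groups, log_binom


def fit(spec: ModelSpec, design: Design, seed: int) -> FitResult:
    """Sample the posterior by HMC; reproducible given ``seed``.

    Emits a :class:`ConvergenceWarning` if any split-chain R-hat exceeds
    the configured threshold or any bulk effective sample size falls
    below it.
    """
    k_rows, W_rows, X_rows, effects, groups_rows, log_binom = _design_arrays(design, spec)
    pr, sc = spec.priors, spec.sampler
    n_beta = len(effects)

    # rows sharing grouping indices and covariates have identical linear
    # predictors: by binomial sufficiency they can be pooled for sampling
    # (pointwise log-likelihoods are still reported per original row)
    key = np.column_stack(
        [idx.astype(float) for _, idx, _ in groups_rows] + [X_rows]
    )
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    k = np.bincount(inverse, weights=k_rows)
    W = np.bincount(inverse, weights=W_rows)
    X = X_rows[first]
    groups = [(g, idx[first], n) for g, idx, n in groups_rows]

    group_sizes = [n for _, _, n in groups]
    dim = 1 + n_beta + sum(group_sizes) + len(groups)

    idx_arrays = [idx for _, idx, _ in groups]
    z_slices = []
    offset = 1 + n_beta
    for n in group_sizes:
        z_slices.append(slice(offset, offset + n))
        offset += n
    logsig_slice = slice(offset, offset + len(groups))

    def logp_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        alpha = theta[0]
        beta = theta[1 : 1 + n_beta]
        logsig = theta[logsig_slice]
        with np.errstate(over="ignore"):
            # overflow -> inf -> -inf log density -> proposal rejected
            sig = np.exp(logsig)
        eta = alpha + (X @ beta if n_beta else 0.0)
        zs = []
        for gi, sl in enumerate(z_slices):
            z = theta[sl]
            zs.append(z)
            eta = eta + sig[gi] * z[idx_arrays[gi]]
        ll = k * log_expit(eta) + (W - k) * log_expit(-eta)
        p = expit(eta)
        r = k - W * p
        logp = float(np.sum(ll) + np.sum(log_binom))
        grad = np.empty(dim)
        # priors
        logp += -0.5 * ((alpha - pr.alpha_loc) / pr.alpha_scale) ** 2
        grad[0] = np.sum(r) - (alpha - pr.alpha_loc) / pr.alpha_scale**2
        if n_beta:
            logp += float(-0.5 * np.sum((beta / pr.beta_scale) ** 2))
            grad[1 : 1 + n_beta] = X.T @ r - beta / pr.beta_scale**2
        for gi, sl in enumerate(z_slices):
            z = zs[gi]
            c = np.bincount(idx_arrays[gi], weights=r, minlength=group_sizes[gi])
            logp += float(-0.5 * np.sum(z**2))
            grad[sl] = sig[gi] * c - z
            # Exponential(rate) prior on sigma, log transform Jacobian
            logp += -pr.sigma_rate * sig[gi] + logsig[gi]
            grad[logsig_slice][gi] = (
                sig[gi] * float(z @ c) - pr.sigma_rate * sig[gi] + 1.0
            )
        return logp, grad

    def init_fn(rng: np.random.Generator) -> np.ndarray:
        theta = 0.1 * rng.standard_normal(dim)
        theta[logsig_slice] = np.log(0.5) + 0.1 * rng.standard_normal(len(groups))
        logp, _ = logp_grad(theta)
        if not np.isfinite(logp):
            raise RuntimeError("non-finite log density at initialisation")
        return theta

    chains = sample_chains(
        logp_grad,
        init_fn,
        n_chains=sc.chains,
        warmup=sc.warmup,
        draws=sc.draws,
        seed=seed,
        target_accept=sc.target_accept,
        path_length=sc.path_length,
        max_steps=sc.max_steps,
        dense_mass=sc.dense_mass,
    )
    samples = np.stack([c.samples for c in chains])  # (C, D, dim)

    posterior: dict[str, np.ndarray] = {"alpha": samples[:, :, 0]}
    for j, e in enumerate(effects):
        posterior[f"beta_{e}"] = samples[:, :, 1 + j]
    for gi, (g, _, n) in enumerate(groups):
        sigma = np.exp(samples[:, :, logsig_slice][:, :, gi])
        posterior[f"sigma_{g}"] = sigma
        posterior[f"a_{g}"] = sigma[:, :, None] * samples[:, :, z_slices[gi]]

    # pointwise log-likelihood per original design row at every saved draw
    C, D = samples.shape[:2]
    log_lik = np.empty((C, D, len(k_rows)))
    for ci in range(C):
        for di in range(D):
            theta = samples[ci, di]
            eta = theta[0] + (X @ theta[1 : 1 + n_beta] if n_beta else 0.0)
            sig = np.exp(theta[logsig_slice])
            for gi, sl in enumerate(z_slices):
                eta = eta + sig[gi] * theta[sl][idx_arrays[gi]]
            eta_r = np.broadcast_to(eta, k.shape)[inverse]
            log_lik[ci, di] = (
                k_rows * log_expit(eta_r)
                + (W_rows - k_rows) * log_expit(-eta_r)
                + log_binom
            )

    diagnostics = _diagnostics(posterior)
    _warn_on_convergence(diagnostics, sc)
    return FitResult(
        posterior=posterior,
        log_lik=log_lik,
        diagnostics=diagnostics,
        spec=spec,
        seed=seed,
        groups_used=tuple(g for g, _, _ in groups),
        sampler_info={
            "accept_rates": [c.accept_rate for c in chains],
            "step_sizes": [c.step_size for c in chains],
            "divergences": [c.divergences for c in chains],
        },
    )


def _diagnostics(posterior: dict[str, np.ndarray]) -> dict[str, dict[str, float]]:
    import arviz as az

    scalars = {n: a for n, a in posterior.items() if a.ndim == 2 and not n.startswith("a_")}
    idata = az.from_dict(posterior=scalars)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    out = {}
    for name in scalars:
        out[name] = {
            "rhat": float(rhat[name].values),
            "ess_bulk": float(ess[name].values),
        }
    return out


def _warn_on_convergence(diagnostics, sc: SamplerConfig) -> None:
    bad_rhat = {n: d["rhat"] for n, d in diagnostics.items() if d["rhat"] > sc.rhat_threshold}
    bad_ess = {n: d["ess_bulk"] for n, d in diagnostics.items() if d["ess_bulk"] < sc.ess_threshold}
    if bad_rhat:
        warnings.warn(
            f"split-chain R-hat above {sc.rhat_threshold}: {bad_rhat}", ConvergenceWarning
        )
    if bad_ess:
        warnings.warn(
            f"bulk effective sample size below {sc.ess_threshold:g}: {bad_ess}",
            ConvergenceWarning,
        )


# ---------------------------------------------------------------------------
# summaries


def summarize(fit_result: FitResult, ci_mass: float = 0.89) -> list[CoefSummary]:
    """Equal-tailed credible interval summaries for all scalar parameters."""
    if fit_result.n_draws < 100:
        raise ValueError("need at least 100 draws to summarise")
    lo_q, hi_q = (1 - ci_mass) / 2, 1 - (1 - ci_mass) / 2
    out = []
    for name, arr in fit_result.posterior.items():
        if arr.ndim != 2:
            continue
        draws = arr.reshape(-1)
        lo, hi = float(np.quantile(draws, lo_q)), float(np.quantile(draws, hi_q))
        out.append(
            CoefSummary(
                name=name,
                mean=float(np.mean(draws)),
                lower=lo,
                upper=hi,
                excludes_zero=not (lo <= 0.0 <= hi),
            )
        )
    return out


def odds_interpretation(beta: float) -> float:
    """Percent change in odds per unit predictor: 100*(exp(beta) - 1)."""
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    return float(100.0 * np.expm1(beta))
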