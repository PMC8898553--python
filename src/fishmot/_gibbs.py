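"""Gibbs samplers for hierarchical probit and Gaussian linear models.

The probit sampler follows the Albert & Chib (1993) data-augmentation
scheme: conditional on the coefficients, each binary response has a
truncated-normal latent utility; conditional on the latents, the full
coefficient vector (fixed effects and per-group random-effect
deviations stacked into one design) is multivariate Gaussian and is
drawn exactly from its conditional.  Random-effect standard deviations
carry half-normal priors and are updated by univariate slice sampling
on the log scale.  All updates are exact conditional draws, so the
chain targets the posterior without tuning.

The Gaussian sampler reuses the same structure with the latent step
replaced by the observed response and an additional slice update for
the residual SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import ndtr, ndtri

__all__ = ["GibbsResult", "sample_probit", "sample_gaussian", "slice_sample"]

_TINY = 1e-300


def slice_sample(logpdf, x0: float, rng: np.random.Generator, w: float = 1.0) -> float:
    """One univariate slice-sampling update (stepping out + shrinkage)."""
    logy = logpdf(x0) - rng.exponential()
    u = rng.uniform()
    lo, hi = x0 - w * u, x0 + w * (1 - u)
    for _ in range(50):
        if logpdf(lo) < logy:
            break
        lo -= w
    for _ in range(50):
        if logpdf(hi) < logy:
            break
        hi += w
    for _ in range(100):
        x1 = rng.uniform(lo, hi)
        if logpdf(x1) >= logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


def _truncnorm_latent(eta: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw z ~ N(eta, 1) truncated to z > 0 where y=1 and z < 0 where y=0.

    Uses tail-stable inverse-CDF forms so extreme linear predictors do
    not produce infinities.
    """
    u = rng.uniform(size=eta.shape)
    z = np.empty_like(eta)
    pos = y > 0.5
    # z > 0:  z = eta - ndtri((1-u) * Phi(-eta))  [upper-tail stable]
    arg = np.maximum((1.0 - u[pos]) * ndtr(eta[pos]), _TINY)
    z[pos] = eta[pos] - ndtri(arg)
    # z < 0:  z = eta + ndtri(u * Phi(-eta))
    neg = ~pos
    arg = np.maximum(u[neg] * ndtr(-eta[neg]), _TINY)
    z[neg] = eta[neg] + ndtri(arg)
    return z


@dataclass
class GibbsResult:
    """Raw posterior draws: coefficients (chain, draw, p) and
    random-effect / residual SDs (chain, draw, k)."""

    beta: np.ndarray
    sigma: np.ndarray
    sigma_resid: np.ndarray | None = None


def _draw_beta(
    WtW: np.ndarray,
    Wtz: np.ndarray,
    prior_prec: np.ndarray,
    rng: np.random.Generator,
    obs_prec: float = 1.0,
) -> np.ndarray:
    q = obs_prec * WtW + np.diag(prior_prec)
    c, low = cho_factor(q, lower=True)
    mean = cho_solve((c, low), obs_prec * Wtz)
    eps = rng.standard_normal(len(mean))
    return mean + solve_triangular(c, eps, lower=low, trans="T")


def _sd_logpdf_factory(m: int, ssq: float, prior_scale: float):
    """Log conditional of log(sigma) for m deviations with sum of squares
    ssq under a half-normal(prior_scale) prior on sigma (incl. Jacobian)."""

    def logpdf(x: float) -> float:
        s2 = math.exp(2.0 * x)
        return -m * x - ssq / (2.0 * s2) - s2 / (2.0 * prior_scale**2) + x

    return logpdf


def sample_probit(
    W: np.ndarray,
    y: np.ndarray,
    fixed_prior_sd: np.ndarray,
    group_cols: list[np.ndarray],
    sd_prior_scale: float = 1.0,
    n_chains: int = 4,
    warmup: int = 1000,
    draws: int = 1000,
    seed: int = 0,
) -> GibbsResult:
    """Hierarchical probit posterior via data augmentation.

    ``W`` stacks fixed-effect columns first, then random-effect
    columns; ``fixed_prior_sd`` gives the Gaussian prior SD of each
    fixed column; ``group_cols[k]`` indexes the columns whose
    coefficients share the k-th random-effect SD.
    """
    W = np.asarray(W, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = W.shape
    n_fixed = len(fixed_prior_sd)
    k_types = len(group_cols)
    WtW = W.T @ W

    seeds = np.random.SeedSequence(seed).spawn(n_chains)
    beta_out = np.empty((n_chains, draws, p))
    sigma_out = np.empty((n_chains, draws, max(k_types, 1)))
    for chain in range(n_chains):
        rng = np.random.default_rng(seeds[chain])
        beta = np.zeros(p)
        sigma = np.ones(max(k_types, 1))
        prior_prec = np.zeros(p)
        prior_prec[:n_fixed] = 1.0 / np.asarray(fixed_prior_sd) ** 2
        for it in range(warmup + draws):
            eta = W @ beta
            z = _truncnorm_latent(eta, y, rng)
            for k in range(k_types):
                prior_prec[group_cols[k]] = 1.0 / sigma[k] ** 2
            beta = _draw_beta(WtW, W.T @ z, prior_prec, rng)
            for k in range(k_types):
                cols = group_cols[k]
                ssq = float(np.sum(beta[cols] ** 2))
                logx = slice_sample(
                    _sd_logpdf_factory(len(cols), ssq, sd_prior_scale),
                    math.log(max(sigma[k], 1e-6)),
                    rng,
                )
                sigma[k] = math.exp(np.clip(logx, -13.0, 13.0))
            if it >= warmup:
                beta_out[chain, it - warmup] = beta
                sigma_out[chain, it - warmup] = sigma
    return GibbsResult(beta=beta_out, sigma=sigma_out)


def sample_gaussian(
    X: np.ndarray,
    y: np.ndarray,
    fixed_prior_sd: np.ndarray,
    group_cols: list[np.ndarray],
    sd_prior_scale: float = 1.0,
    resid_prior_scale: float = 1.0,
    n_chains: int = 4,
    warmup: int = 1000,
    draws: int = 1000,
    seed: int = 0,
) -> GibbsResult:
    """Hierarchical Gaussian linear model posterior.

    Same coefficient layout as :func:`sample_probit`; the residual SD
    gets a half-normal(``resid_prior_scale``) prior and a slice update.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    n_fixed = len(fixed_prior_sd)
    k_types = len(group_cols)
    XtX = X.T @ X
    Xty = X.T @ y

    seeds = np.random.SeedSequence(seed).spawn(n_chains)
    beta_out = np.empty((n_chains, draws, p))
    sigma_out = np.empty((n_chains, draws, max(k_types, 1)))
    resid_out = np.empty((n_chains, draws))
    for chain in range(n_chains):
        rng = np.random.default_rng(seeds[chain])
        beta = np.zeros(p)
        sigma = np.ones(max(k_types, 1))
        sigma_e = float(np.std(y)) or 1.0
        prior_prec = np.zeros(p)
        prior_prec[:n_fixed] = 1.0 / np.asarray(fixed_prior_sd) ** 2
        for it in range(warmup + draws):
            for k in range(k_types):
                prior_prec[group_cols[k]] = 1.0 / sigma[k] ** 2
            beta = _draw_beta(XtX, Xty, prior_prec, rng, obs_prec=1.0 / sigma_e**2)
            resid = y - X @ beta
            rss = float(resid @ resid)
            logx = slice_sample(
                _sd_logpdf_factory(n, rss, resid_prior_scale),
                math.log(max(sigma_e, 1e-6)),
                rng,
            )
            sigma_e = math.exp(np.clip(logx, -13.0, 13.0))
            for k in range(k_types):
                cols = group_cols[k]
                ssq = float(np.sum(beta[cols] ** 2))
                logx = slice_sample(
                    _sd_logpdf_factory(len(cols), ssq, sd_prior_scale),
                    math.log(max(sigma[k], 1e-6)),
                    rng,
                )
                sigma[k] = math.exp(np.clip(logx, -13.0, 13.0))
            if it >= warmup:
                beta_out[chain, it - warmup] = beta
                sigma_out[chain, it - warmup] = sigma
                resid_out[chain, it - warmup] = sigma_e
    return GibbsResult(beta=beta_out, sigma=sigma_out, sigma_resid=resid_out)
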