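"""Maximum-likelihood Gaussian-mixture meta-analysis of QTL positions.

Per chromosome, the observed QTL positions ``x_i`` are modelled as draws
from a K-component mixture of normals whose component means are the
candidate meta-QTL positions. Each observation carries its own known
variance ``sigma_i^2`` derived from the study's confidence interval — the
classic meta-QTL formulation in which the mixture has no free component
variance. The log-likelihood

    L = sum_i log sum_k pi_k N(x_i; mu_k, sigma_i^2)

is maximized by expectation-maximization: responsibilities
``r_ik ∝ pi_k N(x_i; mu_k, sigma_i^2)``, weight updates
``pi_k = mean_i r_ik`` and precision-weighted mean updates
``mu_k = (sum_i r_ik x_i / sigma_i^2) / (sum_i r_ik / sigma_i^2)``.
The number of meta-QTL is selected by refitting for K = 1..kmax and
minimizing an information criterion (AIC by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = ["MetaModelConfig", "MetaQtlFit", "fit_mixture", "select_model", "metaqtl_intervals"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class MetaModelConfig:
    """EM and model-selection settings.

    kmax
        largest number of meta-QTL tried per chromosome (10, the customary
        upper bound in meta-QTL software).
    criterion
        ``AIC`` (default), ``AICc`` or ``BIC``; the per-K criterion that is
        minimized. A mixture with K components has 2K - 1 free parameters
        (K means, K - 1 weights).
    tol / max_iter
        EM stops when the log-likelihood gain falls below ``tol`` or after
        ``max_iter`` iterations.
    restarts
        number of initializations per K: the first places means at
        K-quantiles of the data, the rest jitter those quantiles with the
        seeded generator.
    k_fixed
        force a specific K instead of criterion-based selection.
    """

    kmax: int = 10
    criterion: str = "AIC"
    tol: float = 1e-8
    max_iter: int = 500
    restarts: int = 10
    seed: int = 0
    k_fixed: int | None = None

    def __post_init__(self) -> None:
        if self.kmax < 1:
            raise ValueError("kmax must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.criterion not in ("AIC", "AICc", "BIC"):
            raise ValueError(f"unknown criterion: {self.criterion!r}")


@dataclass
class MetaQtlFit:
    """Converged mixture fit for one chromosome.

    Components are sorted by mean. ``mu_ci`` holds the 95% interval of each
    component mean, half-width ``1.96 / sqrt(sum_i r_ik / sigma_i^2)`` (the
    responsibility-weighted precision of the consensus position).
    """

    K: int
    mu: np.ndarray
    pi: np.ndarray
    loglik: float
    score: float
    resp: np.ndarray
    mu_ci: np.ndarray  # (K, 2)
    n_iter: int = 0
    converged: bool = True


def _log_density(x: np.ndarray, sigmas: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """log N(x_i; mu_k, sigma_i^2) as an (n, K) matrix."""
    z = (x[:, None] - mu[None, :]) / sigmas[:, None]
    return -0.5 * (z * z) - np.log(sigmas)[:, None] - 0.5 * _LOG_2PI


def _em_once(
    x: np.ndarray,
    sigmas: np.ndarray,
    mu0: np.ndarray,
    config: MetaModelConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool]:
    n, K = x.size, mu0.size
    mu = mu0.astype(float).copy()
    pi = np.full(K, 1.0 / K)
    inv_var = 1.0 / (sigmas * sigmas)
    prev_ll = -np.inf
    converged = False
    it = 0
    resp = np.full((n, K), 1.0 / K)
    for it in range(1, config.max_iter + 1):
        log_p = _log_density(x, sigmas, mu) + np.log(np.maximum(pi, 1e-300))[None, :]
        norm = logsumexp(log_p, axis=1)
        ll = float(norm.sum())
        # EM ascent property; tiny negative drift only from floating point
        if ll < prev_ll - 1e-8:
            raise RuntimeError(f"EM log-likelihood decreased: {prev_ll} -> {ll}")
        resp = np.exp(log_p - norm[:, None])
        if ll - prev_ll < config.tol and it > 1:
            prev_ll = ll
            converged = True
            break
        prev_ll = ll
        nk = resp.sum(axis=0)
        # collapse guard: an emptied component restarts at the worst-fit point
        empty = nk < 1e-6
        if np.any(empty):
            worst = int(np.argmin(norm))
            mu[empty] = x[worst]
            pi = np.where(empty, 1.0 / n, nk / n)
            pi = pi / pi.sum()
            continue
        pi = nk / n
        w = resp * inv_var[:, None]
        mu = (w * x[:, None]).sum(axis=0) / w.sum(axis=0)
    return mu, pi, resp, prev_ll, it, converged


def fit_mixture(
    positions, sigmas, K: int, config: MetaModelConfig = MetaModelConfig()
) -> MetaQtlFit:
    """Fit a K-component mixture to QTL positions with known variances.

    Runs ``config.restarts`` EM initializations and returns the best by
    log-likelihood, with components sorted by mean and the criterion score
    attached.
    """
    x = np.asarray(positions, dtype=float)
    s = np.asarray(sigmas, dtype=float)
    if x.size != s.size:
        raise ValueError("positions and sigmas must have equal length")
    if x.size == 0:
        raise ValueError("at least one QTL required")
    if np.any(s <= 0):
        raise ValueError("all sigmas must be positive")
    if K > x.size:
        raise ValueError(f"K={K} exceeds the number of QTL ({x.size})")

    quantiles = np.quantile(x, (np.arange(K) + 0.5) / K)
    rng = np.random.default_rng(config.seed)
    spread = max(float(x.max() - x.min()), 1.0)

    best: tuple[float, tuple] | None = None
    for restart in range(max(config.restarts, 1)):
        mu0 = quantiles if restart == 0 else quantiles + rng.normal(0.0, 0.05 * spread, K)
        mu, pi, resp, ll, it, conv = _em_once(x, s, mu0, config)
        if best is None or ll > best[0] + 1e-12:
            best = (ll, (mu, pi, resp, it, conv))
    ll, (mu, pi, resp, it, conv) = best

    order = np.argsort(mu)
    mu, pi, resp = mu[order], pi[order], resp[:, order]
    pi = pi / pi.sum()

    inv_var = 1.0 / (s * s)
    precision = (resp * inv_var[:, None]).sum(axis=0)
    half = 1.96 / np.sqrt(np.maximum(precision, 1e-12))
    mu_ci = np.column_stack([mu - half, mu + half])

    n_params = 2 * K - 1
    n = x.size
    if config.criterion == "AIC":
        score = 2.0 * n_params - 2.0 * ll
    elif config.criterion == "BIC":
        score = n_params * np.log(n) - 2.0 * ll
    else:  # AICc
        denom = n - n_params - 1
        score = 2.0 * n_params - 2.0 * ll
        score = score + (2.0 * n_params * (n_params + 1) / denom if denom > 0 else np.inf)
    return MetaQtlFit(
        K=K, mu=mu, pi=pi, loglik=ll, score=float(score),
        resp=resp, mu_ci=mu_ci, n_iter=it, converged=conv,
    )


def select_model(
    positions, sigmas, config: MetaModelConfig = MetaModelConfig()
) -> tuple[MetaQtlFit, list[MetaQtlFit]]:
    """Fit K = 1..min(kmax, n) and return the criterion-minimizing fit.

    Ties break toward smaller K. The full per-K table of fits is returned
    alongside for reporting. ``config.k_fixed`` short-circuits selection.
    """
    x = np.asarray(positions, dtype=float)
    if x.size == 0:
        raise ValueError("at least one QTL required")
    if config.k_fixed is not None:
        fit = fit_mixture(positions, sigmas, config.k_fixed, config)
        return fit, [fit]
    table: list[MetaQtlFit] = []
    best: MetaQtlFit | None = None
    for K in range(1, min(config.kmax, x.size) + 1):
        fit = fit_mixture(positions, sigmas, K, config)
        table.append(fit)
        if best is None or fit.score < best.score - 1e-12:
            best = fit
    return best, table


def metaqtl_intervals(
    fit: MetaQtlFit, chrom_length: float | None = None
) -> list[tuple[float, float, float]]:
    """(mu, ci_lo, ci_hi) per component, sorted by mu, clipped to the map."""
    out = []
    for k in range(fit.K):
        lo, hi = fit.mu_ci[k]
        if chrom_length is not None:
            lo, hi = max(lo, 0.0), min(hi, chrom_length)
        out.append((float(fit.mu[k]), float(lo), float(hi)))
    return sorted(out, key=lambda t: t[0])
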