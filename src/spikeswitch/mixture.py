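"""Single Gaussian vs equal-weight two-Gaussian mixture comparison.

A neuron codes difficulty *binarily* when its per-trial mean firing rate in
the encoding window is better described as a 50/50 mixture of two Gaussians
(trials that switched vs trials that did not) than as one Gaussian:

    GM(x) = 0.5 N(x; mu1, sigma1) + 0.5 N(x; mu2, sigma2)

The mixture has 4 free parameters (two means, two SDs; the weights are
fixed), the single Gaussian 2. Models are compared with
BIC = -2 lnL + p ln T (T = number of trials); ΔBIC = BIC_mixture -
BIC_single < 0 favors the mixture. Because small negative ΔBIC values can
arise by chance, significance is assessed by Monte Carlo: datasets of the
same size are drawn from the fitted single Gaussian, both models are refit
on each, and the p-value is the add-one fraction of null ΔBIC values at
least as negative as the observed one.

The mixture is fit by EM with the weights clamped at 0.5; restarts are
initialized from seeded random pairs of data points (plus one restart at
the single-Gaussian solution, an EM fixed point, which guarantees the
mixture likelihood never falls below the single-Gaussian likelihood).
Component SDs are floored at 1e-3 of the data SD to keep the likelihood
bounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "GaussianFit",
    "MixtureFit",
    "MixtureComparison",
    "fit_single_gaussian",
    "fit_equal_weight_mixture",
    "bic",
    "delta_bic_test",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class GaussianFit:
    mu: float
    sigma: float
    log_likelihood: float
    n_params: int = 2


@dataclass
class MixtureFit:
    """Equal-weight two-component Gaussian fit (mu1 <= mu2)."""

    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    log_likelihood: float
    responsibilities: np.ndarray  # (n, 2) posterior component probabilities
    n_params: int = 4
    converged: bool = True


@dataclass
class MixtureComparison:
    """BIC comparison of mixture vs single Gaussian for one neuron/side."""

    single: GaussianFit
    mixture: MixtureFit
    bic_single: float
    bic_mixture: float
    delta_bic: float
    p_value: Optional[float]
    n_resamples: int
    convergence_warning: bool = False

    def summary(self) -> str:
        p = "n/a (ΔBIC >= 0)" if self.p_value is None else f"{self.p_value:.4f}"
        return (
            "Equal-weight mixture vs single Gaussian\n"
            f"single:  mu={self.single.mu:.3f} sigma={self.single.sigma:.3f} "
            f"lnL={self.single.log_likelihood:.3f} BIC={self.bic_single:.3f}\n"
            f"mixture: mu=({self.mixture.mu1:.3f}, {self.mixture.mu2:.3f}) "
            f"sigma=({self.mixture.sigma1:.3f}, {self.mixture.sigma2:.3f}) "
            f"lnL={self.mixture.log_likelihood:.3f} BIC={self.bic_mixture:.3f}\n"
            f"ΔBIC={self.delta_bic:.3f}  Monte-Carlo p={p} "
            f"({self.n_resamples} resamples)")


def _variance_floor(values: np.ndarray) -> float:
    sd = float(np.std(values))
    return 1e-3 * sd if sd > 0 else 1e-6


def fit_single_gaussian(values: np.ndarray,
                        floor: Optional[float] = None) -> GaussianFit:
    """Maximum-likelihood Gaussian (1/n variance, SD floored)."""
    x = np.asarray(values, float)
    if x.size < 4:
        raise ValueError("need at least 4 values")
    if floor is None:
        floor = _variance_floor(x)
    mu = float(x.mean())
    sigma = max(float(x.std()), floor)
    ll = float(-0.5 * x.size * _LOG2PI - x.size * math.log(sigma)
               - np.sum((x - mu) ** 2) / (2.0 * sigma**2))
    return GaussianFit(mu=mu, sigma=sigma, log_likelihood=ll)


def _em_equal_weight_batch_np(data: np.ndarray, mu0: np.ndarray,
                              sigma0: np.ndarray, floor: np.ndarray,
                              max_iter: int = 500, rtol: float = 1e-8):
    """Vectorized equal-weight 2-component EM over a batch of datasets.

    data (B, n); mu0/sigma0 (B, 2); floor (B,). Returns
    (mu, sigma, ll, resp, converged)."""
    B = data.shape[0]
    mu = mu0.astype(float).copy()
    sigma = np.maximum(sigma0.astype(float), floor[:, None])
    ll_old = np.full(B, np.nan)
    converged = np.zeros(B, dtype=bool)
    active = np.arange(B)

    def _estep(d, m_, s_):
        z = (d[:, :, None] - m_[:, None, :]) / s_[:, None, :]
        logp = -0.5 * z**2 - np.log(s_[:, None, :]) - 0.5 * _LOG2PI
        mx = logp.max(axis=2, keepdims=True)
        pe = np.exp(logp - mx)
        tot = pe.sum(axis=2)
        ll = (math.log(0.5) + mx[:, :, 0] + np.log(tot)).sum(axis=1)
        return ll, pe / tot[:, :, None]

    for _ in range(max_iter):
        d = data[active]
        ll_a, resp = _estep(d, mu[active], sigma[active])
        done = np.abs(ll_a - ll_old[active]) <= \
            rtol * (np.abs(ll_old[active]) + 1e-12)
        ll_old[active] = ll_a
        converged[active[done]] = True
        keep = ~done
        active = active[keep]
        if active.size == 0:
            break
        d, resp = d[keep], resp[keep]
        w = np.maximum(resp.sum(axis=1), 1e-300)     # (B_active, 2)
        mu_a = (resp * d[:, :, None]).sum(axis=1) / w
        var = (resp * (d[:, :, None] - mu_a[:, None, :]) ** 2).sum(axis=1) / w
        mu[active] = mu_a
        sigma[active] = np.maximum(np.sqrt(var), floor[active, None])
    # final E-step so the reported likelihood matches the returned params
    ll, resp = _estep(data, mu, sigma)
    return mu, sigma, ll, resp, converged


try:  # compiled inner loop; the numpy path above is the reference fallback
    from numba import njit

    @njit(cache=False)
    def _em_batch_jit(data, mu0, sigma0, floor,
                      max_iter, rtol):  # pragma: no cover - compiled
        B, n = data.shape
        mu = mu0.copy()
        sigma = sigma0.copy()
        ll_out = np.empty(B)
        resp_out = np.empty((B, n, 2))
        conv = np.zeros(B, np.bool_)
        c_half = math.log(0.5)
        c_norm = 0.5 * math.log(2.0 * math.pi)
        for b in range(B):
            x = data[b]
            m1, m2 = mu[b, 0], mu[b, 1]
            s1 = max(sigma[b, 0], floor[b])
            s2 = max(sigma[b, 1], floor[b])
            ll_old = np.nan
            for _ in range(max_iter):
                ll = 0.0
                w1 = w2 = 0.0
                sx1 = sx2 = 0.0
                sq1 = sq2 = 0.0
                for i in range(n):
                    z1 = (x[i] - m1) / s1
                    z2 = (x[i] - m2) / s2
                    lp1 = -0.5 * z1 * z1 - math.log(s1) - c_norm
                    lp2 = -0.5 * z2 * z2 - math.log(s2) - c_norm
                    mx = lp1 if lp1 > lp2 else lp2
                    p1 = math.exp(lp1 - mx)
                    p2 = math.exp(lp2 - mx)
                    tot = p1 + p2
                    ll += c_half + mx + math.log(tot)
                    r1 = p1 / tot
                    r2 = p2 / tot
                    w1 += r1
                    w2 += r2
                    sx1 += r1 * x[i]
                    sx2 += r2 * x[i]
                    resp_out[b, i, 0] = r1
                    resp_out[b, i, 1] = r2
                if not np.isnan(ll_old) and \
                        abs(ll - ll_old) <= rtol * (abs(ll_old) + 1e-12):
                    conv[b] = True
                    break
                ll_old = ll
                m1n = sx1 / max(w1, 1e-300)
                m2n = sx2 / max(w2, 1e-300)
                for i in range(n):
                    sq1 += resp_out[b, i, 0] * (x[i] - m1n) ** 2
                    sq2 += resp_out[b, i, 1] * (x[i] - m2n) ** 2
                m1, m2 = m1n, m2n
                s1 = max(math.sqrt(sq1 / max(w1, 1e-300)), floor[b])
                s2 = max(math.sqrt(sq2 / max(w2, 1e-300)), floor[b])
            # final E-step so ll/resp match the returned parameters
            ll = 0.0
            for i in range(n):
                z1 = (x[i] - m1) / s1
                z2 = (x[i] - m2) / s2
                lp1 = -0.5 * z1 * z1 - math.log(s1) - c_norm
                lp2 = -0.5 * z2 * z2 - math.log(s2) - c_norm
                mx = lp1 if lp1 > lp2 else lp2
                p1 = math.exp(lp1 - mx)
                p2 = math.exp(lp2 - mx)
                tot = p1 + p2
                ll += c_half + mx + math.log(tot)
                resp_out[b, i, 0] = p1 / tot
                resp_out[b, i, 1] = p2 / tot
            mu[b, 0], mu[b, 1] = m1, m2
            sigma[b, 0], sigma[b, 1] = s1, s2
            ll_out[b] = ll
        return mu, sigma, ll_out, resp_out, conv

    def _em_equal_weight_batch(data, mu0, sigma0, floor,
                               max_iter: int = 500, rtol: float = 1e-8):
        return _em_batch_jit(np.ascontiguousarray(data, dtype=np.float64),
                             np.ascontiguousarray(mu0, dtype=np.float64),
                             np.ascontiguousarray(sigma0, dtype=np.float64),
                             np.ascontiguousarray(floor, dtype=np.float64),
                             max_iter, rtol)

except Exception:  # pragma: no cover - numba unavailable
    _em_equal_weight_batch = _em_equal_weight_batch_np


def _mixture_restart_inits(data: np.ndarray, n_restarts: int,
                           rng: np.random.Generator
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Initial (mu, sigma) pairs: restart 0 at the single-Gaussian solution,
    the rest from random pairs of data points with the pooled SD."""
    B, n = data.shape
    mu0 = np.empty((B, n_restarts, 2))
    pooled = np.maximum(data.std(axis=1), 1e-12)
    sigma0 = np.broadcast_to(pooled[:, None, None], (B, n_restarts, 2)).copy()
    mu0[:, 0, :] = data.mean(axis=1)[:, None]
    if n_restarts > 1:
        idx = rng.integers(0, n, size=(B, n_restarts - 1, 2))
        flat = np.take_along_axis(data, idx.reshape(B, -1), axis=1)
        mu0[:, 1:, :] = flat.reshape(B, n_restarts - 1, 2)
    return mu0, sigma0


def _fit_mixture_batch(data: np.ndarray, n_restarts: int,
                       rng: np.random.Generator,
                       floor: Optional[np.ndarray] = None):
    """Best-of-restarts equal-weight mixture fit for a batch of datasets."""
    B, n = data.shape
    if floor is None:
        floor = np.array([_variance_floor(row) for row in data])
    mu0, sigma0 = _mixture_restart_inits(data, n_restarts, rng)
    best_ll = np.full(B, -np.inf)
    best_mu = np.zeros((B, 2))
    best_sigma = np.ones((B, 2))
    best_resp = np.zeros((B, n, 2))
    best_conv = np.zeros(B, dtype=bool)
    for r in range(n_restarts):
        mu, sigma, ll, resp, conv = _em_equal_weight_batch(
            data, mu0[:, r], sigma0[:, r], floor)
        better = ll > best_ll
        best_ll = np.where(better, ll, best_ll)
        best_mu[better] = mu[better]
        best_sigma[better] = sigma[better]
        best_resp[better] = resp[better]
        best_conv[better] = conv[better]
    order = np.argsort(best_mu, axis=1)             # canonical mu1 <= mu2
    best_mu = np.take_along_axis(best_mu, order, axis=1)
    best_sigma = np.take_along_axis(best_sigma, order, axis=1)
    best_resp = np.take_along_axis(best_resp, order[:, None, :], axis=2)
    return best_mu, best_sigma, best_ll, best_resp, best_conv


def fit_equal_weight_mixture(values: np.ndarray, n_restarts: int = 10,
                             seed=None,
                             rng: Optional[np.random.Generator] = None
                             ) -> MixtureFit:
    """EM fit of the 50/50 two-Gaussian mixture, best of ``n_restarts``."""
    x = np.asarray(values, float)
    if x.size < 8:
        raise ValueError("need at least 8 values")
    if rng is None:
        rng = np.random.default_rng(seed)
    mu, sigma, ll, resp, conv = _fit_mixture_batch(x[None, :], n_restarts, rng)
    return MixtureFit(mu1=float(mu[0, 0]), mu2=float(mu[0, 1]),
                      sigma1=float(sigma[0, 0]), sigma2=float(sigma[0, 1]),
                      log_likelihood=float(ll[0]), responsibilities=resp[0],
                      converged=bool(conv[0]))


def bic(log_likelihood: float, n_params: int, n_obs: int) -> float:
    """Bayesian Information Criterion: -2 lnL + p ln T."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return -2.0 * log_likelihood + n_params * math.log(n_obs)


def _single_gaussian_ll_batch(data: np.ndarray) -> np.ndarray:
    n = data.shape[1]
    mu = data.mean(axis=1, keepdims=True)
    floors = np.array([_variance_floor(row) for row in data])
    sigma = np.maximum(data.std(axis=1), floors)
    ss = ((data - mu) ** 2).sum(axis=1)
    return -0.5 * n * _LOG2PI - n * np.log(sigma) - ss / (2.0 * sigma**2)


def delta_bic_test(values: np.ndarray, n_resamples: int = 2000,
                   seed=None, rng: Optional[np.random.Generator] = None,
                   n_restarts: int = 10) -> MixtureComparison:
    """Full ΔBIC procedure for one set of per-trial mean rates.

    If ΔBIC >= 0 the mixture is not considered and no resampling is done.
    Otherwise the null ΔBIC distribution is built from ``n_resamples``
    datasets drawn from the fitted single Gaussian, and
    p = (1 + #{null ΔBIC <= observed ΔBIC}) / (n_resamples + 1).
    """
    x = np.asarray(values, float)
    if rng is None:
        rng = np.random.default_rng(seed)
    single = fit_single_gaussian(x)
    mixture = fit_equal_weight_mixture(x, n_restarts, rng=rng)
    n = x.size
    b_single = bic(single.log_likelihood, single.n_params, n)
    b_mix = bic(mixture.log_likelihood, mixture.n_params, n)
    dbic = b_mix - b_single
    if dbic >= 0:
        return MixtureComparison(single, mixture, b_single, b_mix, dbic,
                                 p_value=None, n_resamples=0)
    null_data = rng.normal(single.mu, single.sigma, size=(n_resamples, n))
    ll_s = _single_gaussian_ll_batch(null_data)
    _, _, ll_m, _, conv = _fit_mixture_batch(null_data, n_restarts, rng)
    null_dbic = (-2.0 * ll_m + 4.0 * math.log(n)) - \
                (-2.0 * ll_s + 2.0 * math.log(n))
    p = (1 + int(np.sum(null_dbic <= dbic))) / (n_resamples + 1)
    warn = bool(np.mean(~conv) > 0.05)
    return MixtureComparison(single, mixture, b_single, b_mix, dbic,
                             p_value=p, n_resamples=n_resamples,
                             convergence_warning=warn)
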