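"""Accuracy estimation and termination: regression of successive-epoch SKL
gaps on the learning rate, prediction of convergence cost, and the
inefficiency-index stopping rule.

The SKL gap between the averaged approximations of adjacent epochs follows
(up to higher-order terms) ``delta_t = C * gamma_t^{2 kappa} (1/rho^kappa -
1)^2``; a small weighted Bayesian regression on ``log delta_t`` recovers C
(and kappa when free), giving an estimate of the SKL to the optimum without
access to it.  Posteriors are computed by dense-grid quadrature — with two
or three parameters this is cheap, deterministic, and easy to validate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "EpochRecord",
    "SKLFit",
    "TerminationDecision",
    "regression_weights",
    "fit_skl_regression",
    "estimate_skl_to_opt",
    "fit_iteration_model",
    "inefficiency",
]


@dataclass
class EpochRecord:
    """Summary of one learning-rate epoch."""

    t: int
    gamma: float
    lam_avg: np.ndarray
    n_iters: int
    delta: Optional[float] = None  # SKL gap to the previous epoch (t >= 1)
    kconv: int = 0
    wconv: int = 0
    kavg: int = 0
    rhat_max: float = float("nan")
    gate_passed: bool = False
    ess_min: float = float("nan")
    mean_mcse: float = float("nan")
    seconds: float = 0.0
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "gamma": self.gamma,
            "lam_avg": np.asarray(self.lam_avg).tolist(),
            "n_iters": self.n_iters,
            "delta": self.delta,
            "kconv": self.kconv,
            "wconv": self.wconv,
            "kavg": self.kavg,
            "rhat_max": self.rhat_max,
            "gate_passed": self.gate_passed,
            "ess_min": self.ess_min,
            "mean_mcse": self.mean_mcse,
            "seconds": self.seconds,
            "seed": self.seed,
        }


def regression_weights(T: int) -> np.ndarray:
    """Observation weights ``w_t = (1 + (T - t)^2 / 32)^(-1/4)``, t = 1..T.

    Recent epochs get full weight; older ones are down-weighted gradually
    (their SKL gaps carry more higher-order contamination).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    t = np.arange(1, T + 1)
    return (1.0 + (T - t) ** 2 / 32.0) ** -0.25


def _log_cauchy(x: np.ndarray, scale: float) -> np.ndarray:
    return -np.log(np.pi * scale * (1.0 + (x / scale) ** 2))


def _log_half_cauchy(x: np.ndarray, scale: float) -> np.ndarray:
    return np.log(2.0) + _log_cauchy(x, scale)


@dataclass
class SKLFit:
    """Grid posterior summary of the SKL-gap regression."""

    C_hat: float
    kappa_hat: float
    mode: str  # 'kappa_fixed_1' or 'kappa_free'
    rho: float
    weights: np.ndarray
    log_c_grid: np.ndarray = field(repr=False)
    log_c_marginal: np.ndarray = field(repr=False)  # normalized probabilities
    kappa_grid: Optional[np.ndarray] = field(default=None, repr=False)
    kappa_marginal: Optional[np.ndarray] = field(default=None, repr=False)
    sigma_mean: float = float("nan")

    def posterior_draws(
        self, n: int, rng: np.random.Generator
    ) -> dict:
        """Monte Carlo draws from the (discretized) posterior marginals."""
        log_c = rng.choice(self.log_c_grid, size=n, p=self.log_c_marginal)
        out = {"log_C": log_c}
        if self.kappa_grid is not None:
            out["kappa"] = rng.choice(
                self.kappa_grid, size=n, p=self.kappa_marginal
            )
        else:
            out["kappa"] = np.ones(n)
        return out


def _mean_structure(
    kappa: np.ndarray, log_gamma: np.ndarray, rho: float
) -> np.ndarray:
    """Regression mean minus log C: 2 log(1/rho^kappa - 1) + 2 kappa log gamma,
    broadcast over a kappa grid (shape (nk, 1)) and epochs (shape (T,))."""
    return 2.0 * np.log(rho**-kappa - 1.0) + 2.0 * kappa * log_gamma


def fit_skl_regression(
    records: Sequence[EpochRecord],
    rho: float,
    mode: str = "kappa_fixed_1",
    n_grid_c: int = 2001,
    n_grid_kappa: int = 201,
    n_grid_sigma: int = 121,
) -> SKLFit:
    """Fit the weighted Bayesian regression of log SKL gaps on log learning
    rate by dense-grid quadrature.

    Priors: ``log C ~ Cauchy(0, 10)``, ``sigma ~ Cauchy+(0, 10)`` and, in
    ``kappa_free`` mode, ``kappa ~ Unif(0, 1)``.  Each observation's
    log-likelihood term is tempered by its weight.  Point estimates are the
    posterior means (C on the log scale: ``C_hat = exp(E[log C])``).
    Non-positive SKL gaps are dropped with a warning.
    """
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must be in (0, 1)")
    if mode not in ("kappa_fixed_1", "kappa_free"):
        raise ValueError(f"unknown mode {mode!r}")

    obs = [(r.t, r.gamma, r.delta) for r in records if r.delta is not None]
    T_all = len(obs)
    weights_all = regression_weights(T_all) if T_all else np.array([])
    kept, w_kept = [], []
    for (t, gamma, delta), w in zip(obs, weights_all):
        if delta is None or not np.isfinite(delta) or delta <= 0:
            warnings.warn(
                f"dropping non-positive SKL gap at epoch t={t}", stacklevel=2
            )
            continue
        kept.append((gamma, delta))
        w_kept.append(w)
    n_min = 1 if mode == "kappa_fixed_1" else 3
    if len(kept) < n_min:
        raise ValueError(
            f"{mode} requires at least {n_min} positive SKL gap(s), "
            f"have {len(kept)}"
        )
    gammas = np.array([g for g, _ in kept])
    y = np.log([d for _, d in kept])
    w = np.asarray(w_kept)
    log_gamma = np.log(gammas)
    w_sum = float(w.sum())

    if mode == "kappa_fixed_1":
        kappa_grid = np.array([1.0])
    else:
        # open interval: endpoints are degenerate in the mean structure
        kappa_grid = np.linspace(0.0, 1.0, n_grid_kappa + 2)[1:-1]

    # partial residuals z[t; kappa] = y_t - mean structure without log C
    z = y[None, :] - _mean_structure(kappa_grid[:, None], log_gamma, rho)

    # center the log C grid on the weighted least-squares solution
    c0 = float(np.sum(w * z, axis=1).mean() / w_sum)
    log_c_grid = np.linspace(c0 - 50.0, c0 + 50.0, n_grid_c)

    # weighted SSR as a function of (log C, kappa); likelihood factorizes as
    # -0.5 * sum(w) * log(2 pi sigma^2) - SSR / (2 sigma^2)
    resid = z[None, :, :] - log_c_grid[:, None, None]
    ssr = np.einsum("t,ckt->ck", w, resid**2)

    log_sigma_grid = np.linspace(-14.0, 8.0, n_grid_sigma)
    sigma = np.exp(log_sigma_grid)
    lp_sigma = _log_half_cauchy(sigma, 10.0) + log_sigma_grid  # + jacobian
    lp_c = _log_cauchy(log_c_grid, 10.0)

    log_post = (
        lp_c[:, None, None]
        + lp_sigma[None, None, :]
        - 0.5 * w_sum * (np.log(2.0 * np.pi) + 2.0 * log_sigma_grid)[None, None, :]
        - ssr[:, :, None] / (2.0 * sigma**2)[None, None, :]
    )
    log_post -= logsumexp(log_post)
    post = np.exp(log_post)

    c_marg = post.sum(axis=(1, 2))
    c_marg /= c_marg.sum()
    mean_log_c = float(np.sum(c_marg * log_c_grid))
    sigma_mean = float(np.sum(post.sum(axis=(0, 1)) * sigma))

    if mode == "kappa_fixed_1":
        kappa_hat = 1.0
        k_grid = k_marg = None
    else:
        k_marg = post.sum(axis=(0, 2))
        k_marg /= k_marg.sum()
        kappa_hat = float(np.sum(k_marg * kappa_grid))
        k_grid = kappa_grid

    return SKLFit(
        C_hat=float(np.exp(mean_log_c)),
        kappa_hat=kappa_hat,
        mode=mode,
        rho=rho,
        weights=w,
        log_c_grid=log_c_grid,
        log_c_marginal=c_marg,
        kappa_grid=k_grid,
        kappa_marginal=k_marg,
        sigma_mean=sigma_mean,
    )


def estimate_skl_to_opt(fit: SKLFit, gamma: float) -> float:
    """Estimated SKL between the gamma-learning-rate approximation and the
    optimum: ``C_hat * gamma^(2 kappa_hat)``."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return float(fit.C_hat * gamma ** (2.0 * fit.kappa_hat))


def fit_iteration_model(
    records: Sequence[EpochRecord], rho: float
) -> Tuple[float, float, float, bool]:
    """Weighted least-squares fit of ``log K_t = alpha log gamma_t + beta``
    and prediction of the iterations needed at the next learning rate.

    Returns ``(alpha_hat, beta_hat, K_next_hat, is_heuristic)``.  With fewer
    than two records the power law cannot be fit; the fallback predicts
    ``K_t / rho`` and flags itself.
    """
    if len(records) == 0:
        raise ValueError("need at least one record")
    gammas = np.array([r.gamma for r in records])
    ks = np.array([r.n_iters for r in records], dtype=float)
    gamma_next = rho * gammas[-1]
    if len(records) < 2:
        return float("nan"), float("nan"), float(ks[-1] / rho), True
    w = regression_weights(len(records))
    x = np.log(gammas)
    y = np.log(ks)
    sw = np.sqrt(w)
    design = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(sw[:, None] * design, sw * y, rcond=None)
    alpha, beta = float(coef[0]), float(coef[1])
    k_next = float(gamma_next**alpha * np.exp(beta))
    return alpha, beta, k_next, False


@dataclass(frozen=True)
class TerminationDecision:
    """Stop/continue verdict from the inefficiency index."""

    rskl_hat: float
    ri_hat: float
    inefficiency_hat: float
    k_next_hat: float
    terminate: bool
    xi: float
    tau: float
    k0: int

    def to_dict(self) -> dict:
        return {
            "rskl_hat": self.rskl_hat,
            "ri_hat": self.ri_hat,
            "inefficiency_hat": self.inefficiency_hat,
            "k_next_hat": self.k_next_hat,
            "terminate": self.terminate,
            "xi": self.xi,
            "tau": self.tau,
            "k0": self.k0,
        }


def inefficiency(
    fit: SKLFit,
    k_next_hat: float,
    k_gamma_t: float,
    gamma_t: float,
    xi: float,
    k0: int,
    tau: float = 1.0,
) -> TerminationDecision:
    """Inefficiency index: relative SKL improvement times relative iteration
    increase; terminate when it exceeds ``tau``.

    ``RSKL_hat = rho^kappa_hat + xi / (C_hat^(1/2) * gamma_t^kappa_hat)``;
    ``RI_hat = K_next_hat / (K_t + K0)``.
    """
    if min(k_next_hat, k_gamma_t, gamma_t, xi) <= 0 or k0 < 0:
        raise ValueError("inputs must be positive")
    kappa = fit.kappa_hat
    rskl = float(fit.rho**kappa + xi / (np.sqrt(fit.C_hat) * gamma_t**kappa))
    ri = float(k_next_hat / (k_gamma_t + k0))
    idx = rskl * ri
    return TerminationDecision(
        rskl_hat=rskl,
        ri_hat=ri,
        inefficiency_hat=idx,
        k_next_hat=float(k_next_hat),
        terminate=bool(idx > tau),
        xi=float(xi),
        tau=float(tau),
        k0=int(k0),
    )
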