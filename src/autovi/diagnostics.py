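"""Markov-chain diagnostics on optimization iterate traces.

Single-chain regime throughout: each scalar chain is split into two halves,
giving the classic split potential-scale-reduction factor and a two-chain
effective sample size with Geyer initial-monotone-positive-sequence
truncation of the autocorrelation sum.  No rank normalization is applied —
iterate chains near stationarity are approximately Gaussian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = [
    "split_rhat",
    "rhat_max",
    "find_opt_window",
    "ess",
    "mcse",
    "trace_summary",
]

RHAT_THRESHOLD = 1.1  # stationarity condition on the worst coordinate


def _split_halves(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Split along axis 0 into two equal halves, dropping the middle
    element when the length is odd."""
    n = x.shape[0] // 2
    return x[:n], x[x.shape[0] - n :]


def _split_rhat_multi(x: np.ndarray) -> np.ndarray:
    """Split-R-hat per column of a (W, m) array; NaN for constant columns,
    +inf when within-variance vanishes but between-variance does not."""
    a, b = _split_halves(x)
    n = a.shape[0]
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    var_a = a.var(axis=0, ddof=1)
    var_b = b.var(axis=0, ddof=1)
    within = 0.5 * (var_a + var_b)
    # between-chain variance: n * sample variance of the two half means
    between = n * 0.5 * (mean_a - mean_b) ** 2
    var_plus = (n - 1) / n * within + between / n
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(var_plus / within)
    out = np.where((within == 0) & (between > 0), np.inf, out)
    out = np.where((within == 0) & (between == 0), np.nan, out)
    return out


def split_rhat(x: np.ndarray) -> float:
    """Split potential-scale-reduction factor of a scalar chain.

    The chain is split into two halves (dropping the middle element if the
    length is odd); the statistic is ``sqrt(var_plus / W)`` with ``W`` the
    mean within-half variance.  Returns +inf when the within-variance is
    zero but the halves differ, and NaN (with a warning) for an
    all-constant chain.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("split_rhat expects a 1-D chain")
    if x.size < 4:
        raise ValueError(f"need at least 4 values, got {x.size}")
    val = float(_split_rhat_multi(x[:, None])[0])
    if np.isnan(val):
        warnings.warn("all-constant chain: split-R-hat undefined", stacklevel=2)
    return val


def rhat_max(trace: np.ndarray, W: int) -> float:
    """Maximum split-R-hat over all coordinates of the trailing W iterates.

    Constant coordinates (NaN) are ignored; an all-constant window returns
    NaN (callers treat it as trivially stationary).
    """
    trace = np.atleast_2d(np.asarray(trace, dtype=float))
    if W > trace.shape[0]:
        raise ValueError(f"window {W} longer than trace ({trace.shape[0]})")
    vals = _split_rhat_multi(trace[trace.shape[0] - W :])
    if np.all(np.isnan(vals)):
        return float("nan")
    return float(np.nanmax(vals))


def _window_grid(k: int, w_min: int) -> np.ndarray:
    upper = int(np.floor(0.95 * k))
    if upper < w_min:
        raise ValueError(
            f"trace too short: 0.95 * {k} < minimum window {w_min}"
        )
    # round-half-even to integers, as in the documented candidate grids
    grid = np.rint(np.linspace(w_min, upper, 5)).astype(int)
    return np.unique(grid)


def find_opt_window(trace: np.ndarray, w_min: int) -> Tuple[int, float]:
    """Grid search for the trailing window minimizing the worst-coordinate
    split-R-hat.

    Five equally spaced window sizes from ``w_min`` to ``floor(0.95 k)``
    are evaluated; ties are broken toward the larger window (more iterates
    available for averaging).  NaN values (all-constant windows) are
    treated as perfectly stationary.
    """
    trace = np.atleast_2d(np.asarray(trace, dtype=float))
    grid = _window_grid(trace.shape[0], w_min)
    vals = np.array([rhat_max(trace, int(w)) for w in grid])
    keyed = np.where(np.isnan(vals), -np.inf, vals)
    best = np.flatnonzero(keyed == keyed.min())[-1]  # grid ascending
    return int(grid[best]), float(vals[best])


def _autocov_fft(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance (divisor n) along axis 0 via FFT."""
    n = x.shape[0]
    centered = x - x.mean(axis=0)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(centered, n=nfft, axis=0)
    acov = np.fft.irfft(f * np.conj(f), n=nfft, axis=0)[:n]
    return acov.real / n


def _ess_one(acov_a, acov_b, mean_a, mean_b, n) -> float:
    """Two-chain ESS with Geyer initial positive/monotone sequence
    truncation of the autocorrelation sum (classic split-chain estimator)."""
    mean_acov = 0.5 * (acov_a + acov_b)
    mean_var = mean_acov[0] * n / (n - 1.0)  # unbiased within-chain variance
    between = 0.5 * (mean_a - mean_b) ** 2  # variance of the 2 means, ddof=1
    var_plus = mean_acov[0] + between
    if var_plus <= 0:
        return float(2 * n)  # constant chain: ESS = length by convention
    rho = np.zeros(n)
    rho_even = 1.0
    rho[0] = 1.0
    rho_odd = 1.0 - (mean_var - mean_acov[1]) / var_plus
    rho[1] = rho_odd

    # initial positive sequence: keep autocorrelation pairs while their sum
    # stays positive
    t = 1
    while t < n - 3 and (rho_even + rho_odd) > 0.0:
        rho_even = 1.0 - (mean_var - mean_acov[t + 1]) / var_plus
        rho_odd = 1.0 - (mean_var - mean_acov[t + 2]) / var_plus
        if rho_even + rho_odd >= 0:
            rho[t + 1] = rho_even
            rho[t + 2] = rho_odd
        t += 2
    max_t = t - 2
    if rho_even > 0:
        rho[max_t + 1] = rho_even

    # initial monotone sequence: pair sums must be non-increasing
    t = 1
    while t <= max_t - 2:
        if rho[t + 1] + rho[t + 2] > rho[t - 1] + rho[t]:
            rho[t + 1] = 0.5 * (rho[t - 1] + rho[t])
            rho[t + 2] = rho[t + 1]
        t += 2

    tau = -1.0 + 2.0 * np.sum(rho[: max_t + 1]) + rho[max_t + 1]
    tau = max(tau, 1.0 / np.log10(2 * n))
    return float(2 * n / tau)


def ess(x: np.ndarray) -> float:
    """Effective sample size of a scalar chain (split into two halves)."""
    return float(_ess_multi(np.asarray(x, dtype=float)[:, None])[0])


def _ess_multi(x: np.ndarray) -> np.ndarray:
    """ESS per column of an (n, m) array."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    total_n = x.shape[0]
    if total_n < 8:
        raise ValueError("need at least 8 iterates for ESS")
    a, b = _split_halves(x)
    n = a.shape[0]
    acov_a = _autocov_fft(a)
    acov_b = _autocov_fft(b)
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    ptp = x.max(axis=0) - x.min(axis=0)
    out = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        if ptp[j] < np.finfo(float).resolution:
            out[j] = total_n  # constant chain, by convention
            continue
        out[j] = _ess_one(acov_a[:, j], acov_b[:, j], mean_a[j], mean_b[j], n)
    return out


def mcse(x: np.ndarray) -> float:
    """Monte Carlo standard error: sample sd times ESS^{-1/2}."""
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return 0.0
    return sd / np.sqrt(ess(x))


def _mcse_multi(x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    sd = np.std(x, axis=0, ddof=1)
    ess_vals = _ess_multi(x)
    with np.errstate(invalid="ignore"):
        out = np.where(sd == 0.0, 0.0, sd / np.sqrt(ess_vals))
    return out


@dataclass(frozen=True)
class ConvergenceReport:
    """Outcome of a stationarity check on a trailing trace window."""

    converged: bool
    kconv: int
    wconv: int
    rhat_max: float


def trace_summary(trace: np.ndarray) -> dict:
    """Worst-coordinate R-hat, minimum ESS and mean MCSE for a full trace."""
    trace = np.atleast_2d(np.asarray(trace, dtype=float))
    ess_vals = _ess_multi(trace)
    mcse_vals = _mcse_multi(trace)
    return {
        "iterations": int(trace.shape[0]),
        "rhat_max": rhat_max(trace, trace.shape[0]),
        "ess_min": float(np.min(ess_vals)),
        "mcse_mean": float(np.mean(mcse_vals)),
    }
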