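"""Fixed-learning-rate stochastic optimization steps.

Provides SGD, RMSProp, Adam, and "averaged" variants of the two adaptive
methods in which the second-moment EMA is replaced by a running average
(``beta_k = 1 - 1/k``), so the accumulated scaling converges to a constant
and the update behaves asymptotically like SGD.  The first moment of the
averaged Adam variant keeps its EMA (only the squared-gradient update is
modified).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

__all__ = ["OptimizerState", "init_state", "step", "METHODS"]

METHODS = ("sgd", "rmsprop", "adam", "avg_rmsprop", "avg_adam")

#: stabilizer added outside the square root: d = g / (sqrt(nu) + eps)
_EPS = 1e-8
#: EMA rates (first moment alpha, second moment beta); standard values,
#: with bias correction applied to EMA accumulators only
_ALPHA = 0.9
_BETA_ADAM = 0.999
_BETA_RMSPROP = 0.9


@dataclass(frozen=True)
class OptimizerState:
    """Serializable per-method accumulator state; ``k`` is the next step
    index (1-based)."""

    method: str
    k: int = 1
    m: Optional[np.ndarray] = None
    nu: Optional[np.ndarray] = None
    alpha: float = _ALPHA
    beta: float = _BETA_ADAM
    eps: float = _EPS

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "k": self.k,
            "m": None if self.m is None else self.m.tolist(),
            "nu": None if self.nu is None else self.nu.tolist(),
            "alpha": self.alpha,
            "beta": self.beta,
            "eps": self.eps,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OptimizerState":
        return cls(
            method=d["method"],
            k=d["k"],
            m=None if d["m"] is None else np.asarray(d["m"]),
            nu=None if d["nu"] is None else np.asarray(d["nu"]),
            alpha=d["alpha"],
            beta=d["beta"],
            eps=d["eps"],
        )


def init_state(method: str, n_params: int, eps: float = _EPS) -> OptimizerState:
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    needs_m = method in ("adam", "avg_adam")
    needs_nu = method != "sgd"
    beta = _BETA_RMSPROP if method == "rmsprop" else _BETA_ADAM
    return OptimizerState(
        method=method,
        k=1,
        m=np.zeros(n_params) if needs_m else None,
        nu=np.zeros(n_params) if needs_nu else None,
        beta=beta,
        eps=eps,
    )


def step(
    state: OptimizerState,
    lam: np.ndarray,
    grad: np.ndarray,
    gamma: float,
) -> Tuple[OptimizerState, np.ndarray]:
    """One update ``lam <- lam - gamma * d`` with the method's descent
    direction d; returns the new state and iterate."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    g = np.asarray(grad, dtype=float)
    k = state.k
    method = state.method

    m_new = state.m
    nu_new = state.nu

    if method == "sgd":
        d = g
    elif method in ("rmsprop", "adam"):
        nu_new = state.beta * state.nu + (1.0 - state.beta) * g * g
        nu_hat = nu_new / (1.0 - state.beta**k)
        if method == "adam":
            m_new = state.alpha * state.m + (1.0 - state.alpha) * g
            m_hat = m_new / (1.0 - state.alpha**k)
            d = m_hat / (np.sqrt(nu_hat) + state.eps)
        else:
            d = g / (np.sqrt(nu_hat) + state.eps)
    else:  # averaged variants: exact running average of squared gradients
        beta_k = 1.0 - 1.0 / k
        nu_new = beta_k * state.nu + (1.0 - beta_k) * g * g
        if method == "avg_adam":
            m_new = state.alpha * state.m + (1.0 - state.alpha) * g
            m_hat = m_new / (1.0 - state.alpha**k)
            d = m_hat / (np.sqrt(nu_new) + state.eps)
        else:
            d = g / (np.sqrt(nu_new) + state.eps)

    lam_new = lam - gamma * d
    if not np.all(np.isfinite(lam_new)):
        bad = int(np.flatnonzero(~np.isfinite(lam_new))[0])
        raise FloatingPointError(
            f"non-finite update at step {k}, coordinate {bad}"
        )
    return replace(state, k=k + 1, m=m_new, nu=nu_new), lam_new
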