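"""Variational families with closed-form symmetrized KL divergence.

The workhorse is the mean-field Gaussian family parameterized by a location
vector and log-scales.  The flat parameter layout is ``(loc, log_scale)``
(length ``2d``) and is the canonical ordering used by every trace-based
diagnostic in this package.  A full-rank Gaussian family is provided behind
the same contract; families without a closed-form SKL are deliberately
unsupported because the termination machinery requires one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import linalg

__all__ = [
    "MeanFieldParams",
    "FullRankParams",
    "FamilySpec",
    "kl_mean_field",
    "skl",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class FamilySpec:
    """Family kind, dimension and flat parameter count."""

    kind: str
    dim: int

    _PARAM_COUNTS = {
        "mean_field_gaussian": lambda d: 2 * d,
        "full_rank_gaussian": lambda d: d + d * (d + 1) // 2,
    }

    def __post_init__(self) -> None:
        if self.kind not in self._PARAM_COUNTS:
            raise ValueError(f"unknown family kind {self.kind!r}")
        if self.dim < 1:
            raise ValueError("dim must be positive")

    @property
    def n_params(self) -> int:
        return self._PARAM_COUNTS[self.kind](self.dim)

    def params_from_flat(self, flat: np.ndarray):
        if self.kind == "mean_field_gaussian":
            return MeanFieldParams.from_flat(flat)
        return FullRankParams.from_flat(flat, self.dim)

    def init_params(self):
        """Standard-normal initialization (loc 0, unit scales)."""
        if self.kind == "mean_field_gaussian":
            return MeanFieldParams(np.zeros(self.dim), np.zeros(self.dim))
        flat = np.zeros(self.n_params)
        return FullRankParams.from_flat(flat, self.dim)


@dataclass(frozen=True)
class MeanFieldParams:
    """Diagonal Gaussian N(loc, diag(exp(2 * log_scale)))."""

    loc: np.ndarray
    log_scale: np.ndarray

    def __post_init__(self) -> None:
        loc = np.asarray(self.loc, dtype=float)
        log_scale = np.asarray(self.log_scale, dtype=float)
        if loc.shape != log_scale.shape or loc.ndim != 1:
            raise ValueError("loc and log_scale must be 1-D of equal length")
        if not (np.all(np.isfinite(loc)) and np.all(np.isfinite(log_scale))):
            raise ValueError("parameters must be finite")
        object.__setattr__(self, "loc", loc)
        object.__setattr__(self, "log_scale", log_scale)

    @property
    def dim(self) -> int:
        return self.loc.size

    @property
    def scale(self) -> np.ndarray:
        return np.exp(self.log_scale)

    def to_flat(self) -> np.ndarray:
        return np.concatenate([self.loc, self.log_scale])

    @classmethod
    def from_flat(cls, flat: np.ndarray) -> "MeanFieldParams":
        flat = np.asarray(flat, dtype=float)
        if flat.ndim != 1 or flat.size % 2:
            raise ValueError("flat vector must be 1-D with even length")
        d = flat.size // 2
        return cls(loc=flat[:d], log_scale=flat[d:])

    def sample(
        self,
        n_draws: Optional[int] = None,
        noise: Optional[np.ndarray] = None,
        rng: Optional[np.random.Generator] = None,
    ) -> np.ndarray:
        """Reparameterized draws ``loc + scale * z``.

        Either explicit standard-normal ``noise`` of shape ``(n_draws, d)``
        or an ``rng`` must be supplied.
        """
        if noise is None:
            if rng is None:
                raise ValueError("provide either noise or rng")
            noise = rng.standard_normal((n_draws, self.dim))
        noise = np.asarray(noise, dtype=float)
        if noise.shape[-1] != self.dim or (
            n_draws is not None and noise.shape[0] != n_draws
        ):
            raise ValueError(
                f"noise shape {noise.shape} incompatible with "
                f"(n_draws={n_draws}, d={self.dim})"
            )
        return self.loc + self.scale * noise

    def log_density(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        z = (np.atleast_2d(theta) - self.loc) / self.scale
        out = -0.5 * np.sum(z * z, axis=-1) - np.sum(self.log_scale) \
            - 0.5 * self.dim * _LOG_2PI
        return out if theta.ndim > 1 else out[0]

    def entropy(self) -> float:
        return float(
            np.sum(self.log_scale) + 0.5 * self.dim * (1.0 + _LOG_2PI)
        )


def kl_mean_field(p: MeanFieldParams, q: MeanFieldParams) -> float:
    """KL(p || q) between diagonal Gaussians, in closed form."""
    if p.dim != q.dim:
        raise ValueError("dimension mismatch")
    ls_p, ls_q = p.log_scale, q.log_scale
    var_ratio = np.exp(2.0 * (ls_p - ls_q))
    mean_term = ((p.loc - q.loc) / q.scale) ** 2
    return float(
        0.5 * np.sum(var_ratio + mean_term - 1.0) + np.sum(ls_q - ls_p)
    )


@dataclass(frozen=True)
class FullRankParams:
    """Gaussian N(loc, L L^T) with lower-triangular L; the flat layout is
    (loc, log diag L, strict lower rows of L)."""

    loc: np.ndarray
    chol: np.ndarray  # lower triangular, positive diagonal

    def __post_init__(self) -> None:
        loc = np.asarray(self.loc, dtype=float)
        chol = np.asarray(self.chol, dtype=float)
        if chol.shape != (loc.size, loc.size):
            raise ValueError("chol must be d x d")
        if np.any(np.diag(chol) <= 0):
            raise ValueError("Cholesky diagonal must be positive")
        object.__setattr__(self, "loc", loc)
        object.__setattr__(self, "chol", np.tril(chol))

    @property
    def dim(self) -> int:
        return self.loc.size

    @property
    def cov(self) -> np.ndarray:
        return self.chol @ self.chol.T

    def to_flat(self) -> np.ndarray:
        d = self.dim
        idx = np.tril_indices(d, k=-1)
        return np.concatenate(
            [self.loc, np.log(np.diag(self.chol)), self.chol[idx]]
        )

    @classmethod
    def from_flat(cls, flat: np.ndarray, d: int) -> "FullRankParams":
        flat = np.asarray(flat, dtype=float)
        loc = flat[:d]
        chol = np.zeros((d, d))
        np.fill_diagonal(chol, np.exp(flat[d : 2 * d]))
        chol[np.tril_indices(d, k=-1)] = flat[2 * d :]
        return cls(loc=loc, chol=chol)

    def sample(
        self,
        n_draws: Optional[int] = None,
        noise: Optional[np.ndarray] = None,
        rng: Optional[np.random.Generator] = None,
    ) -> np.ndarray:
        if noise is None:
            if rng is None:
                raise ValueError("provide either noise or rng")
            noise = rng.standard_normal((n_draws, self.dim))
        noise = np.asarray(noise, dtype=float)
        if noise.shape[-1] != self.dim:
            raise ValueError("noise shape mismatch")
        return self.loc + noise @ self.chol.T

    def log_density(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        delta = np.atleast_2d(theta) - self.loc
        z = linalg.solve_triangular(self.chol, delta.T, lower=True).T
        out = (
            -0.5 * np.sum(z * z, axis=-1)
            - np.sum(np.log(np.diag(self.chol)))
            - 0.5 * self.dim * _LOG_2PI
        )
        return out if theta.ndim > 1 else out[0]

    def entropy(self) -> float:
        return float(
            np.sum(np.log(np.diag(self.chol)))
            + 0.5 * self.dim * (1.0 + _LOG_2PI)
        )


def _kl_full_rank(p: FullRankParams, q: FullRankParams) -> float:
    d = p.dim
    # solve L_q X = L_p gives the whitened cross-factor
    m = linalg.solve_triangular(q.chol, p.chol, lower=True)
    trace = np.sum(m * m)
    delta = linalg.solve_triangular(q.chol, q.loc - p.loc, lower=True)
    logdet = 2.0 * (
        np.sum(np.log(np.diag(q.chol))) - np.sum(np.log(np.diag(p.chol)))
    )
    return float(0.5 * (trace + delta @ delta - d + logdet))


def skl(p1, p2) -> float:
    """Symmetrized KL divergence ``KL(p1||p2) + KL(p2||p1)`` in closed form.

    Supported for pairs of :class:`MeanFieldParams` or pairs of
    :class:`FullRankParams` of equal dimension.
    """
    if getattr(p1, "dim", None) != getattr(p2, "dim", None):
        raise ValueError("dimension mismatch")
    if isinstance(p1, MeanFieldParams) and isinstance(p2, MeanFieldParams):
        return kl_mean_field(p1, p2) + kl_mean_field(p2, p1)
    if isinstance(p1, FullRankParams) and isinstance(p2, FullRankParams):
        return _kl_full_rank(p1, p2) + _kl_full_rank(p2, p1)
    raise TypeError(
        f"no closed-form SKL for {type(p1).__name__} vs {type(p2).__name__}"
    )
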