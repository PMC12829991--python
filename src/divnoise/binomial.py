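"""Binomial partitioning and the mapping between sigma_f and division bias.

If each of the mother's N_i tagged components segregates independently to
one daughter with probability p (bias; q = 1 - p), the inherited-fraction
variance conditional on N_i is pq / N_i.  Averaging over the mother
component-count distribution P(N_i) and over the two exchangeable branch
labels gives the full partition variance

    sigma_f^2 = pq * Sigma(N) + (p^2 + q^2) / 2 - 1/4,

with Sigma(N) = E[1/N_i].  For components present in large numbers the
Sigma term is negligible and the relation collapses to
sigma_f = |p - 1/2|, inverted as p = 1/2 - sigma_f (labels canonicalized
so p <= 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats
from scipy.special import erf, ndtr

__all__ = [
    "MotherCountModel",
    "sigma_integral",
    "binomial_sigma_f_sq",
    "bias_from_sigma_f",
    "printed_variance_lognormal",
]


@dataclass(frozen=True)
class MotherCountModel:
    """Distribution P(N_i) of the mother's component count at division.

    ``delta(N)``: every mother carries exactly N components.
    ``lognormal(mu_ln, sigma_ln)``: ln N_i ~ Normal(mu_ln, sigma_ln^2),
    truncated at N >= 1 and renormalized (counts below one component are
    not physical).
    """

    family: str
    N: float | None = None
    mu_ln: float | None = None
    sigma_ln: float | None = None

    def __post_init__(self) -> None:
        if self.family == "delta":
            if self.N is None or self.N <= 0:
                raise ValueError("delta model needs N > 0")
        elif self.family == "lognormal":
            if self.mu_ln is None or self.sigma_ln is None or self.sigma_ln <= 0:
                raise ValueError("lognormal model needs mu_ln and sigma_ln > 0")
        else:
            raise ValueError(f"unknown mother-count family {self.family!r}")

    @classmethod
    def delta(cls, N: float) -> "MotherCountModel":
        return cls("delta", N=float(N))

    @classmethod
    def lognormal(cls, mu_ln: float, sigma_ln: float) -> "MotherCountModel":
        return cls("lognormal", mu_ln=float(mu_ln), sigma_ln=float(sigma_ln))

    @property
    def truncation_mass(self) -> float:
        """P(N_i >= 1) under the untruncated lognormal (1 for delta)."""
        if self.family == "delta":
            return 1.0
        # P(ln N >= 0) = Phi(mu / sigma)
        return float(ndtr(self.mu_ln / self.sigma_ln))

    def pdf(self, n: np.ndarray) -> np.ndarray:
        """Renormalized truncated density on N >= 1 (lognormal only)."""
        if self.family != "lognormal":
            raise ValueError("delta model has no density")
        n = np.asarray(n, dtype=float)
        raw = stats.lognorm.pdf(n, s=self.sigma_ln, scale=np.exp(self.mu_ln))
        return np.where(n >= 1.0, raw / self.truncation_mass, 0.0)


def _lognormal_inv_moment_raw(mu: float, sigma: float) -> float:
    """Integral of (1/N) * lognormal pdf over N >= 1 (no renormalization).

    Closed form: (1/2) e^{sigma^2/2 - mu} (1 - erf((sigma^2 - mu)/(sqrt(2) sigma))).
    """
    return float(
        0.5
        * np.exp(sigma**2 / 2.0 - mu)
        * (1.0 - erf((sigma**2 - mu) / (np.sqrt(2.0) * sigma)))
    )


def sigma_integral(model: MotherCountModel, truncated: bool = True) -> float:
    """Sigma(N) = E[1/N_i] over the mother component-count distribution.

    For the delta model this is exactly 1/N.  For the lognormal model the
    erf closed form over N >= 1 is used; ``truncated=False`` returns the
    untruncated E[1/N] = exp(sigma^2/2 - mu) instead.
    """
    if model.family == "delta":
        return 1.0 / model.N
    mu, sigma = model.mu_ln, model.sigma_ln
    if not truncated:
        return float(np.exp(sigma**2 / 2.0 - mu))
    return _lognormal_inv_moment_raw(mu, sigma) / model.truncation_mass


def binomial_sigma_f_sq(p: float, model: MotherCountModel | None = None) -> float:
    """Partition variance sigma_f^2 under binomial segregation with bias p.

    ``model=None`` takes the large-N limit (Sigma = 0), leaving the pure
    bias term (p^2 + q^2)/2 - 1/4 = (p - 1/2)^2.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("bias p must lie in (0, 1)")
    q = 1.0 - p
    sig = 0.0 if model is None else sigma_integral(model)
    return p * q * sig + (p**2 + q**2) / 2.0 - 0.25


def bias_from_sigma_f(sigma_f: float) -> float:
    """Invert the large-N relation: p = 1/2 - sigma_f (convention p <= 1/2)."""
    if not 0.0 <= sigma_f <= 0.5:
        raise ValueError("sigma_f must lie in [0, 1/2]")
    return 0.5 - sigma_f


def printed_variance_lognormal(p: float, mu_ln: float, sigma_ln: float) -> float:
    """Compatibility form of sigma_f^2 with a 1/2 prefactor on the Sigma term.

    Kept for comparison only: it does not reduce to pq/N at p = q = 1/2,
    so ``binomial_sigma_f_sq`` (pq * Sigma composition) is authoritative.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("bias p must lie in (0, 1)")
    q = 1.0 - p
    return 0.5 * _lognormal_inv_moment_raw(mu_ln, sigma_ln) + (p**2 + q**2) / 2.0 - 0.25


def sigma_integral_quadrature(model: MotherCountModel) -> float:
    """Adaptive-quadrature cross-check of the lognormal Sigma closed form."""
    if model.family == "delta":
        return 1.0 / model.N
    val, _ = integrate.quad(
        lambda n: model.pdf(n) / n, 1.0, np.inf, limit=400
    )
    return float(val)
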