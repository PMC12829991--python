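"""Partition distributions and exact moment dynamics of a diluting population.

A non-endogenous dye is split between the two daughters at every division:
one daughter inherits a fraction ``f`` of the mother's tagged amount, its
sibling the remaining ``1 - f``, with ``f`` drawn from a symmetric
partition distribution Pi(f) on [0, 1].  Because daughters are
exchangeable, Pi is symmetric about 1/2, the population mean halves every
generation regardless of Pi, and the population variance evolves
geometrically with ratio ``E[f^2] = sigma_f^2 + 1/4``:

    mu_g      = mu_0 / 2^g
    sigma_g^2 = mu_0^2 (E[f^2]^g - 4^-g) + sigma_0^2 E[f^2]^g

Fitting the variance law to per-generation moments therefore yields the
partitioning-noise magnitude sigma_f, reported as a "division asymmetry"
CV% = 100 * sigma_f / (1/2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, stats

__all__ = [
    "PartitionSpec",
    "MomentSeries",
    "PartitionNoiseEstimate",
    "second_moment",
    "mean_at_generation",
    "variance_at_generation",
    "cv_percent",
    "fit_partition_noise",
]

_FAMILIES = ("delta_half", "two_point", "gaussian", "double_gaussian", "binomial_limit")


@dataclass(frozen=True)
class PartitionSpec:
    """A symmetric partition distribution Pi(f) on [0, 1].

    Construct via the classmethods (``delta_half``, ``two_point``,
    ``gaussian``, ``double_gaussian``, ``binomial_limit``).  Continuous
    families are truncated to [0, 1] and renormalized; all families are
    symmetric under f -> 1 - f, so the mean is exactly 1/2 and the
    variance lies in [0, 1/4].
    """

    family: str
    params: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown partition family {self.family!r}; expected one of {_FAMILIES}"
            )
        p = self.params
        if self.family == "two_point":
            if not 0.0 <= p[0] <= 1.0:
                raise ValueError("two_point fraction must lie in [0, 1]")
        elif self.family == "gaussian":
            if not 0.0 <= p[0] <= 0.5:
                raise ValueError("gaussian sigma_f must lie in [0, 1/2]")
        elif self.family == "double_gaussian":
            if not 0.0 < p[0] <= 1.0:
                raise ValueError("double_gaussian peak must lie in (0, 1]")
            if p[1] < 0.0:
                raise ValueError("double_gaussian width must be non-negative")
        elif self.family == "binomial_limit":
            if not 0.0 < p[0] < 1.0:
                raise ValueError("binomial_limit bias must lie in (0, 1)")

    # -- constructors -------------------------------------------------
    @classmethod
    def delta_half(cls) -> "PartitionSpec":
        """Deterministic halving: Pi(f) = delta(f - 1/2)."""
        return cls("delta_half")

    @classmethod
    def two_point(cls, f: float) -> "PartitionSpec":
        """Pi(f') = (delta(f' - f) + delta(f' - (1-f))) / 2."""
        return cls("two_point", (float(f),))

    @classmethod
    def gaussian(cls, sigma_f: float) -> "PartitionSpec":
        """Normal(1/2, sigma_f) truncated to [0, 1] and renormalized.

        Truncation about the symmetric center preserves the mean; the
        *effective* post-truncation variance is what enters E[f^2].
        """
        return cls("gaussian", (float(sigma_f),))

    @classmethod
    def double_gaussian(cls, f_peak: float, sigma_prime: float) -> "PartitionSpec":
        """Symmetric bimodal mixture (N(f_peak, s') + N(1-f_peak, s'))/2 on [0, 1]."""
        return cls("double_gaussian", (float(f_peak), float(sigma_prime)))

    @classmethod
    def binomial_limit(cls, p: float) -> "PartitionSpec":
        """Large-N binomial partitioning: atoms at p and 1-p with equal mass."""
        return cls("binomial_limit", (float(p),))

    # -- internals ----------------------------------------------------
    def _truncnorm(self) -> stats.rv_continuous:
        sigma = self.params[0]
        a, b = (0.0 - 0.5) / sigma, (1.0 - 0.5) / sigma
        return stats.truncnorm(a, b, loc=0.5, scale=sigma)

    def _dg_norm(self) -> float:
        f0, s = self.params
        # mass of the untruncated symmetric mixture inside [0, 1]
        return 0.5 * (
            stats.norm.cdf(1.0, f0, s)
            - stats.norm.cdf(0.0, f0, s)
            + stats.norm.cdf(1.0, 1.0 - f0, s)
            - stats.norm.cdf(0.0, 1.0 - f0, s)
        )

    # -- distribution interface ---------------------------------------
    def atoms(self) -> tuple[np.ndarray, np.ndarray] | None:
        """(locations, weights) for discrete families, else None."""
        if self.family == "delta_half":
            return np.array([0.5]), np.array([1.0])
        if self.family in ("two_point", "binomial_limit"):
            f0 = self.params[0]
            if f0 == 0.5:
                return np.array([0.5]), np.array([1.0])
            return np.array([f0, 1.0 - f0]), np.array([0.5, 0.5])
        return None

    def pdf(self, x: np.ndarray) -> np.ndarray:
        """Density on [0, 1] for the continuous families."""
        x = np.asarray(x, dtype=float)
        if self.family == "gaussian":
            sigma = self.params[0]
            if sigma == 0.0:
                raise ValueError("degenerate gaussian has no density")
            return self._truncnorm().pdf(x)
        if self.family == "double_gaussian":
            f0, s = self.params
            if s == 0.0:
                raise ValueError("degenerate double_gaussian has no density")
            raw = 0.5 * (stats.norm.pdf(x, f0, s) + stats.norm.pdf(x, 1.0 - f0, s))
            out = np.where((x >= 0.0) & (x <= 1.0), raw / self._dg_norm(), 0.0)
            return out
        raise ValueError(f"{self.family} is discrete; use atoms()")

    @property
    def mean(self) -> float:
        return 0.5

    @property
    def variance(self) -> float:
        """sigma_f^2 of Pi, truncation included for continuous families."""
        at = self.atoms()
        if at is not None:
            locs, w = at
            return float(np.sum(w * (locs - 0.5) ** 2))
        if self.family == "gaussian":
            sigma = self.params[0]
            if sigma == 0.0:
                return 0.0
            return float(self._truncnorm().var())
        # double_gaussian: quadrature over the renormalized density
        f0, s = self.params
        if s == 0.0:
            return (f0 - 0.5) ** 2
        val, _ = integrate.quad(
            lambda x: (x - 0.5) ** 2 * self.pdf(x), 0.0, 1.0, limit=200
        )
        return float(val)

    @property
    def sigma_f(self) -> float:
        return float(np.sqrt(self.variance))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n partition fractions."""
        at = self.atoms()
        if at is not None:
            locs, w = at
            return rng.choice(locs, size=n, p=w)
        if self.family == "gaussian":
            sigma = self.params[0]
            if sigma == 0.0:
                return np.full(n, 0.5)
            a, b = -0.5 / sigma, 0.5 / sigma
            return stats.truncnorm.rvs(
                a, b, loc=0.5, scale=sigma, size=n, random_state=rng
            )
        f0, s = self.params
        if s == 0.0:
            return rng.choice([f0, 1.0 - f0], size=n)
        out = np.empty(n)
        todo = np.arange(n)
        while todo.size:  # redraw out-of-range values = truncated sampling
            centers = np.where(rng.random(todo.size) < 0.5, f0, 1.0 - f0)
            draw = rng.normal(centers, s)
            ok = (draw >= 0.0) & (draw <= 1.0)
            out[todo[ok]] = draw[ok]
            todo = todo[~ok]
        return out


def second_moment(spec: PartitionSpec) -> float:
    """E[f^2] = sigma_f^2 + 1/4; the geometric ratio of the variance law."""
    return spec.variance + 0.25


def mean_at_generation(mu0: float, g: int) -> float:
    """Population mean after g divisions: mu0 / 2^g, independent of Pi."""
    if mu0 <= 0:
        raise ValueError("mu0 must be positive")
    if g < 0 or int(g) != g:
        raise ValueError("generation must be a non-negative integer")
    return mu0 * 0.5 ** int(g)


def variance_at_generation(
    mu0: float, sigma0_sq: float, spec: PartitionSpec, g: int
) -> float:
    """Population variance after g divisions.

    sigma_g^2 = mu0^2 (E[f^2]^g - 4^-g) + sigma0^2 E[f^2]^g
    """
    if mu0 <= 0:
        raise ValueError("mu0 must be positive")
    if sigma0_sq < 0:
        raise ValueError("sigma0_sq must be non-negative")
    if g < 0 or int(g) != g:
        raise ValueError("generation must be a non-negative integer")
    g = int(g)
    ef2 = second_moment(spec)
    return mu0**2 * (ef2**g - 0.25**g) + sigma0_sq * ef2**g


def cv_percent(sigma_f: float) -> float:
    """Division asymmetry: CV of Pi as a percent, 100 * sigma_f / (1/2)."""
    if not 0.0 <= sigma_f <= 0.5:
        raise ValueError("sigma_f must lie in [0, 1/2]")
    return 200.0 * sigma_f


@dataclass
class MomentSeries:
    """Per-generation linear-space moments of the dye-intensity population.

    One entry per generation index ``g`` (strictly increasing integers):
    linear mean, linear variance, number of contributing events ``n`` and
    a fit weight (defaults to ``n``).
    """

    g: np.ndarray
    mean: np.ndarray
    variance: np.ndarray
    n: np.ndarray
    weight: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=int)
        self.mean = np.asarray(self.mean, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.weight is None:
            self.weight = self.n.astype(float)
        else:
            self.weight = np.asarray(self.weight, dtype=float)
        if not (np.diff(self.g) > 0).all():
            raise ValueError("generation indices must be strictly increasing")
        if (self.g < 0).any():
            raise ValueError("generation indices must be non-negative")
        if (self.variance < 0).any():
            raise ValueError("variances must be non-negative")
        if (self.n < 1).any():
            raise ValueError("event counts must be >= 1")

    def __len__(self) -> int:
        return len(self.g)


@dataclass
class PartitionNoiseEstimate:
    """Result of fitting the variance law to a moment series."""

    sigma_f: float
    E_f2: float
    cv_percent: float
    stderr_sigma_f: float
    mean_slope_log2: float
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_entries: int = 0


def _fit_ef2(g: np.ndarray, var_norm: np.ndarray, s0n: float, w: np.ndarray) -> float:
    """Weighted LS of var/mu0^2 = (E^g - 4^-g) + (sigma0/mu0)^2 E^g over E."""

    def sse(ef2: float) -> float:
        pred = (ef2**g - 0.25**g) + s0n * ef2**g
        return float(np.sum(w * (var_norm - pred) ** 2))

    res = optimize.minimize_scalar(
        sse, bounds=(0.25, 0.5), method="bounded", options={"xatol": 1e-12}
    )
    # bounded Brent cannot land exactly on a boundary; snap if it is as good
    cands = [float(res.x), 0.25, 0.5]
    return min(cands, key=sse)


def fit_partition_noise(
    series: MomentSeries,
    n_bootstrap: int = 1000,
    seed: int | None = 0,
) -> PartitionNoiseEstimate:
    """Estimate sigma_f from per-generation moments.

    The generation-0 entry anchors ``mu0`` and ``sigma0^2``; moments are
    normalized by them and the single parameter E[f^2] in [1/4, 1/2] is
    fitted to the variance law by weighted least squares.  The OLS slope
    of log2(mean) versus g is reported as a diagnostic (expected -1).
    The standard error comes from a nonparametric bootstrap over the
    non-anchor entries (the anchor is always retained, since it defines
    the normalization).
    """
    if len(series) < 3:
        raise ValueError("need moments from at least 3 generations")
    if series.g[0] != 0:
        raise ValueError("generation 0 must be present to anchor mu0, sigma0^2")

    mu0 = series.mean[0]
    sigma0_sq = series.variance[0]
    if mu0 <= 0:
        raise ValueError("generation-0 mean must be positive")

    g = series.g.astype(float)
    var_norm = series.variance / mu0**2
    s0n = sigma0_sq / mu0**2
    w = series.weight / series.weight.sum()

    if np.allclose(series.variance, 0.0):
        warnings.warn("all variances are zero; sigma_f = 0", stacklevel=2)
        ef2 = 0.25
    else:
        ef2 = _fit_ef2(g, var_norm, s0n, w)

    sigma_f = float(np.sqrt(max(ef2 - 0.25, 0.0)))
    pred = (ef2**g - 0.25**g) + s0n * ef2**g
    residuals = var_norm - pred

    ok = series.mean > 0
    slope = float(np.polyfit(g[ok], np.log2(series.mean[ok]), 1)[0])

    stderr = float("nan")
    if n_bootstrap > 0 and len(series) > 3:
        rng = np.random.default_rng(seed)
        rest = np.arange(1, len(series))
        boots = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            idx = np.sort(rng.choice(rest, size=rest.size, replace=True))
            gb = np.concatenate(([0.0], g[idx]))
            vb = np.concatenate(([var_norm[0]], var_norm[idx]))
            wb = np.concatenate(([w[0]], w[idx]))
            eb = _fit_ef2(gb, vb, s0n, wb / wb.sum())
            boots[b] = np.sqrt(max(eb - 0.25, 0.0))
        stderr = float(np.std(boots, ddof=1))

    return PartitionNoiseEstimate(
        sigma_f=sigma_f,
        E_f2=ef2,
        cv_percent=cv_percent(sigma_f),
        stderr_sigma_f=stderr,
        mean_slope_log2=slope,
        residuals=residuals,
        n_entries=len(series),
    )
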