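"""Generation deconvolution of dye-dilution cytometry histograms.

Each acquisition of a dye-dilution time course is a mixture of
generations: in log2-intensity space the generations appear as roughly
unit-spaced Gaussian peaks (each generation is lognormal in linear
intensity, and the dye halves per division).  A Gaussian mixture fitted
by EM decomposes each snapshot into per-generation weights, means and
SDs; converting back to linear moments and pooling across time points
yields a per-generation moment series from which the partitioning noise
sigma_f is estimated via the variance law.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .partition import MomentSeries, PartitionNoiseEstimate, fit_partition_noise

__all__ = [
    "CytometrySnapshot",
    "GenerationComponent",
    "DecompositionResult",
    "fit_generation_mixture",
    "assign_generation_indices",
    "lognormal_to_linear",
    "pool_generations",
    "estimate_from_timecourse",
]

_MIN_EVENTS = 200
_SIGMA_FLOOR = 1e-4  # log2 units; guards EM variance collapse


@dataclass
class CytometrySnapshot:
    """One acquisition: positive linear fluorescence values of one channel."""

    time_h: float
    channel: str
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)

    @property
    def n_events(self) -> int:
        return int(self.intensities.size)

    def positive(self) -> tuple[np.ndarray, int]:
        """(positive intensities, number of dropped non-positive events)."""
        ok = self.intensities > 0
        return self.intensities[ok], int((~ok).sum())


@dataclass
class GenerationComponent:
    """One generation's peak in log2-intensity space."""

    generation: int
    weight: float
    mu_log2: float
    sigma_log2: float


@dataclass
class DecompositionResult:
    snapshot: CytometrySnapshot
    components: list[GenerationComponent]
    log_likelihood: float
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    n_dropped: int = 0
    bic: float = float("nan")


def _em_1d(
    x: np.ndarray,
    mu0: np.ndarray,
    sigma0: np.ndarray,
    w0: np.ndarray,
    tied_sigma: bool,
    mean_mode: str,
    max_offset: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, bool]:
    """EM for a 1-D Gaussian mixture; returns (w, mu, sigma, loglik_trace, conv).

    ``mean_mode``: "free" updates each mean independently; "comb" keeps
    the means on the initialization grid shifted by a single shared
    offset (its M-step is the precision-weighted mean residual — a
    concave quadratic, so clipping to |offset| <= max_offset is the
    constrained maximizer and the likelihood stays monotone); "fixed"
    freezes the means.  The offset bound breaks the aliasing between a
    window of generations shifted by one and its neighbour window.
    """
    n = x.size
    mu, sigma, w = mu0.copy(), sigma0.copy(), w0.copy()
    comb = mu0.copy()
    trace = []
    converged = False
    for _ in range(max_iter):
        # E-step
        logp = (
            np.log(w)[None, :]
            - 0.5 * np.log(2.0 * np.pi)
            - np.log(sigma)[None, :]
            - 0.5 * ((x[:, None] - mu[None, :]) / sigma[None, :]) ** 2
        )
        lse = logsumexp(logp, axis=1)
        ll = float(lse.sum())
        trace.append(ll)
        r = np.exp(logp - lse[:, None])
        # M-step
        nk = r.sum(axis=0)
        w = nk / n
        if mean_mode == "free":
            mu = (r * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-300)
        elif mean_mode == "comb":
            prec = 1.0 / sigma**2
            num = float((r * (x[:, None] - comb[None, :]) * prec[None, :]).sum())
            den = float((nk * prec).sum())
            delta = float(np.clip(num / max(den, 1e-300), -max_offset, max_offset))
            mu = comb + delta
        sq = (r * (x[:, None] - mu[None, :]) ** 2).sum(axis=0)
        if tied_sigma:
            sigma = np.full_like(sigma, np.sqrt(max(sq.sum() / n, _SIGMA_FLOOR**2)))
        else:
            sigma = np.sqrt(np.maximum(sq / np.maximum(nk, 1e-300), _SIGMA_FLOOR**2))
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * abs(trace[-2]):
            converged = True
            break
    return w, mu, sigma, np.asarray(trace), converged


def _bic(ll: float, k_free: int, n: int) -> float:
    return -2.0 * ll + k_free * np.log(n)


def fit_generation_mixture(
    snapshot: CytometrySnapshot,
    anchor_mu0: float,
    max_generations: int = 12,
    spacing: float = 1.0,
    tied_sigma: bool = False,
    mean_mode: str = "comb",
    init_sigma: float = 0.3,
    strict_assignment: bool = False,
) -> DecompositionResult:
    """Decompose one snapshot into generation components by EM.

    Candidate component sets are windows of consecutive generations
    [g_min, g_max] bracketing the bulk of the log2 data relative to the
    anchor (the sorted t=0 peak position); means are initialized at
    ``anchor_mu0 - g * spacing``, the window is selected by BIC, and
    components are labeled by rounding their offset from the anchor.

    ``mean_mode="comb"`` (default) ties the peak means to the unit-log2
    dilution comb up to a shared fitted offset — the halving of the dye
    pins the spacing, only the anchor calibration can shift; "free"
    releases every mean; "fixed" freezes them at the initialization.
    """
    if mean_mode not in ("comb", "free", "fixed"):
        raise ValueError("mean_mode must be 'comb', 'free' or 'fixed'")
    if not np.isfinite(anchor_mu0):
        raise ValueError("anchor_mu0 must be finite")
    vals, n_dropped = snapshot.positive()
    if vals.size < _MIN_EVENTS:
        raise ValueError(
            f"snapshot has {vals.size} usable events; need >= {_MIN_EVENTS}"
        )
    x = np.log2(vals)

    g_hat = (anchor_mu0 - x) / spacing
    lo = int(np.clip(np.floor(np.quantile(g_hat, 0.005) + 0.5), 0, max_generations))
    hi = int(np.clip(np.ceil(np.quantile(g_hat, 0.995) - 0.5), lo, max_generations))

    # candidate windows bracket the occupied bulk [lo, hi] with one
    # generation of freedom on each edge; BIC arbitrates
    best: tuple[float, DecompositionResult] | None = None
    a_cands = sorted({max(lo - 1, 0), lo, min(lo + 1, hi)})
    b_cands_all = sorted({max(hi - 1, lo), hi, min(hi + 1, max_generations)})
    for a in a_cands:
        for b in (b for b in b_cands_all if b >= a):
            gens = np.arange(a, b + 1)
            mu0 = anchor_mu0 - gens * spacing
            sigma0 = np.full(gens.size, init_sigma)
            # occupancy-based initial weights from nearest-comb assignment
            counts = np.array(
                [np.sum(np.abs(g_hat - g) < 0.5) for g in gens], dtype=float
            )
            w0 = (counts + 1.0) / (counts + 1.0).sum()
            w, mu, sigma, trace, conv = _em_1d(
                x, mu0, sigma0, w0, tied_sigma, mean_mode, max_offset=0.5 * spacing
            )
            k = gens.size
            k_mean = {"free": k, "comb": 1, "fixed": 0}[mean_mode]
            k_free = (k - 1) + k_mean + (1 if tied_sigma else k)
            bic = _bic(trace[-1], k_free, x.size)
            comps = [
                GenerationComponent(int(g), float(wi), float(mi), float(si))
                for g, wi, mi, si in zip(gens, w, mu, sigma)
            ]
            if mean_mode == "free":
                # released means must be re-labeled (and may collide)
                try:
                    comps = assign_generation_indices(
                        comps, anchor_mu0, spacing, strict=strict_assignment
                    )
                except ValueError:
                    continue  # colliding / ambiguous labels: over-fitted window
            res = DecompositionResult(
                snapshot=snapshot,
                components=comps,
                log_likelihood=float(trace[-1]),
                loglik_trace=trace,
                converged=conv,
                n_iter=len(trace),
                n_dropped=n_dropped,
                bic=bic,
            )
            if best is None or bic < best[0]:
                best = (bic, res)
    if best is None:
        raise ValueError(
            "no candidate generation window produced a valid decomposition"
        )
    res = best[1]
    if not res.converged:
        warnings.warn("EM did not converge within the iteration budget", stacklevel=2)
    return res


def assign_generation_indices(
    components: list[GenerationComponent],
    anchor_mu0: float,
    spacing: float = 1.0,
    strict: bool = True,
    midpoint_tol: float = 0.05,
) -> list[GenerationComponent]:
    """Label components by g = round((anchor - mu)/spacing), clipped at 0.

    A component sitting within ``midpoint_tol`` of a rounding midpoint is
    ambiguous (error when strict, warning otherwise); two components
    mapping to the same generation signal an over-fitted mixture and
    raise.
    """
    out = []
    for c in components:
        g_float = (anchor_mu0 - c.mu_log2) / spacing
        frac = abs(g_float - np.floor(g_float) - 0.5)
        if frac < midpoint_tol:
            msg = (
                f"component at mu={c.mu_log2:.3f} sits {g_float:.2f} generations "
                "from the anchor: ambiguous assignment"
            )
            if strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)
        g = max(int(round(g_float)), 0)
        out.append(GenerationComponent(g, c.weight, c.mu_log2, c.sigma_log2))
    gens = [c.generation for c in out]
    if len(set(gens)) != len(gens):
        raise ValueError(
            f"generation collision in assignment ({sorted(gens)}): over-fitted mixture"
        )
    return sorted(out, key=lambda c: c.generation)


def lognormal_to_linear(mu_log2: float, sigma_log2: float) -> tuple[float, float]:
    """Linear mean and variance of a lognormal given log2-space parameters."""
    if sigma_log2 < 0:
        raise ValueError("sigma_log2 must be non-negative")
    s = sigma_log2 * np.log(2.0)
    mean = 2.0**mu_log2 * np.exp(s**2 / 2.0)
    var = mean**2 * (np.exp(s**2) - 1.0)
    return float(mean), float(var)


def pool_generations(
    decompositions: list[DecompositionResult],
    min_effective_events: float = 100.0,
    min_component_weight: float = 0.005,
) -> MomentSeries:
    """Pool per-generation linear moments across time points.

    Components of the same generation from different acquisitions are
    combined as the pi_g * n_events weighted average of their means and
    of their variances.  (Averaging variances, rather than taking the
    moments of the concatenated mixture, keeps any drift of a
    generation's mean across acquisition times — e.g. the selection
    drift that division-time/partition coupling induces — out of the
    variance, which must reflect within-population spread only.)
    Components with
    mixture weight below ``min_component_weight`` are outlier absorbers
    with unidentifiable moments (the log-to-linear conversion amplifies
    their inflated SDs explosively) and are skipped; generations
    supported by fewer than ``min_effective_events`` events summed over
    the whole course are excluded for the same reason.
    """
    if not decompositions:
        raise ValueError("no decompositions to pool")
    acc: dict[int, list[tuple[float, float, float]]] = {}
    for dec in decompositions:
        n = dec.snapshot.n_events - dec.n_dropped
        for c in dec.components:
            if c.weight < min_component_weight:
                continue
            mean, var = lognormal_to_linear(c.mu_log2, c.sigma_log2)
            acc.setdefault(c.generation, []).append((c.weight * n, mean, var))
    gs = [g for g in sorted(acc) if sum(e[0] for e in acc[g]) >= min_effective_events]
    if not gs:
        gs = sorted(acc)  # tiny course: keep everything rather than fail
    means, variances, ns = [], [], []
    for g in gs:
        w = np.array([e[0] for e in acc[g]])
        mu = np.array([e[1] for e in acc[g]])
        var = np.array([e[2] for e in acc[g]])
        W = w.sum()
        m = float((w * mu).sum() / W)
        v = float((w * var).sum() / W)
        means.append(m)
        variances.append(max(v, 0.0))
        ns.append(max(W, 1.0))
    return MomentSeries(
        g=np.array(gs), mean=np.array(means), variance=np.array(variances), n=np.array(ns)
    )


def anchor_from_snapshot(snapshot: CytometrySnapshot) -> float:
    """Anchor log2 position of the sorted founder peak (median of log2 I)."""
    vals, _ = snapshot.positive()
    if vals.size == 0:
        raise ValueError("snapshot has no positive intensities")
    return float(np.median(np.log2(vals)))


def estimate_from_timecourse(
    snapshots: list[CytometrySnapshot],
    spacing: float = 1.0,
    max_generations: int = 12,
    tied_sigma: bool = False,
    mean_mode: str = "comb",
    n_bootstrap: int = 1000,
    seed: int | None = 0,
) -> tuple[PartitionNoiseEstimate, list[DecompositionResult], MomentSeries]:
    """Full pipeline: deconvolve each snapshot, pool, fit the variance law.

    The earliest snapshot must be the post-sort t=0 acquisition; it fixes
    the anchor and supplies the generation-0 moments.
    """
    if not snapshots:
        raise ValueError("no snapshots provided")
    snaps = sorted(snapshots, key=lambda s: s.time_h)
    anchor = anchor_from_snapshot(snaps[0])
    decs = [
        fit_generation_mixture(
            s,
            anchor_mu0=anchor,
            max_generations=max_generations,
            spacing=spacing,
            tied_sigma=tied_sigma,
            mean_mode=mean_mode,
        )
        for s in snaps
    ]
    series = pool_generations(decs)
    est = fit_partition_noise(series, n_bootstrap=n_bootstrap, seed=seed)
    return est, decs, series
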